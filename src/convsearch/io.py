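"""File readers and writers: phenotype / state tables and result reports.

Phenotype tables are tab-delimited text with a header row; the first
column, named ``tip``, holds the tip label and the remaining columns the
trait variables.  State tables are two columns (tip, state).  Constraint
tables mirror the phenotype layout but are keyed by internal-node label or
integer node id.  Reports are written as TSV (one row per tested pair or
state) and as JSON, optionally embedding the null distribution.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = [
    "read_phenotype", "write_phenotype", "read_states", "write_states",
    "read_constraints", "write_clade_report", "write_state_report",
]


def read_phenotype(path, sep="\t"):
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a tip column plus >= 1 variable")
    first = df.columns[0]
    df = df.set_index(first)
    df.index = df.index.astype(str)
    df.index.name = "tip"
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate tip rows {dups}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric phenotype value: {exc}") \
            from exc
    return df


def write_phenotype(phen, path, sep="\t"):
    out = phen.copy()
    out.index.name = "tip"
    out.to_csv(path, sep=sep)


def read_states(path, sep="\t"):
    df = pd.read_csv(path, sep=sep, header=None, comment="#",
                     names=["tip", "state"], dtype=str, skipinitialspace=True)
    # tolerate a header row
    if df.iloc[0].tolist() == ["tip", "state"]:
        df = df.iloc[1:]
    return dict(zip(df["tip"], df["state"]))


def write_states(states, path, sep="\t"):
    with open(path, "w") as fh:
        fh.write(f"tip{sep}state\n")
        for tip, state in states.items():
            fh.write(f"{tip}{sep}{state}\n")


def read_constraints(path, tree, sep="\t"):
    """Constraint table -> {internal node id: phenotype vector}.

    The first column may hold either an internal-node label known to the
    tree or a bare integer node id.
    """
    df = read_phenotype(path, sep=sep)
    label_map = {v: k for k, v in tree.internal_labels.items()}
    out = {}
    for key, row in df.iterrows():
        if key in label_map:
            node = label_map[key]
        else:
            try:
                node = int(key)
            except ValueError:
                raise ValueError(
                    f"constraint key {key!r} is neither an internal-node "
                    "label nor a node id") from None
        out[node] = row.to_numpy(dtype=float)
    return out


def _fmt_p(p, n):
    return f"<{1 / n:g}" if p == 0 else f"{p:g}"


def write_clade_report(search, tsv_path=None, json_path=None,
                       embed_null=False, seed=None):
    """Write a clade-search result as TSV and/or JSON."""
    df = search.to_frame()
    n = search.null.n
    if tsv_path:
        out = df.copy()
        out["p_theta_real"] = [_fmt_p(p, n) for p in out["p_theta_real"]]
        out["p_theta_real_plus_ace"] = [
            _fmt_p(p, n) for p in out["p_theta_real_plus_ace"]]
        out.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if json_path:
        null = search.null
        payload = {
            "alpha": search.alpha,
            "n_null": n,
            "seed": seed,
            "null_summary": {
                "min": float(np.min(null.theta_time)),
                "q05": float(np.quantile(null.theta_time, 0.05)),
                "median": float(np.median(null.theta_time)),
            },
            "results": json.loads(
                df.to_json(orient="records", double_precision=10)),
        }
        if embed_null:
            payload["null_theta_time"] = null.theta_time.tolist()
            if null.theta_sum_time is not None:
                payload["null_theta_sum_time"] = \
                    null.theta_sum_time.tolist()
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return df


def write_state_report(result, tsv_path=None, json_path=None, seed=None):
    row = {
        "states": "+".join(result.states),
        "mean_angle": result.mean_angle,
        "mean_angle_by_time": result.mean_angle_time,
        "p_mean_angle": _fmt_p(result.p_angle, result.n_shuffles),
        "p_mean_angle_by_time": _fmt_p(result.p_angle_time,
                                       result.n_shuffles),
        "n_shuffles": result.n_shuffles,
    }
    if tsv_path:
        pd.DataFrame([row]).to_csv(tsv_path, sep="\t", index=False,
                                   float_format="%.6g")
    if json_path:
        payload = dict(row, seed=seed,
                       p_mean_angle_raw=result.p_angle,
                       p_mean_angle_by_time_raw=result.p_angle_time)
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return row
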