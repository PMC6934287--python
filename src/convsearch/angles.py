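"""Angles between multivariate phenotype vectors.

The angle between two species' phenotypic vectors,
``theta = arccos(A.B / (|A||B|))`` in degrees, measures the similarity in
*direction* of the two phenotypes: its cosine is the vector correlation, so
0 means identical direction, 90 unrelated, 180 opposed.  For geometric
morphometric data (PC scores) the origin is the consensus shape and theta
describes how two species deviate from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateVectorError",
    "AngleSummary",
    "vector_angle",
    "angle_matrix",
    "mean_cross_angle",
    "mean_within_angle",
]

# slack absorbed by the arccos clamp; anything worse than this is a bug
_CLAMP_TOL = 1e-12


class DegenerateVectorError(ValueError):
    """A zero-norm phenotype vector has no direction, hence no angle.

    For shape data the zero vector is the consensus shape; hitting it
    exactly is pathological rather than meaningful."""


@dataclass(frozen=True)
class AngleSummary:
    """Mean angle over a collection of vector pairs (degrees)."""

    mean: float
    angles: np.ndarray = field(repr=False)
    n_pairs: int
    normalizing_distance: float | None = None


def _as_matrix(phen, rows=None):
    if isinstance(phen, pd.DataFrame):
        if rows is not None:
            missing = [r for r in rows if r not in phen.index]
            if missing:
                raise KeyError(f"tips missing from phenotype table: {missing}")
            return phen.loc[list(rows)].to_numpy(dtype=float)
        return phen.to_numpy(dtype=float)
    arr = np.asarray(phen, dtype=float)
    if rows is not None:
        arr = arr[np.asarray(list(rows))]
    return arr


def vector_angle(a, b):
    """Angle between two phenotype vectors, in degrees, clamped to [0, 180]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 1:
        raise ValueError("vectors must share a length p >= 1")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateVectorError("zero-norm phenotype vector")
    c = float(a @ b) / (na * nb)
    c = min(1.0, max(-1.0, c))
    return float(np.degrees(np.arccos(c)))


def angle_matrix(x, y=None):
    """Pairwise angles (degrees) between rows of ``x`` and rows of ``y``.

    With ``y=None`` the matrix is the symmetric self-angle matrix of ``x``
    (zero diagonal up to floating point).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    nx = np.linalg.norm(x, axis=1)
    if (nx == 0).any():
        raise DegenerateVectorError("zero-norm phenotype vector")
    xu = x / nx[:, None]
    if y is None:
        yu = xu
    else:
        y = np.atleast_2d(np.asarray(y, dtype=float))
        ny = np.linalg.norm(y, axis=1)
        if (ny == 0).any():
            raise DegenerateVectorError("zero-norm phenotype vector")
        yu = y / ny[:, None]
    cos = np.clip(xu @ yu.T, -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def mean_cross_angle(phen, set_a, set_b):
    """Mean angle over all cross pairs, one member per set.

    ``set_a`` and ``set_b`` must be disjoint, non-empty collections of row
    keys (tip labels for a DataFrame, row indices otherwise).
    """
    set_a = list(set_a)
    set_b = list(set_b)
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    if set(set_a) & set(set_b):
        raise ValueError("sets must be disjoint")
    xa = _as_matrix(phen, set_a)
    xb = _as_matrix(phen, set_b)
    ang = angle_matrix(xa, xb).ravel()
    return AngleSummary(mean=float(ang.mean()), angles=ang,
                        n_pairs=int(ang.size))


def mean_within_angle(phen, tips):
    """Mean angle over all unordered pairs within a single set of tips."""
    tips = list(tips)
    if len(tips) < 2:
        raise ValueError("need at least 2 tips for within-set angles")
    x = _as_matrix(phen, tips)
    full = angle_matrix(x)
    iu = np.triu_indices(len(tips), k=1)
    ang = full[iu]
    return AngleSummary(mean=float(ang.mean()), angles=ang,
                        n_pairs=int(ang.size))


def pair_indices_within(n):
    """Unordered index pairs (i, j), i < j — the within-set enumeration."""
    return list(combinations(range(n), 2))
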