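"""Simulation framework: trees, trait models, planted convergence, and
error-rate experiments.

Everything here is a pure function of its inputs and the supplied random
generator, so whole experiments replay exactly from a master seed.  The
generators implement the validation designs used to measure the
convergence test's type I and type II error:

* birth-death trees with extinct lineages kept as fossil tips, so the
  trees are non-ultrametric like paleontological phylogenies;
* Brownian-motion traits, tree rescalings for the kappa / delta / lambda /
  trend models, and a drift model (BM plus a linear trend in the mean);
* planted convergence between clades — a clade is duplicated, perturbed,
  rescaled, and grafted elsewhere in the tree, and both copies receive
  phenotypes drawn around f times the per-variable maxima of the original
  data with the original standard deviations;
* planted convergence among 'states' — random tip subsets given such
  phenotypes in place;
* a 26-tip three-lineage design in which convergence, when present, is an
  Ornstein-Uhlenbeck pull of the selected terminal branches toward a
  shared optimum at 1.25 times the per-trait maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .clades import search_conv_clades, test_clade_pair, NodePair
from .rrfit import fit_rrphylo
from .states import BACKGROUND_STATE, search_conv_states
from .tree import PhyloTree, _MNode, graft_subtree, swap_one

__all__ = [
    "SimulationError",
    "CladePlantSpec",
    "StaytonConfig",
    "SimulationTruth",
    "simulate_bd_tree",
    "simulate_bm",
    "simulate_drift",
    "rescale_tree",
    "plant_convergent_clades",
    "plant_convergent_states",
    "random_state_map",
    "stayton_replicate",
    "error_rate_suite",
]


class SimulationError(RuntimeError):
    """A simulation design constraint could not be satisfied."""


def _rng(rng):
    return rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)


# ---------------------------------------------------------------------- #
# trees
# ---------------------------------------------------------------------- #
def simulate_bd_tree(birth, death, min_tips, rng=None, max_retries=100):
    """Forward-time birth-death tree grown until ``min_tips`` lineages are
    simultaneously alive; extinct lineages are retained as fossil tips, so
    with death > 0 the tree is non-ultrametric."""
    if not birth > death >= 0:
        raise ValueError("need birth > death >= 0")
    if min_tips < 2:
        raise ValueError("min_tips must be >= 2")
    rng = _rng(rng)
    total = birth + death
    p_birth = birth / total
    for _ in range(max_retries):
        root = _MNode()
        c1, c2 = _MNode(), _MNode()
        root.children = [c1, c2]
        birth_time = {id(c1): 0.0, id(c2): 0.0}
        alive = [c1, c2]
        t = 0.0
        failed = False
        while len(alive) < min_tips:
            t += rng.exponential(1.0 / (len(alive) * total))
            i = int(rng.integers(len(alive)))
            nd = alive.pop(i)
            if rng.random() < p_birth:
                k1, k2 = _MNode(), _MNode()
                nd.children = [k1, k2]
                nd.length = t - birth_time.pop(id(nd))
                birth_time[id(k1)] = t
                birth_time[id(k2)] = t
                alive.extend([k1, k2])
            else:
                nd.length = t - birth_time.pop(id(nd))
                if not alive:
                    failed = True
                    break
        if failed:
            continue
        # extend surviving lineages by one more waiting time so terminal
        # branches never end exactly at the last event
        t_end = t + rng.exponential(1.0 / (len(alive) * total))
        for nd in alive:
            nd.length = t_end - birth_time[id(nd)]
        counter = [0]
        stack = [root]
        while stack:
            nd = stack.pop()
            if not nd.children:
                counter[0] += 1
                nd.label = f"t{counter[0]}"
            stack.extend(reversed(nd.children))
        tree, _ = PhyloTree.from_mutable(root)
        return tree
    raise SimulationError(
        f"total extinction in {max_retries} consecutive attempts; "
        "check the birth/death rates")


def rescale_tree(tree, model, param):
    """Standard branch-length transformations for trait-model simulation.

    kappa  — each branch length raised to the power kappa (kappa=0 makes
             every branch length 1, the speciational model);
    delta  — node depths d mapped to d**delta, then rescaled so the tree
             height is unchanged;
    lambda — internal-node depths shrunk by the factor lambda with tip
             depths preserved (the covariance transform);
    trend  — a branch spanning depths t0..t1 becomes
             l * (1 + param * (t0 + t1) / 2), floored at a small epsilon.

    The neutral parameters (kappa=1, delta=1, lambda=1, trend=0) leave the
    tree unchanged.
    """
    ranges = {"kappa": (0.0, 1.0), "delta": (0.1, 3.0),
              "lambda": (0.1, 1.0), "trend": (-0.01, 0.01)}
    if model not in ranges:
        raise ValueError(f"unknown rescaling model {model!r}")
    lo, hi = ranges[model]
    if not lo <= param <= hi:
        warnings.warn(f"{model} parameter {param} outside the usual range "
                      f"[{lo}, {hi}]", stacklevel=2)
    depth = tree.time_depth
    length = tree.length.copy()
    h = tree.height
    if model == "kappa":
        mask = np.arange(tree.nnodes) != tree.root
        length[mask] = length[mask] ** param
    elif model == "delta":
        new_depth = depth ** param * h ** (1.0 - param)
        for nd in range(tree.nnodes):
            p = tree.parent[nd]
            if p >= 0:
                length[nd] = new_depth[nd] - new_depth[p]
    elif model == "lambda":
        new_depth = depth.copy()
        new_depth[tree.ntips:] *= param
        new_depth[: tree.ntips] = depth[: tree.ntips]
        for nd in range(tree.nnodes):
            p = tree.parent[nd]
            if p >= 0:
                length[nd] = new_depth[nd] - new_depth[p]
    elif model == "trend":
        eps = 1e-8 * max(h, 1.0)
        for nd in range(tree.nnodes):
            p = tree.parent[nd]
            if p >= 0:
                mid = (depth[p] + depth[nd]) / 2.0
                length[nd] = max(length[nd] * (1.0 + param * mid), eps)
    return PhyloTree(tree.parent.copy(), length, list(tree.tip_labels),
                     dict(tree.internal_labels))


# ---------------------------------------------------------------------- #
# traits
# ---------------------------------------------------------------------- #
def simulate_bm(tree, p, sigma2=1.0, rng=None, return_node_states=False,
                variances=None):
    """Brownian-motion traits: the root sits at the origin and every branch
    adds an independent Gaussian increment with variance sigma2 * length.

    ``variances`` optionally gives a per-variable rate vector overriding
    the scalar ``sigma2``.
    """
    rng = _rng(rng)
    if variances is None:
        variances = np.full(p, float(sigma2))
    else:
        variances = np.asarray(variances, dtype=float)
        if variances.shape != (p,):
            raise ValueError("variances must have length p")
    if (variances <= 0).any():
        raise ValueError("trait variances must be > 0")
    scale = np.sqrt(tree.length[:, None] * variances[None, :])
    inc = rng.normal(0.0, 1.0, size=(tree.nnodes, p)) * scale
    states = np.zeros((tree.nnodes, p))
    for nd in tree.preorder[1:]:
        states[nd] = states[tree.parent[nd]] + inc[nd]
    phen = pd.DataFrame(states[: tree.ntips], index=tree.tip_labels,
                        columns=[f"v{i + 1}" for i in range(p)])
    if return_node_states:
        return phen, states
    return phen


def simulate_drift(tree, p, sigma2=1.0, ds=0.0, rng=None):
    """BM plus a deterministic trend ``ds`` in the mean per unit time: each
    branch adds ds * length to every variable.  ds=0 reproduces
    ``simulate_bm`` draw for draw at the same seed."""
    phen = simulate_bm(tree, p, sigma2, rng)
    if ds != 0.0:
        phen = phen.add(ds * tree.time_depth[: tree.ntips], axis=0)
    return phen


# ---------------------------------------------------------------------- #
# planted convergence
# ---------------------------------------------------------------------- #
@dataclass
class CladePlantSpec:
    """Parameters of the duplicate-and-graft convergence recipe."""

    f: float | None = None              # None: drawn Uniform(0.5, 2)
    size_bounds: tuple = (1 / 10, 1 / 4)   # source clade size, tip fraction
    max_height_frac: float = 0.8        # source mrca depth / tree height
    min_graft_distance: int | str = "auto"   # "auto" = ntips / 10 edges
    exact_graft_distance: int | None = None  # e.g. 3 for the close-pair case
    n_drop: int = 2                     # tips dropped from the duplicate
    swap_tip_fraction: float = 0.5
    swap_branch_fraction: float = 0.5
    jitter: float = 0.02                # relative spread of planted clusters

    def __post_init__(self):
        if self.f is not None and self.f <= 0:
            raise ValueError("f must be > 0")
        lo, hi = self.size_bounds
        if not (0 < lo < hi < 1):
            raise ValueError("size_bounds must be increasing fractions")
        if self.n_drop < 0:
            raise ValueError("n_drop must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth for scoring a planted-convergence replicate."""

    mrca_a: int | None
    mrca_b: int | None
    tips_a: list
    tips_b: list
    f: float | None
    convergent: bool
    log: dict = field(default_factory=dict)


def _planted_phenotypes(k, m_prime, rng, rel_amplitude=0.02):
    """Phenotypes jittered around the target vector m'.

    Each variable takes its target value plus uniform noise of amplitude
    ``rel_amplitude * |target|``, i.e. the planted species form a tight
    cluster whose spread scales with the cluster center — so the angular
    dispersion of the planted clade is essentially independent of f.
    """
    amp = rel_amplitude * np.abs(m_prime)
    return m_prime[None, :] + rng.uniform(-1.0, 1.0,
                                          size=(k, m_prime.size)) * amp


def plant_convergent_clades(tree, phen, spec=None, rng=None,
                            convergent=True):
    """Duplicate a clade, perturb it, graft it far away, and give both
    copies matching phenotypes.

    Steps: choose a source clade s sized within ``spec.size_bounds`` (as
    fractions of the tips) whose mrca lies no deeper than
    ``max_height_frac`` of the tree height; copy it, drop ``n_drop`` tips
    at random, shuffle half its tips and half its branch lengths; graft it
    at an internal node at least ``min_graft_distance`` edges from s (or
    exactly ``exact_graft_distance``); then redraw the phenotypes of both
    copies as tight jittered clusters around f times the per-variable
    maxima of the original data.  With ``convergent=False`` the
    same structural edits are applied but a fresh BM phenotype is
    simulated on the final tree, so nothing converges — the matched type-I
    condition.

    Returns ``(tree, phenotype, truth)``.
    """
    spec = spec or CladePlantSpec()
    rng = _rng(rng)
    n = tree.ntips
    lo = max(int(np.floor(spec.size_bounds[0] * n)), spec.n_drop + 3)
    hi = int(np.ceil(spec.size_bounds[1] * n))
    depth = tree.time_depth
    h = tree.height
    sizes = {nd: len(tree.clade_tips(nd))
             for nd in range(tree.ntips, tree.nnodes) if nd != tree.root}
    sources = [nd for nd, sz in sizes.items()
               if lo <= sz <= hi and depth[nd] <= spec.max_height_frac * h]
    if not sources:
        raise SimulationError(
            f"no source clade with {lo}-{hi} tips and mrca depth <= "
            f"{spec.max_height_frac:.0%} of tree height")
    sources.sort()
    source = int(sources[rng.integers(len(sources))])

    min_dist = ceil(n / 10) if spec.min_graft_distance == "auto" \
        else int(spec.min_graft_distance)
    anc = tree.ancestor_matrix
    targets = []
    for nd in range(tree.ntips, tree.nnodes):
        if nd == tree.root or nd == source:
            continue
        if anc[source, nd] or anc[nd, source]:
            continue
        d = tree.node_distance(source, nd)
        if spec.exact_graft_distance is not None:
            if d == spec.exact_graft_distance:
                targets.append(nd)
        elif d >= min_dist:
            targets.append(nd)
    if not targets:
        constraint = (f"node distance == {spec.exact_graft_distance}"
                      if spec.exact_graft_distance is not None
                      else f"node distance >= {min_dist}")
        raise SimulationError(f"no graft target satisfying {constraint}")
    target = int(targets[rng.integers(len(targets))])

    sub, _ = tree.extract_clade(source)
    if spec.n_drop:
        drop = [sub.tip_labels[i] for i in
                rng.choice(sub.ntips, size=spec.n_drop, replace=False)]
        sub, _ = sub.drop_tips(drop)
    sub = swap_one(sub, spec.swap_tip_fraction, spec.swap_branch_fraction,
                   rng)
    dup_labels = [f"{lbl}_dup" for lbl in sub.tip_labels]
    sub = PhyloTree(sub.parent.copy(), sub.length.copy(), dup_labels,
                    dict(sub.internal_labels))
    new_tree = graft_subtree(tree, sub, target)

    tips_a = [tree.tip_labels[i] for i in tree.clade_tips(source)]
    tips_b = dup_labels
    mrca_a = new_tree.mrca(tips_a)
    mrca_b = new_tree.mrca(tips_b)

    base = phen.to_numpy(dtype=float) if isinstance(phen, pd.DataFrame) \
        else np.asarray(phen, dtype=float)
    columns = list(phen.columns) if isinstance(phen, pd.DataFrame) \
        else [f"v{i + 1}" for i in range(base.shape[1])]
    f = spec.f
    if convergent:
        if f is None:
            f = float(rng.uniform(0.5, 2.0))
        m = base.max(axis=0)
        new_phen = pd.DataFrame(
            np.zeros((new_tree.ntips, base.shape[1])),
            index=new_tree.tip_labels, columns=columns)
        orig = pd.DataFrame(base, index=list(phen.index)
                            if isinstance(phen, pd.DataFrame)
                            else tree.tip_labels, columns=columns)
        for lbl in new_tree.tip_labels:
            if lbl in orig.index:
                new_phen.loc[lbl] = orig.loc[lbl]
        new_phen.loc[tips_a] = _planted_phenotypes(
            len(tips_a), f * m, rng, spec.jitter)
        new_phen.loc[tips_b] = _planted_phenotypes(
            len(tips_b), f * m, rng, spec.jitter)
    else:
        f = None
        new_phen = simulate_bm(new_tree, base.shape[1], 1.0, rng)
        new_phen.columns = columns
    truth = SimulationTruth(
        mrca_a=mrca_a, mrca_b=mrca_b, tips_a=tips_a, tips_b=tips_b, f=f,
        convergent=convergent,
        log={"source": source, "target": target,
             "source_size": sizes[source],
             "graft_distance": tree.node_distance(source, target)})
    return new_tree, new_phen, truth


def random_state_map(tree, n_states=1, rng=None, max_frac=0.1, min_size=3):
    """Assign random disjoint tip subsets to states, sizes drawn between
    ``min_size`` and ceil(max_frac * ntips) tips."""
    rng = _rng(rng)
    n = tree.ntips
    k_max = ceil(max_frac * n)
    if k_max < min_size:
        raise SimulationError(f"tree too small for states of >= {min_size} "
                              "tips at a tenth of the tree")
    pool = list(rng.permutation(n))
    states = {}
    for s in range(n_states):
        k = int(rng.integers(min_size, k_max + 1))
        chosen = [pool.pop() for _ in range(k)]
        for i in chosen:
            states[tree.tip_labels[i]] = f"state{s + 1}"
    return states


def plant_convergent_states(tree, phen, n_states=1, f=None, rng=None,
                            jitter=0.02):
    """Give randomly sampled tip subsets convergent phenotypes in place.

    Each state holds at most a tenth of the tips.  State members' values
    are redrawn as tight jittered clusters around f times the per-variable
    maxima; with two states, the second state's cluster gets twice the
    spread.  Background tips are untouched.
    """
    if tree.ntips < 20:
        raise SimulationError("state planting needs >= 20 tips")
    if n_states not in (1, 2):
        raise ValueError("n_states must be 1 or 2")
    rng = _rng(rng)
    states = random_state_map(tree, n_states, rng)
    if f is None:
        f = float(rng.uniform(0.5, 2.0))
    base = phen.loc[tree.tip_labels].to_numpy(dtype=float)
    m = base.max(axis=0)
    new_phen = phen.copy()
    for s in range(n_states):
        members = [t for t, lab in states.items() if lab == f"state{s + 1}"]
        mult = 2.0 if s == 1 else 1.0
        new_phen.loc[members] = _planted_phenotypes(
            len(members), f * m, rng, mult * jitter)
    truth = SimulationTruth(
        mrca_a=None, mrca_b=None,
        tips_a=[t for t, lab in states.items() if lab == "state1"],
        tips_b=[t for t, lab in states.items() if lab == "state2"],
        f=f, convergent=True, log={"n_states": n_states})
    return new_phen, states, truth


# ---------------------------------------------------------------------- #
# 26-tip three-lineage experiments
# ---------------------------------------------------------------------- #
@dataclass
class StaytonConfig:
    """Settings of the fixed-size three-lineage simulation design."""

    ntips: int = 26
    birth: float = 0.5
    death: float = 0.0
    n_traits: int = 10
    traits_min: int = 2
    traits_max: int = 10
    alpha_range: tuple = (1.0, 50.0)
    theta_factor: float = 1.25
    n_lineages: int = 3
    min_node_distance: int = 3

    def __post_init__(self):
        if self.ntips < 4:
            raise ValueError("ntips must be >= 4")
        if self.alpha_range[0] <= 0:
            raise ValueError("alpha range must be positive")


def broken_stick_variances(n):
    """Expected ordered proportions of a randomly broken unit stick:
    v_i = (1/n) * sum_{j=i..n} 1/j; descending, summing to 1."""
    j = np.arange(1, n + 1)
    inv = 1.0 / j
    return np.array([inv[i:].sum() / n for i in range(n)])


def _pick_distant_tips(tree, k, min_dist, rng, max_tries=2000):
    for _ in range(max_tries):
        tips = rng.choice(tree.ntips, size=k, replace=False)
        ok = all(tree.node_distance(int(a), int(b)) >= min_dist
                 for i, a in enumerate(tips) for b in tips[i + 1:])
        if ok:
            return np.sort(tips)
    raise SimulationError(
        f"could not find {k} tips pairwise >= {min_dist} nodes apart")


def stayton_replicate(config=None, convergent=False, rng=None,
                      alpha=None):
    """One replicate of the 26-tip design.

    A pure-birth tree; ten BM traits whose variances follow the
    broken-stick distribution; a random subset of 2-10 traits retained;
    three tips pairwise at least three nodes apart selected.  Under the
    convergent condition each selected lineage evolves toward a common
    optimum theta = 1.25 x the per-trait maxima by an OU process with
    strength alpha ~ Uniform(1, 50), acting over the lineage's history
    since the three lineages last shared an ancestor:

        tip = s_a * exp(-a t) + theta * (1 - exp(-a t)) + OU noise,

    with s_a the lineage's state at the selected tips' common ancestor,
    t the time from that ancestor to the tip, and the noise at the OU
    stationary-variance scaling sigma2 (1 - exp(-2 a t)) / (2 a).

    Returns ``(tree, phenotype, selected tip labels, truth)``.
    """
    config = config or StaytonConfig()
    rng = _rng(rng)
    tree = simulate_bd_tree(config.birth, config.death, config.ntips, rng)
    variances = broken_stick_variances(config.n_traits)
    phen, node_states = simulate_bm(tree, config.n_traits, rng=rng,
                                    return_node_states=True,
                                    variances=variances)
    k = int(rng.integers(config.traits_min, config.traits_max + 1))
    chosen = np.sort(rng.choice(config.n_traits, size=k, replace=False))
    tips = _pick_distant_tips(tree, config.n_lineages,
                              config.min_node_distance, rng)
    if convergent:
        if alpha is None:
            alpha = float(rng.uniform(*config.alpha_range))
        theta = config.theta_factor * phen.to_numpy().max(axis=0)
        vals = phen.to_numpy(dtype=float)
        anchor = tree.mrca([int(t) for t in tips])
        for t in tips:
            dt = float(tree.time_depth[t] - tree.time_depth[anchor])
            s_a = node_states[anchor]
            decay = np.exp(-alpha * dt)
            sd = np.sqrt(variances * (1.0 - np.exp(-2.0 * alpha * dt))
                         / (2.0 * alpha))
            vals[t] = (s_a * decay + theta * (1.0 - decay)
                       + rng.normal(0.0, 1.0, size=config.n_traits) * sd)
        phen = pd.DataFrame(vals, index=tree.tip_labels,
                            columns=phen.columns)
    phen_sel = phen.iloc[:, chosen]
    tip_labels = [tree.tip_labels[int(t)] for t in tips]
    log = {"alpha": alpha, "traits": chosen.tolist()}
    if convergent:
        log["theta"] = theta[chosen].tolist()
    truth = SimulationTruth(
        mrca_a=None, mrca_b=None, tips_a=tip_labels, tips_b=[],
        f=None, convergent=convergent, log=log)
    return tree, phen_sel, tip_labels, truth


# ---------------------------------------------------------------------- #
# error-rate experiments
# ---------------------------------------------------------------------- #
def _binom_ci(successes, n, level=0.95):
    if n == 0:
        return (np.nan, np.nan)
    a = (1.0 - level) / 2.0
    lo = beta_dist.ppf(a, successes, n - successes + 1) if successes else 0.0
    hi = beta_dist.ppf(1 - a, successes + 1, n - successes) \
        if successes < n else 1.0
    return float(lo), float(hi)


def _pair_hit(tree, result, truth, slop=2):
    da1 = tree.node_distance(result.node_a, truth.mrca_a)
    db1 = tree.node_distance(result.node_b, truth.mrca_b)
    da2 = tree.node_distance(result.node_a, truth.mrca_b)
    db2 = tree.node_distance(result.node_b, truth.mrca_a)
    return (da1 <= slop and db1 <= slop) or (da2 <= slop and db2 <= slop)


def _clade_replicate(rng, convergent=True, exact_graft_distance=None,
                     min_tips=80, p=3, sigma2=1.0, n_null=1000, alpha=0.05,
                     phen_model=("bm", None), run_auto=True, lam="auto"):
    """One planted-convergence (or matched null) replicate plus scoring."""
    spec = CladePlantSpec(exact_graft_distance=exact_graft_distance)
    model, param = phen_model
    for attempt in range(20):
        tree = simulate_bd_tree(0.5, 0.2, min_tips, rng)
        if model == "bm":
            phen = simulate_bm(tree, p, sigma2, rng)
        elif model == "drift":
            phen = simulate_drift(tree, p, sigma2, ds=param, rng=rng)
        else:
            scaled = rescale_tree(tree, model, param)
            phen = simulate_bm(scaled, p, sigma2, rng)
        try:
            tree2, phen2, truth = plant_convergent_clades(
                tree, phen, spec, rng, convergent=convergent)
            break
        except SimulationError:
            # tree without an eligible source/target; draw a fresh one
            if attempt == 19:
                raise
    fit = fit_rrphylo(tree2, phen2, lam=lam)
    rec = {"ntips": tree2.ntips, "f": truth.f,
           "graft_distance": truth.log["graft_distance"]}
    search = search_conv_clades(
        tree2, phen2, pairs="auto", fit=fit, n_null=n_null, alpha=alpha,
        rng=rng)
    if run_auto:
        sig = search.significant
        rec["any_significant"] = bool(sig)
        # detection / false positive is scored at the planted pair: a
        # significant pair whose mrcas both fall within 2 edges of the
        # planted mrcas
        matching = [r for r in sig if _pair_hit(tree2, r, truth)]
        rec["hit_within2"] = bool(matching)
        if sig:
            top = search.representatives[0]
            rec["top_within2"] = _pair_hit(tree2, top, truth)
        else:
            rec["top_within2"] = None
        if matching:
            # species-level recovery: planted tips inside the union of
            # the detected clades
            det_tips = set()
            for r in matching:
                det_tips.update(
                    tree2.tip_labels[i]
                    for i in np.concatenate([tree2.clade_tips(r.node_a),
                                             tree2.clade_tips(r.node_b)]))
            planted = set(truth.tips_a) | set(truth.tips_b)
            rec["species_fraction"] = len(planted & det_tips) / len(planted)
        else:
            rec["species_fraction"] = None
    # specified mode reuses the same fit and null on the true pair
    res = test_clade_pair(
        tree2, (truth.mrca_a, truth.mrca_b), phen2, fit, search.null)
    rec["spec_p_real"] = res.p_real
    rec["spec_p_sum"] = res.p_sum
    rec["spec_both_significant"] = (res.p_real < alpha
                                    and res.p_sum < alpha)
    return rec


def _state_replicate(rng, design="within", convergent=True, min_tips=80,
                     p=3, sigma2=1.0, n_shuffles=1000, alpha=0.05):
    tree = simulate_bd_tree(0.5, 0.2, min_tips, rng)
    phen = simulate_bm(tree, p, sigma2, rng)
    n_states = 1 if design == "within" else 2
    if convergent:
        phen, states, _ = plant_convergent_states(tree, phen, n_states,
                                                  rng=rng)
    else:
        states = random_state_map(tree, n_states, rng)
    if design == "within":
        res = search_conv_states(tree, phen, states, "state1",
                                 n_shuffles=n_shuffles, rng=rng)
    else:
        res = search_conv_states(tree, phen, states, "state1", "state2",
                                 n_shuffles=n_shuffles, rng=rng)
    return {"ntips": tree.ntips, "p_angle": res.p_angle,
            "p_angle_time": res.p_angle_time,
            "significant": res.significant(alpha)}


def _stayton_replicate_record(rng, convergent, n_shuffles=1000, alpha=0.05,
                              config=None):
    tree, phen, tips, truth = stayton_replicate(config, convergent, rng)
    states = {t: "conv" for t in tips}
    res = search_conv_states(tree, phen, states, "conv",
                             n_shuffles=n_shuffles, rng=rng)
    return {"significant": res.significant(alpha),
            "p_angle_time": res.p_angle_time,
            "alpha_ou": truth.log.get("alpha")}


_DESIGNS = ("clade-auto", "clade-specified", "clade-close", "state-within",
            "state-between", "model-grid", "stayton-bm", "stayton-ou")


def error_rate_suite(design, replicates, rng=None, convergent=True,
                     n_null=1000, alpha=0.05, min_tips=80, model=None,
                     model_param_range=None, ci_level=0.95, **kw):
    """Run a named simulation + test pipeline and score the error rate.

    Designs: clade-auto (automatic search on planted or matched-null
    trees), clade-specified (the true pair tested directly),
    clade-close (planted clades exactly three nodes apart), state-within /
    state-between, model-grid (phenotypes under a named non-BM model;
    pass ``model=`` one of kappa/delta/lambda/trend/drift), stayton-bm /
    stayton-ou (the 26-tip three-lineage design).

    A detection in the clade designs means a significant pair whose mrcas
    both lie within 2 edges of the planted mrcas.  Returns a dict with the
    per-replicate ``records`` DataFrame and the summary ``rates``
    including binomial confidence intervals.
    """
    if design not in _DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from "
                         f"{_DESIGNS}")
    rng = _rng(rng)
    if replicates == 0:
        return {"design": design,
                "records": pd.DataFrame(),
                "rates": {}}
    child_rngs = rng.spawn(replicates)

    param_ranges = {"kappa": (0.0, 1.0), "delta": (0.1, 3.0),
                    "lambda": (0.1, 1.0), "trend": (-0.01, 0.01),
                    "drift": (0.0, 1.0)}
    records = []
    for i, crng in enumerate(child_rngs):
        if design in ("clade-auto", "clade-specified", "clade-close",
                      "model-grid"):
            phen_model = ("bm", None)
            if design == "model-grid":
                if model not in param_ranges:
                    raise ValueError(
                        "model-grid needs model= one of "
                        f"{sorted(param_ranges)}")
                lo, hi = model_param_range or param_ranges[model]
                phen_model = (model, float(crng.uniform(lo, hi)))
            rec = _clade_replicate(
                crng, convergent=convergent,
                exact_graft_distance=3 if design == "clade-close" else None,
                min_tips=min_tips, n_null=n_null, alpha=alpha,
                phen_model=phen_model,
                run_auto=design not in ("clade-specified", "clade-close"),
                **kw)
        elif design in ("state-within", "state-between"):
            rec = _state_replicate(
                crng, design=design.split("-")[1], convergent=convergent,
                min_tips=min_tips, n_shuffles=n_null, alpha=alpha, **kw)
        else:
            rec = _stayton_replicate_record(
                crng, convergent=design == "stayton-ou",
                n_shuffles=n_null, alpha=alpha, **kw)
        rec["replicate"] = i
        records.append(rec)
    df = pd.DataFrame(records)

    rates = {"design": design, "replicates": replicates,
             "convergent": convergent}

    def add_rate(name, successes):
        successes = int(successes)
        rate = successes / replicates
        lo, hi = _binom_ci(successes, replicates, ci_level)
        rates[name] = rate
        rates[f"{name}_count"] = successes
        rates[f"{name}_ci"] = (lo, hi)

    if design in ("clade-auto", "model-grid"):
        if convergent:
            add_rate("type_ii", (~df["hit_within2"]).sum())
            add_rate("specified_power", df["spec_both_significant"].sum())
            sig = df[df["any_significant"]]
            if len(sig):
                rates["top_within2_rate"] = float(
                    sig["top_within2"].mean())
                rates["species_fraction_mean"] = float(
                    sig["species_fraction"].mean())
        else:
            # false positive scored at the planted pair, symmetric with
            # the detection criterion of the convergent condition
            add_rate("type_i", df["hit_within2"].sum())
            rates["any_pair_rate"] = float(df["any_significant"].mean())
    elif design in ("clade-specified", "clade-close"):
        sig_real = df["spec_p_real"] < alpha
        if convergent:
            add_rate("type_ii", (~sig_real).sum())
            add_rate("specified_power", df["spec_both_significant"].sum())
        else:
            add_rate("type_i", sig_real.sum())
    elif design in ("state-within", "state-between"):
        if convergent:
            add_rate("type_ii", (~df["significant"]).sum())
        else:
            add_rate("type_i", df["significant"].sum())
    elif design == "stayton-bm":
        add_rate("type_i", df["significant"].sum())
    elif design == "stayton-ou":
        add_rate("type_ii", (~df["significant"]).sum())
    return {"design": design, "records": df, "rates": rates}
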