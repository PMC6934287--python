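"""Clade-mode convergence search.

Two clades converge when the mean angle between their species' phenotype
vectors (``theta_real``, averaged over all cross pairs, one species per
clade) is smaller, per unit of phylogenetic separation, than expected by
chance.  The observed statistic ``theta_real / d`` — where d is the
patristic distance between the two clades' most recent common ancestors —
is ranked against a null built by repeatedly drawing random tip pairs from
the same tree and data: for each draw, the angle between the two tips
divided by the patristic distance between their immediate ancestors.  A
second statistic, ``(theta_real + theta_ace) / d`` with ``theta_ace`` the
angle between the two reconstructed (or user-supplied) ancestral
phenotypes, distinguishes convergence along parallel trajectories — clades
that started similar and stayed similar; its null adds, per random draw,
the angle between the ancestral phenotypes at the two tips' immediate
ancestors before dividing.

P-values are ECDF proportions of null draws at or below the observed
statistic; the smallest reportable value is 1/n_null, and a statistic below
every draw is stored as p = 0 and printed as "<1/n".  Clade pairs found
significant are ranked by phenotypic dispersion — the mean distance of
their species from the clade centroids — from tightest to loosest, since
true convergence toward an attractor keeps species close to the joint
centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .angles import angle_matrix, vector_angle
from .rrfit import RRFit, align_phenotype, fit_rrphylo
from .tree import PhyloTree, TreeError

__all__ = [
    "NodePair",
    "NullDistribution",
    "ConvergenceResult",
    "CladeSearchResult",
    "enumerate_candidate_pairs",
    "build_null",
    "test_clade_pair",
    "dispersion_rank",
    "search_conv_clades",
]


@dataclass(frozen=True)
class NodePair:
    node_a: int
    node_b: int
    node_distance: int
    time_distance: float


@dataclass
class NullDistribution:
    """Random tip-pair null: per-draw angle/time values."""

    theta_time: np.ndarray = field(repr=False)
    theta_sum_time: np.ndarray | None = field(repr=False, default=None)
    n: int = 0

    def pvalue(self, stat, use_sum=False):
        draws = self.theta_sum_time if use_sum else self.theta_time
        if draws is None:
            raise ValueError("null was built without ancestral states; "
                             "the parallel-trajectory test is unavailable")
        return float(np.count_nonzero(draws <= stat)) / draws.size


@dataclass
class ConvergenceResult:
    node_a: int
    node_b: int
    theta_real: float
    theta_ace: float
    node_distance: int
    time_distance: float
    p_real: float
    p_sum: float
    dispersion: float = np.nan
    rank: int | None = None

    def significant(self, alpha=0.05):
        return self.p_real < alpha


@dataclass
class CladeSearchResult:
    results: list
    null: NullDistribution
    fit: RRFit
    alpha: float

    @property
    def significant(self):
        return [r for r in self.results if r.significant(self.alpha)]

    @property
    def representatives(self):
        """Significant pairs collapsed by overlapping region.

        Phenotypes at neighboring nodes are strongly autocorrelated, so
        several significant pairs usually map onto the same region of the
        tree.  Pairs whose clades overlap (on both sides) are grouped, and
        each group is represented by its most inclusive member — the pair
        subtending the most tips (ties broken by smaller p, then smaller
        dispersion).  Representatives are ordered by dispersion.
        """
        sig = self.significant
        if not sig:
            return []
        tree = self.fit.tree
        tipsets = [(set(tree.clade_tips(r.node_a)),
                    set(tree.clade_tips(r.node_b))) for r in sig]
        parent = list(range(len(sig)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(sig)):
            for j in range(i + 1, len(sig)):
                a1, b1 = tipsets[i]
                a2, b2 = tipsets[j]
                same = (a1 & a2 and b1 & b2) or (a1 & b2 and b1 & a2)
                if same:
                    pi, pj = find(i), find(j)
                    if pi != pj:
                        parent[pj] = pi
        groups = {}
        for i in range(len(sig)):
            groups.setdefault(find(i), []).append(i)
        reps = []
        for members in groups.values():
            best = min(members, key=lambda i: (
                -(len(tipsets[i][0]) + len(tipsets[i][1])),
                sig[i].p_real, sig[i].dispersion,
                (sig[i].node_a, sig[i].node_b)))
            reps.append(sig[best])
        reps.sort(key=lambda r: (r.dispersion, r.p_real,
                                 (r.node_a, r.node_b)))
        return reps

    def to_frame(self):
        rows = [{
            "node_a": r.node_a, "node_b": r.node_b,
            "theta_real": r.theta_real, "theta_ace": r.theta_ace,
            "node_distance": r.node_distance,
            "time_distance": r.time_distance,
            "p_theta_real": r.p_real, "p_theta_real_plus_ace": r.p_sum,
            "dispersion": r.dispersion, "rank": r.rank,
        } for r in self.results]
        return pd.DataFrame(rows)


def enumerate_candidate_pairs(tree, min_node_distance="auto",
                              min_clade_size=5,
                              time_distance_threshold=None):
    """All testable clade pairs under the distance and size rules.

    A pair qualifies when neither mrca is an ancestor of the other, both
    clades hold at least ``min_clade_size`` tips, and the two nodes are at
    least ``min_node_distance`` edges apart ("auto" = ntips/10, rounded
    up).  When ``time_distance_threshold`` is given it replaces the node
    count criterion.
    """
    if min_node_distance == "auto":
        min_node_distance = ceil(tree.ntips / 10)
    if min_node_distance <= 0 or min_clade_size <= 0:
        raise ValueError("thresholds must be positive")
    sizes = np.array([len(t) for t in tree.clade_tip_lists])
    nodes = [n for n in range(tree.ntips, tree.nnodes)
             if sizes[n] >= min_clade_size]
    anc = tree.ancestor_matrix
    ed = tree.edge_depth
    td = tree.time_depth
    pairs = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if anc[a, b] or anc[b, a]:
                continue
            m = tree.mrca([a, b])
            nd = int(ed[a] + ed[b] - 2 * ed[m])
            tdist = float(td[a] + td[b] - 2 * td[m])
            if time_distance_threshold is not None:
                if tdist < time_distance_threshold:
                    continue
            elif nd < min_node_distance:
                continue
            pairs.append(NodePair(a, b, nd, tdist))
    if not pairs:
        warnings.warn("no candidate clade pairs satisfy the thresholds",
                      stacklevel=2)
    return pairs


def build_null(tree, phen, aces=None, n=1000, rng=None):
    """Random tip-pair null distribution.

    Each draw takes two distinct tips, computes the angle between their
    phenotypes and divides by the patristic distance between the tips'
    immediate ancestors; draws whose divisor is zero (sister tips, or
    coincident ancestors through zero-length branches) are rejected and
    redrawn.  When ``aces`` (node-state matrix, rows indexed by node id) is
    provided, the parallel-trajectory variant — (tip angle + angle between
    the two ancestors' phenotypes) / distance — is recorded alongside.
    """
    if tree.ntips < 4:
        raise TreeError("null distribution needs a tree with >= 4 tips")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    y, _ = align_phenotype(phen, tree)
    td = tree.time_depth
    out_theta = np.empty(n)
    out_sum = np.empty(n) if aces is not None else None
    filled = 0
    guard = 0
    while filled < n:
        guard += 1
        if guard > 200:
            raise RuntimeError("null sampling failed to find valid tip "
                               "pairs; tree may be degenerate")
        k = 2 * (n - filled) + 8
        t1 = rng.integers(tree.ntips, size=k)
        t2 = rng.integers(tree.ntips, size=k)
        ok = t1 != t2
        t1, t2 = t1[ok], t2[ok]
        n1 = tree.parent[t1]
        n2 = tree.parent[t2]
        m = tree.mrca_many(n1, n2)
        div = td[n1] + td[n2] - 2.0 * td[m]
        ok = div > 0
        t1, t2, n1, n2, div = t1[ok], t2[ok], n1[ok], n2[ok], div[ok]
        if t1.size == 0:
            continue
        take = min(t1.size, n - filled)
        sl = slice(0, take)
        ya = y[t1[sl]]
        yb = y[t2[sl]]
        cos = np.einsum("ij,ij->i", ya, yb) / (
            np.linalg.norm(ya, axis=1) * np.linalg.norm(yb, axis=1))
        theta = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
        out_theta[filled:filled + take] = theta / div[sl]
        if aces is not None:
            aa = aces[n1[sl]]
            ab = aces[n2[sl]]
            cos2 = np.einsum("ij,ij->i", aa, ab) / (
                np.linalg.norm(aa, axis=1) * np.linalg.norm(ab, axis=1))
            tace = np.degrees(np.arccos(np.clip(cos2, -1.0, 1.0)))
            out_sum[filled:filled + take] = (theta + tace) / div[sl]
        filled += take
    return NullDistribution(theta_time=out_theta, theta_sum_time=out_sum,
                            n=n)


def _clade_pair_stats(tree, theta_tips, a, b):
    tips_a = tree.clade_tips(a)
    tips_b = tree.clade_tips(b)
    if np.intersect1d(tips_a, tips_b).size:
        raise ValueError(f"clades {a} and {b} overlap")
    return float(theta_tips[np.ix_(tips_a, tips_b)].mean())


def test_clade_pair(tree, pair, phen, fit, null):
    """Test one clade pair against a prebuilt null distribution."""
    if isinstance(pair, NodePair):
        a, b = pair.node_a, pair.node_b
        nd, tdist = pair.node_distance, pair.time_distance
    else:
        a, b = pair
        nd = tree.node_distance(a, b)
        tdist = tree.patristic_distance(a, b)
    if tdist <= 0:
        raise ValueError(f"zero time distance between mrcas {a} and {b}")
    y, _ = align_phenotype(phen, tree)
    theta_tips = angle_matrix(y)
    theta_real = _clade_pair_stats(tree, theta_tips, a, b)
    theta_ace = vector_angle(fit.node_states[a], fit.node_states[b])
    stat1 = theta_real / tdist
    stat2 = (theta_real + theta_ace) / tdist
    return ConvergenceResult(
        node_a=a, node_b=b, theta_real=theta_real, theta_ace=theta_ace,
        node_distance=nd, time_distance=tdist,
        p_real=null.pvalue(stat1),
        p_sum=null.pvalue(stat2, use_sum=True))


def _dispersion(tree, y, a, b):
    vals = []
    for node in (a, b):
        tips = tree.clade_tips(node)
        pts = y[tips]
        centroid = pts.mean(axis=0)
        vals.append(np.linalg.norm(pts - centroid, axis=1))
    return float(np.concatenate(vals).mean())


def dispersion_rank(tree, phen, results):
    """Order significant pairs by within-pair dispersion, tightest first.

    Dispersion is the mean Euclidean distance of each species from its own
    clade's centroid, averaged over the species of both clades.  Ties break
    by smaller p(theta_real), then by (node_a, node_b).
    """
    y, _ = align_phenotype(phen, tree)
    for r in results:
        r.dispersion = _dispersion(tree, y, r.node_a, r.node_b)
    ordered = sorted(results,
                     key=lambda r: (r.dispersion, r.p_real,
                                    (r.node_a, r.node_b)))
    for i, r in enumerate(ordered):
        r.rank = i + 1
    return ordered


def search_conv_clades(tree, phen, pairs="auto", fit=None,
                       node_constraints=None, lam="auto", n_null=1000,
                       alpha=0.05, min_node_distance="auto",
                       min_clade_size=5, time_distance_threshold=None,
                       bonferroni=False, rng=None):
    """Run the full clade-mode convergence search.

    ``pairs="auto"`` enumerates candidate mrca pairs under the distance and
    size thresholds; alternatively pass an explicit list of (node_a,
    node_b) tuples.  One shared null distribution of size ``n_null`` serves
    all pairs.  Significant pairs (p(theta_real) < alpha, Bonferroni-scaled
    across candidates if requested) are ranked by dispersion.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    y, _ = align_phenotype(phen, tree)
    if fit is None:
        fit = fit_rrphylo(tree, phen, lam=lam,
                          node_constraints=node_constraints)
    elif node_constraints:
        raise ValueError("pass node_constraints when fitting, not alongside "
                         "a prebuilt fit")
    if pairs == "auto":
        pair_list = enumerate_candidate_pairs(
            tree, min_node_distance=min_node_distance,
            min_clade_size=min_clade_size,
            time_distance_threshold=time_distance_threshold)
    else:
        pair_list = []
        anc = tree.ancestor_matrix
        for a, b in pairs:
            a = tree._check_node(a)
            b = tree._check_node(b)
            if anc[a, b] or anc[b, a]:
                raise ValueError(f"nodes {a} and {b} are nested; specified "
                                 "pairs must be ancestor-disjoint")
            pair_list.append(NodePair(a, b, tree.node_distance(a, b),
                                      tree.patristic_distance(a, b)))
    null = build_null(tree, phen, aces=fit.node_states, n=n_null, rng=rng)

    theta_tips = angle_matrix(y)
    results = []
    for pr in pair_list:
        theta_real = _clade_pair_stats(tree, theta_tips, pr.node_a,
                                       pr.node_b)
        theta_ace = vector_angle(fit.node_states[pr.node_a],
                                 fit.node_states[pr.node_b])
        stat1 = theta_real / pr.time_distance
        stat2 = (theta_real + theta_ace) / pr.time_distance
        results.append(ConvergenceResult(
            node_a=pr.node_a, node_b=pr.node_b, theta_real=theta_real,
            theta_ace=theta_ace, node_distance=pr.node_distance,
            time_distance=pr.time_distance, p_real=null.pvalue(stat1),
            p_sum=null.pvalue(stat2, use_sum=True)))

    eff_alpha = alpha / max(len(results), 1) if bonferroni else alpha
    sig = [r for r in results if r.p_real < eff_alpha]
    ranked = dispersion_rank(tree, phen, sig)
    rest = [r for r in results if r not in sig]
    return CladeSearchResult(results=ranked + rest, null=null, fit=fit,
                             alpha=eff_alpha)
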