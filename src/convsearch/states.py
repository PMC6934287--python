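"""State-mode convergence test.

Instead of whole clades, the species presumed to converge are tagged with
a user-assigned 'state' (an ecomorph, a diet category, ...) and may sit
anywhere on the tree; unassigned species carry the background label
``"nostate"``.  Within one state, the observed statistics are the mean
angle over all unordered pairs of state members and the mean of each
pair's angle divided by the pair's patristic tip-to-tip distance; between
two states, pairs are taken one species per state.  Significance comes
from shuffling the complete label vector across all tips (background
included) a fixed number of times and recomputing both statistics: the
null asks whether the labeled species are more mutually similar than a
random species set of the same size.  Both raw-angle and time-normalized
p-values are reported; they can disagree, and significance calls are left
to the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .angles import angle_matrix
from .rrfit import align_phenotype
from .tree import PhyloTree

__all__ = ["BACKGROUND_STATE", "StateConvergenceResult",
           "search_conv_states"]

BACKGROUND_STATE = "nostate"


@dataclass
class StateConvergenceResult:
    states: tuple
    mean_angle: float
    mean_angle_time: float
    p_angle: float
    p_angle_time: float
    n_shuffles: int
    n_tips: tuple

    def significant(self, alpha=0.05):
        """Convergence call based on the time-normalized statistic."""
        return self.p_angle_time < alpha


def _stats_within(theta, dist, idx):
    sub_t = theta[np.ix_(idx, idx)]
    sub_d = dist[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    ang = sub_t[iu]
    dd = sub_d[iu]
    return _finish(ang, dd)


def _stats_between(theta, dist, idx_a, idx_b):
    ang = theta[np.ix_(idx_a, idx_b)].ravel()
    dd = dist[np.ix_(idx_a, idx_b)].ravel()
    return _finish(ang, dd)


def _finish(ang, dd):
    ok = dd > 0
    if not ok.all():
        warnings.warn("tip pairs at zero patristic distance excluded from "
                      "the time-normalized mean", stacklevel=3)
    mean_by_time = float((ang[ok] / dd[ok]).mean()) if ok.any() else np.nan
    return float(ang.mean()), mean_by_time


def search_conv_states(tree, phen, states, state, state2=None,
                       n_shuffles=1000, rng=None):
    """Test convergence within one state or between two states.

    Parameters
    ----------
    tree : PhyloTree
    phen : DataFrame indexed by tip label (or array in tip order)
    states : mapping tip label -> state label; unmapped tips take the
        background label
    state : the state to test (within design when ``state2`` is None)
    state2 : optional second state for the between design
    n_shuffles : number of label permutations for the null (default 1000)
    rng : seed or numpy Generator
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    y, _ = align_phenotype(phen, tree)
    unknown = [t for t in states if t not in tree.label_to_tip]
    if unknown:
        raise ValueError(f"state map names tips not in the tree: {unknown}")
    labels = np.array([states.get(t, BACKGROUND_STATE)
                       for t in tree.tip_labels])
    idx_a = np.where(labels == state)[0]
    theta = angle_matrix(y)
    dist = tree.tip_distance_matrix

    if state2 is None:
        if idx_a.size < 2:
            raise ValueError(
                f"state {state!r} has {idx_a.size} tips; the within design "
                "needs at least 2")
        obs_ang, obs_time = _stats_within(theta, dist, idx_a)
        n_tips = (int(idx_a.size),)
    else:
        idx_b = np.where(labels == state2)[0]
        if idx_a.size < 1 or idx_b.size < 1:
            raise ValueError("both states need at least one tip")
        obs_ang, obs_time = _stats_between(theta, dist, idx_a, idx_b)
        n_tips = (int(idx_a.size), int(idx_b.size))

    count_ang = 0
    count_time = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(labels)
        ia = np.where(perm == state)[0]
        if state2 is None:
            r_ang, r_time = _stats_within(theta, dist, ia)
        else:
            ib = np.where(perm == state2)[0]
            r_ang, r_time = _stats_between(theta, dist, ia, ib)
        count_ang += r_ang <= obs_ang
        count_time += r_time <= obs_time
    which = (state,) if state2 is None else (state, state2)
    return StateConvergenceResult(
        states=which, mean_angle=obs_ang, mean_angle_time=obs_time,
        p_angle=count_ang / n_shuffles, p_angle_time=count_time / n_shuffles,
        n_shuffles=n_shuffles, n_tips=n_tips)
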