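"""Multivariate phylogenetic ridge regression.

Every branch of the tree carries an evolutionary rate vector (one entry per
trait variable) such that each tip phenotype equals the root phenotype plus
the rate-weighted sum of branch lengths along its root-to-tip path:

    y_tip = y_root + sum_j beta_j * l_j     (branches j on the path)

Per variable, the rates solve a penalized least-squares system over the
path design: one row per tip, one column per branch, where branch j
contributes its length l_j to the path of every tip descending from it.
The penalty is scaled by branch length — it charges ``lambda * beta_j^2 *
l_j``, i.e. the squared phenotypic change across a branch divided by its
duration — so rate deviations are priced the way Brownian-motion
increments accumulate.  Substituting ``gamma_j = beta_j * sqrt(l_j)``
turns this into an ordinary ridge problem on a square-root-length design.
Two consequences worth knowing: (i) in the ``lambda -> 0`` limit the fit
interpolates the tips and the ancestral states coincide with the BM
maximum-likelihood (independent-contrasts) reconstruction, and (ii) a
short branch cannot soak up a large phenotypic jump for free, but neither
is it priced out entirely, as it would be under an unweighted penalty on
the raw rates.

The root phenotype is the Brownian-motion generalized-least-squares root
(the phylogenetically weighted tip mean), which reduces to the plain mean
on symmetric trees.  Ancestral phenotypes at internal nodes follow from
the same path sum, which makes the identity
``state(n) - state(parent(n)) = beta_n * l_n`` exact by construction.

With ``lambda="auto"`` the penalty is chosen per variable by minimizing
5-fold cross-validated squared tip prediction error over a log grid
refined by a bounded scalar search; fold assignment is fixed by
``fold_seed``, so the selection is deterministic.

Phenotypes at chosen internal nodes can be fixed by the user (e.g. fossil
ancestors).  A constrained node's clade is then fit as a separate subtree
whose root phenotype is the supplied vector, and the remainder of the tree
is fit with the constrained node standing in as a pseudo-tip carrying that
vector, so the requested values are honored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .tree import PhyloTree, TreeError

__all__ = ["RRFit", "fit_rrphylo", "select_lambda", "ancestral_states"]

LAMBDA_BOUNDS = (1e-6, 1e4)


@dataclass
class RRFit:
    """Result of a phylogenetic ridge regression fit."""

    tree: PhyloTree
    variables: list
    root: np.ndarray                    # (p,)
    betas: np.ndarray = field(repr=False)   # (nnodes, p); root row is zero
    node_states: np.ndarray = field(repr=False)  # (nnodes, p)
    lambdas: np.ndarray = None          # (p,)
    constraints: dict = None            # node id -> fixed vector

    @property
    def p(self):
        return len(self.variables)

    def ace(self, node):
        """Ancestral phenotype vector at an internal node."""
        node = self.tree._check_node(node)
        if node < self.tree.ntips:
            raise ValueError(f"node {node} is a tip, not an ancestor")
        return self.node_states[node]


def align_phenotype(phen, tree):
    """Validate and order a phenotype table against the tree tips.

    Returns (matrix ntips x p, variable names).
    """
    if not isinstance(phen, pd.DataFrame):
        arr = np.atleast_2d(np.asarray(phen, dtype=float))
        if arr.shape[0] != tree.ntips:
            raise ValueError("phenotype rows do not match tree tips")
        return arr.astype(float), [f"v{i + 1}" for i in range(arr.shape[1])]
    missing = [t for t in tree.tip_labels if t not in phen.index]
    extra = [t for t in phen.index if t not in tree.label_to_tip]
    if missing or extra:
        raise ValueError(
            f"phenotype/tree tip mismatch; missing from table: {missing}; "
            f"not in tree: {extra}")
    mat = phen.loc[tree.tip_labels].to_numpy(dtype=float)
    if not np.all(np.isfinite(mat)):
        raise ValueError("phenotype table contains non-finite values")
    if mat.shape[1] < 1:
        raise ValueError("phenotype table needs at least one variable")
    return mat, list(phen.columns)


def _design_matrix(tree):
    """(ntips, nnodes) sqrt-length path design for the gamma
    parameterization (gamma_j = beta_j * sqrt(l_j)); root column is all
    zero."""
    anc = tree.ancestor_matrix[: tree.ntips].astype(float)
    return anc * np.sqrt(tree.length)[None, :]


def _internal_path_matrix(tree):
    anc = tree.ancestor_matrix.astype(float)
    return anc * np.sqrt(tree.length)[None, :]


def gls_root(tree, y):
    """BM generalized-least-squares root estimate, one value per column."""
    c = tree.shared_path_matrix
    jitter = 1e-10 * max(float(np.mean(np.diag(c))), 1.0)
    cf = cho_factor(c + jitter * np.eye(c.shape[0]), lower=True)
    ones = np.ones(c.shape[0])
    a = cho_solve(cf, ones)
    return (a @ y) / (a @ ones)


def _ridge_betas(x, yc, lam, svd=None):
    """Solve the ridge system for centered tip values ``yc`` (n, p)."""
    if lam == 0.0:
        beta, *_ = np.linalg.lstsq(x, yc, rcond=None)
        return beta
    if svd is None:
        svd = np.linalg.svd(x, full_matrices=False)
    u, s, vt = svd
    filt = s / (s ** 2 + lam)
    return vt.T @ (filt[:, None] * (u.T @ yc))


def _cv_folds(n, k, fold_seed):
    rng = np.random.default_rng(fold_seed)
    perm = rng.permutation(n)
    return [np.sort(perm[i::k]) for i in range(k)]


def select_lambda(tree, phen, n_folds=5, fold_seed=0, bounds=LAMBDA_BOUNDS,
                  grid_size=9):
    """Per-variable ridge penalty by cross-validated tip prediction error.

    Deterministic given inputs: the fold assignment derives from
    ``fold_seed`` only.  Output lies within ``bounds``.
    """
    y, _ = align_phenotype(phen, tree)
    yc = y - gls_root(tree, y)
    x = _design_matrix(tree)
    n = x.shape[0]
    k = min(n_folds, max(2, n // 2))
    folds = _cv_folds(n, k, fold_seed)
    parts = []
    for hold in folds:
        keep = np.setdiff1d(np.arange(n), hold)
        svd = np.linalg.svd(x[keep], full_matrices=False)
        parts.append((keep, hold, svd))

    def cv_error(log_lam, v):
        lam = 10.0 ** log_lam
        err = 0.0
        for keep, hold, svd in parts:
            beta = _ridge_betas(None, yc[keep, v:v + 1], lam, svd=svd)
            resid = x[hold] @ beta[:, 0] - yc[hold, v]
            err += float(resid @ resid)
        return err

    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    grid = np.linspace(lo, hi, grid_size)
    lambdas = np.empty(yc.shape[1])
    for v in range(yc.shape[1]):
        scores = np.array([cv_error(g, v) for g in grid])
        if not np.all(np.isfinite(scores)):
            raise RuntimeError(
                f"lambda search failed for variable {v}: non-finite CV "
                f"scores {scores}")
        best = int(scores.argmin())
        a = grid[max(best - 1, 0)]
        b = grid[min(best + 1, grid_size - 1)]
        res = minimize_scalar(cv_error, bounds=(a, b), args=(v,),
                              method="bounded",
                              options={"xatol": 0.05, "maxiter": 20})
        cand = float(res.x)
        chosen = cand if cv_error(cand, v) <= scores[best] else grid[best]
        lambdas[v] = 10.0 ** chosen
    return lambdas


def _fit_plain(tree, y, lam, fold_seed, root_value=None):
    """Core single-tree fit; ``root_value`` fixes the root instead of GLS."""
    if root_value is None:
        root = gls_root(tree, y)
    else:
        root = np.asarray(root_value, dtype=float)
    yc = y - root
    x = _design_matrix(tree)

    if isinstance(lam, str):
        if lam != "auto":
            raise ValueError(f"unknown lambda mode {lam!r}")
        lambdas = select_lambda(tree, pd.DataFrame(y, index=tree.tip_labels),
                                fold_seed=fold_seed)
    else:
        lambdas = np.broadcast_to(np.asarray(lam, dtype=float),
                                  (y.shape[1],)).copy()
        if (lambdas < 0).any():
            raise ValueError("lambda must be >= 0")

    gammas = np.zeros((tree.nnodes, y.shape[1]))
    svd = np.linalg.svd(x, full_matrices=False)
    for lam_v in np.unique(lambdas):
        cols = np.where(lambdas == lam_v)[0]
        gammas[:, cols] = _ridge_betas(x, yc[:, cols], float(lam_v),
                                       svd=svd)
    gammas[tree.root] = 0.0
    # zero-length branches carry no time hence no change
    gammas[tree.length == 0.0] = 0.0
    node_states = root[None, :] + _internal_path_matrix(tree) @ gammas
    # back-transform to rates: beta_j = gamma_j / sqrt(l_j)
    sqrt_l = np.sqrt(tree.length)
    betas = np.divide(gammas, sqrt_l[:, None],
                      out=np.zeros_like(gammas), where=sqrt_l[:, None] > 0)
    return root, betas, node_states, lambdas


def fit_rrphylo(tree, phen, lam="auto", node_constraints=None, fold_seed=0):
    """Fit branch-wise rates, the root, and ancestral phenotypes.

    Parameters
    ----------
    tree : PhyloTree
    phen : DataFrame (tips x p) indexed by tip label, or array in tip order
    lam : "auto", scalar, or per-variable array of penalties >= 0
    node_constraints : dict, optional
        Internal node id (or internal-node label) -> phenotype vector to be
        fixed at that node.  Constrained nodes must not be nested.
    fold_seed : int
        Seed fixing the cross-validation folds of the automatic penalty
        search.
    """
    y, variables = align_phenotype(phen, tree)
    if not node_constraints:
        root, betas, states, lambdas = _fit_plain(tree, y, lam, fold_seed)
        return RRFit(tree=tree, variables=variables, root=root, betas=betas,
                     node_states=states, lambdas=lambdas, constraints={})

    cons = {}
    label_map = {v: k for k, v in tree.internal_labels.items()}
    for key, vec in node_constraints.items():
        node = label_map.get(key, key) if isinstance(key, str) else key
        node = tree._check_node(node)
        if node < tree.ntips:
            raise ValueError(f"constrained node {key!r} is a tip")
        if node == tree.root:
            raise ValueError("constrain the root by passing lam/root "
                             "explicitly, not via node_constraints")
        vec = np.asarray(vec, dtype=float).ravel()
        if vec.size != y.shape[1]:
            raise ValueError(
                f"constraint at node {key!r} has {vec.size} values, "
                f"expected {y.shape[1]}")
        cons[node] = vec
    anc = tree.ancestor_matrix
    nodes = sorted(cons)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if anc[a, b] or anc[b, a]:
                raise ValueError(
                    f"nested constrained nodes {a} and {b} are not supported")

    # reduced tree: each constrained clade collapses to a pseudo-tip
    root_m, mnodes = tree.to_mutable()
    for node in nodes:
        m = mnodes[node]
        m.children = []
        m.label = f"__fixed_{node}"
    reduced, red_oids = PhyloTree.from_mutable(root_m)
    y_red = np.empty((reduced.ntips, y.shape[1]))
    for i, lbl in enumerate(reduced.tip_labels):
        if lbl.startswith("__fixed_"):
            y_red[i] = cons[int(lbl[len("__fixed_"):])]
        else:
            y_red[i] = y[tree.label_to_tip[lbl]]
    root, betas_red, states_red, lambdas = _fit_plain(
        reduced, y_red, lam, fold_seed)

    betas = np.zeros((tree.nnodes, y.shape[1]))
    states = np.zeros((tree.nnodes, y.shape[1]))
    for new_id in range(reduced.nnodes):
        oid = red_oids[new_id]
        if oid is None:
            continue
        betas[oid] = betas_red[new_id]
        states[oid] = states_red[new_id]
    for node, vec in cons.items():
        states[node] = vec
        sub, sub_oids = tree.extract_clade(node)
        y_sub = y[[tree.label_to_tip[l] for l in sub.tip_labels]]
        _, betas_sub, states_sub, _ = _fit_plain(
            sub, y_sub, lam, fold_seed, root_value=vec)
        for new_id in range(sub.nnodes):
            oid = sub_oids[new_id]
            if oid is None or oid == node:
                continue
            betas[oid] = betas_sub[new_id]
            states[oid] = states_sub[new_id]
    return RRFit(tree=tree, variables=variables, root=root, betas=betas,
                 node_states=states, lambdas=lambdas, constraints=cons)


def ancestral_states(fit):
    """Phenotypes at every internal node as a DataFrame (node id index)."""
    ids = np.arange(fit.tree.ntips, fit.tree.nnodes)
    return pd.DataFrame(fit.node_states[ids], index=ids,
                        columns=fit.variables)
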