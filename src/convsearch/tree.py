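"""Rooted bifurcating phylogenies and the structural edits used in simulation.

The tree model is deliberately minimal: a parent array over integer node ids,
a branch length per non-root node, and tip labels.  Node ids are canonical —
tips take ``0 .. ntips-1`` in preorder (left-to-right newick) order and
internal nodes take ``ntips .. 2*ntips-2`` in preorder, so the root is always
``ntips``.  All reports echo these ids, which stay stable as long as the
topology does not change.

Branch lengths are in time units (e.g. Myr).  Zero-length branches are legal,
which allows fossil tips that sit exactly on a node and the stub edges
produced by grafting.  Polytomies are rejected: the downstream ridge design
matrix assumes bifurcation.
"""

from __future__ import annotations

import warnings
from io import StringIO

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "PhyloTree",
    "read_newick",
    "from_newick_string",
    "write_newick",
    "to_newick_string",
    "swap_one",
    "graft_subtree",
]


class TreeError(ValueError):
    """Raised when a tree violates the bifurcating-with-lengths contract."""


class _MNode:
    """Mutable helper node used for structural surgery."""

    __slots__ = ("children", "length", "label", "oid")

    def __init__(self, length=0.0, label=None, oid=None):
        self.children = []
        self.length = float(length)
        self.label = label
        self.oid = oid


class PhyloTree:
    """A rooted, fully bifurcating phylogenetic tree with branch lengths.

    Parameters
    ----------
    parent : array of int
        ``parent[i]`` is the parent node id of node ``i``; ``-1`` for the root.
    length : array of float
        Branch length subtending each node (0 for the root), >= 0.
    tip_labels : sequence of str
        Unique labels for tips ``0 .. ntips-1``.
    internal_labels : dict, optional
        Optional labels for internal nodes (id -> str), preserved on write.
    """

    def __init__(self, parent, length, tip_labels, internal_labels=None,
                 validate=True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.tip_labels = [str(x) for x in tip_labels]
        self.ntips = len(self.tip_labels)
        self.nnodes = int(self.parent.shape[0])
        self.root = self.ntips if self.nnodes > 1 else 0
        self.internal_labels = dict(internal_labels or {})
        self._cache = {}
        if validate:
            self.validate()

    # ------------------------------------------------------------------ #
    # invariants
    # ------------------------------------------------------------------ #
    def validate(self):
        n = self.ntips
        if self.nnodes == 1:
            # degenerate single-tip tree, only meaningful as a graft donor
            if n != 1 or self.parent[0] != -1:
                raise TreeError("malformed single-node tree")
            return
        if self.nnodes != 2 * n - 1:
            raise TreeError(
                f"a bifurcating tree with {n} tips must have {2 * n - 1} "
                f"nodes, got {self.nnodes}")
        if self.length.shape[0] != self.nnodes:
            raise TreeError("length array does not match node count")
        if self.parent[self.root] != -1:
            raise TreeError("root node must have parent -1")
        if np.count_nonzero(self.parent == -1) != 1:
            raise TreeError("exactly one root required")
        others = np.delete(np.arange(self.nnodes), self.root)
        if ((self.parent[others] < 0) | (self.parent[others] >= self.nnodes)).any():
            raise TreeError("parent ids out of range")
        if not np.all(np.isfinite(self.length)) or (self.length < 0).any():
            raise TreeError("branch lengths must be finite and >= 0")
        counts = np.bincount(self.parent[others], minlength=self.nnodes)
        if (counts[:n] != 0).any():
            raise TreeError("tips cannot have children")
        if (counts[n:] != 2).any():
            raise TreeError("polytomy or unifurcation: every internal node "
                            "must have exactly 2 children")
        if len(set(self.tip_labels)) != n:
            seen, dup = set(), set()
            for x in self.tip_labels:
                (dup if x in seen else seen).add(x)
            raise TreeError(f"duplicate tip labels: {sorted(dup)}")
        # connectivity: every node must reach the root
        for i in range(self.nnodes):
            j, steps = i, 0
            while self.parent[j] != -1:
                j = self.parent[j]
                steps += 1
                if steps > self.nnodes:
                    raise TreeError("cycle detected in parent map")
            if j != self.root:
                raise TreeError("disconnected node")

    # ------------------------------------------------------------------ #
    # cached structure
    # ------------------------------------------------------------------ #
    def _get(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    @property
    def children(self):
        def build():
            ch = [[] for _ in range(self.nnodes)]
            for i in range(self.nnodes):
                p = self.parent[i]
                if p >= 0:
                    ch[p].append(i)
            return ch
        return self._get("children", build)

    @property
    def preorder(self):
        def build():
            order = []
            stack = [self.root]
            ch = self.children
            while stack:
                nd = stack.pop()
                order.append(nd)
                stack.extend(reversed(ch[nd]))
            return np.asarray(order, dtype=np.int64)
        return self._get("preorder", build)

    @property
    def postorder(self):
        return self._get("postorder", lambda: self.preorder[::-1].copy())

    @property
    def time_depth(self):
        """Patristic distance of every node from the root."""
        def build():
            d = np.zeros(self.nnodes)
            for nd in self.preorder[1:]:
                d[nd] = d[self.parent[nd]] + self.length[nd]
            return d
        return self._get("time_depth", build)

    @property
    def edge_depth(self):
        """Number of edges between every node and the root."""
        def build():
            d = np.zeros(self.nnodes, dtype=np.int64)
            for nd in self.preorder[1:]:
                d[nd] = d[self.parent[nd]] + 1
            return d
        return self._get("edge_depth", build)

    @property
    def height(self):
        return float(self.time_depth[: self.ntips].max())

    @property
    def ancestor_matrix(self):
        """Boolean (nnodes, nnodes); entry [i, j] True iff j is an
        ancestor of i or i itself."""
        def build():
            anc = np.zeros((self.nnodes, self.nnodes), dtype=bool)
            for nd in self.preorder:
                p = self.parent[nd]
                if p >= 0:
                    anc[nd] = anc[p]
                anc[nd, nd] = True
            return anc
        return self._get("ancestor_matrix", build)

    @property
    def clade_tip_lists(self):
        """List of tip-id arrays per node (a tip's own list is itself)."""
        def build():
            lists = [None] * self.nnodes
            ch = self.children
            for nd in self.postorder:
                if nd < self.ntips:
                    lists[nd] = np.array([nd], dtype=np.int64)
                else:
                    lists[nd] = np.concatenate([lists[c] for c in ch[nd]])
            return lists
        return self._get("clade_tip_lists", build)

    def clade_tips(self, node):
        self._check_node(node)
        return self.clade_tip_lists[node]

    @property
    def label_to_tip(self):
        return self._get(
            "label_to_tip",
            lambda: {lbl: i for i, lbl in enumerate(self.tip_labels)})

    @property
    def shared_path_matrix(self):
        """BM covariance structure: (ntips, ntips) matrix of root-to-mrca
        distances (shared path length) for every tip pair."""
        def build():
            anc = self.ancestor_matrix[: self.ntips].astype(float)
            return (anc * self.length[None, :]) @ anc.T
        return self._get("shared_path_matrix", build)

    @property
    def tip_distance_matrix(self):
        """Patristic distance between every pair of tips."""
        def build():
            td = self.time_depth[: self.ntips]
            return td[:, None] + td[None, :] - 2.0 * self.shared_path_matrix
        return self._get("tip_distance_matrix", build)

    # ------------------------------------------------------------------ #
    # queries
    # ------------------------------------------------------------------ #
    def _check_node(self, node):
        node = int(node)
        if not (0 <= node < self.nnodes):
            raise TreeError(f"unknown node id {node}")
        return node

    def is_tip(self, node):
        return self._check_node(node) < self.ntips

    def resolve_tips(self, tips):
        """Map tip labels or ids to tip ids."""
        out = []
        for t in tips:
            if isinstance(t, str):
                if t not in self.label_to_tip:
                    raise TreeError(f"unknown tip label {t!r}")
                out.append(self.label_to_tip[t])
            else:
                out.append(self._check_node(t))
        return out

    def mrca(self, nodes):
        """Most recent common ancestor of a non-empty set of nodes
        (tip labels or node ids).  A singleton is its own mrca."""
        ids = self.resolve_tips(nodes)
        if not ids:
            raise TreeError("mrca of empty set")
        cur = ids[0]
        anc = self.ancestor_matrix
        depth = self.edge_depth
        for other in ids[1:]:
            common = anc[cur] & anc[other]
            cur = int(np.where(common, depth, -1).argmax())
        return cur

    def mrca_many(self, a, b):
        """Vectorized pairwise mrca for equal-length id arrays."""
        a = np.asarray(a, dtype=np.int64)
        b = np.asarray(b, dtype=np.int64)
        anc = self.ancestor_matrix
        common = anc[a] & anc[b]
        depth = np.where(common, self.edge_depth[None, :], -1)
        return depth.argmax(axis=1)

    def patristic_distance(self, a, b):
        """Sum of branch lengths on the path between nodes a and b."""
        a = self._check_node(a)
        b = self._check_node(b)
        m = self.mrca([a, b])
        td = self.time_depth
        return float(td[a] + td[b] - 2.0 * td[m])

    def node_distance(self, a, b):
        """Number of edges on the path between nodes a and b."""
        a = self._check_node(a)
        b = self._check_node(b)
        m = self.mrca([a, b])
        ed = self.edge_depth
        return int(ed[a] + ed[b] - 2 * ed[m])

    # ------------------------------------------------------------------ #
    # conversion
    # ------------------------------------------------------------------ #
    def to_mutable(self):
        """Return (root _MNode, list node id -> _MNode); oid carries the id."""
        nodes = [_MNode(length=self.length[i], oid=i)
                 for i in range(self.nnodes)]
        for i, nd in enumerate(nodes):
            if i < self.ntips:
                nd.label = self.tip_labels[i]
            else:
                nd.label = self.internal_labels.get(i)
        for nd in self.preorder:
            p = self.parent[nd]
            if p >= 0:
                nodes[p].children.append(nodes[nd])
        return nodes[self.root], nodes

    @classmethod
    def from_mutable(cls, root, validate=True):
        """Build a canonical tree from a mutable node structure.

        Returns ``(tree, oids)`` where ``oids[new_id]`` is the ``oid``
        attribute carried by the corresponding mutable node (None for
        newly created nodes).
        """
        order = []
        stack = [root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(reversed(nd.children))
        tips = [nd for nd in order if not nd.children]
        internals = [nd for nd in order if nd.children]
        ntips = len(tips)
        nnodes = ntips + len(internals)
        ids = {}
        for i, nd in enumerate(tips):
            ids[id(nd)] = i
        for k, nd in enumerate(internals):
            ids[id(nd)] = ntips + k
        parent = np.full(nnodes, -1, dtype=np.int64)
        length = np.zeros(nnodes)
        oids = [None] * nnodes
        internal_labels = {}
        tip_labels = [None] * ntips
        for nd in order:
            i = ids[id(nd)]
            length[i] = nd.length
            oids[i] = nd.oid
            if nd.children:
                if nd.label is not None:
                    internal_labels[i] = nd.label
                for c in nd.children:
                    parent[ids[id(c)]] = i
            else:
                if nd.label is None:
                    raise TreeError("tip without a label")
                tip_labels[i] = nd.label
        length[ids[id(root)]] = 0.0
        tree = cls(parent, length, tip_labels, internal_labels,
                   validate=validate)
        return tree, oids

    def copy(self):
        return PhyloTree(self.parent.copy(), self.length.copy(),
                         list(self.tip_labels), dict(self.internal_labels),
                         validate=False)

    # ------------------------------------------------------------------ #
    # surgery
    # ------------------------------------------------------------------ #
    def extract_clade(self, node):
        """Copy the subtree rooted at ``node`` as a standalone tree.

        Returns ``(subtree, oids)`` mapping new ids to ids in ``self``.
        The subtree root has branch length 0.
        """
        node = self._check_node(node)
        if node < self.ntips:
            sub = PhyloTree(np.array([-1]), np.array([0.0]),
                            [self.tip_labels[node]], validate=False)
            return sub, [node]
        _, nodes = self.to_mutable()
        sroot = nodes[node]
        sroot.length = 0.0
        return PhyloTree.from_mutable(sroot)

    def drop_tips(self, labels):
        """Remove the named tips, suppressing resulting unifurcations.

        Returns ``(tree, oids)``; oid None marks merged edges' surviving
        child (it keeps its own original id).
        """
        drop = set(labels)
        unknown = drop - set(self.tip_labels)
        if unknown:
            raise TreeError(f"unknown tips: {sorted(unknown)}")
        if len(set(self.tip_labels) - drop) < 2:
            raise TreeError("cannot drop tips: fewer than 2 would remain")
        root, nodes = self.to_mutable()
        parent_of = {}
        stack = [root]
        while stack:
            nd = stack.pop()
            for c in nd.children:
                parent_of[id(c)] = nd
                stack.append(c)

        for i, lbl in enumerate(self.tip_labels):
            if lbl not in drop:
                continue
            tip = nodes[i]
            par = parent_of[id(tip)]
            par.children.remove(tip)
            # suppress the unifurcation left behind
            while len(par.children) == 1:
                child = par.children[0]
                gp = parent_of.get(id(par))
                if gp is None:
                    # par was the root: its single child becomes the root
                    child.length = 0.0
                    root = child
                    parent_of.pop(id(child), None)
                    break
                child.length += par.length
                gp.children[gp.children.index(par)] = child
                parent_of[id(child)] = gp
                par = gp
        return PhyloTree.from_mutable(root)

    # ------------------------------------------------------------------ #
    # newick i/o
    # ------------------------------------------------------------------ #
    def to_dendropy(self, taxon_namespace=None):
        tns = taxon_namespace if taxon_namespace is not None \
            else dendropy.TaxonNamespace()
        dt = dendropy.Tree(taxon_namespace=tns)
        dt.taxon_namespace = tns

        def build(node, dnode):
            for c in self.children[node]:
                child = dnode.new_child()
                child.edge.length = float(self.length[c])
                if c < self.ntips:
                    child.taxon = tns.require_taxon(label=self.tip_labels[c])
                elif c in self.internal_labels:
                    child.label = self.internal_labels[c]
                build(c, child)

        if self.root in self.internal_labels:
            dt.seed_node.label = self.internal_labels[self.root]
        build(self.root, dt.seed_node)
        return dt


def _from_dendropy(dt, resolve_polytomies=False):
    def convert(dnode):
        nd = _MNode(length=dnode.edge.length if dnode.edge.length else 0.0)
        if dnode.is_leaf():
            if dnode.taxon is not None:
                nd.label = dnode.taxon.label
            else:
                nd.label = dnode.label
            if nd.label is None:
                raise TreeError("tip without a label in newick input")
            return nd
        nd.label = dnode.label
        kids = dnode.child_nodes()
        if len(kids) == 1:
            raise TreeError("unifurcation in newick input")
        if len(kids) > 2:
            if not resolve_polytomies:
                raise TreeError(
                    f"polytomy with {len(kids)} children; pass "
                    "resolve_polytomies=True to resolve with zero-length "
                    "branches")
            # deterministic left-comb resolution with zero-length branches
            converted = [convert(k) for k in kids]
            cur = converted[0]
            for other in converted[1:-1]:
                join = _MNode(length=0.0)
                join.children = [cur, other]
                cur = join
            nd.children = [cur, converted[-1]]
            return nd
        for k in kids:
            if k.edge.length is None:
                raise TreeError("missing branch length in newick input")
            nd.children.append(convert(k))
        return nd

    root = convert(dt.seed_node)
    tree, _ = PhyloTree.from_mutable(root)
    return tree


def from_newick_string(s, resolve_polytomies=False):
    try:
        dt = dendropy.Tree.get(data=s, schema="newick",
                               preserve_underscores=True)
    except Exception as exc:  # dendropy raises assorted error classes
        raise TreeError(f"newick parse failure: {exc}") from exc
    return _from_dendropy(dt, resolve_polytomies=resolve_polytomies)


def read_newick(path, resolve_polytomies=False):
    with open(path) as fh:
        return from_newick_string(fh.read(),
                                  resolve_polytomies=resolve_polytomies)


def to_newick_string(tree, precision=12):
    dt = tree.to_dendropy()
    out = StringIO()
    dt.write(file=out, schema="newick", suppress_rooting=True,
             unquoted_underscores=True,
             real_value_format_specifier=f".{precision}g")
    return out.getvalue().strip() + "\n"


def write_newick(tree, path, precision=12):
    with open(path, "w") as fh:
        fh.write(to_newick_string(tree, precision=precision))


# ---------------------------------------------------------------------- #
# perturbation and grafting
# ---------------------------------------------------------------------- #
def swap_one(tree, tip_fraction, branch_fraction, rng):
    """Perturb topology and branch lengths while keeping the tree valid.

    Topology: repeatedly pick a tip, find its grandparent g, and exchange
    its label with a random tip descending from g but not from the tip's
    own parent — a localized transposition — until about ``tip_fraction``
    of the tips have moved.  Branch lengths: a ``branch_fraction`` subset
    of branches is multiplied by Uniform(0.5, 1.5) factors.

    The tip label set is unchanged; fractions (0, 0) return an identical
    copy.
    """
    if not (0 <= tip_fraction <= 1 and 0 <= branch_fraction <= 1):
        raise ValueError("fractions must be in [0, 1]")
    if tree.ntips < 4:
        raise TreeError("tree too small to swap (need >= 4 tips)")
    labels = list(tree.tip_labels)
    length = tree.length.copy()
    n = tree.ntips
    n_target = int(round(tip_fraction * n))
    moved = set()
    attempts = 0
    while len(moved) < n_target and attempts < 20 * n:
        attempts += 1
        t1 = int(rng.integers(n))
        p = tree.parent[t1]
        g = tree.parent[p]
        if g < 0:
            continue
        pool = np.setdiff1d(tree.clade_tips(g), tree.clade_tips(p))
        if pool.size == 0:
            continue
        t2 = int(pool[rng.integers(pool.size)])
        labels[t1], labels[t2] = labels[t2], labels[t1]
        moved.update((t1, t2))
    n_branch = int(round(branch_fraction * (tree.nnodes - 1)))
    if n_branch > 0:
        branches = np.delete(np.arange(tree.nnodes), tree.root)
        chosen = rng.choice(branches, size=n_branch, replace=False)
        length[chosen] *= rng.uniform(0.5, 1.5, size=n_branch)
    return PhyloTree(tree.parent.copy(), length, labels,
                     dict(tree.internal_labels))


def graft_subtree(tree, subtree, target):
    """Attach ``subtree`` next to the clade under ``target``.

    The branch above ``target`` is bisected at its midpoint; the subtree
    hangs from the new midpoint node on a positive stub (half the local
    branch scale) and is uniformly rescaled so its deepest tip ends at the
    same root-to-tip distance as the deepest tip currently descending from
    ``target``.  The stub must be positive: a zero-length stem would pin
    the grafted clade's ancestral state to the attachment point in any
    rate fit.  A single-tip donor is attached directly as a new tip.
    """
    target = tree._check_node(target)
    if target < tree.ntips:
        raise TreeError("graft target must be an internal node")
    if target == tree.root:
        raise TreeError("cannot graft at the root (no subtending branch)")
    clash = set(tree.tip_labels) & set(subtree.tip_labels)
    if clash:
        raise TreeError(f"tip label collision: {sorted(clash)}")

    target_tips = tree.clade_tips(target)
    h_target = float(tree.time_depth[target_tips].max())
    root, nodes = tree.to_mutable()
    tnode = nodes[target]
    pnode = nodes[tree.parent[target]]
    half = tnode.length / 2.0
    mid = _MNode(length=half)
    tnode.length = half
    pnode.children[pnode.children.index(tnode)] = mid
    depth_mid = float(tree.time_depth[tree.parent[target]]) + half
    avail = h_target - depth_mid
    if avail <= 0:
        raise TreeError("target clade too shallow to receive a graft")

    sroot, _ = subtree.to_mutable()
    if subtree.nnodes == 1:
        sroot.length = avail
    else:
        stub = 0.5 * half if half > 0 else 0.5 * avail
        stub = min(stub, 0.5 * avail)
        h_sub = float(subtree.time_depth[: subtree.ntips].max())
        if h_sub <= 0:
            raise TreeError("degenerate subtree with zero height")
        scale = (avail - stub) / h_sub
        stack = [sroot]
        while stack:
            nd = stack.pop()
            nd.length *= scale
            stack.extend(nd.children)
        sroot.length = stub
    # clear stale ids carried over from the donor tree
    stack = [sroot]
    while stack:
        nd = stack.pop()
        nd.oid = None
        stack.extend(nd.children)
    mid.children = [tnode, sroot]
    new_tree, _ = PhyloTree.from_mutable(root)
    return new_tree
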