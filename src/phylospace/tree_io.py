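"""Reading, validating, measuring and writing phylogenies.

A phylogeny is held as a :class:`TreeRecord`: flat parent/branch-length
arrays over all nodes with a fixed indexing convention — tips first (in
input order), then internal nodes in postorder, root last.  With this
ordering ``parent[i] > i`` for every non-root node, so a single ascending
(descending) index sweep visits children before (after) parents, which keeps
every traversal vectorizable.

All downstream stages (the modified graph Laplacian, the Laplacian sampler,
the birth–death simulator) consume the node-to-node distance machinery
defined here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "TreeRecord",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "tree_metrics",
    "node_distance_matrix",
    "resolve_polytomies",
    "mpl_ultrametricize",
]

#: default relative tolerance (w.r.t. tree height) for ultrametricity checks
DEFAULT_ULTRAMETRIC_TOL = 1e-8


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or lacks branch lengths."""


@dataclass
class TreeRecord:
    """A rooted phylogeny plus per-tree metadata.

    Attributes
    ----------
    parent
        ``(n_nodes,)`` int array; ``parent[i]`` is the index of node *i*'s
        parent, ``-1`` for the root.  Indexing convention: tips occupy
        ``0..n_tips-1`` in input order, internal nodes follow in postorder,
        the root is last, so ``parent[i] > i`` for all non-root nodes.
    edge_length
        ``(n_nodes,)`` float array of branch lengths above each node
        (time units, >= 0); the root entry is 0.
    tip_labels
        unique labels for nodes ``0..n_tips-1``.
    root_edge_length
        length annotated on the root in the source Newick, if any.  Kept for
        round-tripping only: it joins the root to nothing, so it enters
        neither the distance matrix nor the crown age.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    tip_labels: list[str]
    family: Optional[str] = None
    taxon_class: Optional[str] = None
    sampling_fraction: Optional[float] = None
    root_edge_length: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.edge_length = np.asarray(self.edge_length, dtype=np.float64)
        n = self.parent.size
        if n < 1 or self.edge_length.size != n:
            raise ValueError("parent and edge_length must have equal length >= 1")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1 or roots[0] != n - 1:
            raise ValueError("exactly one root required, at the last index")
        if np.any(self.edge_length < 0):
            raise ValueError("negative branch length")
        if np.any(self.parent[:-1] <= np.arange(n - 1)):
            raise ValueError("parent index must exceed child index (postorder)")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels must be unique")
        if self.sampling_fraction is not None and not (
            0.0 <= self.sampling_fraction <= 1.0
        ):
            raise ValueError("sampling_fraction must lie in [0, 1]")

    # -- basic structure -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def children(self) -> list[list[int]]:
        """Child lists per node (tips have empty lists)."""
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent[:-1]):
            ch[p].append(i)
        return ch

    def depths(self) -> np.ndarray:
        """Distance of every node from the root (root edge excluded)."""
        d = np.zeros(self.n_nodes)
        for i in range(self.n_nodes - 2, -1, -1):
            d[i] = d[self.parent[i]] + self.edge_length[i]
        return d

    def crown_node(self) -> int:
        """First node at or below the root with >= 2 children."""
        ch = self.children()
        node = self.root
        while len(ch[node]) == 1:
            node = ch[node][0]
        return node

    def with_scaled_branches(self, c: float) -> "TreeRecord":
        """A copy with every branch length multiplied by ``c > 0``."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return replace(
            self,
            edge_length=self.edge_length * c,
            root_edge_length=(
                None if self.root_edge_length is None else self.root_edge_length * c
            ),
        )

    @staticmethod
    def from_links(
        parent_of: dict,
        length_of: dict,
        children_of: dict,
        tip_order: Sequence,
        tip_labels: Sequence[str],
        root,
        **meta,
    ) -> "TreeRecord":
        """Canonicalize an arbitrarily-keyed node structure.

        ``parent_of``/``length_of`` map node keys to parent key / branch
        length; ``children_of`` maps node keys to ordered child keys;
        ``tip_order`` fixes the tip indexing.  Internal nodes are numbered in
        postorder (children visited in the order given), root last.
        """
        index = {k: i for i, k in enumerate(tip_order)}
        post: list = []
        # iterative postorder over internal nodes
        stack = [(root, False)]
        while stack:
            node, done = stack.pop()
            if not children_of.get(node):
                continue  # tip
            if done:
                post.append(node)
            else:
                stack.append((node, True))
                for c in reversed(children_of[node]):
                    stack.append((c, False))
        for k in post:
            index[k] = len(index)
        n = len(index)
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n)
        for k, i in index.items():
            if k == root:
                continue
            parent[i] = index[parent_of[k]]
            length[i] = length_of[k]
        return TreeRecord(parent, length, list(tip_labels), **meta)


# -- Newick I/O ----------------------------------------------------------


def parse_newick(text: str, **meta) -> TreeRecord:
    """Parse a Newick string (branch lengths required) into a TreeRecord.

    Polytomies are allowed.  Malformed input raises
    :class:`NewickParseError` carrying dendropy's line/column location;
    missing branch lengths raise explicitly.
    """
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from None

    children_of: dict = {}
    parent_of: dict = {}
    length_of: dict = {}
    tips: list = []
    labels: list[str] = []
    for nd in dt.postorder_node_iter():
        children_of[nd] = list(nd.child_nodes())
        if nd.parent_node is not None:
            parent_of[nd] = nd.parent_node
            if nd.edge.length is None:
                raise NewickParseError("missing branch length in Newick input")
            length_of[nd] = float(nd.edge.length)
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else None
            if label is None:
                raise NewickParseError("unlabeled tip in Newick input")
            tips.append(nd)
            labels.append(label)
    root_edge = dt.seed_node.edge.length
    rec = TreeRecord.from_links(
        parent_of,
        length_of,
        children_of,
        tips,
        labels,
        dt.seed_node,
        root_edge_length=None if root_edge is None else float(root_edge),
        **meta,
    )
    return rec


def write_newick(t: TreeRecord) -> str:
    """Serialize a TreeRecord to a Newick string with branch lengths.

    Float formatting uses ``repr`` so parse -> write -> parse round-trips
    branch lengths exactly.
    """
    ch = t.children()
    frag = [""] * t.n_nodes
    for i in range(t.n_nodes):
        if i < t.n_tips:
            frag[i] = t.tip_labels[i]
        else:
            frag[i] = "(" + ",".join(frag[c] for c in ch[i]) + ")"
        if i != t.root:
            frag[i] += f":{float(t.edge_length[i])!r}"
    out = frag[t.root]
    if t.root_edge_length is not None:
        out += f":{float(t.root_edge_length)!r}"
    return out + ";"


def read_newick_file(path, **meta) -> TreeRecord:
    with io.open(path, "r") as fh:
        return parse_newick(fh.read(), **meta)


# -- measurement ---------------------------------------------------------


def tree_metrics(t: TreeRecord, tol: float = DEFAULT_ULTRAMETRIC_TOL) -> dict:
    """Tip count, crown age, ultrametricity and binarity of a tree.

    Crown age is the maximum distance from the crown node (first split) to
    any tip; ``is_ultrametric`` is true iff all crown-to-tip spans agree
    within ``tol`` relative to the tree height.
    """
    depths = t.depths()
    crown = t.crown_node()
    tip_depths = depths[: t.n_tips] - depths[crown]
    crown_age = float(tip_depths.max()) if t.n_tips else 0.0
    height = max(crown_age, np.finfo(float).tiny)
    is_ultra = bool(tip_depths.max() - tip_depths.min() <= tol * height)
    ch = t.children()
    is_binary = all(len(c) in (0, 2) for c in ch[: t.root]) and len(ch[t.root]) == 2
    return {
        "n_tips": t.n_tips,
        "crown_age": crown_age,
        "is_ultrametric": is_ultra,
        "is_binary": is_binary,
    }


def node_distance_matrix(t: TreeRecord) -> np.ndarray:
    """All-pairs path-length matrix over every node (tips + internals + root).

    Entry (i, j) is the sum of branch lengths on the unique path between
    nodes i and j; computed as shortest paths over the tree's weighted edge
    graph, which for a tree coincides with the tree metric.
    """
    n = t.n_nodes
    rows = np.arange(n - 1)
    cols = t.parent[:-1]
    w = t.edge_length[:-1]
    adj = csr_matrix(
        (np.concatenate([w, w]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    )
    return dijkstra(adj, directed=False)


# -- topology surgery ----------------------------------------------------


def resolve_polytomies(t: TreeRecord, seed: int = 0) -> TreeRecord:
    """Randomly resolve multifurcations into bifurcations with 0-length edges.

    Tip-to-tip distances are unchanged; already-binary trees are returned
    as-is.  Deterministic for a fixed seed.
    """
    ch = t.children()
    if all(len(c) in (0, 2) for c in ch):
        return t
    rng = np.random.default_rng(seed)
    parent_of: dict = {}
    length_of: dict = {}
    children_of: dict = {}
    for i in range(t.n_nodes - 1):
        length_of[i] = float(t.edge_length[i])
    next_key = [t.n_nodes]

    def fresh() -> int:
        next_key[0] += 1
        return next_key[0]

    for i in range(t.n_nodes):
        kids = list(ch[i])
        while len(kids) > 2:
            a, b = sorted(rng.choice(len(kids), size=2, replace=False))
            kb, ka = kids.pop(b), kids.pop(a)
            new = fresh()
            for k in (ka, kb):
                parent_of[k] = new
            children_of[new] = [ka, kb]
            length_of[new] = 0.0
            kids.append(new)
        children_of[i] = kids
        for k in kids:
            parent_of[k] = i
    return TreeRecord.from_links(
        parent_of,
        length_of,
        children_of,
        list(range(t.n_tips)),
        t.tip_labels,
        t.root,
        family=t.family,
        taxon_class=t.taxon_class,
        sampling_fraction=t.sampling_fraction,
        root_edge_length=t.root_edge_length,
        label=t.label,
    )


def mpl_ultrametricize(t: TreeRecord) -> TreeRecord:
    """Make a tree ultrametric by the mean-path-length scheme.

    Each internal node's age is set to the mean path length from the node to
    its descendant tips (tips at age 0); a child age exceeding its parent's
    is clamped to the parent age.  Branch lengths become parent-age minus
    child-age, so the output is ultrametric by construction.
    """
    n = t.n_nodes
    tip_count = np.zeros(n)
    tip_count[: t.n_tips] = 1.0
    path_sum = np.zeros(n)
    for i in range(n - 1):  # ascending: children before parents
        p = t.parent[i]
        tip_count[p] += tip_count[i]
        path_sum[p] += path_sum[i] + tip_count[i] * t.edge_length[i]
    age = np.zeros(n)
    internal = tip_count > 1
    age[internal] = path_sum[internal] / tip_count[internal]
    # clamp inversions: parents before children
    for i in range(n - 2, -1, -1):
        if age[i] > age[t.parent[i]]:
            age[i] = age[t.parent[i]]
    new_len = np.zeros(n)
    new_len[:-1] = age[t.parent[:-1]] - age[:-1]
    if np.any(new_len < 0):
        raise ValueError("negative implied branch length after clamping")
    return replace(t, edge_length=new_len)
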