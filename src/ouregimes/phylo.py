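"""Rooted, dated phylogenies: ingestion, validation, fossil grafting, serialization.

Trees are stored in a flat array representation (parent pointers + branch
lengths) that the likelihood code consumes directly.  Branch lengths are in
millions of years (Myr) throughout; no unit autodetection is attempted.
Polytomies are preserved as-is and handled natively downstream.

Newick and Nexus parsing is delegated to dendropy; the simmap-annotated
Newick dialect (per-branch regime segments written as
``{state,duration:state,duration:...}`` in place of the branch length) is
parsed and written here, since no installed library reads it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeError",
    "read_tree",
    "write_tree",
    "graft_fossil_clade",
    "parse_simmap_newick",
    "write_simmap_newick",
]


class TreeError(ValueError):
    """Raised for malformed, inconsistent, or unresolvable tree input."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths in Myr.

    Nodes are integers ``0 .. n_nodes-1``.  ``parent[i]`` is the parent of
    node ``i`` (``-1`` for the root); ``lengths[i]`` is the length of the
    branch above node ``i`` (0.0 for the root).  ``labels[i]`` is the tip
    label for leaves and ``None`` for internal nodes.

    Node *depths* measure time from the root; node *ages* measure time
    before present, with the deepest tip defining age 0.  Non-ultrametric
    trees (fossil tips at positive age) are fully supported.
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: list

    _children: list = field(default=None, repr=False, compare=False)
    _postorder: np.ndarray = field(default=None, repr=False, compare=False)
    _depths: np.ndarray = field(default=None, repr=False, compare=False)
    _tmat: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.validate()

    # ---------------------------------------------------------------- basic
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        roots = np.flatnonzero(self.parent < 0)
        return int(roots[0])

    @property
    def children(self) -> list:
        if self._children is None:
            ch = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    @property
    def tips(self) -> np.ndarray:
        """Indices of leaf nodes, in index order."""
        return np.array([i for i in range(self.n_nodes) if not self.children[i]])

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tips]

    def tip_index(self, label: str) -> int:
        for i in self.tips:
            if self.labels[i] == label:
                return int(i)
        raise KeyError(f"no tip labelled {label!r}")

    @property
    def postorder(self) -> np.ndarray:
        """Node indices ordered children-before-parents."""
        if self._postorder is None:
            order, stack = [], [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self.children[node])
            self._postorder = np.array(order[::-1], dtype=int)
        return self._postorder

    @property
    def depths(self) -> np.ndarray:
        """Time from the root to each node (Myr)."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for node in self.postorder[::-1]:
                p = self.parent[node]
                if p >= 0:
                    d[node] = d[p] + self.lengths[node]
            self._depths = d
        return self._depths

    @property
    def height(self) -> float:
        """Depth of the deepest tip (defines the present, age 0)."""
        return float(self.depths[self.tips].max())

    @property
    def ages(self) -> np.ndarray:
        """Myr before present for each node."""
        return self.height - self.depths

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        td = self.depths[self.tips]
        return bool(td.max() - td.min() <= tol)

    # ------------------------------------------------------------ validation
    def validate(self):
        n = self.n_nodes
        if n == 0:
            raise TreeError("empty tree")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        if np.any(self.lengths < 0):
            bad = int(np.flatnonzero(self.lengths < 0)[0])
            raise TreeError(f"negative branch length at node {bad}")
        seen = set()
        for i in self.tips:
            lab = self.labels[i]
            if lab is None:
                raise TreeError(f"unlabelled tip node {i}")
            if lab in seen:
                raise TreeError(f"duplicate tip label {lab!r}")
            seen.add(lab)
        # reachability / acyclicity: every node must reach the root
        for i in range(n):
            hops, j = 0, i
            while self.parent[j] >= 0:
                j = self.parent[j]
                hops += 1
                if hops > n:
                    raise TreeError(f"cycle detected at node {i}")

    # ------------------------------------------------------- tree statistics
    def mrca_depth_matrix(self) -> np.ndarray:
        """Pairwise depth of the MRCA of tips i and j (shared path time).

        The diagonal holds each tip's own depth.  Computed by intersecting
        root-to-tip paths; O(n^2) in the number of tips, adequate for the
        tree sizes used here.  Memoized (trees are treated as immutable).
        """
        if self._tmat is not None:
            return self._tmat
        tips = self.tips
        paths = []
        for t in tips:
            anc, j = {}, int(t)
            while j >= 0:
                anc[j] = self.depths[j]
                j = self.parent[j]
            paths.append(anc)
        n = len(tips)
        out = np.zeros((n, n))
        for a in range(n):
            out[a, a] = self.depths[tips[a]]
            for b in range(a + 1, n):
                shared = paths[a].keys() & paths[b].keys()
                d = max(paths[a][k] for k in shared)
                out[a, b] = out[b, a] = d
        self._tmat = out
        return out

    def path_to_root(self, node: int) -> list:
        """Nodes from ``node`` up to and including the root."""
        out, j = [], int(node)
        while j >= 0:
            out.append(j)
            j = self.parent[j]
        return out

    # --------------------------------------------------------- serialization
    def _newick_parts(self, node: int, branch_text) -> str:
        kids = self.children[node]
        if kids:
            inner = ",".join(self._newick_parts(k, branch_text) for k in kids)
            body = f"({inner})"
        else:
            body = self.labels[node]
        if self.parent[node] < 0:
            return body
        return body + branch_text(node)

    def to_newick(self, precision: int = 12) -> str:
        return self._newick_parts(self.root, lambda i: f":{self.lengths[i]:.{precision}g}") + ";"


# ------------------------------------------------------------------ file I/O

def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    lengths = np.zeros(len(nodes))
    labels = [None] * len(nodes)
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
        if nd.is_leaf():
            labels[i] = nd.taxon.label if nd.taxon is not None else nd.label
    return Phylogeny(parent, lengths, labels)


def read_tree(path, format: str = "newick") -> Phylogeny:
    """Read a rooted tree from a Newick or Nexus file.

    Raises :class:`TreeError` on malformed input or duplicate tip labels.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported format {format!r}")
    try:
        dtree = dendropy.Tree.get(
            path=str(path),
            schema=format,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises many parse-error types
        raise TreeError(f"cannot parse {path} as {format}: {exc}") from exc
    return _from_dendropy(dtree)


def read_tree_string(text: str, format: str = "newick") -> Phylogeny:
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=format,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"cannot parse tree string: {exc}") from exc
    return _from_dendropy(dtree)


def write_tree(tree: Phylogeny, path, format: str = "newick"):
    text = tree.to_newick()
    if format == "newick":
        with open(path, "w") as fh:
            fh.write(text + "\n")
    elif format == "nexus":
        dtree = dendropy.Tree.get(data=text + "\n", schema="newick",
                                  preserve_underscores=True)
        dtree.write(path=str(path), schema="nexus")
    else:
        raise ValueError(f"unsupported format {format!r}")


# ------------------------------------------------------------ fossil grafting

def graft_fossil_clade(tree: Phylogeny, host_clade, fossil_names,
                       stem_age: float, tip_ages=None) -> Phylogeny:
    """Attach fossil tips as a polytomy with a host clade at ``stem_age``.

    A new node is inserted on the branch subtending the MRCA of
    ``host_clade`` at age ``stem_age``; each fossil hangs from it with
    branch length ``stem_age - tip_age``.  Extant tips keep age 0.

    Parameters
    ----------
    host_clade : iterable of tip labels defining the clade to join.
    fossil_names : labels of the fossils to add.
    stem_age : Myr before present of the polytomy node.
    tip_ages : Myr before present of each fossil tip (scalar, mapping, or
        sequence aligned with ``fossil_names``); default 0.
    """
    fossil_names = list(fossil_names)
    if not fossil_names:
        return Phylogeny(tree.parent.copy(), tree.lengths.copy(), list(tree.labels))
    if tip_ages is None:
        ages = {f: 0.0 for f in fossil_names}
    elif np.isscalar(tip_ages):
        ages = {f: float(tip_ages) for f in fossil_names}
    elif isinstance(tip_ages, dict):
        ages = {f: float(tip_ages[f]) for f in fossil_names}
    else:
        ages = dict(zip(fossil_names, map(float, tip_ages)))
    for f, a in ages.items():
        if a >= stem_age:
            raise TreeError(f"fossil {f!r}: tip age {a} must be < stem age {stem_age}")

    try:
        host_ids = [tree.tip_index(lbl) for lbl in host_clade]
    except KeyError as exc:
        raise TreeError(f"unknown host tip: {exc}") from exc
    if not host_ids:
        raise TreeError("empty host clade")

    # MRCA of the host tips
    ancestor_sets = [set(tree.path_to_root(t)) for t in host_ids]
    common = set.intersection(*ancestor_sets)
    mrca = max(common, key=lambda j: tree.depths[j])

    node_ages = tree.ages
    mrca_age = node_ages[mrca]
    if tree.parent[mrca] >= 0:
        parent_age = node_ages[tree.parent[mrca]]
    else:
        parent_age = np.inf
    if not (mrca_age <= stem_age <= parent_age):
        raise TreeError(
            f"stem age {stem_age} outside the attachment edge "
            f"[{mrca_age:.4g}, {parent_age:.4g}] above the host clade")

    n = tree.n_nodes
    attach = n  # new internal node on the edge above the MRCA
    parent = np.concatenate([tree.parent, [tree.parent[mrca]],
                             np.full(len(fossil_names), attach)])
    lengths = np.concatenate([tree.lengths,
                              [parent_age - stem_age if np.isfinite(parent_age) else 0.0],
                              [stem_age - ages[f] for f in fossil_names]])
    lengths = lengths.copy()
    parent[mrca] = attach
    lengths[mrca] = stem_age - mrca_age
    labels = list(tree.labels) + [None] + fossil_names
    return Phylogeny(parent, lengths, labels)


def prune_to_tips(tree: Phylogeny, keep_labels) -> Phylogeny:
    """Subtree spanned by the named tips, unifurcations collapsed.

    Branch lengths along collapsed chains are summed, so root-to-tip path
    lengths are preserved.
    """
    keep = set(keep_labels)
    unknown = keep - set(tree.tip_labels)
    if unknown:
        raise TreeError(f"unknown tips: {sorted(unknown)[:5]}")
    marked = np.zeros(tree.n_nodes, dtype=bool)
    for t in tree.tips:
        if tree.labels[t] in keep:
            j = int(t)
            while j >= 0 and not marked[j]:
                marked[j] = True
                j = tree.parent[j]
    kept_children = [[c for c in tree.children[i] if marked[c]]
                     for i in range(tree.n_nodes)]

    new_parent, new_len, new_label = [], [], []

    def build(old, new_par, extra_len):
        while len(kept_children[old]) == 1:
            nxt = kept_children[old][0]
            extra_len += tree.lengths[nxt]
            old = nxt
        idx = len(new_parent)
        new_parent.append(new_par)
        new_len.append(extra_len)
        new_label.append(tree.labels[old] if not kept_children[old] else None)
        for c in kept_children[old]:
            build(c, idx, float(tree.lengths[c]))
        return idx

    build(tree.root, -1, 0.0)
    return Phylogeny(np.array(new_parent), np.array(new_len), new_label)


# --------------------------------------------------------------- simmap I/O
# The simmap dialect replaces every branch length with a braced list of
# (state, duration) segments ordered from the rootward end of the branch to
# its tipward end, e.g.  (A:{ground,1.5:glider,0.5},B:{ground,2});

def write_simmap_newick(tree: Phylogeny, segments) -> str:
    """Serialize a tree plus per-branch regime segments as simmap Newick.

    ``segments[i]`` is the ordered (state, duration) list for the branch
    above node ``i``.
    """
    def btext(i):
        segs = ":".join(f"{s},{d:.12g}" for s, d in segments[i])
        return ":{" + segs + "}"
    return tree._newick_parts(tree.root, btext) + ";"


def parse_simmap_newick(text: str):
    """Parse simmap Newick; returns ``(Phylogeny, segments)``.

    Segments follow the same per-node convention as
    :func:`write_simmap_newick`.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise TreeError("simmap string must end with ';'")
    stream = io.StringIO(text[:-1])

    parents, lengths, labels, segments = [], [], [], []

    def new_node(parent_id):
        parents.append(parent_id)
        lengths.append(0.0)
        labels.append(None)
        segments.append([])
        return len(parents) - 1

    def parse_node(parent_id):
        node = new_node(parent_id)
        ch = stream.read(1)
        if ch == "(":
            while True:
                parse_node(node)
                ch = stream.read(1)
                if ch == ")":
                    break
                if ch != ",":
                    raise TreeError(f"unexpected token {ch!r} in simmap string")
            ch = stream.read(1)
        # optional label
        lab = []
        while ch not in ("", ":", ",", ")", "{"):
            lab.append(ch)
            ch = stream.read(1)
        if lab:
            labels[node] = "".join(lab)
        if ch == ":":
            ch = stream.read(1)
            if ch != "{":
                raise TreeError("expected '{' after ':' in simmap string")
            body = []
            ch = stream.read(1)
            while ch != "}":
                if ch == "":
                    raise TreeError("unterminated simmap segment list")
                body.append(ch)
                ch = stream.read(1)
            for part in "".join(body).split(":"):
                state, dur = part.split(",")
                segments[node].append((state, float(dur)))
            lengths[node] = sum(d for _, d in segments[node])
        else:
            # push back the lookahead character
            if ch:
                stream.seek(stream.tell() - 1)

    parse_node(-1)
    rest = stream.read()
    if rest.strip():
        raise TreeError(f"trailing characters after tree: {rest!r}")
    tree = Phylogeny(np.array(parents), np.array(lengths), labels)
    return tree, segments
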