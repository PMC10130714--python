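"""Ultrametric time-calibrated phylogenies: parsing, validation and queries.

The central object is :class:`Phylogeny`, an array-backed rooted tree whose
branch lengths are in millions of years (Myr).  Time is measured backward
from the present: every tip sits at age 0 and the age of an internal node is
its maximum distance to a descendant tip, so the root age equals the tree
height.  Trees must be ultrametric (all root-to-tip path lengths equal within
a relative tolerance); non-ultrametric input is rejected, never rescaled.

Depth slicing follows a half-open convention: a branch (identified by its
child node) is alive at depth ``t`` iff ``child_age <= t < parent_age``.
At ``t`` equal to the root age, where that interval is empty for every
branch, the root's child branches are returned, so a tree whose basal
splits coincide with the root still exposes its deepest lineages.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import (
    DomainError,
    NewickParseError,
    UltrametricityError,
    UnknownSpeciesError,
    ValidationError,
)

__all__ = [
    "Phylogeny",
    "Lineage",
    "LineageSlice",
    "read_newick",
    "write_newick",
    "induced_subtree",
    "slice_lineages",
    "ltt_counts",
]

DEFAULT_ULTRAMETRIC_RTOL = 1e-6


@dataclass(frozen=True)
class Lineage:
    """One branch crossing a slice depth, with its extant descendants."""

    branch: int  # child-node index identifying the branch
    parent_age: float
    child_age: float
    tips: frozenset


@dataclass(frozen=True)
class LineageSlice:
    """All branches of a tree crossing evolutionary depth ``depth`` (Myr)."""

    depth: float
    lineages: tuple

    def __len__(self):
        return len(self.lineages)

    def tip_sets(self):
        return [lin.tips for lin in self.lineages]


class Phylogeny:
    """Rooted ultrametric tree stored as parent-pointer arrays.

    Parameters
    ----------
    parent : array of int
        ``parent[i]`` is the parent node of ``i``; the root has ``-1``.
    length : array of float
        Branch length (Myr) of the branch above node ``i``; 0 for the root.
    labels : sequence of str or None
        Tip labels are mandatory and unique; internal labels optional.
    """

    def __init__(self, parent, length, labels, *, rtol=DEFAULT_ULTRAMETRIC_RTOL):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=np.float64)
        self.labels = list(labels)
        n = self.parent.size
        if self.length.size != n or len(self.labels) != n:
            raise ValidationError("parent/length/labels size mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValidationError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        if np.any(self.length < 0):
            raise ValidationError("negative branch lengths")

        self._children = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self._children[self.parent[i]].append(i)
        self.is_tip = np.array([len(c) == 0 for c in self._children])
        if not self.is_tip.any():
            raise ValidationError("tree has no tips")

        tips = np.flatnonzero(self.is_tip)
        tip_labels = [self.labels[i] for i in tips]
        if any(lab is None for lab in tip_labels):
            raise ValidationError("every tip must be labelled")
        if len(set(tip_labels)) != len(tip_labels):
            dupes = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        self.tip_indices = tips
        self.tip_labels = tip_labels
        self._tip_pos = {lab: k for k, lab in enumerate(tip_labels)}

        self._preorder = self._compute_preorder()
        self.depth_from_root = self._root_distances()
        self.age = self._ages()
        self._validate_ultrametric(rtol)
        self._tip_matrix = None

    # ------------------------------------------------------------------ build

    def _compute_preorder(self):
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self._children[v]))
        return np.array(order, dtype=np.int64)

    def _root_distances(self):
        d = np.zeros(self.parent.size)
        for v in self._preorder[1:]:
            d[v] = d[self.parent[v]] + self.length[v]
        return d

    def _ages(self):
        """Node age = max distance to a descendant tip (tips exactly 0)."""
        age = np.zeros(self.parent.size)
        for v in self._preorder[::-1]:
            if not self.is_tip[v]:
                age[v] = max(age[c] + self.length[c] for c in self._children[v])
        return age

    def _validate_ultrametric(self, rtol):
        depths = self.depth_from_root[self.tip_indices]
        t_max = depths.max()
        if t_max == 0:
            return
        ref = np.median(depths)
        dev = np.abs(depths - ref)
        worst = int(np.argmax(dev))
        if dev[worst] > rtol * t_max:
            lab = self.tip_labels[worst]
            raise UltrametricityError(
                f"tree is not ultrametric: tip {lab!r} has root-to-tip length "
                f"{depths[worst]:.6g} vs typical depth {ref:.6g} "
                f"(deviation {dev[worst]:.3g} > rtol {rtol:g})"
            )

    # ------------------------------------------------------------- properties

    @property
    def n_nodes(self):
        return self.parent.size

    @property
    def n_tips(self):
        return len(self.tip_labels)

    @property
    def root_age(self):
        """Root age T in Myr (maximum root-to-tip distance)."""
        return float(self.age[self.root])

    @property
    def total_length(self):
        """Sum of all branch lengths (Myr)."""
        return float(self.length.sum())

    def children(self, v):
        return list(self._children[v])

    @property
    def tip_matrix(self):
        """Boolean (n_nodes, n_tips) matrix: descendant tips of each node."""
        if self._tip_matrix is None:
            m = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
            m[self.tip_indices, np.arange(self.n_tips)] = True
            for v in self._preorder[::-1]:
                p = self.parent[v]
                if p >= 0:
                    m[p] |= m[v]
            self._tip_matrix = m
        return self._tip_matrix

    def tip_index(self, labels):
        """Positions of tip ``labels`` in ``tip_labels`` order."""
        missing = [l for l in labels if l not in self._tip_pos]
        if missing:
            raise UnknownSpeciesError(missing)
        return np.array([self._tip_pos[l] for l in labels], dtype=np.int64)

    def mrca(self, labels):
        """Node index of the most recent common ancestor of ``labels``."""
        pos = self.tip_index(labels)
        mask = self.tip_matrix[:, pos].all(axis=1)
        # deepest-from-root node covering all requested tips
        cands = np.flatnonzero(mask)
        return int(cands[np.argmax(self.depth_from_root[cands])])

    # ------------------------------------------------------------------- I/O

    def to_newick(self):
        """Newick string with branch lengths; internal labels preserved."""
        out = io.StringIO()

        def rec(v):
            kids = self._children[v]
            if kids:
                out.write("(")
                for k, c in enumerate(kids):
                    if k:
                        out.write(",")
                    rec(c)
                out.write(")")
            if self.labels[v] is not None:
                out.write(_quote_label(self.labels[v]))
            if v != self.root:
                out.write(f":{self.length[v]:.10g}")

        rec(self.root)
        out.write(";")
        return out.getvalue()

    def __repr__(self):
        return (
            f"<Phylogeny {self.n_tips} tips, root age "
            f"{self.root_age:.4g} Myr, total length {self.total_length:.4g} Myr>"
        )


def _quote_label(label):
    if any(ch in label for ch in " (),:;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------- I/O


def _from_dendropy(dtree, rtol):
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    length = np.zeros(len(nodes))
    labels = []
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise ValidationError(
                    "branch lengths are mandatory; found an edge without one"
                )
            length[i] = nd.edge.length
        if nd.taxon is not None:
            labels.append(nd.taxon.label)
        else:
            labels.append(nd.label)
    return Phylogeny(parent, length, labels, rtol=rtol)


def read_newick_string(text, *, rtol=DEFAULT_ULTRAMETRIC_RTOL):
    """Parse a Newick string into a validated :class:`Phylogeny`."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree, rtol)


def read_newick(path, *, rtol=DEFAULT_ULTRAMETRIC_RTOL):
    """Read a rooted ultrametric tree (branch lengths in Myr) from ``path``."""
    with open(path) as fh:
        return read_newick_string(fh.read(), rtol=rtol)


def write_newick(tree, path):
    """Write ``tree`` to ``path`` as Newick (with trailing newline)."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ----------------------------------------------------------------- queries


def induced_subtree(tree, species):
    """Subtree spanned by ``species`` plus the full path to the global root.

    Branch lengths are preserved and degree-2 internal nodes are *not*
    suppressed, so the total length of the result is the rooted Faith PD of
    the species set.
    """
    species = list(species)
    if not species:
        raise ValidationError("species set must be non-empty")
    pos = tree.tip_index(species)  # raises UnknownSpeciesError
    keep = np.zeros(tree.n_nodes, dtype=bool)
    for tip in tree.tip_indices[pos]:
        v = int(tip)
        while v >= 0 and not keep[v]:
            keep[v] = True
            v = int(tree.parent[v])
    old = np.flatnonzero(keep)
    remap = {int(o): i for i, o in enumerate(old)}
    parent = np.array(
        [remap[int(tree.parent[o])] if tree.parent[o] >= 0 else -1 for o in old],
        dtype=np.int64,
    )
    return Phylogeny(parent, tree.length[old], [tree.labels[o] for o in old])


def slice_lineages(tree, t):
    """Branches of ``tree`` alive at evolutionary depth ``t`` (Myr).

    Half-open convention ``child_age <= t < parent_age``; at ``t`` equal to
    the root age the root's child branches are returned.
    """
    T = tree.root_age
    if t < 0 or t > T:
        raise DomainError(f"slice depth {t} outside [0, {T}]")
    if t == T:
        branches = np.array(tree.children(tree.root), dtype=np.int64)
    else:
        child_age = tree.age
        parent_age = np.where(tree.parent >= 0, tree.age[tree.parent], np.inf)
        alive = (child_age <= t) & (t < parent_age)
        alive[tree.root] = False
        branches = np.flatnonzero(alive)
    tm = tree.tip_matrix
    lineages = tuple(
        Lineage(
            branch=int(b),
            parent_age=float(tree.age[tree.parent[b]]),
            child_age=float(tree.age[b]),
            tips=frozenset(
                tree.tip_labels[k] for k in np.flatnonzero(tm[b])
            ),
        )
        for b in branches
    )
    return LineageSlice(depth=float(t), lineages=lineages)


def ltt_counts(tree, times):
    """Number of lineages crossing each depth in ``times`` (Myr).

    Equals ``len(slice_lineages(tree, t))`` for every ``t``; monotonically
    non-increasing in ``t`` and equal to the tip count at ``t = 0``.
    """
    times = np.asarray(times, dtype=float)
    T = tree.root_age
    if times.size and (times.min() < 0 or times.max() > T):
        raise DomainError(f"times outside [0, {T}]")
    child_age = tree.age
    parent_age = np.where(tree.parent >= 0, tree.age[tree.parent], -np.inf)
    nonroot = np.ones(tree.n_nodes, dtype=bool)
    nonroot[tree.root] = False
    counts = np.empty(times.size, dtype=np.int64)
    n_root_children = len(tree.children(tree.root))
    for i, t in enumerate(times):
        if t == T:
            counts[i] = n_root_children
        else:
            counts[i] = int(
                np.count_nonzero(nonroot & (child_age <= t) & (t < parent_age))
            )
    return counts
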