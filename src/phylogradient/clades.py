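"""Partitioning PD among named clades by latitude and evolutionary depth.

Clades (families or superorders) are identified on the tree by the most
recent common ancestor (MRCA) of their member species; a clade's branch set
is the MRCA's subtree *plus its stem branch*.  Branches ancestral to every
clade at a level (the root spine) are genuinely unattributable under this
definition and are reported as an explicit ``(unassigned)`` category rather
than pro-rated.  Clades with a single extant member are excluded by default.

Depth truncation keeps, for each branch, only the segment older than the
slice depth, so the depth-0 partition coincides with the full-length
latitudinal partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

UNASSIGNED = "(unassigned)"

__all__ = [
    "CladeMap",
    "clade_branch_sets",
    "clade_pd_by_bin",
    "clade_pd_by_depth",
    "UNASSIGNED",
]

DEFAULT_REGIONS = {
    # approximate limits of the three biogeographic subdivisions used for
    # the Western Ghats (splits at the Palghat and Goa gaps); configurable.
    "southern": (-90.0, 13.0),
    "central": (13.0, 15.5),
    "northern": (15.5, 90.0),
}


@dataclass
class CladeMap:
    """Species -> (family, superorder) labels.

    ``table`` is indexed by species name with columns ``family`` and
    ``superorder``.
    """

    table: pd.DataFrame

    def __post_init__(self):
        for col in ("family", "superorder"):
            if col not in self.table.columns:
                raise ValidationError(f"clade map missing column {col!r}")
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate species in clade map")

    def labels(self, level):
        if level not in ("family", "superorder"):
            raise ValidationError("level must be 'family' or 'superorder'")
        return self.table[level]

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path):
        self.table.to_csv(path, index_label="species")


def _check_labelled(clade_map, species, level):
    labels = clade_map.labels(level)
    missing = [sp for sp in species if sp not in labels.index
               or pd.isna(labels.get(sp))]
    if missing:
        raise ValidationError(
            f"species without a {level} label: {missing[:10]}"
        )


def clade_branch_sets(tree, clade_map, level, species=None,
                      include_monotypic=False):
    """Branch ids (child-node indices) belonging to each clade at ``level``.

    ``species`` restricts membership (default: all labelled species that
    are tips of the tree).  Each clade's set is the MRCA subtree plus the
    MRCA's stem branch; sets are checked for disjointness.
    """
    labels = clade_map.labels(level)
    if species is None:
        species = [sp for sp in labels.index if sp in tree._tip_pos]
    _check_labelled(clade_map, species, level)
    groups = {}
    for sp in species:
        groups.setdefault(labels[sp], []).append(sp)
    sets = {}
    mrcas = {}
    for clade, members in sorted(groups.items()):
        if len(members) < 2 and not include_monotypic:
            continue
        m = tree.mrca(members)
        mrcas[clade] = m
        branches = set()
        stack = [m]
        while stack:
            v = stack.pop()
            kids = tree.children(v)
            stack.extend(kids)
            branches.update(kids)
        if m != tree.root:
            branches.add(m)  # the stem branch above the MRCA
        sets[clade] = branches
    seen = {}
    for clade, branches in sets.items():
        for b in branches:
            if b in seen:
                raise ValidationError(
                    f"clade branch sets overlap at {level} level: "
                    f"{seen[b]!r} and {clade!r} share branch {b} "
                    "(non-monophyletic labels?)"
                )
            seen[b] = clade
    return sets


def _attribution(tree, clade_sets):
    """Array mapping each node to a clade label (or UNASSIGNED)."""
    attr = np.full(tree.n_nodes, UNASSIGNED, dtype=object)
    for clade, branches in clade_sets.items():
        for b in branches:
            attr[b] = clade
    return attr


def clade_pd_by_bin(tree, pm, clade_map, level="family", *, width=1.0,
                    include_monotypic=False):
    """PD contribution of each clade within each latitudinal bin.

    For each bin the induced subtree of its species (root path included) is
    partitioned among clade branch sets; proportions normalise by the bin's
    summed clade contributions (the unassigned root spine is reported but
    excluded from the normalisation).  Long-format output with columns
    ``bin, clade, pd, proportion``.
    """
    from .depth import bin_presence_by_latitude
    from .diversity import _presence_by_branch

    _check_labelled(clade_map, pm.species, level)
    clade_sets = clade_branch_sets(
        tree, clade_map, level, species=pm.species,
        include_monotypic=include_monotypic,
    )
    attr = _attribution(tree, clade_sets)
    binned = bin_presence_by_latitude(pm, width=width)
    B, branches = _presence_by_branch(tree, _as_bin_pm(binned, pm))
    lengths = tree.length[branches]
    rows = []
    clade_names = sorted(clade_sets) + [UNASSIGNED]
    for i, bin_lo in enumerate(binned.data.index):
        present = B[i]
        contrib = {c: 0.0 for c in clade_names}
        for b_idx in np.flatnonzero(present):
            contrib[attr[branches[b_idx]]] += lengths[b_idx]
        total = sum(v for c, v in contrib.items() if c != UNASSIGNED)
        for c in clade_names:
            prop = contrib[c] / total if (total > 0 and c != UNASSIGNED) else np.nan
            rows.append({"bin": float(bin_lo), "clade": c,
                         "pd": contrib[c], "proportion": prop})
    return pd.DataFrame(rows)


def _as_bin_pm(binned, pm):
    """View the bins x species matrix as a PresenceMatrix-like object for
    the branch-presence kernel (duck-typed: needs .data/.species/.cells)."""

    class _BinPM:
        data = binned.data
        species = list(binned.data.columns)
        cells = binned.data.index

    return _BinPM


def clade_pd_by_depth(tree, pm, clade_map, level="superorder", depths=None,
                      regions=None, *, include_monotypic=False):
    """Clade shares of deep-time PD per region and evolutionary depth.

    For each named latitude interval and depth ``t``, branch segments of
    the region's induced subtree older than ``t`` are summed per clade.
    Rows where nothing is older than ``t`` are flagged with NaN
    proportions.  Output columns: ``region, depth_ma, clade, pd,
    proportion``.
    """
    from .diversity import _presence_by_branch

    _check_labelled(clade_map, pm.species, level)
    if regions is None:
        regions = DEFAULT_REGIONS
    if depths is None:
        T = tree.root_age
        depths = [0.0] + list(np.arange(10.0, T, 10.0)) + [T]
    clade_sets = clade_branch_sets(
        tree, clade_map, level, species=pm.species,
        include_monotypic=include_monotypic,
    )
    attr = _attribution(tree, clade_sets)
    B, branches = _presence_by_branch(tree, pm)
    child_age = tree.age[branches]
    parent_age = tree.age[tree.parent[branches]]
    lats = pm.grid.lats().to_numpy(float)
    clade_names = sorted(clade_sets) + [UNASSIGNED]
    rows = []
    for region, (lo, hi) in regions.items():
        in_region = (lats > lo) & (lats <= hi)
        present = B[in_region].any(axis=0) if in_region.any() else np.zeros(len(branches), bool)
        for t in depths:
            seg = np.maximum(0.0, parent_age - np.maximum(child_age, float(t)))
            seg = np.where(present, seg, 0.0)
            contrib = {c: 0.0 for c in clade_names}
            for b_idx in np.flatnonzero(seg > 0):
                contrib[attr[branches[b_idx]]] += seg[b_idx]
            total = sum(v for c, v in contrib.items() if c != UNASSIGNED)
            for c in clade_names:
                prop = (contrib[c] / total
                        if (total > 0 and c != UNASSIGNED) else np.nan)
                rows.append({"region": region, "depth_ma": float(t),
                             "clade": c, "pd": contrib[c], "proportion": prop})
    return pd.DataFrame(rows)
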