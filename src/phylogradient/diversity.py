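"""Per-cell richness-dimension diversity indices: SR, PD, PE and TILD.

All indices are computed from one shared construction: the induced subtree
of a cell's species including the path to the global root (rooted-PD
convention, switchable for PD).

* SR  -- species richness, the row sum of the presence matrix.
* PD  -- Faith's phylogenetic diversity, total branch length (Myr) of the
  cell's induced subtree.
* PE  -- phylogenetic endemism: each branch's length divided by the number
  of grid cells occupied by its descendant clade, summed over branches
  present in the cell.  Summed over all cells PE recovers the total tree
  length exactly (each branch contributes length/range in range cells).
* TILD -- time-integrated lineage diversity, the exact integral over
  [0, T] (T = global root age) of the natural log of the cell subtree's
  lineage count through time, evaluated as a sum over inter-node intervals.

Also hosts the two occurrence-cleaning steps that precede index
calculation: dropping species-poor cells and clipping each species to its
observed latitudinal extent.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptyResultError, UnknownSpeciesError, ValidationError
from .grid import PresenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "species_richness",
    "faith_pd",
    "phylo_endemism",
    "tild",
    "diversity_table",
    "filter_low_richness_cells",
    "clip_to_observed_latitudes",
]


def _presence_by_branch(tree, pm):
    """Boolean (n_cells, n_branches) matrix: branch has >= 1 descendant
    species present in the cell.  Branch order = non-root node index order."""
    missing = [sp for sp in pm.species if sp not in tree._tip_pos]
    if missing:
        raise UnknownSpeciesError(missing)
    branches = np.array([v for v in range(tree.n_nodes) if v != tree.root])
    pos = tree.tip_index(pm.species)
    desc = tree.tip_matrix[np.ix_(branches, pos)]  # branches x species-in-pm
    pres = pm.data.to_numpy(dtype=bool)  # cells x species
    return pres @ desc.T, branches


def species_richness(pm):
    """Species count per grid cell (Series indexed by cell id)."""
    return pm.data.sum(axis=1).astype(int).rename("sr")


def faith_pd(tree, pm, *, include_root_path=True):
    """Faith PD (Myr) per cell.

    With ``include_root_path`` (default) PD is the total branch length of
    the induced subtree spanning the cell's species *and* the global root;
    a single-species cell then scores that tip's root distance.  With the
    flag off, branches ancestral to the cell's MRCA are excluded (classic
    minimum-spanning convention; single-species cells score 0).
    """
    B, branches = _presence_by_branch(tree, pm)
    lengths = tree.length[branches]
    if include_root_path:
        pd_vals = B @ lengths
    else:
        pos = tree.tip_index(pm.species)
        desc = tree.tip_matrix[np.ix_(branches, pos)]
        counts = pm.data.to_numpy() @ desc.T.astype(np.int64)  # cells x branches
        sr = pm.data.to_numpy().sum(axis=1, keepdims=True)
        below_mrca = B & (counts < sr)
        pd_vals = below_mrca @ lengths
    return pd.Series(pd_vals, index=pm.cells, name="pd")


def phylo_endemism(tree, pm, *, min_range_cells=0):
    """Phylogenetic endemism (Myr) per cell.

    Every species must occupy at least one cell (enforced by
    :class:`PresenceMatrix`).  PE is highly sensitive to tiny ranges, so
    ``min_range_cells`` optionally drops species occupying fewer cells
    before weighting (the usual protocol when point endemics lack reliable
    range estimates); the conservation identity (sum of PE over cells =
    total tree length) holds only with no exclusions.
    """
    if min_range_cells > 0:
        keep = [sp for sp in pm.species
                if pm.data[sp].sum() >= min_range_cells]
        if not keep:
            raise ValidationError(
                f"no species occupy >= {min_range_cells} cells"
            )
        if len(keep) < len(pm.species):
            logger.info("PE: excluding %d narrow-range species",
                        len(pm.species) - len(keep))
            pm = PresenceMatrix(pm.data[keep], pm.grid)
    B, branches = _presence_by_branch(tree, pm)
    branch_range = B.sum(axis=0)  # cells occupied by each branch's clade
    # branches whose descendants are all absent from the matrix are not
    # part of any cell's subtree and carry zero weight
    weights = np.where(branch_range > 0,
                       tree.length[branches] / np.maximum(branch_range, 1),
                       0.0)
    return pd.Series(B @ weights, index=pm.cells, name="pe")


def tild(tree, pm):
    """Time-integrated lineage diversity per cell: integral of ln n(t).

    n(t) is the number of branches of the cell's induced subtree (root path
    included) crossing depth t.  The integral is exact: a sum of
    (interval width) x ln(lineage count) over the intervals between the
    subtree's node ages, clipped to [0, T].
    """
    B, branches = _presence_by_branch(tree, pm)
    child_age = tree.age[branches]
    parent_age = tree.age[tree.parent[branches]]
    T = tree.root_age
    out = np.zeros(B.shape[0])
    for i in range(B.shape[0]):
        sel = B[i]
        if not sel.any():
            continue
        starts = child_age[sel]
        ends = parent_age[sel]
        events = np.unique(np.concatenate([starts, ends, [0.0, T]]))
        events = events[(events >= 0) & (events <= T)]
        acc = 0.0
        for a, b in zip(events[:-1], events[1:]):
            n = int(np.count_nonzero((starts <= a) & (ends >= b)))
            if n > 1:
                acc += (b - a) * np.log(n)
        out[i] = acc
    return pd.Series(out, index=pm.cells, name="tild")


def diversity_table(tree, pm, *, include_root_path=True):
    """Per-cell table of SR, PD, PE and TILD (one row per grid cell)."""
    t = pd.concat(
        [
            species_richness(pm),
            faith_pd(tree, pm, include_root_path=include_root_path),
            phylo_endemism(tree, pm),
            tild(tree, pm),
        ],
        axis=1,
    )
    t.index.name = "cell"
    return t


def filter_low_richness_cells(pm, min_sr=10):
    """Drop cells with fewer than ``min_sr`` species.

    Species columns emptied by the filter are dropped with a warning.
    Raises :class:`EmptyResultError` if no cell survives.
    """
    sr = pm.data.sum(axis=1)
    keep = sr >= min_sr
    if not keep.any():
        raise EmptyResultError(
            f"all {len(sr)} cells have richness < {min_sr}; nothing retained"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("richness filter: removed %d of %d cells (SR < %d)",
                    dropped, len(sr), min_sr)
    data = pm.data.loc[keep]
    dropped_sp = [sp for sp in data.columns if data[sp].sum() == 0]
    if dropped_sp:
        logger.warning("richness filter emptied %d species columns: %s",
                       len(dropped_sp), dropped_sp[:10])
        data = data[[sp for sp in data.columns if data[sp].sum() > 0]]
    return PresenceMatrix(data, pm.grid.subset(data.index))


def clip_to_observed_latitudes(pm, occurrences: Mapping):
    """Zero out presences outside each species' observed latitude interval.

    ``occurrences`` maps species name -> iterable of observed latitudes
    (degrees N).  Presences in cells whose centroid latitude falls outside
    [min obs, max obs] (inclusive) are removed.
    """
    missing = [sp for sp in pm.species if sp not in occurrences
               or len(list(occurrences[sp])) == 0]
    if missing:
        raise ValidationError(
            f"species without observed latitudes: {missing[:10]}"
        )
    lats = pm.grid.lats().to_numpy(float)
    data = pm.data.copy()
    n_removed = 0
    for sp in pm.species:
        obs = np.asarray(list(occurrences[sp]), dtype=float)
        inside = (lats >= obs.min()) & (lats <= obs.max())
        col = data[sp].to_numpy()
        n_removed += int((col & ~inside).sum())
        data[sp] = col * inside
    if n_removed:
        logger.info("latitudinal clipping removed %d presences", n_removed)
    dropped_sp = [sp for sp in data.columns if data[sp].sum() == 0]
    if dropped_sp:
        logger.warning("clipping emptied %d species columns: %s",
                       len(dropped_sp), dropped_sp[:10])
        data = data[[sp for sp in data.columns if data[sp].sum() > 0]]
    return PresenceMatrix(data, pm.grid)
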