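"""Latitudinal structure of lineages at sliced evolutionary depths.

Implements the metacommunity-style nestedness test: species presences are
collapsed into latitudinal bins, lineages crossing a given evolutionary
depth inherit the union of their descendants' bin presences, and the
observed number of pairwise lineage replacements along the ordered gradient
is compared against a resampling null ("r1": each bin keeps its observed
lineage richness, lineages are drawn without replacement with probability
proportional to their overall occurrence frequencies).  Observed turnover
below the null mean indicates nestedness; above it, turnover.

The replacement count follows the classic metacommunity turnover statistic:
for every pair of lineages (i, j), (number of bins holding i but not j)
times (number of bins holding j but not i), summed over pairs.  Counting
over all bin pairs is the default; an adjacent-bins-only variant and an
optional embedded-absence filling step (making each lineage's occupied bins
contiguous before counting) are exposed as flags.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ValidationError
from .tree import slice_lineages

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedMatrix",
    "TurnoverResult",
    "RestrictedCounts",
    "bin_presence_by_latitude",
    "lineage_presence_at_depth",
    "lineage_latitudinal_ranges",
    "count_restricted",
    "restricted_table",
    "turnover_observed",
    "fill_embedded_absences",
    "r1_resample",
    "r1_null",
    "nestedness_test",
    "turnover_table",
]


@dataclass
class BinnedMatrix:
    """Ordered (south -> north) latitudinal bins x columns binary matrix.

    ``data`` is indexed by bin lower edge (degrees N, strictly increasing);
    columns are species or lineage identifiers.  ``depth`` is the
    evolutionary depth (Myr) for lineage-level matrices, None for species.
    """

    data: pd.DataFrame
    width: float = 1.0
    depth: float = None

    def __post_init__(self):
        edges = self.data.index.to_numpy(float)
        if edges.size and np.any(np.diff(edges) <= 0):
            raise ValidationError("bins must be strictly increasing in latitude")

    @property
    def n_bins(self):
        return self.data.shape[0]

    @property
    def n_columns(self):
        return self.data.shape[1]


@dataclass(frozen=True)
class TurnoverResult:
    """One nestedness-test row (one evolutionary depth)."""

    depth: float
    n_lineages: int
    n_bins: int
    observed: int
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float
    p_normal: float
    verdict: str
    replicates: int
    seed: int


@dataclass(frozen=True)
class RestrictedCounts:
    """Lineage totals and latitude-restricted counts at one depth."""

    depth: float
    total: int
    south_only: int  # entire occupied range at latitude <= threshold
    north_only: int  # entire occupied range at latitude > threshold
    threshold: float = 13.0

    @property
    def south_fraction(self):
        """Share of lineages wholly south of the threshold (0-1)."""
        return self.south_only / self.total if self.total else math.nan

    @property
    def south_north_ratio(self):
        """South-restricted over north-restricted lineage richness."""
        return (self.south_only / self.north_only
                if self.north_only else math.inf)


# ------------------------------------------------------------------ binning


def bin_presence_by_latitude(pm, width=1.0):
    """Collapse cells into latitudinal bins of ``width`` degrees.

    Bins are aligned to multiples of ``width`` (half-open, ``[lo, lo+w)``)
    and ordered south to north; bins containing no grid cell are dropped.
    A species is present in a bin iff present in >= 1 cell whose centroid
    falls in it.
    """
    lats = pm.grid.lats().to_numpy(float)
    if lats.size == 0:
        raise ValidationError("empty grid")
    edges = np.floor(lats / width) * width
    frame = pm.data.copy()
    frame["_bin"] = edges
    binned = (frame.groupby("_bin").sum() > 0).astype(np.int8)
    binned = binned.sort_index()
    binned.index.name = "lat_bin"
    return BinnedMatrix(binned, width=width, depth=None)


def lineage_presence_at_depth(tree, binned, t):
    """Bins x lineages matrix at depth ``t``: a lineage occupies a bin iff
    any descendant species does.  Columns are branch ids of the slice."""
    sl = slice_lineages(tree, t)
    cols = {}
    species = set(binned.data.columns)
    for lin in sl.lineages:
        members = [sp for sp in lin.tips if sp in species]
        if not members:
            continue
        cols[lin.branch] = (binned.data[members].sum(axis=1) > 0).astype(np.int8)
    data = pd.DataFrame(cols, index=binned.data.index)
    return BinnedMatrix(data, width=binned.width, depth=float(t))


def lineage_latitudinal_ranges(tree, pm, t):
    """Min/max occupied centroid latitude per lineage at depth ``t``.

    Returns a DataFrame indexed by branch id with columns
    ``min_lat, max_lat, n_species`` (lineages with no presence are omitted).
    """
    sl = slice_lineages(tree, t)
    lats = pm.grid.lats().to_numpy(float)
    rows = {}
    species = set(pm.species)
    for lin in sl.lineages:
        members = [sp for sp in lin.tips if sp in species]
        if not members:
            continue
        occupied = pm.data[members].to_numpy().sum(axis=1) > 0
        if not occupied.any():
            continue
        rows[lin.branch] = (
            float(lats[occupied].min()),
            float(lats[occupied].max()),
            len(members),
        )
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["min_lat", "max_lat", "n_species"]
    )
    out.index.name = "lineage"
    return out.sort_index()


def count_restricted(tree, pm, t, threshold=13.0):
    """Lineages wholly south (max lat <= threshold) or wholly north
    (min lat > threshold) of a latitude threshold, at depth ``t``."""
    ranges = lineage_latitudinal_ranges(tree, pm, t)
    south = int((ranges["max_lat"] <= threshold).sum())
    north = int((ranges["min_lat"] > threshold).sum())
    return RestrictedCounts(
        depth=float(t),
        total=len(ranges),
        south_only=south,
        north_only=north,
        threshold=threshold,
    )


def restricted_table(tree, pm, depths, threshold=13.0):
    """Table of restricted-lineage counts, one row per depth."""
    rows = [count_restricted(tree, pm, t, threshold) for t in depths]
    return pd.DataFrame(
        {
            "depth_ma": [r.depth for r in rows],
            "total_lineages": [r.total for r in rows],
            "south_only": [r.south_only for r in rows],
            "north_only": [r.north_only for r in rows],
        }
    )


# ----------------------------------------------------------------- turnover


def fill_embedded_absences(mat):
    """Make each column contiguous over the ordered bins (range filling)."""
    out = np.asarray(mat, dtype=np.int8).copy()
    for j in range(out.shape[1]):
        hits = np.flatnonzero(out[:, j])
        if hits.size:
            out[hits[0]: hits[-1] + 1, j] = 1
    return out


def _replacements_all_pairs(m):
    """Sum over column pairs of (#rows i-only) x (#rows j-only)."""
    m = m.astype(np.int64)
    c = m.T @ (1 - m)  # c[i, j] = rows with i present, j absent
    prod = c * c.T
    return int(prod.sum() // 2)


def _replacements_adjacent(m):
    total = 0
    for s in range(m.shape[0] - 1):
        a = m[s].astype(bool)
        b = m[s + 1].astype(bool)
        total += int((a & ~b).sum()) * int((b & ~a).sum())
    return total


def turnover_observed(blm, *, fill_embedded=False, pairs="all"):
    """Number of pairwise lineage replacements in an ordered binary matrix.

    ``blm`` may be a :class:`BinnedMatrix`, DataFrame or 2-D array with rows
    ordered south to north.  With ``fill_embedded`` each column is first
    made contiguous over its occupied bin range.  ``pairs`` selects whether
    replacements are counted over all bin pairs (default, the metacommunity
    convention) or adjacent bins only.
    """
    m = blm.data if isinstance(blm, BinnedMatrix) else blm
    m = np.asarray(m, dtype=np.int8)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("turnover needs >= 2 bins and >= 2 lineages")
    if fill_embedded:
        m = fill_embedded_absences(m)
    if m.all():
        logger.info("turnover: matrix is all-ones (degenerate), returning 0")
        return 0
    if pairs == "all":
        return _replacements_all_pairs(m)
    if pairs == "adjacent":
        return _replacements_adjacent(m)
    raise ValueError(f"pairs must be 'all' or 'adjacent', got {pairs!r}")


# ---------------------------------------------------------------- r1 null


def r1_resample(m, rng):
    """One r1 replicate: every row keeps its richness and draws that many
    distinct columns with probability proportional to column totals.

    Weighted sampling without replacement via exponential keys
    (Efraimidis-Spirakis), equivalent in distribution to sequential
    probability-proportional draws.
    """
    m = np.asarray(m, dtype=np.int8)
    n_rows, n_cols = m.shape
    weights = m.sum(axis=0).astype(float)
    if np.any(weights <= 0):
        raise ValidationError("r1 null: every column needs >= 1 presence")
    richness = m.sum(axis=1)
    if richness.max() > n_cols:
        raise ValidationError("row richer than the number of columns")
    out = np.zeros_like(m)
    for i in range(n_rows):
        k = int(richness[i])
        if k == 0:
            continue
        if k == n_cols:
            out[i] = 1
            continue
        keys = rng.exponential(size=n_cols) / weights
        chosen = np.argpartition(keys, k)[:k]
        out[i, chosen] = 1
    return out


def r1_null(blm, replicates=1000, seed=0, *, fill_embedded=False, pairs="all"):
    """Null turnover distribution under the r1 model (seeded, reproducible).

    Each replicate resamples the matrix and scores it with the same
    turnover settings as the observed statistic.
    """
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    m = blm.data.to_numpy() if isinstance(blm, BinnedMatrix) else np.asarray(blm)
    rng = np.random.default_rng(seed)
    vals = np.empty(replicates, dtype=np.int64)
    for r in range(replicates):
        null = r1_resample(m, rng)
        if fill_embedded:
            null = fill_embedded_absences(null)
        if pairs == "all":
            vals[r] = _replacements_all_pairs(null)
        else:
            vals[r] = _replacements_adjacent(null)
    return vals


# ------------------------------------------------------------ the test


def nestedness_test(
    tree,
    pm,
    depths=None,
    *,
    width=1.0,
    replicates=1000,
    seed=0,
    fill_embedded=False,
    pairs="all",
    alpha=0.05,
):
    """Leibold-Mikkelson turnover vs r1 null at each evolutionary depth.

    ``depths`` defaults to 10 Myr steps from 10 to the root age (the root
    age itself included).  Empirical p is one-sided in the nestedness
    direction, ``(#{null <= observed} + 1) / (replicates + 1)``; a z-score
    and its two-sided normal p are reported alongside.  Verdicts:
    ``nested`` (observed < null mean, p_empirical < alpha), ``turnover``
    (observed > null mean and the analogous upper-tail p < alpha),
    ``indeterminate`` otherwise, or ``untestable`` when fewer than two
    lineages are present or the null is degenerate.

    Returns a list of :class:`TurnoverResult`; per-depth seeds are spawned
    deterministically from ``seed`` and recorded in the results.
    """
    T = tree.root_age
    if depths is None:
        depths = list(np.arange(10.0, T, 10.0))
        if not depths or depths[-1] < T:
            depths.append(T)
    binned = bin_presence_by_latitude(pm, width=width)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(depths)) % (2**31)
    results = []
    for t, child_seed in zip(depths, child_seeds):
        blm = lineage_presence_at_depth(tree, binned, t)
        n_lin = blm.n_columns
        child_seed = int(child_seed)
        if n_lin < 2 or blm.n_bins < 2:
            results.append(
                TurnoverResult(float(t), n_lin, blm.n_bins, 0, math.nan,
                               math.nan, math.nan, math.nan, math.nan,
                               "untestable", replicates, child_seed)
            )
            continue
        obs = turnover_observed(blm, fill_embedded=fill_embedded, pairs=pairs)
        null = r1_null(blm, replicates, child_seed,
                       fill_embedded=fill_embedded, pairs=pairs)
        mean = float(null.mean())
        sd = float(null.std(ddof=1)) if replicates > 1 else math.nan
        p_lower = (int((null <= obs).sum()) + 1) / (replicates + 1)
        p_upper = (int((null >= obs).sum()) + 1) / (replicates + 1)
        if sd and sd > 0:
            z = (obs - mean) / sd
            p_norm = 2 * stats.norm.sf(abs(z))
        else:
            z, p_norm = math.nan, math.nan
        if sd == 0 or mean == obs == 0:
            verdict = "untestable"
        elif obs < mean and p_lower < alpha:
            verdict = "nested"
        elif obs > mean and p_upper < alpha:
            verdict = "turnover"
        else:
            verdict = "indeterminate"
        results.append(
            TurnoverResult(float(t), n_lin, blm.n_bins, obs, mean, sd,
                           z, p_lower, p_norm, verdict, replicates, child_seed)
        )
    return results


def turnover_table(results):
    """Tidy DataFrame view of :func:`nestedness_test` output."""
    return pd.DataFrame(
        {
            "depth_ma": [r.depth for r in results],
            "n_lineages": [r.n_lineages for r in results],
            "n_bins": [r.n_bins for r in results],
            "observed": [r.observed for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "z": [r.z for r in results],
            "p_empirical": [r.p_empirical for r in results],
            "p_normal": [r.p_normal for r in results],
            "verdict": [r.verdict for r in results],
            "replicates": [r.replicates for r in results],
            "seed": [r.seed for r in results],
        }
    )
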