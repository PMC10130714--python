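"""Synthetic trees, landscapes and species ranges for the full pipeline.

The generator emulates the statistical structure of a tropical mountain
latitudinal gradient of the Western Ghats type: a deep (~135 Myr) woody
plant phylogeny with three very unequal basal clades, a south-to-north
gradient of increasing seasonal drought (climatic water deficit, CWD), and
species ranges produced by phylogenetically conserved drought tolerance, so
that northern assemblages are nested subsets of southern ones.

Two tree models are available.  ``"ltt_profile"`` (default) draws merge
ages by inverting a log-linear interpolation of the lineage-through-time
curve published for Western Ghats evergreen woody plants (scaled to the
requested tip count), which is strongly "deep-heavy" compared to a constant
-rate tree: many lineages already exist by 120-90 Ma.  ``"yule"`` is a
classic constant-rate pure-birth tree conditioned on the tip count and
rescaled to the root age.

Drought tolerance evolves by Brownian motion on log(-threshold), bounded by
hierarchically inherited clade-level caps: each basal clade carries a
physiological limit on how drought-tolerant its members can become, and
each lineage crossing the "major clade" depth (default 120 Ma) tightens
that limit again (the largest major clade of each basal clade keeps the
ancestral limit).  Without such caps the maximum over hundreds of unbounded
Brownian tips would make every deep lineage span the whole gradient,
erasing exactly the deep-time range structure the analysis studies.

All outputs are byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clades import CladeMap
from .errors import DomainError, ValidationError
from .grid import PresenceMatrix, SiteGrid
from .tree import Phylogeny, slice_lineages
from .environment import tri as tri_grid

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "Landscape",
    "SimulatedRanges",
    "SyntheticDataset",
    "ToyFixture",
    "simulate_tree",
    "simulate_landscape",
    "simulate_ranges",
    "simulate_dataset",
    "make_toy_fixture",
    "WG_LTT_PROFILE",
]

# Published lineage-through-time counts for Western Ghats evergreen woody
# plants (lineage count at evolutionary depth in Ma), used as the default
# shape of the simulated tree's merge-age distribution.
WG_LTT_PROFILE = (
    (0.0, 470.0),
    (10.0, 337.0),
    (30.0, 153.0),
    (60.0, 85.0),
    (90.0, 54.0),
    (120.0, 12.0),
    (135.0, 3.0),
)


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic generator."""

    seed: int = 0
    n_species: int = 300
    root_age: float = 135.0
    tree_model: str = "ltt_profile"  # or "yule"
    n_basal: int = 3
    basal_fractions: tuple = (0.72, 0.18, 0.10)
    # least-negative CWD (mm/yr) members of each basal clade can tolerate;
    # ordered to match basal clades by decreasing size
    basal_caps: tuple = (-1500.0, -750.0, -530.0)
    major_clade_depth: float = 120.0
    cap_floor: float = 250.0  # smallest |cap| a major clade may draw
    bm_rate: float = 0.01  # Brownian variance per Myr on log(-threshold)
    bm_root: float = math.log(450.0)
    age_jitter: float = 0.02

    grid_rows: int = 11
    grid_cols: int = 4
    lat_extent: tuple = (8.0, 19.0)
    lon_extent: tuple = (75.0, 76.0)
    resolution_km: float = 10.0
    cwd_south: float = -100.0
    cwd_north: float = -900.0
    cwd_noise: float = 15.0
    map_south: float = 5000.0
    map_north: float = 1500.0
    map_noise: float = 150.0
    elev_base: float = 500.0
    elev_relief: float = 900.0
    elev_noise: float = 120.0

    mode: str = "nested"  # or "turnover"
    dropout: float = 0.02  # probability a realised presence is lost
    band_halfwidth: float = 150.0  # turnover mode: CWD niche half-width (mm)
    band_halfwidth_sd: float = 0.4  # lognormal sd of the half-width

    family_depth: float = 60.0
    superorder_depth: float = 120.0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValidationError("n_species must be >= 2")
        if self.n_basal < 2:
            raise ValidationError("n_basal must be >= 2")
        if len(self.basal_fractions) != self.n_basal or \
                len(self.basal_caps) != self.n_basal:
            raise ValidationError(
                "basal_fractions and basal_caps must have n_basal entries"
            )
        if abs(sum(self.basal_fractions) - 1.0) > 1e-9:
            raise ValidationError("basal_fractions must sum to 1")
        if self.cwd_south > 0 or self.cwd_north > 0:
            raise ValidationError("CWD endpoints must be <= 0")
        if self.mode not in ("nested", "turnover"):
            raise ValidationError("mode must be 'nested' or 'turnover'")
        if self.grid_rows < 2 or self.grid_cols < 1:
            raise ValidationError("grid must have >= 2 rows and >= 1 column")

    def _rng(self, stream):
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), stream])
        )


@dataclass
class Landscape:
    grid: SiteGrid
    env: pd.DataFrame  # per cell: cwd, map, tri
    elevation: np.ndarray  # rows x cols
    cwd_grid: np.ndarray  # rows x cols


@dataclass
class SimulatedRanges:
    presence: PresenceMatrix
    observed_latitudes: dict  # species -> array of occupied-cell latitudes
    species: pd.DataFrame  # per-species tolerances and realised limits


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    tree: Phylogeny
    landscape: Landscape
    ranges: SimulatedRanges
    clade_map: CladeMap


# ------------------------------------------------------------------- trees


def _profile_merge_ages(n, root_age, n_basal, rng, jitter):
    """Ages (ascending) of the n - n_basal pair merges below the root,
    drawn from the scaled published LTT curve."""
    ts = np.array([p[0] for p in WG_LTT_PROFILE]) * (root_age / 135.0)
    cs = np.array([p[1] for p in WG_LTT_PROFILE])
    ln_target = np.log(n * cs / cs[0])  # ln expected count at each knot

    def invert(ln_k):
        # age at which the ln-count curve crosses ln_k (curve decreasing)
        if ln_k >= ln_target[0]:
            return 0.0
        if ln_k <= ln_target[-1]:
            return root_age * 0.995
        i = int(np.searchsorted(-ln_target, -ln_k)) - 1
        f = (ln_target[i] - ln_k) / (ln_target[i] - ln_target[i + 1])
        return ts[i] + f * (ts[i + 1] - ts[i])

    ages = np.array([invert(math.log(k - 0.5))
                     for k in range(n, n_basal, -1)])
    if jitter > 0:
        ages = ages * np.exp(rng.normal(0.0, jitter, size=ages.size))
    ages = np.clip(ages, 1e-6, root_age * 0.999)
    return np.sort(ages)


def _yule_merge_ages(n, root_age, rng):
    """Pair-merge ages of a pure-birth tree conditioned on n tips,
    rescaled so the root (oldest merge) sits at ``root_age``."""
    waits = rng.exponential(1.0 / np.arange(2, n + 1))  # leaving k lineages
    split_times = np.concatenate([[0.0], np.cumsum(waits[:-1])])  # s_2..s_n
    height = split_times[-1] + waits[-1]
    ages = (height - split_times) * (root_age / height)
    ages[0] = root_age  # exact
    return np.sort(ages[1:]), True  # root merge handled by assembler


def _assemble_tree(n, merge_ages, clade_sizes, root_age, rng):
    """Random-join topology: tips partitioned into basal clades, merges
    assigned young-to-old with probability proportional to (count - 1),
    clade roots joined at ``root_age``."""
    n_basal = len(clade_sizes)
    labels = [f"sp{i + 1:04d}" for i in range(n)]
    parent = [-1] * n
    length = [0.0] * n
    node_age = [0.0] * n
    node_labels = list(labels)
    active = []
    start = 0
    for size in clade_sizes:
        active.append(list(range(start, start + size)))
        start += size

    for age in merge_ages:
        counts = np.array([len(a) - 1 for a in active], dtype=float)
        if counts.sum() <= 0:
            raise ValidationError("more merges than tips allow")
        c = rng.choice(n_basal, p=counts / counts.sum())
        i, j = rng.choice(len(active[c]), size=2, replace=False)
        a, b = active[c][i], active[c][j]
        new = len(parent)
        parent.append(-1)
        length.append(0.0)
        node_age.append(float(age))
        node_labels.append(None)
        for child in (a, b):
            parent[child] = new
            length[child] = float(age) - node_age[child]
        active[c] = [x for x in active[c] if x not in (a, b)] + [new]

    roots = [x for a in active for x in a]
    if len(roots) == 1:
        root = roots[0]
        node_age[root] = root_age  # degenerate, should not happen
    else:
        root = len(parent)
        parent.append(-1)
        length.append(0.0)
        node_age.append(root_age)
        node_labels.append(None)
        for r in roots:
            parent[r] = root
            length[r] = root_age - node_age[r]
    return Phylogeny(parent, length, node_labels)


def _clade_sizes(n, fractions):
    sizes = [int(round(f * n)) for f in fractions]
    sizes[0] += n - sum(sizes)
    if min(sizes) < 1:
        raise ValidationError("basal fractions give an empty basal clade")
    return sizes


def simulate_tree(cfg):
    """Seeded ultrametric tree with ``cfg.n_species`` tips and root age
    ``cfg.root_age`` (Myr)."""
    rng = cfg._rng(1)
    n = cfg.n_species
    if cfg.tree_model == "yule":
        ages, _ = _yule_merge_ages(n, cfg.root_age, rng)
        return _assemble_tree(n, ages, [n], cfg.root_age, rng)
    if cfg.tree_model == "ltt_profile":
        sizes = _clade_sizes(n, cfg.basal_fractions)
        ages = _profile_merge_ages(n, cfg.root_age, cfg.n_basal, rng,
                                   cfg.age_jitter)
        return _assemble_tree(n, ages, sizes, cfg.root_age, rng)
    raise ValidationError(f"unknown tree_model {cfg.tree_model!r}")


# --------------------------------------------------------------- landscape


def simulate_landscape(cfg):
    """Grid, environment table and elevation raster for the gradient.

    CWD interpolates linearly from the wet south end to the dry north end
    (plus cell-level noise, always <= -10 mm/yr); MAP decreases northward;
    elevation is a smooth west-east ridge plus roughness so TRI varies.
    """
    rng = cfg._rng(2)
    rows, cols = cfg.grid_rows, cfg.grid_cols
    lat_lo, lat_hi = cfg.lat_extent
    lon_lo, lon_hi = cfg.lon_extent
    lat_step = (lat_hi - lat_lo) / rows
    lats = lat_lo + (np.arange(rows) + 0.5) * lat_step
    lons = lon_lo + (np.arange(cols) + 0.5) * (lon_hi - lon_lo) / cols

    frac = (lats - lats[0]) / (lats[-1] - lats[0])
    cwd_rows = cfg.cwd_south + frac * (cfg.cwd_north - cfg.cwd_south)
    cwd = cwd_rows[:, None] + rng.normal(0.0, cfg.cwd_noise, (rows, cols)) \
        if cfg.cwd_noise > 0 else np.tile(cwd_rows[:, None], (1, cols))
    cwd = np.minimum(cwd, -10.0)

    map_rows = cfg.map_south + frac * (cfg.map_north - cfg.map_south)
    map_ = map_rows[:, None] + (
        rng.normal(0.0, cfg.map_noise, (rows, cols)) if cfg.map_noise > 0
        else 0.0
    )
    map_ = np.maximum(map_, 0.0)

    ridge = (cols - 1) / 2.0
    j = np.arange(cols)
    elev = (
        cfg.elev_base
        + cfg.elev_relief * np.exp(-((j - ridge) / max(cols / 3.0, 1.0)) ** 2)[None, :]
        + 30.0 * frac[:, None]
    )
    if cfg.elev_noise > 0:
        elev = elev + rng.normal(0.0, cfg.elev_noise, (rows, cols))
    tri_vals = tri_grid(elev)

    cell_ids = [f"c{r:02d}{c:02d}" for r in range(rows) for c in range(cols)]
    table = pd.DataFrame(
        {
            "lat": np.repeat(lats, cols),
            "lon": np.tile(lons, rows),
        },
        index=pd.Index(cell_ids, name="cell"),
    )
    grid = SiteGrid(table, resolution_km=cfg.resolution_km,
                    lat_extent=cfg.lat_extent)
    env = pd.DataFrame(
        {
            "cwd": cwd.ravel(),
            "map": map_.ravel(),
            "tri": tri_vals.ravel(),
        },
        index=table.index,
    )
    return Landscape(grid=grid, env=env, elevation=elev, cwd_grid=cwd)


# ------------------------------------------------------------------ ranges


def _basal_clade_of_tips(tree):
    """Series tip label -> basal clade rank (0 = largest root child)."""
    kids = tree.children(tree.root)
    tm = tree.tip_matrix
    sizes = [int(tm[k].sum()) for k in kids]
    order = np.argsort(sizes)[::-1]
    out = {}
    for rank, ki in enumerate(order):
        for pos in np.flatnonzero(tm[kids[ki]]):
            out[tree.tip_labels[pos]] = rank
    return pd.Series(out)


def _brownian_log_tolerance(tree, cfg, rng):
    x = np.zeros(tree.n_nodes)
    x[tree.root] = cfg.bm_root
    for v in tree._preorder[1:]:
        sd = math.sqrt(cfg.bm_rate * max(tree.length[v], 0.0))
        x[v] = x[tree.parent[v]] + (rng.normal(0.0, sd) if sd > 0 else 0.0)
    return pd.Series(x[tree.tip_indices], index=tree.tip_labels)


def _major_clade_caps(tree, cfg, rng):
    """Per-tip drought cap from hierarchical clade limits (CWD mm/yr)."""
    basal_rank = _basal_clade_of_tips(tree)
    depth = min(cfg.major_clade_depth, tree.root_age * 0.999)
    sl = slice_lineages(tree, depth)
    # group major lineages by basal clade
    per_basal = {}
    for lin in sl.lineages:
        any_tip = next(iter(lin.tips))
        per_basal.setdefault(int(basal_rank[any_tip]), []).append(lin)
    caps = pd.Series(index=tree.tip_labels, dtype=float)
    for rank, lineages in sorted(per_basal.items()):
        basal_cap = abs(cfg.basal_caps[rank])
        lineages = sorted(lineages, key=lambda l: -len(l.tips))
        for k, lin in enumerate(lineages):
            if k == 0:
                mag = basal_cap  # main line keeps the ancestral limit
            else:
                lo, hi = math.log(cfg.cap_floor), math.log(basal_cap)
                mag = math.exp(rng.uniform(min(lo, hi), max(lo, hi)))
            for sp in lin.tips:
                caps[sp] = -mag
    return caps


def simulate_ranges(tree, landscape, cfg):
    """Species ranges on the landscape under conserved drought tolerance.

    Nested mode: a species occupies every cell at least as wet as its
    threshold (cell CWD >= threshold), so tolerant species span the
    gradient and intolerant ones are confined to the wet south.  Turnover
    mode: each species occupies a band of the CWD axis around a Brownian
    niche centre, producing replacement along the gradient.  Realised
    presences are then thinned by ``cfg.dropout`` (detection/occupancy
    noise); a species losing every cell keeps its single wettest cell.
    """
    rng = cfg._rng(3)
    cwd = landscape.env["cwd"].to_numpy()
    lats = landscape.grid.lats().to_numpy()
    wettest = int(np.argmax(cwd))

    log_tol = _brownian_log_tolerance(tree, cfg, rng)
    thr_bm = -np.exp(log_tol.to_numpy())
    species = list(log_tol.index)

    if cfg.mode == "nested":
        caps = _major_clade_caps(tree, cfg, rng).loc[species].to_numpy()
        thr = np.maximum(thr_bm, caps)  # cap limits drought tolerance
        occ = np.zeros((len(cwd), len(species)), dtype=np.int8)
        n_widened = 0
        for s in range(len(species)):
            t, tries = thr[s], 0
            while not (cwd >= t).any():
                t, tries = t * 1.3, tries + 1
                if tries > 60:
                    raise DomainError(
                        "infeasible config: no cell wet enough for "
                        f"species {species[s]}"
                    )
            if tries:
                n_widened += 1
                thr[s] = t
            occ[:, s] = (cwd >= t).astype(np.int8)
        extra = {"cap": caps}
    else:
        # Replacement structure: clades occupy staggered bands of the CWD
        # axis, hierarchically (basal clade -> major clade -> species), so
        # lineages replace each other along the gradient at every depth.
        basal_rank = _basal_clade_of_tips(tree)
        depth = min(cfg.major_clade_depth, tree.root_age * 0.999)
        sl = slice_lineages(tree, depth)
        lo, hi = cwd.min(), cwd.max()
        span = hi - lo
        centre = np.empty(len(species))
        pos = {sp: s for s, sp in enumerate(species)}
        basal_centres = lo + span * (
            (np.arange(cfg.n_basal) + 0.5) / cfg.n_basal
        )
        for lin in sl.lineages:
            rank = int(basal_rank[next(iter(lin.tips))])
            major_centre = basal_centres[rank] + rng.normal(0.0, span / 10.0)
            members = [pos[sp] for sp in lin.tips]
            dev = log_tol.to_numpy()[members]
            dev = dev - dev.mean()
            centre[members] = major_centre + dev * (span / 16.0)
        half = cfg.band_halfwidth * np.exp(
            rng.normal(0.0, cfg.band_halfwidth_sd, len(species))
        )
        occ = np.zeros((len(cwd), len(species)), dtype=np.int8)
        n_widened = 0
        thr = centre
        for s in range(len(species)):
            h, tries = half[s], 0
            while not ((cwd >= centre[s] - h) & (cwd <= centre[s] + h)).any():
                h, tries = h * 1.3, tries + 1
                if tries > 60:
                    raise DomainError(
                        f"infeasible config: empty band for {species[s]}"
                    )
            if tries:
                n_widened += 1
            half[s] = h
            occ[:, s] = ((cwd >= centre[s] - h) & (cwd <= centre[s] + h)
                         ).astype(np.int8)
        extra = {"band_halfwidth": half}
    if n_widened:
        logger.info("widened tolerance for %d empty-range species", n_widened)

    if cfg.dropout > 0:
        keep = rng.random(occ.shape) >= cfg.dropout
        thinned = occ * keep
        for s in range(len(species)):
            if thinned[:, s].sum() == 0:
                col = np.zeros(len(cwd), dtype=np.int8)
                owned = np.flatnonzero(occ[:, s])
                col[owned[np.argmax(cwd[owned])]] = 1
                thinned[:, s] = col
        occ = thinned.astype(np.int8)

    data = pd.DataFrame(occ, index=landscape.grid.cells, columns=species)
    pm = PresenceMatrix(data, landscape.grid)
    observed = {
        sp: lats[np.flatnonzero(occ[:, s])] for s, sp in enumerate(species)
    }
    realized = np.clip(thr, cwd.min(), cwd.max())
    species_table = pd.DataFrame(
        {
            "threshold_cwd": thr,
            # drought tolerance as a positive magnitude (mm/yr of deficit
            # tolerated), clipped to the deficits realised on the landscape
            "tolerance_mm": -realized,
            "north_limit_lat": [observed[sp].max() for sp in species],
            "south_limit_lat": [observed[sp].min() for sp in species],
            "n_cells": occ.sum(axis=0),
            **extra,
        },
        index=pd.Index(species, name="species"),
    )
    return SimulatedRanges(presence=pm, observed_latitudes=observed,
                           species=species_table)


# -------------------------------------------------------------- clade map


def _labels_from_slice(tree, depth, prefix):
    sl = slice_lineages(tree, min(depth, tree.root_age))
    out = {}
    for k, lin in enumerate(sorted(sl.lineages, key=lambda l: -len(l.tips))):
        for sp in lin.tips:
            out[sp] = f"{prefix}{k + 1:02d}"
    return pd.Series(out)


def synthetic_clade_map(tree, cfg):
    """Family/superorder labels from tree slices (families are the lineages
    crossing ``cfg.family_depth``, superorders those crossing
    ``cfg.superorder_depth``), mirroring how named higher taxa partition a
    real phylogeny into disjoint MRCA subtrees."""
    table = pd.DataFrame(
        {
            "family": _labels_from_slice(tree, cfg.family_depth, "F"),
            "superorder": _labels_from_slice(tree, cfg.superorder_depth, "SO"),
        }
    )
    table.index.name = "species"
    return CladeMap(table)


def simulate_dataset(cfg):
    """Full synthetic study: tree + landscape + ranges + clade map."""
    tree = simulate_tree(cfg)
    landscape = simulate_landscape(cfg)
    ranges = simulate_ranges(tree, landscape, cfg)
    clade_map = synthetic_clade_map(tree, cfg)
    return SyntheticDataset(config=cfg, tree=tree, landscape=landscape,
                            ranges=ranges, clade_map=clade_map)


# ------------------------------------------------------------ toy fixture

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@dataclass
class ToyFixture:
    tree: Phylogeny
    grid: SiteGrid
    presence: PresenceMatrix
    clade_map: CladeMap
    env: pd.DataFrame
    occurrences: dict


def make_toy_fixture():
    """The hand-checkable worked example used throughout the package.

    Tree ``((A:1,B:1):1,C:2);`` and three cells on a small latitudinal
    run: cell1 {A, B} at 9.5 N, cell2 {A, C} at 10.5 N, cell3 empty at
    11.5 N.  Known values: PD(cell1) = 3, PD(cell2) = 4; PE(cell1) = 2,
    PE(cell2) = 3; TILD of a cell holding all three species = ln 3 + ln 2.
    """
    from .tree import read_newick_string

    tree = read_newick_string(TOY_NEWICK)
    table = pd.DataFrame(
        {"lat": [9.5, 10.5, 11.5], "lon": [75.5, 75.5, 75.5]},
        index=pd.Index(["cell1", "cell2", "cell3"], name="cell"),
    )
    grid = SiteGrid(table)
    presence = PresenceMatrix(
        pd.DataFrame(
            {"A": [1, 1, 0], "B": [1, 0, 0], "C": [0, 1, 0]},
            index=grid.cells,
        ),
        grid,
    )
    clade_map = CladeMap(
        pd.DataFrame(
            {"family": ["Fab", "Fab", "Fc"],
             "superorder": ["SO1", "SO1", "SO1"]},
            index=pd.Index(["A", "B", "C"], name="species"),
        )
    )
    env = pd.DataFrame(
        {"cwd": [-120.0, -260.0, -420.0],
         "map": [3200.0, 2600.0, 2100.0],
         "tri": [60.0, 90.0, 140.0]},
        index=grid.cells,
    )
    occurrences = {"A": [9.5, 10.5], "B": [9.5], "C": [10.5]}
    return ToyFixture(tree=tree, grid=grid, presence=presence,
                      clade_map=clade_map, env=env, occurrences=occurrences)
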