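"""Gridded occurrence containers: cell grid and binary presence matrix.

Both containers are thin, validated wrappers around pandas DataFrames so the
rest of the package (and users) can fall back on ordinary DataFrame idioms.
CSV is the canonical interchange format: a SiteGrid is ``cell,lat,lon``; a
presence matrix is either wide (first column ``cell``, one 0/1 column per
species) or a sparse triplet dialect (``cell,species`` rows, one per
presence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["SiteGrid", "PresenceMatrix"]


@dataclass
class SiteGrid:
    """Cell centroids of a regular grid (nominal resolution in km).

    ``table`` is indexed by unique cell id with float columns ``lat`` and
    ``lon`` (degrees N / E).
    """

    table: pd.DataFrame
    resolution_km: float = 10.0
    lat_extent: tuple = (8.0, 19.0)

    def __post_init__(self):
        t = self.table
        if not {"lat", "lon"}.issubset(t.columns):
            raise ValidationError("SiteGrid table needs 'lat' and 'lon' columns")
        if t.index.duplicated().any():
            raise ValidationError("duplicate cell ids in SiteGrid")
        lo, hi = self.lat_extent
        lats = t["lat"].to_numpy(float)
        if lats.size and (lats.min() < lo or lats.max() > hi):
            raise ValidationError(
                f"cell latitudes outside declared extent [{lo}, {hi}]: "
                f"range ({lats.min():.3f}, {lats.max():.3f})"
            )

    @property
    def cells(self):
        return self.table.index

    def lats(self):
        return self.table["lat"]

    def subset(self, cells):
        return SiteGrid(self.table.loc[cells], self.resolution_km, self.lat_extent)

    @classmethod
    def from_csv(cls, path, **kw):
        t = pd.read_csv(path, index_col=0)
        return cls(t, **kw)

    def to_csv(self, path):
        self.table.to_csv(path, index_label="cell")


@dataclass
class PresenceMatrix:
    """Binary cells x species table bound to a :class:`SiteGrid`.

    Invariants: entries in {0, 1}; row index equals the grid's cell ids;
    every species column has at least one presence.
    """

    data: pd.DataFrame
    grid: SiteGrid

    def __post_init__(self):
        d = self.data
        vals = d.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValidationError("presence matrix entries must be 0/1")
        self.data = d.astype(np.int8)
        if not d.index.equals(self.grid.cells):
            extra = d.index.difference(self.grid.cells)
            missing = self.grid.cells.difference(d.index)
            if len(extra) or len(missing):
                raise ValidationError(
                    "presence matrix cells and grid cells differ "
                    f"(only in matrix: {list(extra)[:5]}, "
                    f"only in grid: {list(missing)[:5]})"
                )
            # same set, different order: align to the grid
            self.data = self.data.loc[self.grid.cells]
        if d.columns.duplicated().any():
            raise ValidationError("duplicate species columns")
        empty = [sp for sp in d.columns if d[sp].sum() == 0]
        if empty:
            raise ValidationError(
                f"species with no presences: {empty[:10]}"
                + ("..." if len(empty) > 10 else "")
            )

    @property
    def species(self):
        return list(self.data.columns)

    @property
    def cells(self):
        return self.data.index

    def richness(self):
        return self.data.sum(axis=1)

    def species_in_cell(self, cell):
        row = self.data.loc[cell]
        return [sp for sp in self.data.columns if row[sp]]

    def drop_empty_species(self):
        """Return a copy without all-zero species columns (post filtering)."""
        keep = [sp for sp in self.data.columns if self.data[sp].sum() > 0]
        dropped = [sp for sp in self.data.columns if sp not in set(keep)]
        return PresenceMatrix(self.data[keep], self.grid), dropped

    # ------------------------------------------------------------------- I/O

    @classmethod
    def from_csv(cls, path, grid):
        d = pd.read_csv(path, index_col=0)
        return cls(d, grid)

    @classmethod
    def from_triplets(cls, path, grid):
        """Sparse dialect: CSV with columns ``cell,species`` (one presence
        per row)."""
        t = pd.read_csv(path)
        if not {"cell", "species"}.issubset(t.columns):
            raise ValidationError("triplet CSV needs 'cell' and 'species' columns")
        d = pd.crosstab(t["cell"], t["species"]).clip(upper=1)
        d = d.reindex(index=grid.cells, fill_value=0)
        return cls(d, grid)

    def to_csv(self, path):
        self.data.to_csv(path, index_label="cell")
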