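"""End-to-end orchestration: inputs (files or synthetic) to output bundle.

``run_pipeline`` executes the full analysis: optional latitudinal clipping,
the species-poor cell filter, per-cell diversity indices, the per-depth
nestedness test and restricted-lineage counts, lineage latitudinal ranges,
clade PD partitions, and environment correlations.  Every output is a CSV;
a JSON manifest records the configuration, derived seeds, library versions
and row counts so a run can be reproduced byte-for-byte from its seed.

Stage failures are surfaced with the stage name; partially written outputs
are moved to a ``quarantine/`` subdirectory of the output folder.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clades import CladeMap, clade_pd_by_bin, clade_pd_by_depth
from .depth import nestedness_test, restricted_table, turnover_table, \
    lineage_latitudinal_ranges
from .diversity import (
    clip_to_observed_latitudes,
    diversity_table,
    filter_low_richness_cells,
)
from .environment import correlate_diversity_env, validate_env_table
from .errors import PhylogradientError, ValidationError
from .grid import PresenceMatrix, SiteGrid
from .simulate import SyntheticConfig, simulate_dataset
from .tree import read_newick, write_newick

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_inputs"]


@dataclass
class PipelineConfig:
    """Everything a run needs.  Defaults reproduce the study settings:
    ten-species cell filter, 1 degree bins, 10-Myr slices to the root age,
    1000 null replicates, 13 degree N restriction threshold."""

    # file inputs (all-or-nothing; leave None to use the synthetic block)
    tree_path: str = None
    presence_path: str = None
    grid_path: str = None
    env_path: str = None
    clade_map_path: str = None
    occurrences_path: str = None

    synthetic: dict = field(default_factory=dict)

    min_richness: int = 10
    bin_width: float = 1.0
    restriction_threshold: float = 13.0
    slice_interval: float = 10.0
    max_depth: float = None  # default: root age
    replicates: int = 1000
    seed: int = 0
    out_dir: str = "phylogradient_out"

    fill_embedded: bool = False
    pairs: str = "all"
    include_root_path: bool = True
    tri_variant: str = "mean_abs"
    apply_clip: bool = True

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self):
        return dataclasses.asdict(self)

    def uses_files(self):
        return self.tree_path is not None

    def validate(self):
        if self.uses_files():
            for name in ("tree_path", "presence_path", "grid_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValidationError(f"{name} is required with file input")
                if not Path(p).exists():
                    raise ValidationError(f"{name}: no such file: {p}")
            for name in ("env_path", "clade_map_path", "occurrences_path"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ValidationError(f"{name}: no such file: {p}")
        if self.min_richness < 0 or self.replicates < 1:
            raise ValidationError("min_richness >= 0 and replicates >= 1")
        return self


def read_occurrences_csv(path):
    """Long CSV ``species,lat`` -> mapping species -> list of latitudes."""
    t = pd.read_csv(path)
    if not {"species", "lat"}.issubset(t.columns):
        raise ValidationError("occurrences CSV needs 'species' and 'lat'")
    return {sp: g["lat"].tolist() for sp, g in t.groupby("species")}


def load_inputs(config):
    """Resolve the configured inputs into in-memory objects."""
    if config.uses_files():
        tree = read_newick(config.tree_path)
        grid = SiteGrid.from_csv(config.grid_path)
        pm = PresenceMatrix.from_csv(config.presence_path, grid)
        env = (pd.read_csv(config.env_path, index_col=0)
               if config.env_path else None)
        if env is not None:
            validate_env_table(env)
        clade_map = (CladeMap.from_csv(config.clade_map_path)
                     if config.clade_map_path else None)
        occurrences = (read_occurrences_csv(config.occurrences_path)
                       if config.occurrences_path else None)
        return tree, pm, env, clade_map, occurrences
    scfg = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
    ds = simulate_dataset(scfg)
    return (ds.tree, ds.ranges.presence, ds.landscape.env, ds.clade_map,
            ds.ranges.observed_latitudes)


def _depths(config, tree):
    T = config.max_depth if config.max_depth is not None else tree.root_age
    step = config.slice_interval
    depths = list(np.arange(step, T, step))
    if not depths or depths[-1] < T:
        depths.append(float(T))
    return depths


def run_pipeline(config):
    """Run every stage and write the output bundle; returns a dict of the
    in-memory result tables plus the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    stage = "setup"

    def save(df, name, **kw):
        path = out / name
        df.to_csv(path, **kw)
        written.append(str(path))
        return path

    results = {}
    try:
        stage = "load"
        tree, pm, env, clade_map, occurrences = load_inputs(config)
        if not config.uses_files():
            # persist the generated inputs so a run is self-contained
            write_newick(tree, out / "tree.nwk")
            written.append(str(out / "tree.nwk"))
            pm.grid.to_csv(out / "grid.csv")
            pm.to_csv(out / "presence_raw.csv")
            written += [str(out / "grid.csv"), str(out / "presence_raw.csv")]

        n_cells_in = len(pm.cells)
        stage = "clip"
        if config.apply_clip and occurrences is not None:
            pm = clip_to_observed_latitudes(pm, occurrences)

        stage = "filter"
        pm = filter_low_richness_cells(pm, config.min_richness)
        logger.info("cell filter: %d -> %d cells", n_cells_in, len(pm.cells))

        stage = "diversity"
        div = diversity_table(tree, pm,
                              include_root_path=config.include_root_path)
        save(div, "diversity.csv")
        results["diversity"] = div

        depths = _depths(config, tree)

        stage = "nestedness"
        nest_seed = int(
            np.random.SeedSequence([config.seed, 10]).generate_state(1)[0]
            % (2**31)
        )
        nest = turnover_table(
            nestedness_test(
                tree, pm, depths,
                width=config.bin_width,
                replicates=config.replicates,
                seed=nest_seed,
                fill_embedded=config.fill_embedded,
                pairs=config.pairs,
            )
        )
        save(nest, "turnover_by_depth.csv", index=False)
        results["turnover"] = nest

        stage = "restricted"
        restr = restricted_table(tree, pm, depths,
                                 config.restriction_threshold)
        save(restr, "restricted_lineages.csv", index=False)
        results["restricted"] = restr

        stage = "lineage_ranges"
        ranges = []
        for t in depths:
            r = lineage_latitudinal_ranges(tree, pm, t).reset_index()
            r.insert(0, "depth_ma", t)
            ranges.append(r)
        ranges = pd.concat(ranges, ignore_index=True)
        save(ranges, "lineage_ranges.csv", index=False)
        results["lineage_ranges"] = ranges

        if clade_map is not None:
            stage = "clade_contributions"
            fam = clade_pd_by_bin(tree, pm, clade_map, "family",
                                  width=config.bin_width)
            save(fam, "clade_pd_family_by_bin.csv", index=False)
            so_bin = clade_pd_by_bin(tree, pm, clade_map, "superorder",
                                     width=config.bin_width)
            save(so_bin, "clade_pd_superorder_by_bin.csv", index=False)
            so_depth = clade_pd_by_depth(tree, pm, clade_map, "superorder",
                                         depths=[0.0] + depths)
            save(so_depth, "clade_pd_superorder_by_depth.csv", index=False)
            results["clade_family"] = fam
            results["clade_superorder_depth"] = so_depth

        if env is not None:
            stage = "correlates"
            corr = correlate_diversity_env(div, env.loc[pm.cells])
            save(corr, "correlations.csv", index=False)
            results["correlations"] = corr
            save(env.loc[pm.cells], "environment.csv")

        stage = "manifest"
        manifest = {
            "package": "phylogradient",
            "version": _version(),
            "config": config.to_dict(),
            "derived_seeds": {"nestedness": nest_seed},
            "library_versions": _library_versions(),
            "counts": {
                "cells_in": int(n_cells_in),
                "cells_retained": int(len(pm.cells)),
                "species_retained": int(len(pm.species)),
                "depths": [float(t) for t in depths],
                "rows": {k: int(len(v)) for k, v in results.items()},
            },
            "outputs": sorted(written),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        results["manifest"] = manifest
        return results
    except Exception as exc:
        q = out / "quarantine"
        q.mkdir(exist_ok=True)
        for p in written:
            p = Path(p)
            if p.exists():
                shutil.move(str(p), q / p.name)
        if isinstance(exc, PhylogradientError):
            raise type(exc)(f"stage {stage!r}: {exc}") from exc
        raise PhylogradientError(f"stage {stage!r} failed: {exc}") from exc


def _version():
    from . import __version__
    return __version__


def _library_versions():
    import dendropy
    import scipy
    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "dendropy": dendropy.__version__,
    }
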