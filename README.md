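# phylogradient

Spatial phylogenetics of latitudinal diversity gradients: per-grid-cell
evolutionary diversity indices on a time-calibrated phylogeny, lineage sets
at sliced evolutionary depths, metacommunity nestedness testing against a
resampling null, environmental correlates, and clade-level partitioning of
phylogenetic diversity.

The package is written for macroecologists and biogeographers analysing
gridded species occurrences (e.g. stacked species distribution maps) on an
ultrametric phylogeny with branch lengths in millions of years (Myr).  Its
design case is a tropical mountain gradient of the Western Ghats type: wet
aseasonal forests in the south grading into strongly drought-seasonal sites
in the north, with the expectation that phylogenetic niche conservatism for
wet sites produces nested assemblages at all evolutionary depths.  A seeded
synthetic-data generator reproduces this structure so the entire pipeline
runs and is testable without any downloads.

## The indices and the test

For each grid cell holding species set *S* on a rooted ultrametric tree
with root age *T*:

- **SR** — species richness, |*S*|.
- **PD** — Faith's phylogenetic diversity: total branch length of the
  subtree spanning *S*, path to the root included (switchable), in Myr.
- **PE** — phylogenetic endemism: Σ over branches *b* present in the cell
  of *L(b)* / *range(b)*, where *range(b)* is the number of grid cells
  occupied by *b*'s descendant clade.  Summed over all cells, PE returns
  the total tree length exactly.
- **TILD** — time-integrated lineage diversity: ∫₀ᵀ ln *n*(*t*) d*t*,
  where *n*(*t*) is the number of branches of the cell's subtree crossing
  depth *t*; evaluated exactly as a sum over inter-node intervals.  TILD
  shifts weight toward deep-time diversity, complementing PD.

Slicing the tree at depth *t* Ma yields the ancestral lineages alive at
*t*; each lineage's modern range is the union of its descendants'
occurrences.  For each depth, species presences are collapsed into
latitudinal bins and the ordered lineage-by-bin matrix is scored by the
metacommunity turnover statistic — for every lineage pair, (bins holding
*i* but not *j*) × (bins holding *j* but not *i*) — against the **r1
null**: every bin keeps its observed lineage richness while lineages are
drawn without replacement with probability proportional to their overall
occurrence frequencies.  Observed turnover below the null mean indicates
nestedness; above it, true turnover.

## Worked example

```python
import phylogradient as pg

toy = pg.make_toy_fixture()          # tree ((A:1,B:1):1,C:2); three cells
print(pg.diversity_table(toy.tree, toy.presence).round(4))
```

```
       sr   pd   pe    tild
cell
cell1   2  3.0  2.0  0.6931
cell2   2  4.0  3.0  1.3863
cell3   0  0.0  0.0  0.0000
```

Cell 1 holds {A, B}: its spanning subtree is the branches A (1 Myr),
B (1) and their 1-Myr stem, so PD = 3.  Its PE is 1/2 + 1/1 + 1/2 = 2
(branch A and the AB stem are shared with cell 2; B occurs nowhere else),
and its TILD is ln 2 over one Myr of depth = 0.6931.  The empty cell
scores zero everywhere.

The same pipeline at study scale, on synthetic nested-gradient data:

```python
ds = pg.simulate_dataset(pg.SyntheticConfig(seed=1))       # 300 species
pm = pg.filter_low_richness_cells(ds.ranges.presence, 10)  # study filter
res = pg.nestedness_test(ds.tree, pm, replicates=1000, seed=101)
```

```
 depth_ma  n_lineages  observed  null_mean  null_sd  p_empirical verdict
     10.0         216         0   51988.50  3009.93         0.00  nested
     30.0          98         0   10381.80   900.45         0.00  nested
     60.0          55         0    3036.47   338.98         0.00  nested
     90.0          34         0     881.78   118.49         0.00  nested
    120.0           6         0      27.73     7.83         0.00  nested
    135.0           3         0       6.24     2.74         0.04  nested
```

Observed lineage turnover sits far below the r1 null mean at every depth
from 10 Ma to the 135-Ma root: northern assemblages are nested subsets of
southern ones at all evolutionary depths.  (At the deepest slices only
three ancestral lineages remain, so the empirical p cannot be sharp; see
`docs/methods.md`.)

From the shell, the same run is:

```bash
phylogradient run --seed 1 --out-dir out/
```

which writes the diversity table, per-depth turnover and restricted-
lineage tables, lineage latitudinal ranges, clade PD partitions, the
environment correlation table and a manifest that makes the run
reproducible byte-for-byte from its seed.  Individual stages are exposed
as `simulate`, `diversity`, `slice`, `nestedness`, `correlates` and
`contributions` subcommands.

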