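# Methods

This note documents the models, conventions and numerical choices behind
phylogradient, and what the synthetic data generator does and does not
emulate.

## Tree model and age conventions

Trees are rooted, ultrametric, with branch lengths in Myr.  Time runs
backward from the present: tips sit at age 0 and a node's age is its
maximum distance to a descendant tip, so the root age *T* equals the tree
height.  Ultrametricity is validated on read (default relative tolerance
1e-6 against the tree height, configurable); failing trees are rejected
with the most deviant tip named, never silently rescaled.

**Depth slicing** uses a half-open convention: a branch is alive at depth
*t* iff `child_age <= t < parent_age`.  How a slicing implementation
breaks exact ties between node ages and slice depths is an arbitrary
choice; ours is documented rather than inferred.  At *t = T* the interval
is empty for every branch, so the root's child branches are returned —
this keeps the deepest slice meaningful for trees whose basal splits
coincide with the root (the angiosperm case, where three ancestral
lineages — monocots, magnoliids, eudicots — are present at the root age).

**Induced subtrees** retain the path to the global root and do not
suppress degree-2 nodes.  This gives PD, PE and TILD one shared subtree
definition.  PD therefore includes the root path by default (a
single-species cell scores that tip's root distance); the classic
minimum-spanning convention is available via `include_root_path=False`.

## Indices

- **SR**: row sum of the binary presence matrix.
- **PD** (Myr): total branch length of the cell's induced subtree.
- **PE** (Myr): each branch's length divided by the number of grid cells
  occupied by its descendant clade, summed over branches present in the
  cell.  Range is measured in occupied grid cells, matching the gridded
  design.  The conservation identity Σ_cells PE = total tree length holds
  exactly (each branch contributes length/range in exactly range cells)
  and is asserted to 1e-9 in tests.  Because 1/range weights make PE very
  sensitive to tiny ranges, `min_range_cells` optionally excludes species
  below a range threshold before weighting — the standard protocol when
  point endemics lack reliable range estimates.
- **TILD** (dimensionless·Myr): ∫₀ᵀ ln n(t) dt with n(t) the cell
  subtree's lineage count at depth t.  The integral is computed exactly as
  Σ (interval width × ln count) over the intervals between the subtree's
  node ages — no quadrature.  Natural log is used; the base only rescales
  TILD, so correlations are base-invariant.  Integrating over the common
  [0, T] rather than each cell's own span puts cells on one scale;
  intervals with a single lineage contribute ln 1 = 0 either way.
  TILD ≤ T·ln(SR), with equality only for star-like subtrees.

## Occurrence cleaning

Two steps precede index calculation, mirroring how stacked distribution
maps are made conservative: per-species clipping to the observed
latitudinal extent (presences outside [min, max] observed latitude are
removed), and removal of grid cells with fewer than 10 species (the
minimum plot richness observed in the source data; configurable).  Cells
and species emptied by these filters are dropped with logged counts.
Species present in the matrix but absent from the tree are a hard error:
silent dropping hides provenance problems.

## Nestedness at evolutionary depths

Species presences are collapsed into latitudinal bins (default 1°,
half-open, aligned to whole degrees, ordered south to north; bins without
grid cells are dropped).  At each depth the lineages from the slice
inherit the union of their descendants' bin presences.  The turnover
statistic counts pairwise replacements over **all** bin pairs — for each
lineage pair (i, j), (#bins with i only) × (#bins with j only) — the
metacommunity convention; an adjacent-bins-only variant is exposed as a
flag.  Bins are ordered by latitude (the gradient of interest), not by
reciprocal-averaging ordination.

The **r1 null** holds each bin's lineage richness fixed and draws that
many distinct lineages with probability proportional to lineage column
totals.  Sampling uses exponential-key (Efraimidis–Spirakis) weighted
sampling without replacement, distributionally equivalent to sequential
probability-proportional draws.  Per-depth seeds are spawned
deterministically from one top-level seed and recorded in the output.

Reported per depth: observed turnover, null mean and SD, a z-score with
its two-sided normal p, and the one-sided empirical p in the nestedness
direction, (#{null ≤ observed} + 1)/(replicates + 1).  The verdict is
"nested" iff observed < null mean and the empirical p < α (default 0.05),
"turnover" for the mirror case, "untestable" with fewer than two lineages
or a degenerate null.

**Embedded-absence filling** (making each lineage's bins contiguous
before counting) is available but **off by default**.  With filling, any
matrix whose lineages all occur in the southernmost bin — which is what
strongly nested data look like — collapses to south-anchored intervals,
and any two such intervals are nested.  Since r1 preserves row richness,
every replicate of such a matrix is anchored too, making observed and
null turnover identically zero: the null is degenerate precisely on the
data the method targets.  Without filling the null has resolution and the
test behaves as intended.

**Power at the deepest slices.**  With ~11 one-degree bins and only three
ancestral lineages at the root age, the r1 null's outcome space is small:
the probability that a replicate is itself perfectly nested is a few
percent regardless of parametrization, so the empirical p at the deepest
one or two slices cannot fall below ≈0.03–0.05 even when the observed
turnover is zero.  The direction (observed below the null mean) and the
α = 0.05 verdict are still recovered; sharp significance at 3-lineage
depths would require either finer latitudinal bins or a normal
approximation, and we report the z-based p alongside for that purpose.

## Restricted lineages and clade contributions

A lineage is south-restricted at a threshold latitude (default 13° N,
roughly the Palghat gap) iff its maximum occupied centroid latitude is ≤
the threshold, north-restricted iff its minimum is above it.

Clades (families, superorders) are located on the tree by the MRCA of
their member species; a clade's branch set is the MRCA subtree **plus its
stem branch**, and branch sets at one level must be disjoint
(non-monophyletic labels are an error).  Branches above every clade's
stem (the root spine) are reported as an explicit "(unassigned)" category
and excluded from proportion normalisation rather than pro-rated.
Clades with one extant member are excluded by default.  Depth truncation
keeps the branch segments older than the slice depth, so the depth-0
partition equals the full-length latitudinal partition; at the root age
nothing remains and rows are flagged (NaN proportions) instead of
fabricated.  Default region boundaries (13° N and 15.5° N, the
approximate Palghat and Goa gaps) are configuration, not constants.

## Environment layers

- **TRI**: mean absolute elevation difference between a cell and its ≤8
  neighbours (edge cells use available neighbours; NaN propagates).  The
  original root-of-summed-squares variant is available as `"riley"`.
- **CWD** (≤ 0, mm/yr): Σ over months where precipitation − ET < 0 of
  that difference; ET defaults to a fixed 100 mm/month (the usual
  fixed-ET convention) or a monthly vector.
- Aggregation is a block mean with partial edge blocks averaged over the
  cells available.
- Diversity–environment association is plain Pearson on
  pairwise-complete cells with per-pair n reported; zero-variance columns
  yield NaN, flagged not fabricated.  No spatial autocorrelation
  correction is applied — with strongly autocorrelated gradients the
  p-values are anti-conservative, a known limitation of simple
  correlation reporting.

## Synthetic data generator

The generator's defaults are the study conditions of a Western Ghats
type gradient; they are fixed, not tuning knobs.

**Tree.**  Default `ltt_profile`: merge ages are drawn by inverting a
log-linear interpolation of the published Western Ghats woody-plant
lineage-through-time counts (3, 12, 54, 85, 153, 337 lineages at 135,
120, 90, 60, 30, 10 Ma; 470 at present), scaled to the requested tip
count (default 300), with small lognormal age jitter and a basal split
into three clades of very unequal size (0.72/0.18/0.10) at the 135-Myr
root.  A constant-rate pure-birth model (`"yule"`) conditioned on the tip
count and rescaled to the root age is available; it is far too
shallow-heavy to reproduce the deep-time structure (a Yule-300 tree has
~2 lineages older than 120 Ma against the study's 12).

**Landscape.**  Default 11 × 4 grid spanning 8–19° N.  CWD interpolates
linearly from −100 mm/yr (south) to −900 (north) with cell noise (SD 15,
clipped ≤ −10); MAP decreases northward; elevation is a smooth
west–east ridge plus roughness so TRI varies.  TRI is deliberately
uncorrelated with latitude, so the generator reproduces the CWD and MAP
correlations with diversity but not a TRI–diversity association.

**Ranges (nested mode).**  Drought tolerance evolves by Brownian motion
on log(−threshold) (rate 0.01/Myr, root ≈ −450 mm/yr), bounded by
hierarchically inherited caps: each basal clade has a physiological limit
on the drought tolerance its members can reach (−1500, −750, −530 mm/yr,
by decreasing clade size), tightened again (log-uniform) for each lineage
crossing 120 Ma, with the largest major clade of each basal clade keeping
the ancestral limit.  A species occupies every cell at least as wet as
its threshold.  The caps are what preserve deep-time range structure:
without them, the maximum over hundreds of unbounded Brownian tips drives
every deep lineage across the whole gradient and deep slices degenerate
to all-ones matrices.  Realised presences are thinned by a 2 % dropout
(detection/occupancy noise; a species losing every cell keeps its
wettest cell); dropout is one-directional because spurious
beyond-range presences are exactly what the latitudinal clipping step
removes.  With noise and dropout at 0, ranges are strictly nested by
construction: tolerance(i) ≤ tolerance(j) implies cells(j) ⊆ cells(i).

**Ranges (turnover mode).**  A positive control: clades occupy staggered
bands of the CWD axis placed hierarchically (basal clade centres at even
quantiles of the gradient, major-clade jitter, within-clade deviations
derived from the Brownian trait), each species occupying a band of
half-width 150 mm × lognormal noise, producing replacement rather than
nesting at every depth.

**What the generator does not emulate:** distribution-model artefacts
(overprediction, bias layers), non-interval ranges, elevational range
limits, true absences from dispersal limitation, and any TRI–diversity
link.  Passing tests therefore demonstrate correctness of the machinery
and the qualitative behaviour of the statistics under idealised
niche-conserved ranges, not the effect sizes to be expected of real
occurrence data, whose matrices are patchier and give the nulls more
resolution.

**Problem sizes.**  Default study size is 300 species on the 11 × 4
grid with 1000 null replicates; oracle tests use 10-tip, 20-cell
instances; the chi-square calibration uses a 5 × 8 fixture with equal
column totals (for which the r1 selection frequencies are exactly
uniform by symmetry) and 10,000 replicates.

## Reproducibility

All randomness flows from integer seeds through `numpy` SeedSequence
substreams (tree/landscape/ranges use fixed substream indices; per-depth
null seeds are spawned from the test seed and recorded in the output).
Pipeline runs write a manifest (config echo, derived seeds, library
versions, row counts) and contain no timestamps, so a rerun with the same
seed is byte-identical.
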