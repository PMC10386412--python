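# Methods

This note records the modelling conventions the package commits to, the
choices made where the literature leaves them open, what the synthetic
data generator does and does not emulate, and the numerical details that
matter for reproducing results.

## Data model and analysis domain

The substrate is a strictly boolean species × cell incidence matrix;
abundance information, if present in the input, is ignored with a
warning. Grid cells are abstract identifiers with optional x/y
coordinates — no projection or CRS handling. All metrics, percentile
thresholds and regression models are computed over the **occupied-cell
domain** (cells holding at least one species). Including empty cells as
zeros would make every percentile threshold depend on the arbitrary
extent of the empty sea/land mask and would put zeros under a log10
transform; restricting to occupied cells keeps every quantity
well-defined. Callers who want an all-cells domain can pass a full-grid
incidence matrix whose empty cells have been filled explicitly.

## Phylogenetic conventions

**Rooted PD.** PD of a cell is the branch length of the minimal subtree
connecting the cell's species *and the root* of the bound tree, so a
single-species cell scores that tip's root distance and the full species
set scores the total tree length. This is the standard rooted-PD
convention (it is also what picante's `pd(..., include.root = TRUE)`
computes, which the test suite uses as an independent oracle); it makes
the spatial decomposition of PE exact: summed over cells, PE returns the
total tree length.

**Megatree binding.** A species list is bound to a larger tree by
renaming substituted tips (sister species or near-synonyms, one tip per
species; many-to-one reuse is rejected) and pruning. Any residual edge
above the MRCA of the retained tips is dropped: a dangling stem above the
MRCA has no defined interpretation after pruning. Zero-length branches
(a routine artifact of megatree pruning) are legal everywhere and
contribute nothing to any metric. Polytomies are preserved, never
resolved.

**The sesPD null.** Each replicate permutes the tip labels of the whole
tree once and recomputes PD for every cell under that single permutation.
Per cell this is the same marginal null as independent richness-matched
draws, but the joint structure across cells differs; the whole-tree
permutation is used because it is the natural reading of label-shuffling
nulls and is what tip-shuffle implementations do. The z-score uses the
sample (n−1) standard deviation over replicates; if the null standard
deviation is zero (e.g. a cell containing every species), z is defined
as 0 and the cell is classed neutral, with a log message. Classes use
the ±1.96 normal thresholds. With the same seed the result is
bit-reproducible.

**EDGE.** GE codes CR=4, EN=3, VU=2, NT=1, LC=0, so each Red List step
adds exactly ln 2 to EDGE — a doubling of assumed extinction risk.
DD species stay in every taxonomic and phylogenetic metric but carry no
GE or EDGE score; a cell whose species are all DD has grid EDGE 0 and is
flagged in the log.

## Hotspots

The top-q set of a surface is every cell whose value reaches the k-th
largest value, k = ceil(qN). Ties at the threshold are all included:
deterministic, order-independent, and faithful to "the top q% of values"
even when the selected set exceeds k cells. Consequently top-q sets are
nested in q, and coverage tables are monotone non-decreasing across
fractions by construction. For sesPD, "top" ranks +z (the
overdispersion direction), treating all seven metrics as
maximise-is-best; ranking by |z| is available behind a flag.
A nano-hotspot is a cell where at least 5 of the 7 metrics coincide in
the top-1% sets (configurable).

Coverage means are unweighted means over species (per category and
overall), so a single-cell endemic counts as much as a widespread one.
Gap analysis classifies hotspot cells by a pre-rasterised per-cell
protection attribute; a cell inside both the Natura 2000 and a local
network counts as natura2000.

## Environmental models

Predictor screening iteratively removes, from the pair with the largest
Spearman |ρ| ≥ 0.7, the member with the larger mean absolute correlation
to the remaining predictors (deterministic; ties break toward the later
column). Responses other than sesPD are log10-transformed — positive by
construction on the occupied domain — and all variables are z-scored so
slopes are comparable.

All 2^p predictor subsets are fitted by least squares. AIC is computed
as `n ln(2π) + n ln(RSS/n) + n + 2(k + 2)` with k slopes — Gaussian
maximum likelihood with the variance profiled, counting intercept and
variance as parameters — so values are comparable across subsets. AIC
rather than AICc: at thousands of cells the small-sample correction is
negligible. Models within ΔAIC < 2 of the best are combined with Akaike
weights using **full (shrinkage) averaging**: a predictor absent from a
model contributes a zero estimate there. The unconditional standard
error is `Σ w_i sqrt(se_i² + (β_i − β̄)²)` and p-values use the normal
approximation. Conditional averaging (over models containing the term
only) is available behind a flag. Aspect is treated as a linear
covariate in degrees; a circular encoding would be straightforward but
is off by default.

The species–area relationship is an OLS fit of log10 richness on log10
area; the EDGE-by-IUCN comparison is a one-way ANOVA over categories
with at least two scored species (DD excluded).

## The synthetic generator

The generator produces the statistical structure the analysis assumes,
at desk scale (default 154 species on a 60 × 40 grid; `small_config`
gives 60 species on 30 × 20 for multi-seed experiments):

- a pure-birth tree (exponential waiting times, uniform lineage choice,
  one extra waiting time after the last split so terminal branches are
  positive); internal edges shorter than ε = 0.02 are collapsed into
  polytomies, mimicking unresolved radiations in megatree-bound floras;
- a coastal rectangle whose border cells are coast, a mountain ridge
  with several summits (Gaussian cross-section × cosine summit profile,
  default maximum ≈ 1400 m), and climate coupled to elevation:
  precipitation (bio12) increases and temperatures (bio1, bio8) decrease
  with elevation, slope is the elevation gradient plus sub-grid
  micro-relief, aspect is uniform. Constants were set so all pairwise
  covariate Spearman |ρ| stay below the 0.7 screening cutoff while the
  elevation–precipitation rank correlation stays above 0.5, i.e. the
  generated covariates behave like an already-screened predictor set;
- lognormal range sizes (median 6 cells, σ = 1.4; floored at one cell)
  placed as the nearest cells to a niche optimum, with 35% mountain and
  25% coastal specialists whose optima and distances are biased by
  elevation and coast distance respectively — small ranges therefore
  cluster on high-elevation and near-coast cells;
- planted nano-hotspots: three summit cells each stacked with ten
  single-cell species whose tips are spread evenly across the tree,
  the synthetic analogue of peak concentrations of narrow endemics;
- IUCN categories from range-size thresholds (≤1 CR, ≤4 EN, ≤10 VU,
  ≤25 NT, else LC) plus a 2% DD fraction drawn independently of range so
  DD-exclusion code paths see both narrow and widespread DD species;
- protection: the high ridge is natura2000, part of the southern coast
  local_only, the rest — including some summits — unprotected, so gap
  analysis has genuine gaps to find.

Everything is deterministic per seed; identical configurations produce
byte-identical fixture files.

What the generator does **not** emulate: observation effort and
detection bias, spatial autocorrelation of residual noise, realistic
speciation–extinction biogeography, dispersal limitation, or any
relation between abundance and range size. Because the synthetic IUCN
rule is purely range-driven, EDGE differs systematically among synthetic
categories — unlike real floras, where threat status and evolutionary
distinctiveness are often unrelated. Passing tests therefore demonstrate
the correctness and calibration of the computations, not the ecological
realism of any particular landscape.

## Problem sizes and tolerances

The test suite and the reproduction script use: 100 random fixtures
(3–17 tips, 4–23 cells) for the exact conservation identities
(tolerance 1e-9 relative); 25 random instances (≤15 tips, ≤30 cells)
for brute-force oracle equivalence; 2500 cells × 1000 replicates for
null-model calibration (expected 5% ± 2 points of |z| > 1.96); n = 5000
for coefficient recovery (±0.03, all signs); and 20 seeded landscapes
for planted-hotspot recovery (≥90% of planted cells with count ≥ 5 at
q = 1%). The complete default-scale pipeline (seven metrics, 1000-rep
null, four hotspot fractions, coverage, gaps, six model averages) runs
in a few seconds on one CPU.

## Known limitations

- No spatial autocorrelation correction in the GLMs (coefficient
  standard errors will be optimistic on strongly autocorrelated grids).
- The occupied-only domain means percentile hotspots are relative to
  where endemics occur, not to the whole territory.
- Protection arrives pre-rasterised per cell; no polygon geometry.
- Fair-proportion ED and summed per-cell EDGE are the only
  distinctiveness/priority variants implemented (no equal-splits ED, no
  probabilistic EDGE2, no abundance-weighted PD).
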