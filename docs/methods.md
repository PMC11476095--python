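# Methods

This note documents the statistical procedures implemented in
`biofilmassay`, the assumptions behind them, and the conventions adopted
where the underlying assay protocols leave choices open.

## The assay and its data

A crystal-violet (CV) microplate biofilm assay measures total adherent
biomass as OD570 after staining and solubilization; a resazurin (RZ) assay
measures metabolic viability of the same biofilm from the reduction of blue
resazurin to pink resorufin. Each 96-well plate carries sample wells
(isolate x technical replicate) and sterility-control wells (medium only).
Assays are repeated on independent days (biological replicates) and read at
two incubation times; because the CV stain destroys the well, each
condition x timepoint x day is a separate plate. The canonical in-memory
representation is a pair of tidy tables (readings and layout; see
`plate_model`), with conditions encoded as a stress factor (baseline /
temperature / NaCl / pH) plus a numeric level.

## Cutoff and producer classification

The classification cutoff for a condition x timepoint is

    ODc = mean(control OD570) + 3 * SD(control OD570)

with the sample SD (n-1 denominator; 0 for a single control well). Isolates
are binned by their mean CV OD over all replicate wells:

| class | band |
|---|---|
| non-producer (NP) | OD <= ODc |
| weak (WP) | ODc < OD <= 2 ODc |
| moderate (MP) | 2 ODc < OD <= 4 ODc |
| strong (SP) | OD > 4 ODc |

Conventions: the published inequalities are strict on both sides and leave
the exact boundaries unassigned, so half-open bands (boundary to the lower
class) are used — a measure-zero choice that makes classification
deterministic, scale-invariant and monotone. Controls are pooled over the
replicate plates of one condition x timepoint by default (each condition has
its own sterility wells); pooling across all conditions is an option
(`pool=True`). Classification uses the plain mean over all 9 wells with no
outlier removal. Negative (blanked) absorbances are accepted throughout; a
non-positive ODc is rejected as unclassifiable.

## Resazurin viability correction (AR570)

With absorbance-only reads, the reduced-dye signal is recovered by
subtracting the oxidized-dye contribution:

    AR570 = (OD570 - OD600 * Ro) * 100,   Ro = mean(OD570)/mean(OD600)

where Ro is measured on sterility wells at the baseline read (immediately
after dye addition) of the same plate. The multiplication by 100 puts AR570
on a percent-like scale. AR570 <= 0 means no detectable reduction: the value
is stored as 0 with `detectable=False`, which downstream becomes the
"asterisk" (undefined) marker. Per-cell aggregation computes the correction
per well with that well's plate Ro, averages the *unclamped* values over the
replicate wells, and clamps/flags the aggregate — equivalent, by linearity,
to correcting per-plate channel means, and it keeps the correction exactly
linear under channel rescaling.

## Biofilm per viable cell

The per-cell index is `cv_mean / ar570` for cells with detectable viability
and undefined otherwise; undefined cells are excluded from condition
averages (never imputed). The highest-production flags take the argmax of
the condition average within each factor family and timepoint, flagging all
ties.

## Rank-product timepoint comparison

For each isolate and biological replicate, the production ratio
`OD(48 h)/OD(24 h)` is computed from the per-day technical-well means
(pairs with non-positive denominators are dropped). Within each replicate,
isolates are ranked by ratio — descending for the "up" direction, ascending
for "down" — with mid-ranks for ties. The statistic is the geometric mean of
an isolate's ranks across the k replicates.

The null model permutes ranks independently within each replicate, so a
single isolate's null rank per replicate is uniform over that replicate's
observed rank multiset. The null rank-product distribution is enumerated
exactly over the full Cartesian grid when it has at most B points (e.g. all
n^k combinations for untied data), and sampled with B Monte Carlo draws
otherwise; the one-sided p-value is `(count(null <= observed) + 1)/(N + 1)`.
The reported two-sided p doubles the smaller one-sided p (capped at 1):
the two one-sided rejection events are nearly disjoint, so the raw minimum
would reject ~2x the nominal level, while the doubled p keeps the empirical
type-I rate at alpha (verified at 0.05 by simulation in the acceptance
suite). Both one-sided p-values are reported alongside. No across-isolate
multiplicity correction is applied by default; Benjamini-Hochberg is
available behind `correction="bh"`. Defaults: B = 10,000, alpha = 0.05.

## PCA and UPGMA dendrogram

The feature matrix is the per-isolate vector of CV means and AR570 values
over all condition x timepoint cells (non-detectable viability enters as 0,
consistent with the clamp rule). Because CV and AR570 live on different
scales, columns are standardized to unit variance by default; zero-variance
columns are left centered at zero. PCA is computed by full SVD; components
are ordered by explained variance and signed so each component's
largest-magnitude loading is positive. Requesting more components than the
matrix rank is an error at the library level (the pipeline clamps to the
rank and logs).

The dendrogram uses Euclidean distances and unweighted average linkage
(UPGMA): the closest pair of clusters merges at a height equal to its
size-weighted mean inter-cluster distance. Tied minima are resolved in
favour of the pair containing the lexicographically smallest leaf label, so
the tree is reproducible regardless of input order. Average linkage is
reducible, so merge heights are non-decreasing and the tree is ultrametric;
Newick export places a cluster merged at height h at depth h/2, making leaf
to leaf path lengths equal to merge heights. Cutting at k clusters fails
loudly when tied heights straddle the cut; clusters are ranked by their
members' mean CV production and tagged best / intermediate / worst
(default k = 3).

## Synthetic data generator

The generator (`synthetic`) emulates the study design so that every stage is
testable with known ground truth: 10 panel isolates (latent classes taken
from the packaged classification tables), 14 conditions (baseline; 4, 10,
20, 37 degC; 1, 2, 4, 8% NaCl; pH 5-9), 24/48 h, 3 biological x 3 technical
replicates, 3 sterility wells per plate.

Signal model and defaults:

- Sterility CV OD ~ Normal(0.10, 0.02) truncated at 0, so the implied cutoff
  is ODc = 0.16 (the worked-example control level; the real replicate-level
  variances are unpublished, so these are conventions, not calibrations).
- Sample CV OD = multiplier(class) x ODc x mean-one lognormal noise with
  overall CV `noise_cv` = 0.15, split 2:1 (log-variance) between a per-day
  effect and a per-well effect. Multipliers {NP: 0.5, WP: 1.5, MP: 3, SP: 6}
  sit inside their threshold bands.
- Resazurin: baseline reads have OD570 = Ro x OD600 exactly (Ro = 1.25,
  oxidized OD600 ~ 0.40 with CV 0.05), so the per-plate Ro is recovered
  exactly and sterile wells correct to AR570 = 0. Sample final reads add a
  reduced-dye term making AR570 = 50 x expected CV OD with the same noise
  law — encoding the biofilm/viability proportionality the multivariate
  stage is meant to detect.

What the generator does not emulate: growth kinetics, contamination,
plate-edge effects, instrument drift, or heteroscedastic reader noise.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under a plausible noise model, not robustness to every real-world
artifact.

At these settings the full pipeline recovers >= 90% of latent producer
classes (280 isolate x condition x timepoint cells), and the k = 3 cut of
the UPGMA tree isolates the panel's dominant strong producer in the "best"
cluster.

## Problem sizes and numerical choices

The acceptance script simulates one full default design (84 plates, ~14k
readings), runs the rank-product test with B = 10,000 on the 10-isolate
baseline ratios, and estimates the type-I rate from 200 exchangeable-null
datasets of 50 isolates x 3 replicates at B = 2,000 — sizes chosen to give
stable estimates in seconds on one CPU. Floating-point comparisons when
counting null rank products use a 1e-9 log-slack so that mathematically
equal products (computed via logs) are counted as ties. The tidy TSV writers
emit full-precision floats; Newick branch lengths use 17 significant digits
so round-trips are lossless.

## Known limitations

- The layout schema carries no timepoint column (it lives in the readings),
  so replicate-key uniqueness is enforced within plates, not dataset-wide.
- The published study's own PCA variance and significant-isolate list are
  not reproducible from printed data (raw ODs unpublished); the package
  validates those stages by construction (oracles, simulations) instead.
- Which variables entered the study's ordination (CV only vs CV+RZ; raw vs
  standardized) is unstated; both are configuration flags with defaults
  documented above.
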