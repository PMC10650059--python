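# Methods

This note documents the models, conventions and numerical choices behind
`tamspatial`, in the order the pipeline runs.

## Cell tables and compartments

The unit of analysis is a patient sample; triplicate TMA cores are pooled
into one sample before any summarization. Coordinates are continuous µm in
the image frame (origin top-left, y increasing downward); no pixel indexing
applies. Each cell carries a tissue compartment, `tumor` (inside a
tumor-cell nest) or `stroma`, taken as given from upstream segmentation —
the package never re-derives compartments from real data. Compartment areas
(mm²) are required per-sample metadata from the clinical table, never
estimated from cell coordinates. A full 2.0 mm-diameter core has total area
π·(1 mm)² ≈ 3.14 mm².

When positivity must be derived from continuous intensities,
`apply_intensity_threshold` uses an inclusive comparison
(positive iff intensity ≥ cutoff), matching common gating software; only
markers named in the cutoff map are overwritten.

## Phenotype gating

A phenotype definition is a pair of marker sets (required-positive,
required-negative); all other markers are don't-care. Consequences worth
stating explicitly:

* **Labels are queries, not a partition.** A CD68⁺CD163⁺ cell with all
  other markers negative satisfies both the M2 base
  `CD68+CD163+MRP8-14negCD86neg` and the M2c refinement that adds
  `Arg-1neg`. Adding a required-negative marker can only shrink a set, so
  each M2a/M2c pair partitions its M2 base by Arg-1 state — an identity the
  tests check on random marker vectors.
* **Lineage exclusivity.** CK⁺ cells are malignant and are excluded from
  every CD68-based definition regardless of CD68 state; double-lineage
  cells are treated as segmentation artifacts. PD-L1 is don't-care in all
  M1/M2 definitions.
* **The catalogue is data.** Definitions are parsed from the field's label
  grammar (`MARKER+` / `MARKERneg`, with spellings Arg-1, MRP8-14, PD-L1
  normalized), and can be loaded from YAML/JSON. The shipped default holds
  17 rows: total CK⁺ and CD68⁺, 3 M1, 3 M2, 3 M2a, 1 M2b, 3 M2c, CK⁺PD-L1⁺
  and CD68⁺PD-L1⁺. "Macrophage phenotypes" counts the 13 M-labelled rows
  plus CD68⁺PD-L1⁺ (14); total CD68⁺ is the lineage denominator, not a
  phenotype.

## Density metrics

Density is matching-cell count divided by compartment area (cells/mm²).
`total` is pooled counts over pooled area — the only definition consistent
with cells/mm² semantics; it is *not* the mean of the two compartment
densities (the two coincide only when areas are equal). Cohort statistics
are the median across samples with the (min–max) range; the tumor-vs-stroma
comparison applies the Kruskal–Wallis rank test to the per-sample density
vectors. Composition percentages support two reporting conventions (round
to integer; truncate to 2 decimals) because both occur in published
composition statements.

## Spatial metrics

For each CK⁺ reference cell, the nearest-neighbor distance to a target
phenotype is the Euclidean distance (µm) to the closest *other* target cell:
self-matches are excluded by cell id, not by requiring nonzero distance,
since coincident centroids are legal. Distances are computed within one
sample only, with a k-d tree whose results are exact (the tests compare
against an exhaustive scan bit-for-bit).

Summaries use a two-level median: per-cell distances → per-sample median →
cohort median of per-sample medians. Pooling cells across samples was
rejected because samples have very different cell counts and large cores
would dominate. A sample where the target phenotype has no cells is *not
computable* (NaN sentinel) and is excluded listwise per phenotype; the same
convention flows into the published-table renderings as missing cells.
Clinical-subgroup comparisons use the Kruskal–Wallis test on per-sample
medians and are reported only when at least two subgroups contribute at
least 3 computable values in total.

Median dichotomization (for survival) sends values strictly above the
cohort median to `high_or_long` and everything at or below to
`low_or_close`; ties therefore go low, so the high group never outnumbers
the low group, and an all-tied feature cannot be split.

## Survival analysis

Time is in months; records at exactly zero are perturbed by half the
smallest positive time (logged). The Kaplan–Meier estimator and log-rank
test are delegated to lifelines. Cox models maximize the partial likelihood
via statsmodels `PHReg` with **Efron** tie handling by default (the
better-behaved standard; Breslow is selectable for cross-checks against
software that defaults to it). Derived columns keep the identities
HR = exp(B), Wald = (B/SE)², CI95 = exp(B ± 1.96·SE) exactly, with the
Wald p computed from the same z so printed columns are mutually consistent.

Degenerate inputs: a constant covariate is dropped with a flag (B = 0,
SE = ∞); a monotone likelihood (complete separation) makes the unpenalized
Hessian singular, in which case the model is refit with a small ridge
(penalty 10⁻³) and every coefficient is flagged `separation` — a finite,
clearly-marked large-SE answer instead of an exception. Flagged fits should
be interpreted as "direction only".

The median-split screen fits one Cox model per feature — the low-vs-high
indicator (low = 1) plus the adjusters (e.g. histology, asbestos exposure,
total CD68⁺ distance group) — rather than one joint model over all
features; with tens of collinear density/distance features a joint fit
would be unidentifiable, and the per-feature reading matches the adjusted
screening narrative the output table mirrors. Screen p-values are reported
unadjusted (the stated significance convention); a BH-adjusted column is
emitted alongside, clearly labelled, for convenience only.

## Nonparametric tests

Thin wrappers over scipy/statsmodels with reproducibility-oriented method
selection: Mann–Whitney U (identical to the Wilcoxon rank-sum test, and
exposed under both names) uses the exact distribution for
min(n, m) ≤ 8 without ties and the tie-corrected normal approximation with
continuity correction otherwise; Kruskal–Wallis uses the tie-corrected H
with chi-square df = k−1 (all-identical input short-circuits to H = 0,
p = 1); Spearman is the Pearson correlation of mid-ranks with a t
approximation, labelled strong/moderate/weak at |ρ| ≥ 0.6 / ≥ 0.3 / < 0.3
(configurable bins; 0.6 keeps published "strong" calls such as ρ = 0.669
consistent); Shapiro–Wilk gates reporting language only and never switches
methods silently. Multiplicity uses Benjamini–Hochberg step-up (the field
default for DEG screens; the adjustment method is a config knob).

## Expression screen

log2 fold change compares group mean TPM with a pseudocount of 1 (avoids
log 0; stated in output metadata). The DEG gate is |log2FC| ≥ 1 (inclusive)
AND BH-adjusted p < 0.05 (strict), with a two-sample t test for two groups
and one-way ANOVA for more. Quantiles use linear interpolation (type 7),
and "high expression" means strictly above Q3, so the high group never
exceeds n/4 + 1 samples.

## Synthetic data

The generator emulates the features the analysis depends on, with defaults
chosen once to match the validation-cohort scale:

* **Geometry** — 2.0 mm circular core; tumor nests as a Thomas cluster
  process (Poisson parent centers, 2.5/mm², at least one per core since an
  all-stroma core would not be analyzed; CK⁺ offspring Poisson(120) per
  nest with Gaussian scatter σ = nest_radius/2, nest_radius 150 µm). The
  tumor compartment is the union of nest discs; compartment areas come from
  seeded Monte-Carlo integration with 10⁵ points (relative error ~0.1%,
  ample next to Poisson count noise, and far simpler than exact disc-union
  geometry).
* **Macrophages** — independent Poisson placement per phenotype with
  separate tumor/stroma intensities on the published cells/mm² scale
  (total CD68⁺ around 45–70/mm², the CD163⁺ M2 base around 20–30/mm²,
  minor phenotypes at 1–5/mm²). An optional exponential attraction kernel
  re-weights locations by 1 + strength·exp(−d/scale) toward the nearest
  nest *after* the count is drawn, so distance effects and density effects
  stay separable by construction.
* **Markers** — each generated cell gets its phenotype's full marker
  pattern; PD-L1 is drawn independently (2%); every marker is then flipped
  with a symmetric 1% noise probability (kept ≪ 0.5 so phenotypes remain
  identifiable). Ground-truth counts refer to the pre-noise patterns.
* **Survival** — exponential times with log-hazard linear in chosen
  *realized* covariates (densities, distances, clinical factors; binary
  effects dichotomized at the realized cohort median, above-median coded 1),
  independent exponential censoring. Defaults give median OS ≈ 15 months
  and ~60% deaths, the published clinical profile. Clinical factors are
  Bernoulli draws at the published frequencies (85% epithelioid, 54%
  asbestos-exposed).
* **Expression** — Gaussian copula with target Spearman correlations
  (converted exactly via r = 2·sin(πρ/6)), lognormal TPM marginals
  (baseline means 50–500 TPM, σ = 0.25), and multiplicative fold-change
  spikes in group A. Infeasible correlation targets raise an error naming
  the needed shrinkage.

Everything is deterministic given the seed; per-sample streams derive from
(seed, sample index).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: panel-negative background cells (fibroblasts,
lymphocytes) are not placed, so simulated total cellularity is far below a
real core's; marker intensities are not modelled (positivity is generated
directly); segmentation artifacts, core-edge effects, staining batch
effects and within-patient core heterogeneity are absent; survival follows
a proportional-hazards exponential by construction, so recovery tests
validate the estimator, not the clinical model.

## Problem sizes in the shipped checks

The simulation-based checks use sizes chosen for statistical decisiveness:
Cox recovery uses 200 replicates of n = 300 with true log-HR = ln 2 and
~20% censoring (mean error < 0.05, CI coverage within [0.90, 0.98]); the
null screen calibration uses 10 cohorts of 80 samples × 200 independent
features against the binomial 95% band around 5%; attraction-kernel
recovery compares intensity-matched phenotype pairs across 50 cohorts of
12 samples (12 is the smallest cohort at which the paired comparison is
reliably decisive); the DEG screen spikes 20 of 500 genes 4-fold at
n = 30 + 30.

## Known limitations

* Compartment assignment is purely geometric in simulation and trusted as
  given on real data; no alpha-shape or morphological nest reconstruction.
* No Ripley's K / G-function machinery — the spatial statistic is the
  median NN distance only, by design.
* No proportional-hazards diagnostics or time-varying covariates.
* The expression arm screens a provided matrix; it does not fetch or
  reproduce any external cohort.
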