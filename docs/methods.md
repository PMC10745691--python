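# Methods

`gutbrain` implements an association pipeline between gut-microbiome
profiles and early-childhood neurodevelopmental outcomes: community-level
variance partitioning, per-species linear models, gene-set enrichment of
functional modules, and repeated-cross-validation random-forest ensembles
with fitness-weighted importance aggregation. This note records the models,
their assumptions, the defaults that matter, and the design choices made
where the design was genuinely open.

## Data model and cohort assembly

Taxonomic profiles arrive as merged clade-by-sample tables with
pipe-delimited rank prefixes; only species-level rows (deepest rank `s__`,
no strain suffix) are retained and each sample is renormalized over the
retained species, so downstream values are relative abundances summing
to 1. Whether renormalization after species extraction is appropriate
depends on how much signal sits above species rank; we renormalize because
every downstream statistic assumes a composition. Gene-family tables keep
community-total rows only (species-stratified rows and
UNMAPPED/UNINTEGRATED are dropped) and are likewise renormalized.

One analysis row per subject is produced by one of two pairing rules:

* **concurrent** — among records whose stool age lies in the analysis age
  window and whose cognitive assessment falls within `max_gap_days`
  (default 7 days; ages in months are converted at 30.4375 days/month) of
  the stool, the earliest stool age is selected. The early pick favours the
  least-confounded early sample when longitudinal records exist.
* **future** — the latest stool collected in the first year
  (0 < age ≤ 12 months) is paired with the subject's latest assessment at
  least `min_lead_months` (default 6) later. If the latest stool has no
  eligible assessment the search backs off to earlier stools; subjects with
  no eligible pair are excluded.

Age windows are half-open above (`[min, max)` months): under6 = [0, 6),
over18 = [18, 120), all = [0, 120). Maternal education enters all models as
a single ordinal integer (six levels, 1–6); sequencing depth as
log10(post-QC reads) because depth spans orders of magnitude; sex is coded
F = 0, M = 1. These encodings are package choices — dummy coding of
education is a defensible alternative and would change coefficients but not
the pipeline's structure.

Prevalence filtering keeps features detected (abundance > `min_abundance`,
default 0 — any nonzero counts as detection) in at least `min_prevalence`
of samples: 15% for species entering composite-score models, 10% for
subscale and gene-function analyses. Rows are *not* renormalized after
filtering; models see the retained features' original relative abundances.

Brain-region volumes are divided by total brain volume (white + gray
matter) per sample before any modeling, removing gross head-size and age
scaling from the targets.

## Community-level inference

Bray-Curtis dissimilarity BC(x,y) = 1 − 2·Σmin(x,y)/Σ(x+y) on relative
abundances; ordination by classical PCoA (eigendecomposition of the
Gower-centered −½D²; negative eigenvalues, which Bray-Curtis produces, are
dropped and counted, and variance explained is reported over the positive
eigenmass). Brain-volume ordination is the same machinery on Euclidean
distances of normalized volumes.

PERMANOVA is a one-covariate distance-based linear model: with
G = −½·J·D²·J and H the hat matrix of [1, covariate],
R² = tr(HGH)/tr(G) and pseudo-F = (R²/df₁)/((1−R²)/df₂). Each covariate is
tested marginally (one-term model) and Benjamini-Hochberg correction is
applied across the battery; a joint or sequential decomposition is a
different estimand and is out of scope. Significance comes from permuting
covariate rows with the +1 pseudo-count convention,
p = (1 + #{F* ≥ F})/(1 + n_perm), so p is never 0; default
n_permutations = 9999, which resolves q < 0.001 tiers. For n ≤ 7 the test
switches to exhaustive enumeration of all distinct covariate orderings and
reports the exact p (identity included). The Mantel test correlates upper
triangles of two distance matrices over their shared samples (≥ 4
required), with one-sided (greater) permutation p under the same
conventions.

## Per-feature linear models

Abundances are transformed as log2(x + δ) with δ = half the smallest
nonzero value in the whole table; δ is recorded in the result provenance.
An arcsine-square-root transform is available behind a flag — the log
pseudo-count choice is the package's own, and results for rare features are
sensitive to it. Each feature's transformed abundance enters an OLS model
of the outcome with the fixed covariate block (age, maternal education,
log10 depth); the abundance term's two-sided t p-value is BH-corrected
*within each analysis battery* (per age window, per outcome), and
significance is called at q < 0.2. Rank-deficient feature designs are
skipped with a logged reason rather than failing the battery.

## Gene-set enrichment (FSEA)

Per gene, the statistic is the partial Pearson correlation between
transformed abundance and outcome given age (both sides residualized on
age), with t = r·√(n−2)/√(1−r²). The enrichment score of a set is the
Hodges–Lehmann pseudomedian (median of all Walsh averages) of the
within-set correlations; its sign is the enrichment direction. The p-value
is a two-sided Mann-Whitney U comparing within-set vs all other measured
genes — genes, not samples, are the exchangeability unit — computed exactly
when the smaller side has ≤ 8 members and by the tie-corrected normal
approximation otherwise. BH across the sets of a battery; significance at
q < 0.2. A GSEA-style running-sum curve is emitted for display only and
carries no inferential weight. Because per-gene statistics are correlated
(genes share carrier species and the composition is closed), the rank-test
p-values are approximate; the null-calibration study below measures how
close to uniform they are in practice.

## Random-forest ensembles

The protocol is 100 repetitions of 3-fold CV, each fold fit with 10 forest
RNG states: 3000 models per input set. The fold partition is fixed within a
repetition; the RNG states re-seed forest construction only. Forests use
the classical regression defaults: 100 trees, ⌈p/3⌉ candidate features per
split, minimum leaf 5, unlimited depth. Age in months is a covariate in
every model; the demographics block adds sex and maternal education.
Predictors are raw relative abundances (forests are invariant to monotone
per-feature transforms).

Each model records train/test RMSE, Pearson r (0 with a logged tally when a
split's predictions are constant), MAPE for volume targets, and
mean-decrease-in-impurity importances normalized to sum 1. Importances are
aggregated across all models with weights

    fitness = max(r_train, 0) · max(r_test, 0),

which zeroes both underfit and non-generalizing models; if every fitness is
0 the unweighted mean is used with a warning. Summary intervals are
empirical 2.5/97.5 percentiles of the per-record metric distribution, and
the headline correlation is the mean of per-record test r (pooling
predictions before correlating is a different, slightly less dispersed
estimator). Feature selection reports the shortest descending-importance
prefix reaching a cumulative fraction — 0.6 for cognition models, 0.5 for
brain-region models — with ties broken lexicographically for determinism.
Every forest and partition is seeded from the base seed through a
`SeedSequence` keyed on (seed, repetition, fold, rng-state), so results are
bit-reproducible and independent of execution order.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume, not
any particular real cohort: species compositions are logistic-normal with a
per-species age slope (logit-scale SD 1.0) producing the dominant age
gradient real infant cohorts show; sparsity is imposed by zeroing the
smallest fractions per sample to a target fraction (default 0.7, typical of
species tables); gene-function abundances are weighted sums of 1–3 carrier
species with lognormal noise, so taxonomic and functional spaces co-vary
strongly; the composite score is 100 + covariate effects + Σ planted
effects × standardized log2 abundance + N(0, noise_sd²), clipped to
[40, 160] (instrument floor/ceiling; default noise_sd 10 keeps RMSEs on the
10–20-point scale of standardized instruments); brain-region volumes are
age-trending fractions of a growing total brain volume plus noise. Default
cohort size is 150 subjects, 100 species, 200 gene functions, ages uniform
on 1–120 months. An optional assessment lag (e.g. 6–30 months) produces
future-design cohorts. The null generator removes *every* effect on the
score — planted taxa, gene-set links, and covariate effects — because its
purpose is type-I-error calibration of tests against the score; with an age
effect retained, the age-driven composition would make those tests
correctly (but unhelpfully) reject.

One global seed expands into per-component substreams via a counter scheme,
so adding a component never perturbs earlier draws.

What the generator does not emulate: real co-occurrence networks,
within-subject longitudinal dynamics beyond the age trend, batch effects,
measurement error in assessments, or the taxon-specific effect sizes of any
real cohort. Passing tests therefore demonstrate that the machinery is
correct and calibrated under its assumed data model — not that any
biological association holds, nor that real-data effect sizes would be
recovered.

## Validation studies and problem sizes

The package validates itself with fixed, seeded studies (module
`gutbrain.validation`, rerun by `scripts/acceptance.py`):

* repeated-CV bookkeeping: the full 100×3×10 scheme on a 60-subject,
  30-species cohort with 25-tree forests yields exactly 3000 records;
* PERMANOVA type-I error: 200 null cohorts (n = 30, 50 species,
  199 permutations), rejection at α = 0.05 expected in [0.03, 0.08];
* p-value uniformity: per-taxon LM p-values on a null cohort (n = 150,
  ~200 tested features) and enrichment p-values for 500 random gene sets,
  both compared to Uniform(0,1) by KS distance (< 0.1);
* forest null: mean held-out correlation over 50 reduced ensembles on null
  cohorts inside (−0.1, 0.1);
* power: a planted 0.5-score-SD taxon at n = 300 reaches q < 0.2 and a
  top-5 fitness-weighted importance rank, and a linked gene set tops its
  battery, in ≥ 90% of 20 seeds;
* determinism: two pipeline runs from the same seed produce byte-identical
  CSVs.

The reduced ensemble and cohort sizes in these studies are the package's
own calibration-study design; the full-protocol constants (3000 models,
9999 permutations) are exercised where they are cheap.

## Known limitations

* PERMANOVA is single-covariate (marginal) only; no strata, no sequential
  decomposition, no dispersion (PERMDISP) companion test.
* The linear models are not compositional (no log-ratio transform);
  coefficients inherit the usual closure artifacts.
* Mann-Whitney enrichment p-values ignore inter-gene correlation; they are
  calibrated here by simulation, not by construction.
* MAPE is undefined for zero-valued targets and is reported as NaN there.
* The CLI's `rf-subscales` analysis is reachable through the library
  (`fit_feature_lms`/`run_ensemble` with a subscale outcome) rather than a
  dedicated subcommand.
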