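# Methods

This note documents the statistical procedures, their parameters and
defaults, the synthetic-data model used for validation, and the numerical
conventions adopted where the design was genuinely open.

## Expression preprocessing

Input matrices are log2 ratios (two-color array convention), probes or
genes × samples, with missing entries.

1. **Missingness filter.** A probe is removed when its missing fraction
   strictly exceeds `max_missing_frac` (default 0.2); a probe at exactly
   the threshold is retained.
2. **KNN imputation** (`knn_k`, default 10). For a missing cell (i, j)
   the fill is the unweighted mean, over the k nearest rows, of column j.
   Row distance is Euclidean over the columns observed in both rows; rows
   missing column j are not eligible neighbours. Observed cells are never
   modified. This row-neighbour scheme is the standard microarray
   imputation; it is written here directly because generic imputers treat
   columns, not rows, as the neighbour space.
3. **Median centering.** Each probe's median across arrays is subtracted
   (even-length rows use the midpoint convention). Centering is idempotent
   and shift-invariant.
4. **Probe → gene collapse** (`collapse_rule`, default `max`): per gene
   symbol, the single probe with the highest mean expression across
   samples represents the gene. `mean`/`median` aggregate per cell
   instead. Unmapped probes are dropped and counted in the run report.

Default order is filter → impute → center (at probe level) → collapse;
centering after collapse is available by config because both orders occur
in practice. Accepted missing-value sentinels are empty fields and
`NA`/`NaN` in any case.

## Intrinsic-subset classification

Subset centroids are gene-wise arithmetic means of reference expression
over the samples of each subset (inflammatory, fibroproliferative,
normal-like; a "limited" subset can be excluded for diffuse-only study
populations). Intrinsic genes absent from the study platform are dropped
with a logged count — in the motivating dataset ~81 % of the reference
list survives this intersection.

A sample is assigned by Spearman correlation against each centroid over
shared genes. Ranks use midranks; the two-sided p-value is exact (full
permutation enumeration) for n ≤ 9 genes and the t-approximation
t = ρ√((n−2)/(1−ρ²)) above. The call is the subset with the highest ρ.
The field's dual criterion (highest coefficient *and* lowest p) coincides
with argmax-ρ when every centroid shares the same gene overlap and the
best correlation is positive; when the two criteria point at different
subsets (e.g. a large negative correlation elsewhere) ρ wins and a
warning is recorded on the call. Ties in ρ resolve by smaller p, then
alphabetically. Constant sample vectors (zero rank variance) are an
error, not a silent call.

Because the classifier is rank-based it is invariant under any strictly
monotone transform of the sample vector; this is tested.

**Signature scores** are per-sample means of centered expression over a
gene set's members present in the matrix; baseline→post deltas per
patient quantify loss or gain of a signature. Paired deltas are tested
with a paired t-test.

**Hierarchical clustering** uses average linkage on 1 − Pearson
correlation (uncentered-correlation option for fidelity to the classic
clustering tools); constant items get correlation 0 to everything with a
warning. Leaf order is deterministic given input order (SciPy's condensed
distance tie-handling). Dendrograms export as Newick and an optional
CDT-style table.

## Differential expression

Per-gene Student t: paired designs test per-pair differences, unpaired
designs use the pooled-variance two-sample t. Zero-variance genes are
flagged `degenerate` with p = 1 (no difference) or the smallest
representable p (constant nonzero difference) instead of being dropped.
At trial scale uncorrected p < α (default 0.05) defines significance,
reflecting the small-sample reality of a ten-patient study;
Benjamini–Hochberg q-values are reported alongside for information, and a
label-permutation p is available by option.

## Enrichment

**GSEA.** Genes are ranked by signal-to-noise (meanA − meanB)/(sdA + sdB)
with the conventional sd floor max(sd, 0.2·|mean|, 0.2); a pooled-t metric
is switchable. The enrichment score is the extremum of the weighted
running sum (hit increments |metric|^weight normalized over the set,
weight default 1; miss decrements 1/(N − N_hit)); an exact magnitude tie
between the positive and negative extremum resolves positive. The null
distribution is **gene-set permutation** (random same-size sets): with
two or three samples per class, sample permutation cannot produce enough
distinct relabelings to be sound, so set permutation is the default and
sample permutation is deliberately not offered at these sizes. NES divides
ES by the mean |null ES| of its sign; nominal p is the same-sign tail
fraction with the +1 correction; FDR q follows the standard signed-pool
procedure over all sets' normalized nulls and is forced monotone in |NES|
within each sign pool. Significance defaults to FDR < 10 %. Set-size
filters default to 15–500 but are fully configurable, since meaningful
trial signatures can be smaller.

**ssGSEA.** Per sample, genes are ordered by decreasing expression (ties
broken by stable input order) and given rank values N..1 from the top;
the set score integrates the difference between the in-set ECDF weighted
by rank^α (α default 0.75) and the uniform out-of-set ECDF. A constant
sample carries no ordering information and scores 0 with a warning.
Optional normalization divides the projection by its score range.

**Over-representation.** One-sided hypergeometric upper tail of the
query/set overlap within the universe, BH-adjusted across sets,
significant at q < 5 %. This is a self-contained replacement for external
annotation services so the pipeline has no network dependency.

## Clinical statistics

* **LOCF** over the eight-visit schedule (days 1, 15, 29, 57, 85, 113,
  141, 169); fills are flagged per cell; a missing baseline is an error.
* **Improver**: relative mRSS change (baseline − final)/baseline ≥ 0.30,
  boundary inclusive, final = day-169 value post-LOCF.
* **Fisher exact 2×2**, two-sided by the probability-mass rule: sum of
  hypergeometric probabilities of all same-margin tables with probability
  ≤ observed (relative tolerance 1e−7). This rule reproduces the
  responder-table p = 0.5 exactly. Zero margins give p = 1, flagged.
* **Wilcoxon signed rank**: zeros dropped, midranks on |differences|;
  exact two-sided p for n ≤ 25 via the full distribution of the
  positive-rank sum over sign assignments (dynamic program on doubled
  ranks — identical to 2^n enumeration, verified against it), measured as
  deviation from the null center; above 25, normal approximation with
  continuity and tie correction.
* **Summary t-tests**: pooled (equal-variance) by default — this is the
  convention that reproduces the printed baseline comparisons — with
  Welch/Satterthwaite by flag.
* **Mixed model**: mRSS ~ disease duration + drug + visit index
  (+ visit×drug optionally) with patient random intercept, REML via
  statsmodels MixedLM (optimizer fallback chain lbfgs → powell → cg;
  boundary variance is reported, not hidden). Fixed-effect CIs and p use
  a t reference with residual df = N_obs − n_fixed − n_patients + 1; the
  method string is recorded in the output. Visit enters as the 0-based
  rank of the visit day, making the fit invariant to affine recoding of
  the schedule.

## Synthetic-data model

The generator emulates the study structure, not its raw data. Expression:
background genes ~ Normal(0, σ) with σ = 0.5 (a heavy-tailed t₅ option
exists for robustness checks); each subset owns a 100-gene signature
block shifted +2.0 log2 units in that subset's samples. These values give
a clearly separable but noisy subset structure, the regime the
nearest-centroid method is intended for. Missingness can be injected
completely at random.

The trial cohort (default 7 treated / 3 placebo, matching the study arms,
plus 4 healthy controls for clustering display) draws disease durations
per arm (treated 2.4 ± 1.6 y, placebo 8.8 ± 3.8 y), assigns subsets with
probabilities (0.5, 0.15, 0.35) for inflammatory / fibroproliferative /
normal-like, and generates mRSS as
intercept 30 − 0.9·duration − 9.8·drug − 0.1·visit − 0.9·visit·drug
+ b_i + ε, b_i ~ N(0, 6²), ε ~ N(0, 3²), rounded and clipped to [0, 51].
The constant drug offset and duration slope take the trial's published
mixed-model estimates as generating truth; the visit×drug interaction
carries the within-trial improvement so that responder flags — derived
from the generated trajectories, never imposed (unless
`force_improver_fraction` overrides them for fixed-design experiments) —
concentrate in the treated arm. Treated responders lose `decay` = 1.5
log2 units of their own subset signature post-treatment; non-responders
and placebo drift mildly upward (+0.2), mirroring the observed
stable-or-reversed behaviour.

What passing tests on these cohorts show: the classifier, tests and model
recover known truth under Gaussian log-ratio noise with clean block
signatures. What they do not show: robustness to batch effects, dye bias,
correlated gene blocks, outlier arrays, or non-Gaussian biology — real
arrays are messier, and those factors are out of the generator's scope by
design.

## Problem sizes and determinism

Simulation-based checks use 200 replicates (mixed-model coverage, power)
or 200 samples (subset recovery) and 1000 genes (null calibration) —
sizes at which the binomial noise on the checked proportions is well
below the acceptance margins. All randomness flows from explicit seeds
(`numpy.random.default_rng`); identical config + seed reproduces
byte-identical cohorts, and the pipeline rerun under the same config
yields an identical report.

## Known limitations

* The exact Spearman p enumerates permutations and is only used at
  n ≤ 9 genes; assignment over hundreds of genes uses the
  t-approximation, which is standard but approximate.
* The gene-set permutation null in GSEA answers "is this set more
  enriched than a random set of the same size", not the sample-label
  question; with ≤7 samples per class this is the defensible choice, but
  it is a different null.
* The mixed-model df rule is a pragmatic residual-df convention;
  Satterthwaite/Kenward–Roger adjustments are not implemented.
* The responder threshold treats mRSS as exact; measurement error in
  skin scoring is not modelled.
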