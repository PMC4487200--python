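# sscexpr

Analysis toolkit for linking skin gene-expression change to clinical
response in a small placebo-controlled trial of a T-cell costimulation
blocker (abatacept) in diffuse cutaneous systemic sclerosis (dcSSc).

It is aimed at translational researchers analysing paired-biopsy
expression data alongside a longitudinal clinical endpoint — here the
modified Rodnan skin score (mRSS, 0–51) over eight visits — in cohorts far
too small for anything but careful, exact, small-sample statistics.

## What it computes

**Molecular layer.** Two-color microarray log-ratios are filtered
(probes with >20 % missing data removed), KNN-imputed, median-centered,
and collapsed from probes to gene symbols. Each skin sample is assigned to
an *intrinsic gene-expression subset* (inflammatory, fibroproliferative,
normal-like) by nearest-centroid classification: subset centroids are the
gene-wise means over a labeled reference cohort, and a sample's call is
the centroid with the highest Spearman rank correlation

&nbsp;&nbsp;&nbsp;&nbsp;ρ(x, c_s) over shared intrinsic genes, call = argmax_s ρ.

Per-gene differential expression uses paired or pooled-variance Student
*t*; gene-set level change uses GSEA (weighted Kolmogorov–Smirnov running
sum with a gene-set permutation null and signed-pool FDR), single-sample
ssGSEA projections (weighted-ECDF differences, exponent α = 0.75), and a
hypergeometric over-representation test for discrete signatures.

**Clinical layer.** Missing visits are filled by last observation carried
forward (LOCF). A patient is an *improver* when mRSS falls ≥30 % from
baseline to the final visit. Group comparisons use exact tests sized for
n = 10: a two-sided Fisher exact test (probability-mass rule), exact
Wilcoxon signed-rank (full sign-assignment distribution for n ≤ 25),
and pooled-variance *t* from summary statistics. The treatment effect on
mRSS is estimated by a linear mixed model

&nbsp;&nbsp;&nbsp;&nbsp;mRSS_ij = β₀ + β₁·duration_i + β₂·drug_i + β₃·visit_j (+ β₄·visit_j·drug_i) + b_i + ε_ij,

with a patient random intercept b_i, fitted by REML.

**Synthetic cohorts.** `sscexpr.simulate` generates a labeled reference
cohort and a paired baseline/post trial with known ground truth (subset
labels, responder flags, generating mRSS parameters), so the whole
pipeline is testable end to end without any external download.

## Worked example

```bash
sscexpr run-all config.yaml     # or, from Python:
```

```python
from sscexpr.pipeline import run_pipeline
report = run_pipeline({"seed": 1, "output_dir": "demo"})
```

With the default synthetic design (7 treated / 3 placebo patients, 2000
genes, 100-gene subset signatures at a 2.0 log2 shift, treated responders
losing 1.5 log2 units of their signature) this prints artifacts to
`demo/` and returns a report containing, among others:

```
improvers by arm:   {'abatacept': 6, 'placebo': 0}
fisher exact p:     0.033
drug coefficient:   -14.6  (95% CI -27.7 to -1.5), p = 0.029
subset recovery:    1.0
A03: improver, baseline subset inflammatory, signature delta -1.56
A04: improver, baseline subset inflammatory, signature delta -1.50
```

Reading: all six treated patients but no placebo patient improved
(Fisher exact p = 0.033); the mixed model attributes a ~15-point mRSS
reduction to treatment after adjusting for disease duration (the
generating model put the constant drug offset at −9.8 plus a −0.9/visit
treatment interaction, which the interaction-free fit absorbs into the
drug term); every baseline sample was assigned its generating intrinsic
subset; and treated improvers from the inflammatory subset lost ~1.5 log2
units of the inflammatory signature post-treatment while others did not —
the molecular pattern the clinical response tracks.

Individual steps are available as CLI subcommands (`simulate`,
`preprocess`, `subtype`, `markers`, `gsea`, `ssgsea`, `clinical`) and as
plain library functions.

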