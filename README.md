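# ironsig

Aberrance signatures of iron-regulatory genes and their association with
survival in diffuse gliomas — an end-to-end, fully tested re-implementation
of the analysis pipeline, exercised on synthetic cohorts with known ground
truth.

## The problem

Iron metabolism genes (HFE, TFRC, STEAP3, …) are candidate prognostic
markers in WHO grade II–III ("lower-grade") gliomas. Given a genes × samples
expression matrix and a clinical table with right-censored overall survival,
the pipeline asks: does *aberrant* expression of a small iron-gene panel —
any gene with a per-gene z-score `|z| > 2` across the cohort — define a
patient subgroup with shorter survival, and which genes carry the signal?

The analysis has five stages, all implemented here:

1. **Aberrance calling** (`ironsig.io`) — per-gene z-scores
   `z = (x − x̄)/s` across all samples (sample SD, `ddof=1`), aberrant iff
   `|z| > 2` (strict), a sample is panel-aberrant iff any panel gene is
   aberrant.
2. **Survival statistics** (`ironsig.survival`) — Kaplan–Meier
   product-limit curves `Ŝ(t) = Π(1 − dᵢ/nᵢ)`, medians (smallest *t* with
   `Ŝ(t) ≤ ½`), and the unweighted two-group log-rank test
   `χ² = (ΣO − ΣE)²/ΣV` for the aberrant vs. non-aberrant split, optionally
   per tumor grade.
3. **Survival predictors** (`ironsig.predictors`) — a leave-one-out
   1-nearest-neighbor predictor in panel z-score space, a random-selection
   baseline replicated 100×, the median-of-residuals error
   `med |Y_p − Y_o|`, Mann–Whitney comparison (exact enumeration for small
   samples) and Pearson diagnostics r₁ (observed vs. predicted) and r₂
   (relative risk vs. survival).
4. **Penalized Cox selection** (`ironsig.coxnet`) — elastic-net penalized
   Cox regression, `−(1/n)·ℓ_Breslow(β) + λ(α‖β‖₁ + ½(1−α)‖β‖₂²)`, fit by
   cyclic coordinate descent with soft-thresholding along a log-spaced
   λ-path with warm starts; λ chosen by 10-fold Verweij–van Houwelingen
   cross-validated deviance; the signature is the set of nonzero
   coefficients.
5. **Greedy refinement** (`ironsig.pipeline`) — forward selection of the
   gene maximizing the any-aberrant KM median-survival difference, with
   every test counted toward a Bonferroni familywise threshold.

`ironsig.simulate` generates cohorts with the statistical shape of TCGA
LGG/GBM downloads (continuous expression with rare outliers, exponential
proportional-hazards survival, administrative censoring, grade strata,
optional IDH1 flags) and plants known effects so that every stage can be
validated against ground truth.

## A worked example

`examples/` contains one short script per capability. For instance,
`python examples/02_aberrance_km_split.py` plants a gene whose aberrance
multiplies the hazard fivefold in a 300-patient cohort and recovers it:

```
aberrant patients: 13, non-aberrant: 287
median survival, aberrant:     14.6 months
median survival, non-aberrant: 83.8 months
median difference:             69.3 months
log-rank chi2 = 33.53, p = 7e-09
direction (O - E, aberrant): +10.0
```

Thirteen patients carry an aberration; their median survival is 69 months
shorter, and the aberrant group suffered ten more deaths than expected
under the no-difference null. `examples/03_coxnet_feature_selection.py`
shows the elastic-net Cox fit ranking the three planted genes first with
the planted signs, and `examples/05_greedy_signature.py` shows greedy
refinement picking them in order while the covered-patient fraction grows.

The same functionality is scriptable from the shell:

```bash
ironsig simulate --preset lgg-like --seed 3 --out sim/
ironsig coxnet --expr sim/expression.tsv --clinical sim/clinical.tsv \
    --panel iron61 --seed 1 --out fit.json
ironsig km --expr sim/expression.tsv --clinical sim/clinical.tsv \
    --panel selected8 --grades 2,3 --out comparison.json
ironsig run --expr sim/expression.tsv --clinical sim/clinical.tsv \
    --seed 1 --out report.json
```

Expression files are tab-delimited with a `Hugo_Symbol` first column and
sample-id headers (the cBioPortal export dialect); clinical files carry
`sample_id`, `os_months`, `event` and optional `grade`, `idh1_mutated`,
`dfs_months` columns. Three gene panels ship with the package
(`iron61`, `irgs16`, `selected8`); see `src/ironsig/panels/` for their
provenance notes.

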