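# Methods

## Aberrance model

Expression is summarized per gene as a z-score relative to the gene's
average across all samples of the cohort, with the sample standard
deviation (`ddof=1`; configurable — the convention is not forced by the
statistic, and with hundreds of samples the choice is immaterial). A
(gene, sample) cell is *aberrant* when `|z| > 2`, a strict inequality; a
sample is aberrant for a panel when at least one panel gene is aberrant in
it. Missing expression is excluded from the mean/SD and is never called
aberrant (absence of evidence). Zero-variance genes z-score to all zeros
with a warning rather than an error, so constant control rows do not abort
a run. Because z-scoring removes per-gene location and scale, aberrance
calls are invariant to any per-gene affine transform `a·x + b` (`a > 0`)
of the input — verified as a property test.

Z-scores are always recomputed from the provided matrix rather than
trusting precomputed export z-scores, whose reference population may be a
diploid subset rather than the full cohort; `--zscores-precomputed` skips
recomputation when the file already contains the intended scores.

## Survival statistics

Kaplan–Meier curves use the product-limit form over distinct event times;
censored observations leave the risk set without a drop, and a censoring
time tied with an event time keeps the censored sample at risk for that
event (events first). The survival median is the smallest observed time
with `Ŝ(t) ≤ 0.5`; under heavy censoring a group's median may never be
reached, and it is then reported as such (`None`) rather than
extrapolated. The two-group comparison is the standard unweighted log-rank
test with hypergeometric variance and a chi-square(1) p-value; the sign of
`ΣO − ΣE` for the aberrant group is reported so that a protective
association (aberrations with *longer* survival, which does occur in
grade IV cohorts) is distinguishable from a harmful one at the same
p-value. Group comparisons that are degenerate (an empty arm, or no events
in a stratum) are flagged not-comparable instead of raising, because panel
× grade grids routinely produce empty cells.

## Predictors

Both predictors are evaluated on uncensored (deceased) patients only:
residuals are `|predicted − observed|` months from diagnosis to death, and
a censored time bounds survival from below without measuring it. By the
same argument censored patients are excluded from the 1NN donor pool by
default (`include_censored_neighbors=True` implements the alternative
reading; it biases predictions low).

The 1NN predictor assigns each patient the observed survival of the
nearest other patient in Euclidean distance over the panel's z-scores —
all genes weighted equally, no training phase. Distance ties break on the
smaller sample id so results are independent of input order.

The random baseline draws, for each patient, a survival time uniformly
from the other evaluable patients, replicated 100 times. Its headline
error is the mean over replicates of each replicate's median residual —
the average performance of random selection. The per-draw residuals (not
the residuals of the across-replicate mean prediction) are also what the
Mann–Whitney comparison uses: a mean over 100 draws is a much better
point predictor than a single random draw, and comparing a genuine
predictor against it would both understate the baseline's error and break
the exchangeability that makes the test calibrated on null cohorts. With
this convention the Mann–Whitney p-values are uniform when no
expression–survival signal exists, which the acceptance suite checks.

The Mann–Whitney test enumerates all `C(n₁+n₂, n₁)` group assignments
exactly when both residual sets have ≤ 8 values (midranks handle ties);
larger samples use the tie-corrected normal approximation.

## Elastic-net penalized Cox regression

The selection engine minimizes

    f(β) = −(1/n) ℓ_Breslow(β) + λ ( α‖β‖₁ + ½(1−α)‖β‖₂² )

by iteratively reweighted least squares with cyclic coordinatewise
soft-thresholding — the quadratic expansion uses the diagonal of the
Hessian, coordinates update as
`β_j ← S(c_j, λα) / (v_j + λ(1−α))`, and an active-set schedule (full
sweep, then nonzero-set sweeps until stable, then a full sweep to admit
new coordinates) keeps the cost near the size of the active model. The
inner kernel is JIT-compiled. Tied event times use the Breslow
approximation, the standard choice for coordinate-descent Cox solvers.

The λ-path holds 100 log-spaced values from `λ_max` — computed from the
score at β = 0 so the first solution is exactly zero — down to
`λ_max/100`, with warm starts. Convergence at each path point is a
relative change in the penalized objective below `tol = 1e-7`
(`max_sweeps = 10000`, exceeded → error, never a silent partial fit).
Because the quadratic model can overshoot the true objective, each outer
step backtracks (step-halving) until the objective does not increase;
the per-step objective trace is exposed and asserted non-increasing in
tests. Covariates are the z-scores and are not re-standardized.

λ is selected by 10-fold cross-validation with folds stratified by event
status (heavy censoring makes unstratified folds event-poor). The deviance
is the Verweij–van Houwelingen cross-validated partial likelihood,
`−2[ℓ_full(β₋k) − ℓ_train(β₋k)]`, which credits held-out samples through
the full-data risk sets; the rule is the minimum of the fold-mean curve
(no 1-SE rule — the analysis wants the best-supported signature, not the
sparsest defensible one). The elastic-net mixing defaults to α = 0.95:
mostly-L1 so selection is sparse, with a small ridge component for
stability among correlated genes; it is exposed everywhere as `--alpha`.
Selected features are the genes with nonzero coefficients at the chosen λ,
reported in decreasing |β|; per-sample relative risk is `exp(x·β)`.

At vanishing penalty the fit reproduces the unpenalized partial-likelihood
MLE; the suite verifies ≤ 1e-4 agreement with an independent Newton-type
solver (lifelines) on small censored cohorts, and with direct grid
minimization of the (penalized) objective for single-covariate problems.

## Greedy signature refinement and multiplicity

Step one scans every candidate gene and keeps the one whose
aberrant/non-aberrant split maximizes the absolute KM median-survival
difference; step *k*+1 rescans the remainder with aberrance defined as
any-of(panel + candidate). Ties break by smaller log-rank p, then by gene
name. With *k* candidates a complete run performs `k + (k−1) + … + 1`
comparisons (36 for eight genes); the trace records the count actually
executed and the Bonferroni threshold `α/n_tests`, and
`bonferroni_adjust` caps adjusted p-values at 1. When a stratum's median
is not reached (routine at ~79% censoring), the step objective falls back
to the difference of restricted mean survival times over the common
follow-up window, flagged in the trace, so the search remains defined.
Aberrant-patient fractions along the trace are reported among uncensored
patients and are non-decreasing by construction (panels only grow).

## The synthetic-cohort generator

The generator emulates the *structure* of a TCGA-style glioma download:
genes × samples continuous expression (standard-normal background), rare
outliers (each cell independently with probability `outlier_fraction`
receives a ±`outlier_shift` addition), exponential event times under
proportional hazards `h_i = h₀ · exp(Σ β_g x_{g,i})`, administrative
censoring at a fixed horizon, grade labels, and an optional IDH1 flag.
Two effect mechanisms can be planted: linear log-hazard-ratios per z-unit
(what a Cox model fits) and aberrance-linked hazard multipliers (hazard
× m for samples with `|x| > 2` in a gene — what the KM split detects).
Exponential times keep the model inside proportional hazards with a
closed-form median (`ln 2 / rate`) for verification. One integer seed
drives all draws through deterministically derived per-stage substreams.

Preset conditions:

* `lgg_like_config` — 275 samples, 61 genes, baseline median 90 months
  with a 30-month horizon, hence `exp(−ln2·30/90) ≈ 79%` censored;
  grade II/III roughly even; IDH1 mutation frequency 0.8.
* `gbm_like_config` — 135 grade-IV samples, baseline median 14 months,
  30-month horizon (≈ 23% censored), IDH1 frequency 0.055.

Simulation scenarios used by the validation suite, chosen once as
realistic for this setting:

* *Cox recovery*: n = 300, three causal genes at log-HR ±0.8 among 61,
  LGG-like censoring.
* *KM power / greedy ordering*: hazard ×5 for aberrance in one gene among
  eight, `outlier_fraction = 0.05`, shift 4σ, 60-month follow-up. The
  shift is 4σ rather than 3σ because planted outliers inflate the
  per-gene SD, and a 3σ shift leaves many planted outliers under the
  recomputed |z| > 2 threshold; the magnitude mirrors a single-gene split
  that is overwhelmingly significant, as the motivating application
  reports.
* *Predictor contrast*: same effects as Cox recovery but under the
  GBM-like censoring regime, because residuals exist only for deceased
  patients and a 79%-censored cohort leaves too few evaluable patients
  for a stable contrast.

What the generator does **not** emulate: empirical expression covariance
and batch structure (genes are independent), non-exponential hazards,
staggered study entry (censoring is purely administrative), and any
dependence of grade or IDH1 status on expression. Passing tests therefore
demonstrate correctness of the statistical machinery and recoverability
of planted effects under the stated conditions — not that real glioma
cohorts carry such signals.

## Numerical and design choices

* Strict `>` at the aberrance threshold; a value at exactly z = 2 is not
  aberrant.
* Median convention: even-n medians average the two central order
  statistics everywhere (numpy's convention).
* Log-rank variance terms with a single patient at risk are skipped
  (their hypergeometric variance is 0/0); a comparison with zero total
  variance returns χ² = 0, p = 1.
* `λ_max ≤ 0` (no events contributing score) falls back to a nominal
  small value rather than a degenerate path.
* Greedy and 1NN tie-breaks are lexicographic so reruns and permuted
  inputs give byte-identical results; the full-analysis report is JSON
  with sorted keys and its rerun-identity is asserted in tests.
* Problem sizes in the validation suite (50-seed recovery at n = 300,
  1000 null log-rank splits at n = 120, 100-replicate predictor
  contrast) were chosen to make the binomial success bounds sharp at
  the stated thresholds while keeping a full run in minutes on one CPU.

## Known limitations

* Breslow (not Efron) tie handling; with continuous simulated times the
  two coincide, but heavily tied real data would differ slightly.
* No confidence bands on KM curves, no multivariable adjustment (age,
  resection extent), no competing risks, no left truncation.
* The bundled 61-gene and 16-gene panels are constructed stand-ins for
  published lists (see the panel files' headers); analyses of real
  cohorts should supply the published panels as files.
* The 1NN predictor is exactly k = 1 with unweighted Euclidean distance;
  no calibration of its predictions is attempted.
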