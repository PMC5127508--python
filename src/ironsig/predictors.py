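"""Survival-time predictors and their comparison statistics.

Two point predictors of months of survival from diagnosis to death:

* a leave-one-out *random baseline* — for each patient, survival times are
  drawn uniformly from the other patients and averaged over replicate
  draws;
* a *1-nearest-neighbor* (1NN) predictor — each patient inherits the
  observed survival of the patient closest in Euclidean distance over a
  gene panel's z-scores. 1NN has no training phase and weights all panel
  genes equally.

Both are evaluated on uncensored (deceased) patients only: residuals are
``|predicted - observed|`` months to death, which a censored time cannot
supply. Performance is the *median* residual; predictors are compared with
a two-sided Mann-Whitney U test on their residual sets (exact enumeration
for small samples), and calibration with Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .io import GenePanel

__all__ = [
    "PredictionResult",
    "random_baseline",
    "one_nn_predict",
    "median_residual",
    "compare_residuals",
    "prediction_correlation",
]


@dataclass
class PredictionResult:
    """Per-sample predicted vs. observed survival months."""

    sample_ids: list[str]
    predicted_months: np.ndarray
    observed_months: np.ndarray

    def __post_init__(self) -> None:
        self.predicted_months = np.asarray(self.predicted_months, dtype=float)
        self.observed_months = np.asarray(self.observed_months, dtype=float)
        if not (
            len(self.sample_ids)
            == len(self.predicted_months)
            == len(self.observed_months)
        ):
            raise ValueError("sample_ids, predicted and observed lengths differ")

    @property
    def residuals(self) -> np.ndarray:
        return np.abs(self.predicted_months - self.observed_months)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class RandomBaselineResult(PredictionResult):
    """Leave-one-out random-selection baseline over replicate draws.

    ``predicted_months`` is the per-patient mean over replicate draws (the
    point prediction); the headline error is the mean over replicates of
    each replicate's median per-draw residual, and rank comparisons against
    other predictors use a single replicate's per-draw residuals so that,
    on a cohort with no expression signal, the baseline and a genuine
    predictor are exchangeable.
    """

    replicate_median_residuals: np.ndarray = None
    draw_residuals: np.ndarray = None  # representative (first) replicate

    @property
    def comparison_residuals(self) -> np.ndarray:
        return self.draw_residuals


def _evaluable(clinical: pd.DataFrame) -> pd.DataFrame:
    """Uncensored (deceased) samples — the only ones with known survival."""
    return clinical[clinical["event"].astype(bool)]


def random_baseline(
    clinical: pd.DataFrame, n_reps: int = 100, seed: int = 0
) -> RandomBaselineResult:
    """Leave-one-out random patient selection, replicated ``n_reps`` times.

    For each evaluable patient P, each replicate draws a survival time
    uniformly from the other evaluable patients. Deterministic under
    ``seed``.
    """
    ev = _evaluable(clinical)
    if len(ev) < 2:
        raise ValueError("random baseline needs >= 2 uncensored samples")
    rng = np.random.default_rng(seed)
    times = ev["os_months"].to_numpy(dtype=float)
    n = len(times)
    # Draw uniform indices over the n-1 'other' patients for each target.
    draws = rng.integers(0, n - 1, size=(n, n_reps))
    row = np.arange(n)[:, None]
    draws = draws + (draws >= row)  # skip self
    drawn_times = times[draws]  # n x n_reps
    per_draw_residuals = np.abs(drawn_times - times[:, None])
    return RandomBaselineResult(
        sample_ids=list(ev.index),
        predicted_months=drawn_times.mean(axis=1),
        observed_months=times,
        replicate_median_residuals=np.median(per_draw_residuals, axis=0),
        draw_residuals=per_draw_residuals[:, 0],
    )


def one_nn_predict(
    zscores: pd.DataFrame,
    panel: GenePanel,
    clinical: pd.DataFrame,
    include_censored_neighbors: bool = False,
) -> PredictionResult:
    """1-nearest-neighbor survival prediction over a gene panel.

    For each evaluable (deceased) sample S, find the other sample T whose
    panel z-scores are closest to S's in Euclidean distance and predict T's
    observed survival. Distance ties break on the smaller sample id, so the
    prediction is independent of input ordering. By default the neighbor
    pool is also restricted to deceased samples, whose observed times are
    true survival times; set ``include_censored_neighbors`` to let censored
    samples donate their (under-estimated) observed times.
    """
    missing = [g for g in panel.genes if g not in zscores.index]
    if missing:
        raise KeyError(f"panel {panel.name!r} genes absent from z-matrix: {missing}")
    ev = _evaluable(clinical)
    if len(ev) < 2:
        raise ValueError("1NN needs >= 2 uncensored samples")
    targets = [s for s in ev.index if s in zscores.columns]
    if len(targets) < len(ev):
        absent = sorted(set(ev.index) - set(targets))
        raise KeyError(f"clinical samples absent from z-matrix: {absent}")
    pool_clin = clinical if include_censored_neighbors else ev
    pool = [s for s in pool_clin.index if s in zscores.columns]

    sub_t = zscores.loc[list(panel.genes), targets].to_numpy(dtype=float).T
    sub_p = zscores.loc[list(panel.genes), pool].to_numpy(dtype=float).T
    if np.isnan(sub_t).any() or np.isnan(sub_p).any():
        raise ValueError("missing z-scores in panel genes; impute or drop explicitly")

    dist = cdist(sub_t, sub_p)  # targets x pool
    pool_times = pool_clin.loc[pool, "os_months"].to_numpy(dtype=float)
    pool_ids = np.array(pool)
    predictions = np.empty(len(targets))
    for i, s in enumerate(targets):
        d = dist[i].copy()
        d[pool_ids == s] = np.inf  # leave-one-out
        nearest = np.flatnonzero(d == d.min())
        winner = nearest[np.argsort(pool_ids[nearest])[0]]  # lexicographic tie-break
        predictions[i] = pool_times[winner]
    return PredictionResult(
        sample_ids=targets,
        predicted_months=predictions,
        observed_months=ev.loc[targets, "os_months"].to_numpy(dtype=float),
    )


def median_residual(pred: PredictionResult) -> float:
    """Median of ``|predicted - observed|`` months (even n: mean of middle two).

    For the random baseline this is the mean over replicates of each
    replicate's median per-draw residual — the average performance of
    random selection, not the performance of the averaged prediction.
    """
    if pred.n == 0:
        raise ValueError("empty prediction result")
    if isinstance(pred, RandomBaselineResult):
        return float(np.mean(pred.replicate_median_residuals))
    return float(np.median(pred.residuals))


def _exact_mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact permutation p-value for the Mann-Whitney U statistic.

    Enumerates all C(n1+n2, n1) assignments of the pooled values to group A
    (ties handled naturally by working on midranks), and reports
    P(|U - n1*n2/2| >= |U_obs - n1*n2/2|).
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * n2 / 2
    dev = abs(u_obs - center)
    total = comb(n1 + n2, n1)
    hits = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        if abs(u - center) >= dev - 1e-12:
            hits += 1
    return hits / total


def compare_residuals(a: PredictionResult, b: PredictionResult) -> float:
    """Two-sided Mann-Whitney U p-value on two residual sets.

    Exact enumeration when both samples have <= 8 residuals; otherwise the
    tie-corrected normal approximation.
    """
    ra = getattr(a, "comparison_residuals", None)
    ra = a.residuals if ra is None else ra
    rb = getattr(b, "comparison_residuals", None)
    rb = b.residuals if rb is None else rb
    if len(ra) == 0 or len(rb) == 0:
        raise ValueError("both prediction results must be nonempty")
    if len(ra) <= 8 and len(rb) <= 8:
        return _exact_mannwhitney_p(ra, rb)
    return float(
        stats.mannwhitneyu(ra, rb, alternative="two-sided", method="asymptotic").pvalue
    )


def prediction_correlation(x, y) -> float:
    """Pearson correlation between two paired series (e.g. observed vs.
    predicted survival, or relative risk vs. survival).

    Returns NaN with a warning when either series has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired series must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs >= 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in correlation input; returning NaN")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
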