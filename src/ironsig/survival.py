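"""Kaplan-Meier estimation and the two-group log-rank test.

Both are implemented directly from their defining formulas so that the
rest of the package carries no model assumptions beyond right censoring:

* Kaplan-Meier product-limit: ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)``
  over distinct event times ``t_i`` with ``d_i`` events and ``n_i`` at
  risk. A censored observation leaves the risk set without a drop; when a
  censoring time ties an event time, the censored sample still counts as
  at risk for that event (events first).
* Log-rank: at each pooled distinct event time, the observed events in
  group A are compared with the expectation under the hypergeometric null
  given the margins; ``chi2 = (sum O - sum E)^2 / sum V`` referred to a
  chi-square with 1 df. The sign of ``sum O - sum E`` says which group
  died faster.

The survival median is the smallest observed time at which the KM curve
reaches 0.5 or below; under heavy censoring it may never do so, in which
case it is reported as not reached (None).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "GroupComparison",
    "kaplan_meier",
    "median_survival",
    "restricted_mean_survival",
    "log_rank",
    "compare_by_aberrance",
]


@dataclass
class KMCurve:
    """A Kaplan-Meier step function over the distinct event times."""

    event_times: np.ndarray  # increasing months
    survival_prob: np.ndarray  # value of S just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_samples: int
    max_followup: float

    def survival_at(self, t: float) -> float:
        """S(t): survival probability at time t (step function, right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


@dataclass
class LogRankResult:
    chi2: float
    p: float
    observed_minus_expected: float  # for group A; >0 means A died more than expected

    def __iter__(self):  # allows chi2, p = log_rank(...)
        return iter((self.chi2, self.p))


@dataclass
class GroupComparison:
    """Aberrant vs. non-aberrant KM comparison within an optional grade stratum."""

    curve_aberrant: KMCurve | None
    curve_normal: KMCurve | None
    median_aberrant: float | None
    median_normal: float | None
    median_difference: float | None
    logrank: LogRankResult | None
    n_aberrant: int
    n_normal: int
    comparable: bool
    reason: str | None = None


def kaplan_meier(time, event) -> KMCurve:
    """Product-limit estimate of the survival function."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if len(time) == 0:
        raise ValueError("empty sample")
    if (time < 0).any():
        raise ValueError("negative survival times")
    ev_times = np.unique(time[event])
    n = len(time)
    n_at_risk = np.array([(time >= t).sum() for t in ev_times], dtype=float)
    n_events = np.array([event[time == t].sum() for t in ev_times], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - n_events / n_at_risk)
    return KMCurve(
        event_times=ev_times,
        survival_prob=surv,
        n_at_risk=n_at_risk,
        n_events=n_events,
        n_samples=n,
        max_followup=float(time.max()),
    )


def median_survival(curve: KMCurve) -> float | None:
    """Smallest time with S(t) <= 0.5, or None when never reached."""
    hits = np.flatnonzero(curve.survival_prob <= 0.5 + 1e-12)
    if len(hits) == 0:
        return None
    return float(curve.event_times[hits[0]])


def restricted_mean_survival(curve: KMCurve, tau: float | None = None) -> float:
    """Area under the KM curve up to ``tau`` (default: end of follow-up)."""
    tau = curve.max_followup if tau is None else float(tau)
    times = np.concatenate([[0.0], curve.event_times, [tau]])
    probs = np.concatenate([[1.0], curve.survival_prob, [curve.survival_prob[-1] if len(curve.survival_prob) else 1.0]])
    area = 0.0
    for i in range(len(times) - 1):
        left, right = times[i], min(times[i + 1], tau)
        if right <= left:
            continue
        area += probs[i] * (right - left)
        if times[i + 1] >= tau:
            break
    return float(area)


def log_rank(time_a, event_a, time_b, event_b) -> LogRankResult:
    """Unweighted two-group log-rank test with a chi-square(1) p-value."""
    ta = np.asarray(time_a, dtype=float)
    ea = np.asarray(event_a, dtype=bool)
    tb = np.asarray(time_b, dtype=float)
    eb = np.asarray(event_b, dtype=bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank needs at least one event")

    pooled = np.unique(np.concatenate([ta[ea], tb[eb]]))
    O = E = V = 0.0
    for t in pooled:
        n1 = float((ta >= t).sum())
        n2 = float((tb >= t).sum())
        d1 = float(ea[ta == t].sum())
        d2 = float(eb[tb == t].sum())
        nt, dt = n1 + n2, d1 + d2
        if nt < 1 or dt == 0:
            continue
        O += d1
        E += dt * n1 / nt
        if nt > 1:
            V += dt * (n1 / nt) * (n2 / nt) * (nt - dt) / (nt - 1)
    if V <= 0:
        return LogRankResult(chi2=0.0, p=1.0, observed_minus_expected=O - E)
    chi2 = (O - E) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(chi2=float(chi2), p=p, observed_minus_expected=float(O - E))


def compare_by_aberrance(
    clinical: pd.DataFrame,
    labels: pd.Series,
    grade_filter: set[str] | None = None,
) -> GroupComparison:
    """Aberrant vs. non-aberrant survival comparison, optionally per grade.

    ``labels`` is the per-sample any-aberrant flag (index = sample ids).
    When either group is empty after grade filtering, or no events remain,
    the result is flagged not-comparable rather than raising.
    """
    common = clinical.index.intersection(labels.index)
    table = clinical.loc[common]
    lab = labels.loc[common].astype(bool)
    if grade_filter is not None:
        if "grade" in table.columns:
            keep = table["grade"].isin(list(grade_filter)).fillna(False).to_numpy(bool)
        else:
            keep = np.zeros(len(table), dtype=bool)  # no grades: empty stratum
        table, lab = table[keep], lab[keep]

    mask = lab.to_numpy()
    n_ab, n_no = int(mask.sum()), int((~mask).sum())
    if n_ab == 0 or n_no == 0:
        return GroupComparison(
            curve_aberrant=None, curve_normal=None,
            median_aberrant=None, median_normal=None, median_difference=None,
            logrank=None, n_aberrant=n_ab, n_normal=n_no,
            comparable=False, reason="one group is empty",
        )
    t = table["os_months"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=bool)
    if e.sum() == 0:
        return GroupComparison(
            curve_aberrant=None, curve_normal=None,
            median_aberrant=None, median_normal=None, median_difference=None,
            logrank=None, n_aberrant=n_ab, n_normal=n_no,
            comparable=False, reason="no events in stratum",
        )
    curve_ab = kaplan_meier(t[mask], e[mask])
    curve_no = kaplan_meier(t[~mask], e[~mask])
    med_ab = median_survival(curve_ab)
    med_no = median_survival(curve_no)
    diff = abs(med_ab - med_no) if med_ab is not None and med_no is not None else None
    lr = log_rank(t[mask], e[mask], t[~mask], e[~mask])
    return GroupComparison(
        curve_aberrant=curve_ab,
        curve_normal=curve_no,
        median_aberrant=med_ab,
        median_normal=med_no,
        median_difference=diff,
        logrank=lr,
        n_aberrant=n_ab,
        n_normal=n_no,
        comparable=True,
    )
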