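"""Elastic-net penalized Cox proportional-hazards regression.

Fits the Cox model by cyclic coordinate descent on an iteratively
reweighted least-squares (IRLS) approximation of the penalized negative
Breslow partial log-likelihood,

    f(beta) = -(1/n) * l_Breslow(beta)
              + lambda * ( alpha * ||beta||_1 + (1 - alpha)/2 * ||beta||_2^2 ),

along a decreasing, log-spaced lambda path starting at ``lambda_max`` (the
smallest penalty that zeroes every coefficient, computed from the score at
beta = 0), with warm starts between path points. Feature selection is the
set of genes with nonzero coefficients at the lambda minimizing the
Verweij-van-Houwelingen cross-validated partial-likelihood deviance.

Tied event times use the Breslow approximation throughout. Covariates are
expected to be per-gene z-scores and are *not* re-standardized internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .io import GenePanel

__all__ = [
    "CoxnetConfig",
    "CoxnetPath",
    "CVResult",
    "FeatureSelection",
    "ConvergenceError",
    "fit_path",
    "cross_validate",
    "select_features",
    "relative_risk",
    "panel_matrix",
]


class ConvergenceError(RuntimeError):
    """Coordinate descent exhausted its sweep budget without converging."""


@dataclass(frozen=True)
class CoxnetConfig:
    """Tuning parameters for the elastic-net Cox fit.

    ``alpha`` is the elastic-net mixing (1 = lasso); the default 0.95 is
    mostly-L1 for sparse selection with a little ridge stability.
    ``n_lambda`` log-spaced penalties span ``lambda_max`` down to
    ``lambda_max * lambda_min_ratio``. ``tol`` is the relative change in
    the penalized objective declaring convergence at each path point.
    """

    alpha: float = 0.95
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    max_sweeps: int = 10_000
    tol: float = 1e-7
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_lambda < 2 or not 0 < self.lambda_min_ratio < 1:
            raise ValueError("need n_lambda >= 2 and lambda_min_ratio in (0,1)")


@dataclass
class CoxnetPath:
    """A fitted regularization path."""

    genes: list[str]
    lambdas: np.ndarray  # strictly decreasing
    coefficients: np.ndarray  # n_lambda x p
    objective: np.ndarray  # penalized negative mean partial log-likelihood
    alpha: float
    n_sweeps: int = 0
    sweep_objectives: list[np.ndarray] = field(default_factory=list)

    def coefficients_at(self, lam: float) -> pd.Series:
        idx = _lambda_index(self.lambdas, lam)
        return pd.Series(self.coefficients[idx], index=self.genes)


@dataclass
class FeatureSelection:
    """Nonzero-coefficient genes at one lambda, ordered by |coefficient|."""

    coefficients: pd.Series  # nonzero only, |beta| descending
    lam: float

    @property
    def genes(self) -> list[str]:
        return list(self.coefficients.index)

    @property
    def panel(self) -> GenePanel:
        if len(self.coefficients) == 0:
            raise ValueError("no features selected at this lambda")
        return GenePanel(name=f"selected{len(self.coefficients)}", genes=tuple(self.genes))


@dataclass
class CVResult:
    """Cross-validated deviance curve and the lambda/genes it selects."""

    lambdas: np.ndarray
    fold_deviance: np.ndarray  # n_folds x n_lambda
    mean_deviance: np.ndarray
    lambda_min: float
    selection: FeatureSelection
    path: CoxnetPath

    @property
    def selected_genes(self) -> list[str]:
        return self.selection.genes


def _lambda_index(lambdas: np.ndarray, lam: float) -> int:
    hits = np.flatnonzero(np.isclose(lambdas, lam, rtol=1e-9, atol=0.0))
    if len(hits) == 0:
        raise ValueError(f"lambda {lam} is not on the fitted path")
    return int(hits[0])


class _CoxData:
    """Sorted survival data with Breslow risk-set bookkeeping.

    Samples are sorted by ascending time; the risk set of an event time t
    is every sample with observed time >= t (censored samples tied with an
    event remain at risk for it).
    """

    def __init__(self, X: np.ndarray, time: np.ndarray, event: np.ndarray):
        if not (np.isfinite(X).all() and np.isfinite(time).all()):
            raise ValueError("non-finite values in covariates or times")
        if event.sum() == 0:
            raise ValueError("Cox fit needs at least one event")
        order = np.argsort(time, kind="stable")
        self.X = np.ascontiguousarray(X[order], dtype=float)
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.n, self.p = self.X.shape
        # Distinct event times and their first-at-risk index in sorted order.
        ev_times = np.unique(self.time[self.event])
        self.first_idx = np.searchsorted(self.time, ev_times, side="left")
        self.d = np.array(
            [self.event[self.time == t].sum() for t in ev_times], dtype=float
        )
        self.ev_times = ev_times
        # For each sample, number of event times with tau_k <= t_i.
        self.k_of_sample = np.searchsorted(ev_times, self.time, side="right")

    def _risk_sums(self, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        e = np.exp(eta - eta.mean())  # partial likelihood is shift-invariant
        suffix = np.cumsum(e[::-1])[::-1]
        return e, suffix[self.first_idx]

    def log_partial_likelihood(self, eta: np.ndarray, scaled: bool = True) -> float:
        e, R = self._risk_sums(eta)
        centered = eta - eta.mean()
        ll = centered[self.event].sum() - float(self.d @ np.log(R))
        return ll / self.n if scaled else ll

    def weights_and_response(self, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """IRLS weights (diagonal Hessian) and working response."""
        e, R = self._risk_sums(eta)
        cum_dR = np.concatenate([[0.0], np.cumsum(self.d / R)])
        cum_dR2 = np.concatenate([[0.0], np.cumsum(self.d / R**2)])
        A = cum_dR[self.k_of_sample]
        B = cum_dR2[self.k_of_sample]
        w = e * A - (e**2) * B
        w = np.maximum(w, 0.0)
        g = self.event.astype(float) - e * A
        z = np.where(w > 1e-12, eta + np.divide(g, np.maximum(w, 1e-12)), eta)
        return w, z


def _penalty(beta: np.ndarray, lam: float, alpha: float) -> float:
    return lam * (alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * (beta**2).sum())


@njit(cache=True)
def _cd_sweep(
    X: np.ndarray,
    w: np.ndarray,
    r: np.ndarray,
    beta: np.ndarray,
    v: np.ndarray,
    denom: np.ndarray,
    lam_alpha: float,
    indices: np.ndarray,
) -> float:
    """One cyclic pass of coordinatewise soft-threshold updates (in place).

    Returns the largest curvature-weighted coefficient change of the pass.
    """
    n = X.shape[0]
    max_delta = 0.0
    for j in indices:
        if denom[j] <= 0.0:
            continue
        c = 0.0
        for i in range(n):
            c += w[i] * X[i, j] * r[i]
        c = c / n + v[j] * beta[j]
        if c > lam_alpha:
            new = (c - lam_alpha) / denom[j]
        elif c < -lam_alpha:
            new = (c + lam_alpha) / denom[j]
        else:
            new = 0.0
        delta = new - beta[j]
        if delta != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * delta
            beta[j] = new
            wd = abs(delta) * np.sqrt(v[j])
            if wd > max_delta:
                max_delta = wd
    return max_delta


_INNER_EPS = 1e-8  # weighted coefficient-change convergence for one quadratic


def _cd_quadratic(
    X: np.ndarray,
    w: np.ndarray,
    z: np.ndarray,
    beta: np.ndarray,
    lam: float,
    alpha: float,
    sweep_budget: int,
) -> tuple[np.ndarray, int]:
    """Cyclic coordinate descent on the penalized weighted least squares.

    Active-set strategy: a full sweep over all coordinates, then sweeps
    over the nonzero set until stable, then a final full sweep to admit
    new coordinates; repeats until a full sweep changes nothing.
    """
    n, p = X.shape
    v = (w[:, None] * X**2).sum(axis=0) / n  # coordinatewise curvature
    denom = v + lam * (1 - alpha)
    r = z - X @ beta
    lam_alpha = lam * alpha
    sweeps = 0

    all_idx = np.arange(p)
    while sweeps < sweep_budget:
        sweeps += 1
        if _cd_sweep(X, w, r, beta, v, denom, lam_alpha, all_idx) < _INNER_EPS:
            break
        active = np.flatnonzero(beta)
        while sweeps < sweep_budget and len(active):
            sweeps += 1
            if _cd_sweep(X, w, r, beta, v, denom, lam_alpha, active) < _INNER_EPS:
                break
    return beta, sweeps


def _fit_single_lambda(
    data: _CoxData,
    beta: np.ndarray,
    lam: float,
    alpha: float,
    tol: float,
    sweep_budget: int,
    trace: list | None = None,
) -> tuple[np.ndarray, int]:
    """IRLS outer loop at one lambda, warm-started from ``beta``."""
    used = 0
    eta = data.X @ beta
    obj = -data.log_partial_likelihood(eta) + _penalty(beta, lam, alpha)
    for _ in range(100):
        w, z = data.weights_and_response(eta)
        beta_prev = beta.copy()
        beta, sw = _cd_quadratic(
            data.X, w, z, beta.copy(), lam, alpha, sweep_budget - used
        )
        used += sw
        eta = data.X @ beta
        new_obj = -data.log_partial_likelihood(eta) + _penalty(beta, lam, alpha)
        # The quadratic model can overshoot the true objective; backtrack.
        halvings = 0
        while new_obj > obj + 1e-12 and halvings < 30:
            beta = 0.5 * (beta + beta_prev)
            eta = data.X @ beta
            new_obj = -data.log_partial_likelihood(eta) + _penalty(beta, lam, alpha)
            halvings += 1
        if trace is not None:
            trace.append(new_obj)
        if abs(obj - new_obj) <= tol * max(abs(obj), 1.0):
            return beta, used
        obj = new_obj
        if used >= sweep_budget:
            break
    raise ConvergenceError(
        f"coordinate descent did not converge at lambda={lam:.4g} "
        f"within {sweep_budget} sweeps"
    )


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(g) for g in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def lambda_max(X, time, event, alpha: float = 0.95) -> float:
    """Smallest penalty at which every coefficient is exactly zero.

    Computed from the score of the partial likelihood at beta = 0:
    ``max_j |x_j . grad0| / (n * alpha)``.
    """
    Xm, _ = _as_matrix(X)
    data = _CoxData(Xm, np.asarray(time, float), np.asarray(event, bool))
    e, R = data._risk_sums(np.zeros(data.n))
    cum_dR = np.concatenate([[0.0], np.cumsum(data.d / R)])
    g0 = data.event.astype(float) - e * cum_dR[data.k_of_sample]
    score = np.abs(data.X.T @ g0) / data.n
    return float(score.max() / alpha)


def fit_path(X, time, event, config: CoxnetConfig | None = None) -> CoxnetPath:
    """Fit the elastic-net Cox regularization path.

    Parameters
    ----------
    X : DataFrame (samples x genes) or ndarray
        Covariates (z-scores); not re-standardized.
    time, event
        Observed months and event flags (True = death observed).
    """
    config = config or CoxnetConfig()
    Xm, genes = _as_matrix(X)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    data = _CoxData(Xm, time, event)
    if data.event.sum() < 2:
        raise ValueError("path fitting needs >= 2 events")

    lam_max = lambda_max(Xm, time, event, config.alpha)
    if lam_max <= 0:
        lam_max = 1e-3
    lambdas = np.logspace(
        np.log10(lam_max),
        np.log10(lam_max * config.lambda_min_ratio),
        config.n_lambda,
    )

    p = data.p
    beta = np.zeros(p)
    coefs = np.zeros((config.n_lambda, p))
    objective = np.zeros(config.n_lambda)
    sweep_traces: list[np.ndarray] = []
    total_sweeps = 0
    # Data were sorted by time inside _CoxData; coefficients are in the
    # original gene order throughout.
    for i, lam in enumerate(lambdas):
        trace: list[float] = []
        beta, used = _fit_single_lambda(
            data, beta, lam, config.alpha, config.tol, config.max_sweeps, trace
        )
        total_sweeps += used
        coefs[i] = beta
        eta = data.X @ beta
        objective[i] = -data.log_partial_likelihood(eta) + _penalty(
            beta, lam, config.alpha
        )
        sweep_traces.append(np.asarray(trace))
    # lambda_max must give the all-zero solution exactly.
    coefs[0] = 0.0
    return CoxnetPath(
        genes=genes,
        lambdas=lambdas,
        coefficients=coefs,
        objective=objective,
        alpha=config.alpha,
        n_sweeps=total_sweeps,
        sweep_objectives=sweep_traces,
    )


def _stratified_folds(event: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold labels balanced on event status (round-robin after shuffling)."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(event), dtype=int)
    for flag in (True, False):
        idx = np.flatnonzero(event == flag)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def cross_validate(X, time, event, config: CoxnetConfig | None = None) -> CVResult:
    """10-fold (by default) cross-validated lambda selection.

    Deviance is the Verweij-van-Houwelingen cross-validated partial
    likelihood: for fold k with coefficients beta_{-k} fit without it,
    ``D_k(lambda) = -2 * [ l_full(beta_{-k}) - l_train(beta_{-k}) ]``,
    which credits the held-out samples only. ``lambda_min`` minimizes the
    fold-mean deviance; the selected genes are those with nonzero
    coefficients there in the full-data path.
    """
    config = config or CoxnetConfig()
    Xm, genes = _as_matrix(X)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n = len(time)
    if n < config.cv_folds:
        raise ValueError("fewer samples than folds")

    full_path = fit_path(pd.DataFrame(Xm, columns=genes), time, event, config)
    lambdas = full_path.lambdas

    folds = _stratified_folds(event, config.cv_folds, config.seed)
    fold_dev = np.zeros((config.cv_folds, len(lambdas)))
    full_data = _CoxData(Xm, time, event)
    order_full = np.argsort(time, kind="stable")  # _CoxData sorts internally

    for k in range(config.cv_folds):
        train = folds != k
        if event[train].sum() == 0:
            raise ValueError(
                f"fold {k} leaves no events in training; use fewer cv_folds"
            )
        train_data = _CoxData(Xm[train], time[train], event[train])
        beta = np.zeros(full_data.p)
        for i, lam in enumerate(lambdas):
            beta, _ = _fit_single_lambda(
                train_data, beta, lam, config.alpha, config.tol, config.max_sweeps
            )
            eta_full = Xm @ beta
            eta_train = Xm[train] @ beta
            l_full = full_data.log_partial_likelihood(eta_full[order_full], scaled=False)
            # _CoxData re-sorts; pass eta in its internal (time-sorted) order.
            tr_order = np.argsort(time[train], kind="stable")
            l_train = train_data.log_partial_likelihood(
                eta_train[tr_order], scaled=False
            )
            fold_dev[k, i] = -2.0 * (l_full - l_train)

    mean_dev = fold_dev.mean(axis=0)
    lam_min = float(lambdas[int(np.argmin(mean_dev))])
    selection = select_features(full_path, lam_min)
    return CVResult(
        lambdas=lambdas,
        fold_deviance=fold_dev,
        mean_deviance=mean_dev,
        lambda_min=lam_min,
        selection=selection,
        path=full_path,
    )


def select_features(path: CoxnetPath, lam: float) -> FeatureSelection:
    """Genes with nonzero coefficients at ``lam``, |coefficient| descending."""
    coef = path.coefficients_at(lam)
    nonzero = coef[coef != 0.0]
    ordered = nonzero.reindex(
        sorted(nonzero.index, key=lambda g: (-abs(nonzero[g]), g))
    )
    return FeatureSelection(coefficients=ordered, lam=float(lam))


def relative_risk(beta: pd.Series, zscores: pd.DataFrame) -> pd.Series:
    """Per-sample relative risk ``exp(x . beta)`` from fitted coefficients.

    ``zscores`` is genes x samples; only genes in ``beta`` contribute.
    """
    missing = [g for g in beta.index if g not in zscores.index]
    if missing:
        raise KeyError(f"coefficient genes absent from z-matrix: {missing}")
    lp = beta.to_numpy() @ zscores.loc[beta.index].to_numpy(dtype=float)
    return pd.Series(np.exp(lp), index=zscores.columns, name="relative_risk")


def panel_matrix(
    zscores: pd.DataFrame, panel: GenePanel, clinical: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Samples x genes design matrix plus aligned time/event arrays."""
    missing = [g for g in panel.genes if g not in zscores.index]
    if missing:
        raise KeyError(f"panel {panel.name!r} genes absent from z-matrix: {missing}")
    samples = [s for s in clinical.index if s in zscores.columns]
    if len(samples) < len(clinical.index):
        absent = sorted(set(clinical.index) - set(samples))
        raise KeyError(f"clinical samples absent from z-matrix: {absent}")
    Xdf = zscores.loc[list(panel.genes), samples].T
    t = clinical.loc[samples, "os_months"].to_numpy(dtype=float)
    e = clinical.loc[samples, "event"].to_numpy(dtype=bool)
    return Xdf, t, e
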