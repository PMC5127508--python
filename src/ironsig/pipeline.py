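"""End-to-end signature analysis: panels -> aberrance -> predictors ->
penalized-Cox selection -> per-grade Kaplan-Meier grids -> greedy
refinement with Bonferroni familywise-error accounting.

Greedy refinement mirrors a forward search on the any-aberrant split: step
one picks the single gene whose aberrant/non-aberrant split maximizes the
absolute Kaplan-Meier median-survival difference; each later step adds the
candidate that maximizes the difference when a sample counts as aberrant
in *any* gene of the grown panel. Every log-rank comparison performed is
counted, and the familywise (Bonferroni) threshold reported is
``alpha / n_tests``. When a stratum's median is not reached (heavy
censoring), the step's objective falls back to the difference of
restricted mean survival times so the search stays defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .coxnet import CoxnetConfig, cross_validate, panel_matrix, relative_risk
from .io import GenePanel, call_aberrant, compute_zscores, load_panel, panel_aberrance_label
from .predictors import (
    compare_residuals,
    median_residual,
    one_nn_predict,
    prediction_correlation,
    random_baseline,
)
from .survival import GroupComparison, compare_by_aberrance, restricted_mean_survival

__all__ = [
    "GreedyStep",
    "GreedyTrace",
    "AnalysisConfig",
    "AnalysisReport",
    "bonferroni_adjust",
    "greedy_select",
    "run_full_analysis",
    "comparison_to_dict",
]


def bonferroni_adjust(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value, ``min(1, p * n_tests)``.

    Equivalently, reject at family level alpha iff the raw p is below
    ``alpha / n_tests``.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


@dataclass
class GreedyStep:
    gene: str
    panel_genes: tuple[str, ...]
    median_difference: float | None
    objective: float  # median difference, or RMST difference fallback
    objective_kind: str  # "median" or "rmst"
    logrank_p: float
    aberrant_fraction_uncensored: float
    n_aberrant: int
    n_normal: int


@dataclass
class GreedyTrace:
    steps: list[GreedyStep]
    n_tests_performed: int
    family_alpha: float
    bonferroni_threshold: float  # family_alpha / n_tests_performed
    truncated_reason: str | None = None

    @property
    def selected_genes(self) -> list[str]:
        return [s.gene for s in self.steps]


def _split_objective(
    comp: GroupComparison,
) -> tuple[float, float | None, str] | None:
    """Objective value for one candidate split, or None if not comparable."""
    if not comp.comparable:
        return None
    if comp.median_difference is not None:
        return comp.median_difference, comp.median_difference, "median"
    # Median not reached in one arm: compare restricted means instead.
    rmst_ab = restricted_mean_survival(comp.curve_aberrant)
    rmst_no = restricted_mean_survival(comp.curve_normal)
    return abs(rmst_ab - rmst_no), None, "rmst"


def greedy_select(
    aberrant: pd.DataFrame,
    clinical: pd.DataFrame,
    candidates: GenePanel,
    grade_filter: set[str] | None = None,
    family_alpha: float = 0.05,
) -> GreedyTrace:
    """Forward selection of genes by any-aberrant KM median difference.

    Ties on the objective break by smaller log-rank p, then lexicographic
    gene name, so the trace is deterministic. Aberrant-sample fractions are
    reported among uncensored patients. Every comparison executed is
    counted toward the Bonferroni ledger.
    """
    missing = [g for g in candidates.genes if g not in aberrant.index]
    if missing:
        raise KeyError(f"candidate genes absent from aberrance matrix: {missing}")
    if not clinical["event"].astype(bool).any():
        raise ValueError("greedy selection needs at least one event")

    uncensored = clinical[clinical["event"].astype(bool)]
    unc_ids = [s for s in uncensored.index if s in aberrant.columns]

    selected: list[str] = []
    steps: list[GreedyStep] = []
    n_tests = 0
    truncated = None
    remaining = list(candidates.genes)

    while remaining:
        best = None  # (objective, -p ordering handled via tuple key)
        for gene in remaining:
            genes = selected + [gene]
            labels = aberrant.loc[genes].any(axis=0)
            comp = compare_by_aberrance(clinical, labels, grade_filter)
            n_tests += 1
            scored = _split_objective(comp)
            if scored is None:
                continue
            objective, med_diff, kind = scored
            p = comp.logrank.p
            key = (-objective, p, gene)  # max objective, then min p, then name
            if best is None or key < best[0]:
                best = (key, gene, objective, med_diff, kind, comp)
        if best is None:
            truncated = "every extension yields a not-comparable split"
            break
        _, gene, objective, med_diff, kind, comp = best
        selected.append(gene)
        remaining.remove(gene)
        labels = aberrant.loc[selected].any(axis=0)
        frac = (
            float(labels.loc[unc_ids].mean()) if unc_ids else float("nan")
        )
        steps.append(
            GreedyStep(
                gene=gene,
                panel_genes=tuple(selected),
                median_difference=med_diff,
                objective=float(objective),
                objective_kind=kind,
                logrank_p=float(comp.logrank.p),
                aberrant_fraction_uncensored=frac,
                n_aberrant=comp.n_aberrant,
                n_normal=comp.n_normal,
            )
        )
    return GreedyTrace(
        steps=steps,
        n_tests_performed=n_tests,
        family_alpha=family_alpha,
        bonferroni_threshold=family_alpha / max(n_tests, 1),
        truncated_reason=truncated,
    )


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full pipeline run."""

    panels: tuple[str, ...] = ("iron61", "irgs16", "selected8")
    selection_panel: str = "iron61"  # panel fed to penalized Cox
    aberrance_threshold: float = 2.0
    grade_strata: tuple[tuple[str, ...] | None, ...] = (("II", "III"), ("II",), ("III",))
    coxnet: CoxnetConfig = field(default_factory=CoxnetConfig)
    n_random_reps: int = 100
    family_alpha: float = 0.05
    idh1_subgroups: bool = True
    seed: int = 0


@dataclass
class AnalysisReport:
    """JSON-serializable results of one full pipeline run."""

    config_seed: int
    km_grid: dict  # (panel, stratum) -> comparison summary
    predictor_metrics: dict
    coxnet_coefficients: dict
    coxnet_lambda_min: float
    greedy: dict
    idh1: dict
    notes: list[str]

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, **kwargs)


def comparison_to_dict(comp: GroupComparison) -> dict:
    d = {
        "comparable": comp.comparable,
        "n_aberrant": comp.n_aberrant,
        "n_normal": comp.n_normal,
        "median_aberrant": comp.median_aberrant,
        "median_normal": comp.median_normal,
        "median_difference": comp.median_difference,
        "reason": comp.reason,
    }
    if comp.logrank is not None:
        d["logrank_chi2"] = comp.logrank.chi2
        d["logrank_p"] = comp.logrank.p
        d["direction_observed_minus_expected"] = comp.logrank.observed_minus_expected
    return d


def _stratum_name(stratum: tuple[str, ...] | None) -> str:
    return "all" if stratum is None else "+".join(stratum)


def run_full_analysis(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    config: AnalysisConfig | None = None,
    panels: dict[str, GenePanel] | None = None,
) -> AnalysisReport:
    """Run the whole signature analysis on one cohort.

    ``panels`` may override the bundled panel registry (any panel name in
    ``config.panels``/``config.selection_panel`` is looked up there first).
    Strata whose grades are absent from the cohort are reported as
    not-comparable rather than failing. Deterministic for a fixed config.
    """
    config = config or AnalysisConfig()
    notes: list[str] = []
    panel_map: dict[str, GenePanel] = dict(panels or {})
    for name in set(config.panels) | {config.selection_panel}:
        if name not in panel_map:
            panel_map[name] = load_panel(name)

    z = compute_zscores(expr)
    aberrant = call_aberrant(z, config.aberrance_threshold)

    # Restrict panels to genes present in the matrix (synthetic cohorts may
    # carry generic gene names; then panels must be supplied explicitly).
    usable: dict[str, GenePanel] = {}
    for name, panel in panel_map.items():
        present = tuple(g for g in panel.genes if g in aberrant.index)
        if not present:
            notes.append(f"panel {name!r}: no genes present in matrix; skipped")
            continue
        if len(present) < len(panel.genes):
            notes.append(
                f"panel {name!r}: {len(panel.genes) - len(present)} genes absent "
                "from matrix; restricted"
            )
        usable[name] = GenePanel(name=name, genes=present)

    # Kaplan-Meier grid: panels x grade strata.
    grades_present = set(clinical["grade"].dropna().unique()) if "grade" in clinical else set()
    strata: list[tuple[str, ...] | None] = [None]
    for stratum in config.grade_strata:
        if stratum is not None and grades_present & set(stratum):
            strata.append(stratum)
    km_grid: dict[str, dict] = {}
    for name, panel in usable.items():
        if name not in config.panels and name != config.selection_panel:
            continue
        labels = panel_aberrance_label(aberrant, panel)
        km_grid[name] = {}
        for stratum in strata:
            comp = compare_by_aberrance(
                clinical, labels, None if stratum is None else set(stratum)
            )
            km_grid[name][_stratum_name(stratum)] = comparison_to_dict(comp)

    # Penalized Cox selection on the widest panel.
    sel_panel = usable[config.selection_panel]
    X, t, e = panel_matrix(z, sel_panel, clinical)
    cv = cross_validate(X, t, e, config.coxnet)
    coef = cv.selection.coefficients
    coxnet_coefficients = {g: float(coef[g]) for g in coef.index}

    # Predictor benchmark on the widest panel and the selected genes.
    uncensored = clinical[clinical["event"].astype(bool)]
    predictor_metrics: dict = {}
    if len(uncensored) >= 3:
        base = random_baseline(clinical, n_reps=config.n_random_reps, seed=config.seed)
        bench_panels = {config.selection_panel: sel_panel}
        if cv.selected_genes:
            bench_panels["coxnet_selected"] = GenePanel(
                name="coxnet_selected", genes=tuple(cv.selected_genes)
            )
        predictor_metrics["random_baseline"] = {
            "median_residual": median_residual(base),
            "n": base.n,
        }
        for name, panel in bench_panels.items():
            nn = one_nn_predict(z, panel, clinical)
            predictor_metrics[f"1nn_{name}"] = {
                "median_residual": median_residual(nn),
                "r1_observed_vs_predicted": prediction_correlation(
                    nn.observed_months, nn.predicted_months
                ),
                "p_vs_random_baseline": compare_residuals(nn, base),
                "n": nn.n,
            }
        if cv.selected_genes:
            risks = relative_risk(coef, z)
            predictor_metrics["coxnet"] = {
                "r2_risk_vs_survival": prediction_correlation(
                    risks.loc[uncensored.index],
                    uncensored["os_months"],
                ),
                "n": len(uncensored),
            }
    else:
        notes.append("fewer than 3 uncensored samples; predictor benchmark skipped")

    # Greedy refinement over the selected genes (fall back to the shipped
    # 8-gene signature panel when selection is empty).
    if cv.selected_genes:
        greedy_candidates = GenePanel(
            name="coxnet_selected", genes=tuple(cv.selected_genes)
        )
    else:
        greedy_candidates = usable.get("selected8", sel_panel)
        notes.append("empty Cox selection; greedy ran on fallback panel")
    trace = greedy_select(
        aberrant, clinical, greedy_candidates, family_alpha=config.family_alpha
    )
    greedy_dict = {
        "selected_genes": trace.selected_genes,
        "n_tests_performed": trace.n_tests_performed,
        "bonferroni_threshold": trace.bonferroni_threshold,
        "truncated_reason": trace.truncated_reason,
        "steps": [asdict(s) for s in trace.steps],
    }

    # IDH1-defined subgroup reruns of the refined-panel comparison.
    idh1: dict = {}
    if config.idh1_subgroups and "idh1_mutated" in clinical.columns:
        panel8 = usable.get("selected8", greedy_candidates)
        labels8 = panel_aberrance_label(aberrant, panel8)
        for label, flag in (("mutated", True), ("wildtype", False)):
            sub = clinical[clinical["idh1_mutated"] == flag]
            if len(sub) == 0:
                idh1[label] = {"comparable": False, "reason": "empty subgroup"}
                continue
            idh1[label] = comparison_to_dict(
                compare_by_aberrance(sub, labels8.loc[labels8.index.isin(sub.index)])
            )

    return AnalysisReport(
        config_seed=config.seed,
        km_grid=km_grid,
        predictor_metrics=predictor_metrics,
        coxnet_coefficients=coxnet_coefficients,
        coxnet_lambda_min=cv.lambda_min,
        greedy=greedy_dict,
        idh1=idh1,
        notes=notes,
    )
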