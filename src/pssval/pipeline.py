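"""Orchestration: run every metric for every model and horizon, plus the
complete-case sensitivity analysis, and shape the results as report tables.

A run takes a cohort, a list of prediction sets, and a :class:`RunConfig`.
Score-only models get discrimination (rank-based) always, and Brier/decision
curves only through an explicit score map; calibration and model consistency
are restricted to models that natively output probabilities — mirroring how
validation studies exclude integer-score systems from calibration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    CohortTable,
    HorizonStatus,
    MetricEstimate,
    PredictionSet,
    apply_score_map,
    ascertain_statuses,
)
from .imputation import complete_case_subset, impute_missforest
from .metrics import (
    BrierResult,
    CalibrationResult,
    ConsistencyResult,
    DecisionCurve,
    auc_at_horizon,
    brier_score,
    calibration_fit,
    decision_curve,
    model_consistency,
)

__all__ = [
    "RunConfig",
    "HorizonMetrics",
    "ModelReport",
    "ValidationReport",
    "run_validation",
    "format_report",
    "summarize_cohort",
    "summarize_covariates",
]

EN_DASH = "–"


@dataclass
class RunConfig:
    horizons: tuple[float, ...] = (1.0, 3.0, 6.0, 12.0, 18.0, 24.0)
    n_boot: int = 2000
    seed: int = 0
    clamp_eps: float = 1e-6
    threshold_grid: tuple[float, float, float] = (0.01, 0.99, 0.01)  # start, stop, step
    impute: bool = True
    imputation_max_iter: int = 10
    imputation_learner_params: dict = field(default_factory=dict)
    complete_case_sensitivity: bool = True
    admin_censor: float = 24.0

    def __post_init__(self) -> None:
        if len(self.horizons) == 0:
            raise ValueError("horizons must be non-empty")
        if any(h2 <= h1 for h1, h2 in zip(self.horizons, self.horizons[1:])):
            raise ValueError("horizons must be strictly increasing")

    def grid(self) -> np.ndarray:
        start, stop, step = self.threshold_grid
        return np.arange(start, stop + step / 2, step)

    def hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class HorizonMetrics:
    horizon: float
    n_ascertained: int
    auc: MetricEstimate | None = None
    brier: BrierResult | None = None
    calibration: CalibrationResult | None = None
    decision: DecisionCurve | None = None
    unavailable: dict[str, str] = field(default_factory=dict)


@dataclass
class ModelReport:
    model_name: str
    mode: str
    horizons: dict[float, HorizonMetrics] = field(default_factory=dict)
    consistency: ConsistencyResult | None = None
    consistency_unavailable: str | None = None


@dataclass
class ValidationReport:
    models: dict[str, ModelReport]
    sensitivity: dict[str, ModelReport] | None
    metadata: dict

    def to_json(self) -> str:
        return json.dumps(_jsonable(self), indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, (ValidationReport, ModelReport, HorizonMetrics, BrierResult,
                        CalibrationResult, DecisionCurve, ConsistencyResult,
                        MetricEstimate)):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _metric_seed(base: int, *key: int) -> int:
    return int(np.random.SeedSequence([base, *key]).generate_state(1)[0] % 2**31)


def _validate_models(
    cohort: CohortTable,
    predictions: Sequence[PredictionSet],
    config: RunConfig,
) -> dict[str, ModelReport]:
    ids = set(cohort.df["patient_id"])
    reports: dict[str, ModelReport] = {}
    for mi, pred in enumerate(predictions):
        extra = sorted(set(pred.values.index) - ids)
        if extra:
            raise ValueError(
                f"model {pred.model_name}: prediction patients absent from cohort: {extra}"
            )
        prob = pred
        mapped = False
        if pred.mode == "score" and pred.score_map is not None:
            try:
                prob = apply_score_map(pred, pred.score_map)
                mapped = True
            except KeyError as exc:
                raise ValueError(f"model {pred.model_name}: {exc}") from exc
        report = ModelReport(model_name=pred.model_name, mode=pred.mode)

        for hi, h in enumerate(config.horizons):
            if h not in pred.values.columns:
                continue
            statuses = ascertain_statuses(cohort, h, admin_censor=config.admin_censor)
            n_asc = int(sum(s is not HorizonStatus.UNKNOWN for s in statuses))
            hm = HorizonMetrics(horizon=h, n_ascertained=n_asc)
            values = pred.at_horizon(h)
            try:
                hm.auc = auc_at_horizon(
                    values,
                    statuses,
                    n_boot=config.n_boot,
                    seed=_metric_seed(config.seed, mi, hi, 0),
                )
            except ValueError as exc:
                hm.unavailable["auc"] = str(exc)

            if prob.mode == "probability":
                pvals = prob.at_horizon(h)
                try:
                    hm.brier = brier_score(pvals, statuses)
                except ValueError as exc:
                    hm.unavailable["brier"] = str(exc)
                try:
                    hm.decision = decision_curve(
                        pvals, statuses, horizon=h, threshold_grid=config.grid()
                    )
                except ValueError as exc:
                    hm.unavailable["decision_curve"] = str(exc)
                if pred.mode == "probability":
                    try:
                        hm.calibration = calibration_fit(
                            pvals,
                            statuses,
                            clamp_eps=config.clamp_eps,
                            n_boot=config.n_boot,
                            seed=_metric_seed(config.seed, mi, hi, 1),
                        )
                    except ValueError as exc:
                        hm.unavailable["calibration"] = str(exc)
                else:
                    hm.unavailable["calibration"] = (
                        "integer-score model: calibration not evaluated on mapped probabilities"
                    )
            else:
                reason = "integer-score model without a score map"
                hm.unavailable["brier"] = reason
                hm.unavailable["decision_curve"] = reason
                hm.unavailable["calibration"] = reason
            report.horizons[h] = hm

        if pred.mode == "probability" and len(pred.horizons) >= 2:
            report.consistency = model_consistency(pred)
        elif pred.mode != "probability":
            report.consistency_unavailable = "integer-score model"
        else:
            report.consistency_unavailable = "fewer than 2 horizons"
        if mapped:
            pass  # mapped probabilities feed Brier/DCA only; recorded via mode
        reports[pred.model_name] = report
    return reports


def run_validation(
    cohort: CohortTable,
    predictions: Sequence[PredictionSet],
    run_config: RunConfig | None = None,
) -> ValidationReport:
    """Full validation: (optional) imputation, all metrics, sensitivity.

    The main analysis runs on the imputed cohort (when imputation is on and
    there is anything to impute); the sensitivity analysis re-runs every
    metric on the subset of patients with no missing labs in the *raw*
    cohort. Deterministic given the config seed.
    """
    config = run_config or RunConfig()
    main_cohort = cohort
    iterations = 0
    if config.impute and cohort.df[[c for c in cohort.df.columns]].isna().any().any():
        result = impute_missforest(
            cohort,
            learner_params=config.imputation_learner_params,
            max_iter=config.imputation_max_iter,
            seed=_metric_seed(config.seed, 999),
        )
        main_cohort = result.cohort
        iterations = result.iterations_run

    models = _validate_models(main_cohort, predictions, config)

    sensitivity = None
    if config.complete_case_sensitivity:
        subset = complete_case_subset(cohort)
        if len(subset) > 0:
            keep = set(subset.df["patient_id"])
            preds_cc = [
                PredictionSet(
                    model_name=p.model_name,
                    mode=p.mode,
                    values=p.values.loc[[i for i in p.values.index if i in keep]],
                    score_map=p.score_map,
                )
                for p in predictions
            ]
            sensitivity = _validate_models(subset, preds_cc, config)

    metadata = {
        "seed": config.seed,
        "n_boot": config.n_boot,
        "software_version": __version__,
        "config_hash": config.hash(),
        "n_patients": len(cohort),
        "imputation_iterations": iterations,
        "provenance": cohort.provenance,
    }
    return ValidationReport(models=models, sensitivity=sensitivity, metadata=metadata)


# ---------------------------------------------------------------------------
# Report formatting
# ---------------------------------------------------------------------------

def _fmt_est(est: MetricEstimate | None) -> str:
    if est is None:
        return EN_DASH
    if np.isfinite(est.ci_low) and np.isfinite(est.ci_high):
        return f"{est.value:.2f} ({est.ci_low:.2f}{EN_DASH}{est.ci_high:.2f})"
    return f"{est.value:.2f}"


def _fmt_brier(b: BrierResult | None) -> str:
    if b is None:
        return EN_DASH
    return f"{b.brier.value:.2f} ({b.null_brier:.2f})"


def format_report(report: ValidationReport, style: str = "table2") -> pd.DataFrame:
    """Shape a report for printing.

    ``table2``: c-indexes as "value (lo-hi)" and Brier as "brier (null)" per
    model and horizon; ``table3``: calibration intercept/slope/log(O:E)
    blocks; ``tidy``: long-format numeric CSV rows.
    """
    models = list(report.models)
    horizons = sorted({h for m in report.models.values() for h in m.horizons})
    if style == "table2":
        rows = []
        for metric in ("c-index", "brier"):
            for h in horizons:
                row = {"metric": metric, "horizon_months": h}
                for m in models:
                    hm = report.models[m].horizons.get(h)
                    if hm is None:
                        row[m] = EN_DASH
                    elif metric == "c-index":
                        row[m] = _fmt_est(hm.auc)
                    else:
                        row[m] = _fmt_brier(hm.brier)
                rows.append(row)
        return pd.DataFrame(rows)
    if style == "table3":
        rows = []
        for metric in ("intercept", "slope", "log_oe"):
            for h in horizons:
                row = {"metric": metric, "horizon_months": h}
                for m in models:
                    hm = report.models[m].horizons.get(h)
                    cal = hm.calibration if hm is not None else None
                    if cal is None:
                        row[m] = EN_DASH
                    else:
                        est = getattr(cal, metric if metric != "intercept" else "intercept")
                        row[m] = _fmt_est(est)
                rows.append(row)
        return pd.DataFrame(rows)
    if style == "tidy":
        rows = []
        for m, mr in report.models.items():
            for h, hm in mr.horizons.items():
                for name, est in (("c_index", hm.auc),):
                    if est is not None:
                        rows.append(
                            dict(model=m, horizon_months=h, metric=name, value=est.value,
                                 ci_low=est.ci_low, ci_high=est.ci_high, n=est.n_effective)
                        )
                if hm.brier is not None:
                    rows.append(dict(model=m, horizon_months=h, metric="brier",
                                     value=hm.brier.brier.value, ci_low=np.nan,
                                     ci_high=np.nan, n=hm.brier.n))
                    rows.append(dict(model=m, horizon_months=h, metric="null_brier",
                                     value=hm.brier.null_brier, ci_low=np.nan,
                                     ci_high=np.nan, n=hm.brier.n))
                if hm.calibration is not None:
                    cal = hm.calibration
                    for name, est in (("calibration_intercept", cal.intercept),
                                      ("calibration_slope", cal.slope),
                                      ("log_oe", cal.log_oe)):
                        if est is not None:
                            rows.append(dict(model=m, horizon_months=h, metric=name,
                                             value=est.value, ci_low=est.ci_low,
                                             ci_high=est.ci_high, n=est.n_effective))
            if mr.consistency is not None:
                rows.append(dict(model=m, horizon_months=np.nan, metric="model_consistency",
                                 value=mr.consistency.overall, ci_low=np.nan,
                                 ci_high=np.nan, n=mr.consistency.n_pairs))
        return pd.DataFrame(rows)
    raise ValueError(f"unknown style {style!r}")


def summarize_cohort(
    cohort: CohortTable,
    horizons: Sequence[float] = (1.0, 3.0, 6.0, 12.0, 18.0, 24.0),
    admin_censor: float = 24.0,
) -> pd.DataFrame:
    """Per-horizon deaths / ascertained / mortality percent, plus covariates.

    Mortality percent is ``round(100 * deaths / ascertained)`` to the integer,
    the convention of baseline-characteristics tables.
    """
    rows = []
    for h in horizons:
        statuses = ascertain_statuses(cohort, h, admin_censor=admin_censor)
        dead = sum(s is HorizonStatus.DEAD for s in statuses)
        asc = sum(s is not HorizonStatus.UNKNOWN for s in statuses)
        pct = int(np.floor(100 * dead / asc + 0.5)) if asc else 0
        rows.append(
            dict(horizon_months=h, deaths=dead, ascertained=asc, mortality_percent=pct)
        )
    return pd.DataFrame(rows)


def summarize_covariates(cohort: CohortTable) -> pd.DataFrame:
    """Median (range) for continuous covariates, percent per level for
    categoricals/booleans — the baseline-characteristics companion table."""
    df = cohort.df
    rows = []
    for col in ("age", "bmi"):
        rows.append(dict(
            variable=col, level="",
            summary=f"{df[col].median():.0f} ({df[col].min():.0f}-{df[col].max():.0f})",
        ))
    for col in ("sex", "n_bone_mets", "fracture_status", "primary_tumor"):
        for level, frac in df[col].value_counts(normalize=True).items():
            rows.append(dict(variable=col, level=str(level), summary=f"{100 * frac:.0f}%"))
    for col in ("charlson", "prior_systemic", "prior_radiation", "visceral_mets",
                "brain_mets", "lymph_node_mets"):
        rows.append(dict(variable=col, level="yes",
                         summary=f"{100 * df[col].mean():.0f}%"))
    ecog02 = df["ecog"].isin([0, 1, 2]).mean()
    rows.append(dict(variable="ecog", level="0-2", summary=f"{100 * ecog02:.0f}%"))
    rows.append(dict(variable="ecog", level="3-4", summary=f"{100 * (1 - ecog02):.0f}%"))
    return pd.DataFrame(rows)
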