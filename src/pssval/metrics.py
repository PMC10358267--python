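"""Performance metrics for external validation at fixed survival horizons.

All metrics are computed per horizon on the patients whose status at that
horizon is ascertainable (complete-case: UNKNOWN patients are dropped, which
matches reporting denominators of the form deaths/ascertained).

* Discrimination: horizon AUC / c-index — the probability that a randomly
  chosen survivor received a higher predicted survival value than a randomly
  chosen non-survivor, ties counting one half. Works on probabilities or raw
  integer scores (rank-based).
* Overall performance: Brier score against the alive indicator, benchmarked
  by the null model that predicts the outcome prevalence for everyone
  (null Brier = pbar * (1 - pbar)).
* Calibration: intercept from an intercept-only logistic model with
  logit(predicted survival) as a fixed offset (calibration-in-the-large;
  positive = survival underestimated), slope from the logistic recalibration
  fit, and log(O:E) = ln(observed survivors / sum of predicted survival).
* Clinical utility: decision-curve net benefit on the death event,
  nb(p_t) = TP/n - FP/n * p_t/(1-p_t), against treat-all and treat-none.
* Model consistency (MC): the fraction of within-patient horizon pairs whose
  predicted survival does not increase with time — the "law of attrition by
  time". A pair (t1 < t2) is reasonable iff p_hat(t1) >= p_hat(t2).

Confidence intervals: stratified bootstrap (2000 resamples by default,
seeded) for AUC and the calibration intercept/slope; a delta-method interval
for log(O:E).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import logit

from .data_model import HorizonStatus, MetricEstimate, PredictionSet

__all__ = [
    "BrierResult",
    "CalibrationResult",
    "DecisionCurve",
    "ConsistencyResult",
    "auc_at_horizon",
    "brier_score",
    "calibration_fit",
    "decision_curve",
    "model_consistency",
]


def _alive_mask(statuses: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Split statuses into (keep, alive) boolean arrays, dropping UNKNOWN."""
    arr = statuses.to_numpy()
    keep = np.array([s is not HorizonStatus.UNKNOWN for s in arr])
    alive = np.array([s is HorizonStatus.ALIVE for s in arr])
    return keep, alive


def _align(values: pd.Series, statuses: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Align predictions with statuses on patient id; drop UNKNOWN and NaN."""
    joined = pd.DataFrame({"v": values}).join(
        pd.DataFrame({"s": statuses}), how="inner"
    )
    joined = joined.dropna(subset=["v"])
    keep, alive = _alive_mask(joined["s"])
    return joined["v"].to_numpy(dtype=float)[keep], alive[keep]


@dataclass
class BrierResult:
    brier: MetricEstimate
    null_brier: float
    improvement: float  # brier - null_brier; negative is good
    n: int


@dataclass
class CalibrationResult:
    #: calibration-in-the-large (offset model, slope fixed at 1)
    intercept: MetricEstimate
    slope: MetricEstimate | None  # None when undefined (constant predictions)
    #: intercept of the joint recalibration fit (the pair (a, b) of
    #: logit P(alive) = a + b logit(p_hat)); equals `intercept` when b = 1
    recalibration_intercept: MetricEstimate | None
    log_oe: MetricEstimate
    observed_survivors: int
    expected_survivors: float
    #: (bin midpoint of predicted survival, observed survival fraction, bin n)
    curve: list[tuple[float, float, int]] = field(default_factory=list)


@dataclass
class DecisionCurve:
    horizon: float
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    n: int


@dataclass
class ConsistencyResult:
    pair_mc: dict[tuple[float, float], float]
    overall: float
    n_reasonable: int
    n_pairs: int
    violations: list[tuple[str, float, float, float, float]]
    # (patient_id, t_short, t_long, p_short, p_long)


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

def _auc_value(values: np.ndarray, alive: np.ndarray) -> float:
    ranks = stats.rankdata(values)
    n1 = int(alive.sum())
    n0 = len(alive) - n1
    return float((ranks[alive].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auc_at_horizon(
    values: pd.Series,
    statuses: pd.Series,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> MetricEstimate:
    """Horizon c-index of predicted survival values against vital status.

    Rank-based, so probabilities and raw integer scores are both valid
    inputs; ties count one half. CI by stratified bootstrap (resampling
    survivors and non-survivors separately) or Hanley-McNeil normal
    approximation (``ci_method="hanley"``).
    """
    v, alive = _align(values, statuses)
    n1, n0 = int(alive.sum()), int((~alive).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("degenerate outcome at horizon: need both ALIVE and DEAD")
    auc = _auc_value(v, alive)
    n = n1 + n0
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx1 = np.flatnonzero(alive)
        idx0 = np.flatnonzero(~alive)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate(
                [rng.choice(idx1, size=n1, replace=True), rng.choice(idx0, size=n0, replace=True)]
            )
            a = np.zeros(len(take), dtype=bool)
            a[:n1] = True
            boot[b] = _auc_value(v[take], a)
        lo, hi = np.quantile(boot, [0.025, 0.975])
        lo, hi = min(lo, auc), max(hi, auc)
        method = f"stratified bootstrap ({n_boot})"
    elif ci_method == "hanley":
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (
            auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
        ) / (n1 * n0)
        half = 1.96 * np.sqrt(max(var, 0.0))
        lo, hi = max(auc - half, 0.0), min(auc + half, 1.0)
        method = "hanley-mcneil"
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return MetricEstimate(value=auc, ci_low=float(lo), ci_high=float(hi), n_effective=n, method=method)


# ---------------------------------------------------------------------------
# Overall performance
# ---------------------------------------------------------------------------

def brier_score(values: pd.Series, statuses: pd.Series) -> BrierResult:
    """Brier score of predicted survival probabilities vs the alive indicator,
    with the prevalence-based null model computed on the same patients."""
    p, alive = _align(values, statuses)
    if len(p) == 0:
        raise ValueError("no ascertained patients with predictions")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("Brier score needs probabilities in [0,1]")
    y = alive.astype(float)
    brier = float(np.mean((p - y) ** 2))
    pbar = float(y.mean())
    null = pbar * (1.0 - pbar)
    return BrierResult(
        brier=MetricEstimate(value=brier, n_effective=len(p), method="mean squared error"),
        null_brier=null,
        improvement=brier - null,
        n=len(p),
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _calibration_point(
    p: np.ndarray, y: np.ndarray, clamp_eps: float
) -> tuple[float, float | None, float | None]:
    lp = logit(np.clip(p, clamp_eps, 1 - clamp_eps))
    # calibration-in-the-large: intercept-only logistic model, slope fixed at 1
    intercept = float(
        sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=lp)
        .fit()
        .params[0]
    )
    slope: float | None = None
    joint_intercept: float | None = None
    if len(np.unique(lp)) >= 2:
        X = sm.add_constant(lp)
        params = sm.GLM(y, X, family=sm.families.Binomial()).fit().params
        joint_intercept, slope = float(params[0]), float(params[1])
    return intercept, slope, joint_intercept


def calibration_fit(
    values: pd.Series,
    statuses: pd.Series,
    clamp_eps: float = 1e-6,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
    n_bins: int = 10,
) -> CalibrationResult:
    """Calibration intercept, slope, log(O:E), and a decile calibration curve.

    Sign conventions: a positive intercept and a positive log(O:E) both mean
    observed survival exceeds predicted survival (the model underestimates
    survival); a slope below 1 means predictions are too extreme.
    """
    p, alive = _align(values, statuses)
    if len(p) == 0:
        raise ValueError("no ascertained patients with predictions")
    y = alive.astype(float)
    intercept, slope, joint_intercept = _calibration_point(p, y, clamp_eps)

    O = int(alive.sum())
    E = float(np.sum(p))
    if E <= 0:
        raise ValueError("expected survivors must be positive")
    if O == 0:
        raise ValueError("no observed survivors; log(O:E) undefined")
    log_oe = float(np.log(O / E))
    pbar = O / len(p)
    half = 1.96 * np.sqrt((1.0 - pbar) / O)
    log_oe_est = MetricEstimate(
        value=log_oe, ci_low=log_oe - half, ci_high=log_oe + half,
        n_effective=len(p), method="delta method",
    )

    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx1 = np.flatnonzero(alive)
        idx0 = np.flatnonzero(~alive)
        ints, slopes, joints = [], [], []
        for _ in range(n_boot):
            take = np.concatenate(
                [
                    rng.choice(idx1, size=len(idx1), replace=True),
                    rng.choice(idx0, size=len(idx0), replace=True),
                ]
            )
            yb = np.zeros(len(take))
            yb[: len(idx1)] = 1.0
            try:
                a_b, b_b, j_b = _calibration_point(p[take], yb, clamp_eps)
            except Exception:
                continue
            ints.append(a_b)
            if b_b is not None:
                slopes.append(b_b)
                joints.append(j_b)
        ilo, ihi = np.quantile(ints, [0.025, 0.975])
        label = f"stratified bootstrap ({n_boot})"
        intercept_est = MetricEstimate(
            value=intercept, ci_low=min(ilo, intercept), ci_high=max(ihi, intercept),
            n_effective=len(p), method=label,
        )
        slope_est = joint_est = None
        if slope is not None and slopes:
            slo, shi = np.quantile(slopes, [0.025, 0.975])
            slope_est = MetricEstimate(
                value=slope, ci_low=min(slo, slope), ci_high=max(shi, slope),
                n_effective=len(p), method=label,
            )
            jlo, jhi = np.quantile(joints, [0.025, 0.975])
            joint_est = MetricEstimate(
                value=joint_intercept, ci_low=min(jlo, joint_intercept),
                ci_high=max(jhi, joint_intercept), n_effective=len(p), method=label,
            )
    elif ci_method == "none":
        intercept_est = MetricEstimate(value=intercept, n_effective=len(p), method="point")
        slope_est = (
            MetricEstimate(value=slope, n_effective=len(p), method="point")
            if slope is not None
            else None
        )
        joint_est = (
            MetricEstimate(value=joint_intercept, n_effective=len(p), method="point")
            if joint_intercept is not None
            else None
        )
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    curve = []
    if len(np.unique(p)) >= 2:
        try:
            bins = pd.qcut(p, q=n_bins, duplicates="drop")
            grp = pd.DataFrame({"p": p, "y": y, "bin": bins}).groupby("bin", observed=True)
            for _, g in grp:
                curve.append((float(g["p"].mean()), float(g["y"].mean()), int(len(g))))
        except ValueError:
            pass

    return CalibrationResult(
        intercept=intercept_est,
        slope=slope_est,
        recalibration_intercept=joint_est,
        log_oe=log_oe_est,
        observed_survivors=O,
        expected_survivors=E,
        curve=curve,
    )


# ---------------------------------------------------------------------------
# Decision curve analysis
# ---------------------------------------------------------------------------

def decision_curve(
    values: pd.Series,
    statuses: pd.Series,
    horizon: float = float("nan"),
    threshold_grid: np.ndarray | None = None,
) -> DecisionCurve:
    """Net benefit of treating when predicted death risk exceeds a threshold.

    The event is death by the horizon; predicted risk is ``1 - predicted
    survival``. ``nb_model(p_t) = TP/n - FP/n * p_t/(1-p_t)``; treat-all
    classifies everyone positive and treat-none has zero net benefit by
    definition.
    """
    if threshold_grid is None:
        threshold_grid = np.arange(0.01, 1.0, 0.01)
    threshold_grid = np.asarray(threshold_grid, dtype=float)
    if np.any((threshold_grid <= 0) | (threshold_grid >= 1)):
        raise ValueError("thresholds must lie strictly inside (0,1)")
    p, alive = _align(values, statuses)
    if len(p) == 0:
        raise ValueError("no ascertained patients with predictions")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("decision curve needs probabilities in [0,1]")
    risk = 1.0 - p
    dead = ~alive
    n = len(p)
    w = threshold_grid / (1.0 - threshold_grid)
    positive = risk[None, :] >= threshold_grid[:, None]
    tp = (positive & dead[None, :]).sum(axis=1) / n
    fp = (positive & alive[None, :]).sum(axis=1) / n
    prevalence = dead.mean()
    nb_model = tp - w * fp
    nb_all = prevalence - w * (1.0 - prevalence)
    return DecisionCurve(
        horizon=horizon,
        thresholds=threshold_grid,
        nb_model=nb_model,
        nb_all=nb_all,
        nb_none=np.zeros_like(threshold_grid),
        n=n,
    )


# ---------------------------------------------------------------------------
# Model consistency
# ---------------------------------------------------------------------------

def model_consistency(pred: PredictionSet) -> ConsistencyResult:
    """Fraction of within-patient horizon pairs obeying attrition by time.

    A patient contributes the pair (t1 < t2) only when both cells are
    present; the pair is reasonable iff predicted survival at t1 is >= that
    at t2 (ties are reasonable). Reported per ordered horizon pair and
    overall (total reasonable / total pairs).
    """
    if pred.mode != "probability":
        raise ValueError("model consistency needs probability-mode predictions")
    horizons = pred.horizons
    if len(horizons) < 2:
        raise ValueError("MC requires >= 2 horizons")
    pair_mc: dict[tuple[float, float], float] = {}
    violations: list[tuple[str, float, float, float, float]] = []
    total_reasonable = 0
    total_pairs = 0
    for i, t1 in enumerate(horizons):
        for t2 in horizons[i + 1 :]:
            sub = pred.values[[t1, t2]].dropna()
            if len(sub) == 0:
                continue
            ok = sub[t1].to_numpy() >= sub[t2].to_numpy()
            pair_mc[(t1, t2)] = float(ok.mean())
            total_reasonable += int(ok.sum())
            total_pairs += len(sub)
            for pid, row in sub[~ok].iterrows():
                violations.append((str(pid), t1, t2, float(row[t1]), float(row[t2])))
    if total_pairs == 0:
        raise ValueError("no complete horizon pairs for MC")
    return ConsistencyResult(
        pair_mc=pair_mc,
        overall=total_reasonable / total_pairs,
        n_reasonable=total_reasonable,
        n_pairs=total_pairs,
        violations=violations,
    )
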