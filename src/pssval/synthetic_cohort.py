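"""Calibrated synthetic cohorts and synthetic prediction models.

Real extremity-metastasis cohorts are not publicly shareable, so every
downstream stage (imputation, metrics, the full pipeline) is exercised on
synthetic cohorts built to match the statistical structure of a surgical
validation study: a fixed patient count, cumulative mortality among
ascertained patients at the six standard horizons (1, 3, 6, 12, 18, 24
months), ascertainment counts at those horizons, covariate marginals, and
per-lab missingness rates.

The survival model is piecewise exponential with knots at the horizons —
the simplest family that can match all horizon targets exactly. Loss to
follow-up is an independent piecewise-exponential dropout process plus
administrative censoring at 24 months. Because the study reports mortality
as deaths / ascertained (not marginal cumulative mortality), the death and
dropout hazards are calibrated *jointly*: at each horizon the targets pin
both the probability of an observed death and the probability of being
alive-and-ascertained, which yields a closed form per interval (see
:func:`calibrate_baseline_hazards`). When no dropout is requested this
reduces to the familiar piecewise-exponential identity
``lambda_k = -(ln S(t_k) - ln S(t_{k-1})) / delta_k``.

Synthetic prediction models are distorted views of the latent truth:
``p_hat = expit(a + b * logit(p_true) + eps)`` with patient-level noise
``eps``, so miscalibration (a, b) and discrimination (via the noise SD,
optionally solved to hit a target AUC) can be injected independently and
later recovered by the metrics module.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit

from .data_model import COHORT_COLUMNS, LAB_COLUMNS, CohortTable, PredictionSet

__all__ = [
    "LabSpec",
    "CovariateSpec",
    "SimulationConfig",
    "PredictionSimSpec",
    "HazardSchedule",
    "LatentTruth",
    "GeneratedStudy",
    "sample_covariates",
    "calibrate_baseline_hazards",
    "sample_survival_and_censoring",
    "inject_missingness",
    "simulate_predictions",
    "generate_cohort",
]


@dataclass(frozen=True)
class LabSpec:
    """Marginal distribution of one lab: ``normal`` (mean, sd) or
    ``lognormal`` (median, sigma of log)."""

    dist: str
    loc: float
    scale: float

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.dist == "normal":
            x = stats.norm.ppf(u, loc=self.loc, scale=self.scale)
        elif self.dist == "lognormal":
            x = np.exp(stats.norm.ppf(u, loc=np.log(self.loc), scale=self.scale))
        else:  # pragma: no cover - validated in config
            raise ValueError(f"unknown lab distribution {self.dist!r}")
        return np.maximum(x, 0.01)


def _default_labs() -> dict[str, LabSpec]:
    # Physiologic placeholder marginals (the study's full lab summary lives in
    # a supplement that is not reproduced here); exact lab realism is
    # immaterial to metric correctness.
    return {
        "na": LabSpec("normal", 137.0, 4.0),
        "ca": LabSpec("normal", 9.3, 0.8),
        "alb": LabSpec("normal", 3.7, 0.6),
        "alp": LabSpec("lognormal", 110.0, 0.6),
        "bun": LabSpec("lognormal", 16.0, 0.45),
        "hgb": LabSpec("normal", 11.5, 1.8),
        "alc": LabSpec("lognormal", 1.3, 0.5),
        "anc": LabSpec("lognormal", 4.5, 0.5),
        "wbc": LabSpec("lognormal", 6.8, 0.4),
        "plt": LabSpec("normal", 230.0, 80.0),
    }


@dataclass
class CovariateSpec:
    """Marginal covariate distributions of the emulated cohort.

    Values printed in the study's baseline table (age, sex, BMI, comorbidity,
    ECOG 0-2 fraction, primary tumor mixture) are defaults here; the rest are
    documented placeholders.
    """

    age_median: float = 61.0
    age_sd: float = 13.0
    age_range: tuple[float, float] = (25.0, 95.0)
    female_frac: float = 0.52
    bmi_median: float = 23.0
    bmi_sd: float = 4.0
    bmi_range: tuple[float, float] = (13.0, 39.0)
    charlson_frac: float = 0.60
    prior_systemic_frac: float = 0.55
    prior_radiation_frac: float = 0.30
    visceral_frac: float = 0.35
    brain_frac: float = 0.08
    lymph_node_frac: float = 0.25
    multiple_bone_frac: float = 0.60
    complete_fracture_frac: float = 0.50
    # P(ECOG 0-2) = 0.79 as printed
    ecog_probs: tuple[float, ...] = (0.10, 0.33, 0.36, 0.17, 0.04)
    asa_probs: tuple[float, ...] = (0.02, 0.35, 0.55, 0.07, 0.01)
    tumor_weights: dict[str, float] = field(
        default_factory=lambda: {
            "lung": 0.33,
            "breast": 0.16,
            "hepatocellular": 0.10,
            "other": 0.41,
        }
    )
    labs: dict[str, LabSpec] = field(default_factory=_default_labs)
    #: (lab_a, lab_b, rho) entries of a Gaussian copula between lab marginals.
    lab_correlations: list[tuple[str, str, float]] = field(default_factory=list)


def _default_missingness() -> dict[str, float]:
    return {
        "na": 0.003,
        "alc": 0.022,
        "anc": 0.022,
        "ca": 0.022,
        "alp": 0.050,
        "alb": 0.070,
        "bun": 0.25,
    }


@dataclass
class SimulationConfig:
    """Full parameterisation of the synthetic study.

    Defaults reproduce the emulated cohort: 356 patients, horizon mortality
    5/18/32/51/61/68% among ascertained at 1/3/6/12/18/24 months,
    ascertainment counts 356/350/342/326/314/302, administrative censoring at
    24 months, and the reference per-lab missingness rates.
    """

    n_patients: int = 356
    horizons: tuple[float, ...] = (1.0, 3.0, 6.0, 12.0, 18.0, 24.0)
    target_mortality: tuple[float, ...] = (0.05, 0.18, 0.32, 0.51, 0.61, 0.68)
    #: ascertainment counts; None scales the reference counts
    #: (356, 350, 342, 326, 314, 302 out of 356) to ``n_patients``
    target_ascertained: tuple[int, ...] | None = None
    admin_censor: float = 24.0
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    missingness_rates: dict[str, float] = field(default_factory=_default_missingness)
    missingness_mechanism: str = "mcar"  # or "mar" (depends on ECOG)
    mar_ecog_log_odds: float = 0.5
    hazard_link: str = "marginal"  # or "covariate_linked"
    #: log-hazard ratios per covariate column (covariate_linked mode)
    linear_predictor_coefficients: dict[str, float] = field(default_factory=dict)
    #: SD of the patient-level normal log-frailty. Risk heterogeneity is what
    #: lets a synthetic prediction model discriminate at all (with frailty 0
    #: every patient shares one survival curve and no model can beat AUC 0.5),
    #: so the default is nonzero; population-average targets are still matched
    #: exactly by the calibration.
    frailty_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")
        if self.target_ascertained is None:
            ref = np.array([356, 350, 342, 326, 314, 302]) / 356.0
            if len(ref) != len(self.horizons):
                ref = np.ones(len(self.horizons))
            self.target_ascertained = tuple(
                int(round(f * self.n_patients)) for f in ref
            )
        if len(self.horizons) != len(self.target_mortality) or len(self.horizons) != len(
            self.target_ascertained
        ):
            raise ValueError("horizons, target_mortality, target_ascertained lengths differ")
        m = np.asarray(self.target_mortality, dtype=float)
        # strictly increasing in the emulated study; equality allowed only for
        # degenerate (zero-mortality) configurations
        if np.any(np.diff(m) < 0) or (np.any(np.diff(m) == 0) and m.max() > 0):
            raise ValueError("target_mortality must be strictly increasing")
        if np.any((m < 0) | (m > 1)):
            raise ValueError("target_mortality must lie in [0,1]")
        a = np.asarray(self.target_ascertained, dtype=float)
        if np.any(np.diff(a) > 0):
            raise ValueError("target_ascertained must be non-increasing")
        if np.any(a > self.n_patients) or np.any(a <= 0):
            raise ValueError("target_ascertained must lie in (0, n_patients]")
        for name, r in self.missingness_rates.items():
            if name not in LAB_COLUMNS:
                raise ValueError(f"unknown lab {name!r} in missingness_rates")
            if not (0.0 <= r < 1.0):
                raise ValueError(f"missingness rate for {name} outside [0,1)")
        for probs, label in (
            (self.covariate_spec.ecog_probs, "ecog_probs"),
            (self.covariate_spec.asa_probs, "asa_probs"),
            (tuple(self.covariate_spec.tumor_weights.values()), "tumor_weights"),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{label} must sum to 1")
        if self.missingness_mechanism not in ("mcar", "mar"):
            raise ValueError("missingness_mechanism must be 'mcar' or 'mar'")
        if self.hazard_link not in ("marginal", "covariate_linked"):
            raise ValueError("hazard_link must be 'marginal' or 'covariate_linked'")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from YAML or JSON mirroring the field names."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cov = raw.pop("covariate_spec", None)
        kwargs = dict(raw)
        if cov is not None:
            labs = cov.pop("labs", None)
            corr = cov.pop("lab_correlations", None)
            spec = CovariateSpec(**cov)
            if labs is not None:
                spec.labs = {k: LabSpec(**v) for k, v in labs.items()}
            if corr is not None:
                spec.lab_correlations = [tuple(c) for c in corr]
            kwargs["covariate_spec"] = spec
        for key in ("horizons", "target_mortality", "target_ascertained"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class PredictionSimSpec:
    """Recipe for one synthetic prediction model.

    Either fix the patient-level noise SD directly, or give ``target_auc`` at
    ``reference_horizon`` and the SD is solved by bisection on a large
    auxiliary sample. ``calibration_shift`` and ``calibration_slope`` distort
    the logit of the true survival probability; ``horizon_noise_sd > 0``
    breaks within-patient monotonicity deliberately (for consistency-metric
    testing).
    """

    model_name: str
    target_auc: float | None = None
    reference_horizon: float = 12.0
    #: the calibration intercept a downstream recalibration should recover:
    #: positive shift => the model underestimates survival
    calibration_shift: float = 0.0
    #: the recoverable calibration slope; below 1 => predictions too extreme
    calibration_slope: float = 1.0
    patient_noise_sd: float = 0.0
    horizon_noise_sd: float = 0.0
    mode: str = "probability"
    n_score_levels: int = 10
    horizons: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.target_auc is not None and not (0.5 < self.target_auc <= 1.0):
            raise ValueError("target_auc must be in (0.5, 1]")
        if self.calibration_slope == 0:
            raise ValueError("calibration_slope must be nonzero")
        if self.mode not in ("probability", "score"):
            raise ValueError("mode must be 'probability' or 'score'")


@dataclass
class HazardSchedule:
    """Piecewise-constant death and dropout hazards on the horizon intervals."""

    breaks: np.ndarray  # [0, t_1, ..., t_K]
    death: np.ndarray  # per-interval baseline death hazard (per month)
    dropout: np.ndarray  # per-interval dropout hazard (per month)

    def cumulative_death_hazard(self, t: np.ndarray) -> np.ndarray:
        """Baseline cumulative death hazard at times ``t``."""
        t = np.asarray(t, dtype=float)
        widths = np.clip(
            t[..., None] - self.breaks[:-1], 0.0, np.diff(self.breaks)
        )
        return widths @ self.death


@dataclass
class LatentTruth:
    """True survival probabilities per patient and horizon.

    ``survival_probs`` is indexed by patient_id with one column per horizon;
    ``hazard_multiplier`` is the per-patient proportional-hazards factor
    (1.0 in marginal mode).
    """

    survival_probs: pd.DataFrame
    hazard_multiplier: pd.Series

    def __post_init__(self) -> None:
        p = self.survival_probs.to_numpy()
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("true survival probabilities must lie in (0,1)")
        if np.any(np.diff(p, axis=1) > 1e-12):
            raise ValueError("true survival must be non-increasing in horizon")


@dataclass
class GeneratedStudy:
    """Output bundle of :func:`generate_cohort`."""

    cohort: CohortTable  # labs with injected missingness
    complete_cohort: CohortTable  # labs before missingness (imputation truth)
    truth: LatentTruth
    predictions: list[PredictionSet]


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def _truncated_normal(rng, n, median, sd, lo, hi):
    a, b = (lo - median) / sd, (hi - median) / sd
    return stats.truncnorm.rvs(a, b, loc=median, scale=sd, size=n, random_state=rng)


def sample_covariates(config: SimulationConfig, seed: int | None = None) -> CohortTable:
    """Draw covariates and labs for ``n_patients``; survival fields are
    placeholders (0 / not dead) until :func:`sample_survival_and_censoring`.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cv = config.covariate_spec
    n = config.n_patients
    df = pd.DataFrame(
        {
            "patient_id": [f"S{i:05d}" for i in range(n)],
            "age": _truncated_normal(rng, n, cv.age_median, cv.age_sd, *cv.age_range),
            "sex": np.where(rng.random(n) < cv.female_frac, "female", "male"),
            "bmi": _truncated_normal(rng, n, cv.bmi_median, cv.bmi_sd, *cv.bmi_range),
            "charlson": rng.random(n) < cv.charlson_frac,
            "prior_systemic": rng.random(n) < cv.prior_systemic_frac,
            "prior_radiation": rng.random(n) < cv.prior_radiation_frac,
            "visceral_mets": rng.random(n) < cv.visceral_frac,
            "brain_mets": rng.random(n) < cv.brain_frac,
            "lymph_node_mets": rng.random(n) < cv.lymph_node_frac,
            "n_bone_mets": np.where(
                rng.random(n) < cv.multiple_bone_frac, "multiple", "single"
            ),
            "fracture_status": np.where(
                rng.random(n) < cv.complete_fracture_frac, "complete", "impending"
            ),
            "ecog": rng.choice(5, size=n, p=cv.ecog_probs),
            "asa": rng.choice(np.arange(1, 6), size=n, p=cv.asa_probs),
            "primary_tumor": rng.choice(
                list(cv.tumor_weights), size=n, p=list(cv.tumor_weights.values())
            ),
        }
    )

    # Labs via a Gaussian copula: identity correlation unless pairs declared.
    corr = np.eye(len(LAB_COLUMNS))
    idx = {lab: i for i, lab in enumerate(LAB_COLUMNS)}
    for a_lab, b_lab, rho in cv.lab_correlations:
        corr[idx[a_lab], idx[b_lab]] = corr[idx[b_lab], idx[a_lab]] = rho
    z = rng.multivariate_normal(np.zeros(len(LAB_COLUMNS)), corr, size=n, method="cholesky")
    u = stats.norm.cdf(z)
    for j, lab in enumerate(LAB_COLUMNS):
        df[lab] = cv.labs[lab].ppf(u[:, j])

    df["survival_months"] = 0.0
    df["death_observed"] = False
    return CohortTable(df[COHORT_COLUMNS], provenance="synthetic")


# ---------------------------------------------------------------------------
# Hazard calibration
# ---------------------------------------------------------------------------

def calibrate_baseline_hazards(
    config: SimulationConfig, linear_predictor: np.ndarray | None = None
) -> HazardSchedule:
    """Solve piecewise-constant death and dropout hazards from the targets.

    The study reports, at each horizon ``t_k``, the mortality among
    ascertained patients ``m_k`` and the ascertained fraction ``a_k``. These
    jointly pin, per horizon, the probability of an observed death
    ``D_k = m_k a_k`` and of being alive-and-followed ``A_k = (1-m_k) a_k``.
    With constant death hazard ``lam`` and dropout hazard ``mu`` on the
    interval, the per-interval solution is closed form::

        rho = -(ln A_k - ln A_{k-1}) / delta_k        # total exit hazard
        lam = (D_k - D_{k-1}) * rho / (A_{k-1} - A_k)
        mu  = rho - lam

    When ``a_k = 1`` for all horizons (no dropout) this reduces to
    ``lam_k = -(ln S_k - ln S_{k-1}) / delta_k``.

    In ``covariate_linked`` mode each patient's death hazard is scaled by
    ``exp(linear_predictor_i)`` and the baseline per-interval hazards are
    solved by one-dimensional root-finding so the population-average observed
    death probability and at-risk probability match the same targets.
    """
    t = np.asarray(config.horizons, dtype=float)
    m = np.asarray(config.target_mortality, dtype=float)
    a = np.asarray(config.target_ascertained, dtype=float) / config.n_patients
    breaks = np.concatenate([[0.0], t])
    dt = np.diff(breaks)
    D = m * a
    A = (1.0 - m) * a
    if np.any(np.diff(np.concatenate([[1.0], A])) > 0):
        k = int(np.flatnonzero(np.diff(np.concatenate([[1.0], A])) > 0)[0])
        raise ValueError(
            f"infeasible targets: at-risk probability increases on interval {k}"
            f" ({breaks[k]}-{breaks[k + 1]} months)"
        )
    dD = np.diff(np.concatenate([[0.0], D]))
    if np.any(dD < 0):
        k = int(np.flatnonzero(dD < 0)[0])
        raise ValueError(f"infeasible targets: death probability decreases on interval {k}")

    if linear_predictor is None:
        if config.hazard_link == "covariate_linked":
            raise ValueError("covariate_linked calibration needs the linear predictor")
        A_prev = np.concatenate([[1.0], A[:-1]])
        rho = -(np.log(A) - np.log(A_prev)) / dt
        exits = A_prev - A
        with np.errstate(invalid="ignore"):
            lam = np.where(exits > 0, dD * rho / np.where(exits > 0, exits, 1.0), 0.0)
        mu = rho - lam
        if np.any(mu < -1e-10):
            k = int(np.flatnonzero(mu < -1e-10)[0])
            raise ValueError(
                f"infeasible targets: implied dropout hazard negative on interval {k}"
            )
        return HazardSchedule(breaks=breaks, death=lam, dropout=np.maximum(mu, 0.0))

    # covariate-linked: track each patient's at-risk probability
    mult = np.exp(np.asarray(linear_predictor, dtype=float))
    n = len(mult)
    P = np.ones(n)
    lam = np.zeros(len(dt))
    mu = np.zeros(len(dt))
    for k in range(len(dt)):
        d = dt[k]
        target_dD, target_A = dD[k], A[k]

        def mean_end(l0: float, mk: float) -> float:
            return float(np.mean(P * np.exp(-(l0 * mult + mk) * d)))

        def mean_deaths(l0: float, mk: float) -> float:
            r = l0 * mult + mk
            return float(np.mean(P * l0 * mult / r * (1.0 - np.exp(-r * d))))

        def solve_l0(mk: float) -> float:
            # at-risk probability is strictly decreasing in l0
            lo, hi = 1e-12, 1.0
            if mean_end(lo, mk) <= target_A:
                return lo  # dropout alone already exhausts the exits
            while mean_end(hi, mk) > target_A:
                hi *= 2.0
                if hi > 1e6:  # pragma: no cover - infeasible config
                    raise ValueError(f"cannot match at-risk target on interval {k}")
            return brentq(lambda l0: mean_end(l0, mk) - target_A, lo, hi, xtol=1e-14)

        mu_hi = -np.log(target_A / np.mean(P)) / d  # all exits via dropout
        if mean_deaths(solve_l0(0.0), 0.0) <= target_dD + 1e-12:
            mk = 0.0  # targets need no (or negligible) dropout on this interval
        else:
            mk = brentq(
                lambda mval: mean_deaths(solve_l0(mval), mval) - target_dD,
                0.0,
                mu_hi,
                xtol=1e-13,
            )
        l0 = solve_l0(mk)
        lam[k], mu[k] = l0, mk
        P = P * np.exp(-(l0 * mult + mk) * d)
    return HazardSchedule(breaks=breaks, death=lam, dropout=mu)


def _sample_piecewise_exponential(
    rng: np.random.Generator, breaks: np.ndarray, rates: np.ndarray
) -> np.ndarray:
    """Invert cumulative hazard for one draw per row of ``rates``.

    ``rates``: (n, K) per-patient per-interval hazards. Returns times; inf if
    the event falls beyond the last break.
    """
    n = rates.shape[0]
    dt = np.diff(breaks)
    cumhaz = np.concatenate([np.zeros((n, 1)), np.cumsum(rates * dt, axis=1)], axis=1)
    e = rng.exponential(size=n)
    times = np.full(n, np.inf)
    for k in range(len(dt)):
        inside = (e >= cumhaz[:, k]) & (e < cumhaz[:, k + 1]) & np.isinf(times)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = breaks[k] + (e - cumhaz[:, k]) / rates[:, k]
        times[inside] = t[inside]
    return times


def sample_survival_and_censoring(
    cohort: CohortTable,
    hazards: HazardSchedule,
    config: SimulationConfig,
    seed: int,
    linear_predictor: np.ndarray | None = None,
) -> tuple[CohortTable, LatentTruth]:
    """Draw death and dropout times; fill survival fields; record the truth.

    Observed time is ``min(death, dropout, admin_censor)``; the death flag is
    set only when death comes first. The latent truth stores each patient's
    true survival probability ``exp(-Lambda_i(t))`` at every horizon.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    mult = (
        np.ones(n)
        if linear_predictor is None
        else np.exp(np.asarray(linear_predictor, dtype=float))
    )
    death_rates = mult[:, None] * hazards.death[None, :]
    death_t = _sample_piecewise_exponential(rng, hazards.breaks, death_rates)
    drop_rates = np.broadcast_to(hazards.dropout[None, :], death_rates.shape)
    drop_t = _sample_piecewise_exponential(rng, hazards.breaks, np.ascontiguousarray(drop_rates))

    observed = np.minimum.reduce([death_t, drop_t, np.full(n, config.admin_censor)])
    died = (death_t <= drop_t) & (death_t <= config.admin_censor) & np.isfinite(death_t)

    df = cohort.df.copy()
    df["survival_months"] = observed
    df["death_observed"] = died
    out = CohortTable(df, provenance="synthetic")

    horizons = np.asarray(config.horizons, dtype=float)
    base_cum = hazards.cumulative_death_hazard(horizons)  # (K,)
    probs = np.exp(-np.outer(mult, base_cum))
    probs = np.clip(probs, 1e-12, 1.0 - 1e-12)  # keep strictly inside (0,1)
    truth = LatentTruth(
        survival_probs=pd.DataFrame(
            probs, index=df["patient_id"].to_numpy(), columns=horizons
        ),
        hazard_multiplier=pd.Series(mult, index=df["patient_id"].to_numpy()),
    )
    return out, truth


def inject_missingness(
    cohort: CohortTable, config: SimulationConfig, seed: int
) -> CohortTable:
    """Blank lab cells at the configured per-lab rates.

    MCAR by default; under ``mar`` the missingness log-odds increase with
    ECOG (sicker patients get fewer elective labs) while preserving the
    configured marginal rate in expectation.
    """
    rng = np.random.default_rng(seed)
    df = cohort.df.copy()
    ecog = df["ecog"].to_numpy(dtype=float)
    for lab, rate in config.missingness_rates.items():
        if rate == 0.0:
            continue
        if config.missingness_mechanism == "mcar":
            p = np.full(len(df), rate)
        else:
            shift = config.mar_ecog_log_odds * (ecog - ecog.mean())
            p = expit(logit(rate) + shift)
            p *= rate / p.mean()  # hold the marginal rate
            p = np.clip(p, 0.0, 1.0)
        mask = rng.random(len(df)) < p
        df.loc[mask, lab] = np.nan
    return CohortTable(df, provenance=cohort.provenance)


# ---------------------------------------------------------------------------
# Synthetic prediction models
# ---------------------------------------------------------------------------

def _auc_fast(values: np.ndarray, alive: np.ndarray) -> float:
    """Mann-Whitney AUC (ties count 1/2) of values for alive vs dead."""
    ranks = stats.rankdata(values)
    n1 = int(alive.sum())
    n0 = len(alive) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("degenerate outcome")
    return (ranks[alive].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _solve_noise_sd(
    p_ref: np.ndarray,
    slope: float,
    target_auc: float,
    rng: np.random.Generator,
    n_aux: int = 50_000,
    tol: float = 0.002,
) -> float:
    """Bisection for the patient-noise SD that yields ``target_auc``.

    An auxiliary sample of ``n_aux`` patients is bootstrapped from the true
    reference-horizon probabilities; outcomes are Bernoulli draws from those
    probabilities, the predictor has the rank order of ``logit(p) + eps``
    (times the sign of the calibration slope), and the SD is bisected until
    the empirical AUC is within ``tol`` of the target.
    """
    p = rng.choice(p_ref, size=n_aux, replace=True)
    alive = rng.random(n_aux) < p
    if alive.all() or not alive.any():  # pragma: no cover - degenerate truth
        raise ValueError("auxiliary sample has a single outcome class")
    eta = logit(p)
    eps = rng.standard_normal(n_aux)

    def auc_at(sd: float) -> float:
        return _auc_fast(np.sign(slope) * (eta + sd * eps), alive)

    if auc_at(0.0) < target_auc - tol:
        raise ValueError(
            f"target_auc {target_auc} exceeds the information limit "
            f"{auc_at(0.0):.3f} of the latent truth"
        )
    lo, hi = 0.0, 1.0
    while auc_at(hi) > target_auc:
        lo, hi = hi, hi * 2.0
        if hi > 1e3:  # pragma: no cover
            break
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        a = auc_at(mid)
        if abs(a - target_auc) < tol:
            return mid
        if a > target_auc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_predictions(
    truth: LatentTruth, spec: PredictionSimSpec, seed: int
) -> PredictionSet:
    """Emit a synthetic model's predictions from the latent truth.

    Probability mode::

        p_hat_i(t) = expit((logit(p_i(t)) + eps_i - a) / b)

    with one patient-level ``eps_i`` shared across horizons, so within-patient
    monotonicity is preserved whenever ``b > 0``. The parameters are stated in
    the *recoverable* direction: regressing the alive indicator on
    ``logit(p_hat)`` at large n (and ``eps = 0``) returns intercept ``a`` and
    slope ``b`` — a positive ``a`` means the model underestimates survival.
    Score mode quantile-bins the same latent predictor into
    ``n_score_levels`` integers (higher score = better prognosis).
    """
    rng = np.random.default_rng(seed)
    horizons = (
        list(spec.horizons)
        if spec.horizons is not None
        else list(truth.survival_probs.columns)
    )
    missing = [h for h in horizons if h not in truth.survival_probs.columns]
    if missing:
        raise ValueError(f"truth has no horizons {missing}")

    if spec.target_auc is not None:
        if spec.reference_horizon not in truth.survival_probs.columns:
            raise ValueError(f"truth has no reference horizon {spec.reference_horizon}")
        p_ref = truth.survival_probs[spec.reference_horizon].to_numpy()
        sd = _solve_noise_sd(p_ref, spec.calibration_slope, spec.target_auc, rng)
    else:
        sd = spec.patient_noise_sd

    n = len(truth.survival_probs)
    eps = sd * rng.standard_normal(n)
    cols = {}
    for h in horizons:
        lin = logit(truth.survival_probs[h].to_numpy()) + eps
        if spec.horizon_noise_sd > 0:
            lin = lin + spec.horizon_noise_sd * rng.standard_normal(n)
        cols[h] = expit((lin - spec.calibration_shift) / spec.calibration_slope)
    values = pd.DataFrame(cols, index=truth.survival_probs.index)

    if spec.mode == "score":
        eta = np.sign(spec.calibration_slope) * (
            logit(truth.survival_probs[spec.reference_horizon].to_numpy()) + eps
        )
        qs = np.quantile(eta, np.linspace(0, 1, spec.n_score_levels + 1)[1:-1])
        scores = np.searchsorted(qs, eta, side="right").astype(float)
        values = pd.DataFrame(
            {h: scores for h in horizons}, index=truth.survival_probs.index
        )
        return PredictionSet(model_name=spec.model_name, mode="score", values=values)
    return PredictionSet(model_name=spec.model_name, mode="probability", values=values)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SimulationConfig,
    pred_specs: Sequence[PredictionSimSpec] = (),
    seed: int | None = None,
) -> GeneratedStudy:
    """Generate a full synthetic study: cohort, latent truth, predictions.

    Deterministic given ``seed`` (falls back to ``config.seed``). The
    returned bundle keeps the pre-missingness cohort so imputation error can
    be measured against withheld truth.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    s_cov, s_surv, s_miss, s_frail, s_pred = root.spawn(5)
    covariates = sample_covariates(config, seed=s_cov)

    lp = None
    if config.hazard_link == "covariate_linked":
        lp = np.zeros(len(covariates))
        for col, beta in config.linear_predictor_coefficients.items():
            x = covariates.df[col]
            if x.dtype == bool:
                x = x.astype(float)
            x = pd.to_numeric(x, errors="raise").to_numpy(dtype=float)
            lp = lp + beta * (x - x.mean())
    if config.frailty_sd > 0:
        frail_rng = np.random.default_rng(s_frail)
        frailty = config.frailty_sd * frail_rng.standard_normal(len(covariates))
        lp = frailty if lp is None else lp + frailty
    hazards = calibrate_baseline_hazards(config, linear_predictor=lp)
    complete, truth = sample_survival_and_censoring(
        covariates, hazards, config, seed=int(s_surv.generate_state(1)[0] % 2**31), linear_predictor=lp
    )
    cohort = inject_missingness(
        complete, config, seed=int(s_miss.generate_state(1)[0] % 2**31)
    )
    preds = [
        simulate_predictions(truth, spec, seed=int(child.generate_state(1)[0] % 2**31))
        for spec, child in zip(pred_specs, s_pred.spawn(max(len(pred_specs), 1)))
    ]
    return GeneratedStudy(
        cohort=cohort, complete_cohort=complete, truth=truth, predictions=preds
    )
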