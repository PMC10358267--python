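"""Domain types and I/O for cohort tables, prediction sets, and horizon status.

The validation substrate is a cohort of patients who underwent surgery for
extremity bone metastasis: per-patient covariates, ten preoperative laboratory
values (possibly missing), follow-up time in months, and a death indicator.
Predictions arrive as per-model, per-horizon survival probabilities in [0, 1]
or as integer scores; score-only models can be lifted to the probability scale
through an explicit :class:`ScoreMap`.

Survival status at a fixed month horizon follows the ascertainment rule used
throughout: a patient is DEAD at horizon ``t`` if death occurred at or before
``t``; ALIVE if follow-up reached ``t`` alive; otherwise status is UNKNOWN
(censored alive before the horizon) and the patient drops out of every metric
at that horizon.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LAB_COLUMNS",
    "COHORT_COLUMNS",
    "HorizonStatus",
    "PatientRecord",
    "CohortTable",
    "ScoreMap",
    "PredictionSet",
    "MetricEstimate",
    "ascertain_status",
    "ascertain_statuses",
    "read_cohort",
    "write_cohort",
    "read_predictions",
    "write_predictions",
    "read_score_map",
    "apply_score_map",
]

#: The ten preoperative laboratory values, in CSV column order.
#: na: sodium mmol/L; ca: calcium mg/dL; alb: albumin g/dL; alp: alkaline
#: phosphatase U/L; bun: blood urea nitrogen mg/dL; hgb: hemoglobin g/dL;
#: alc/anc: absolute lymphocyte / neutrophil count 10^3/uL; wbc: white count
#: 10^3/uL; plt: platelet 10^3/uL.
LAB_COLUMNS = ["na", "ca", "alb", "alp", "bun", "hgb", "alc", "anc", "wbc", "plt"]

BOOL_COLUMNS = [
    "charlson",
    "prior_systemic",
    "prior_radiation",
    "visceral_mets",
    "brain_mets",
    "lymph_node_mets",
    "death_observed",
]

CATEGORICAL_LEVELS = {
    "sex": ("female", "male"),
    "n_bone_mets": ("single", "multiple"),
    "fracture_status": ("impending", "complete"),
}

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "bmi",
    "charlson",
    "prior_systemic",
    "prior_radiation",
    "visceral_mets",
    "brain_mets",
    "lymph_node_mets",
    "n_bone_mets",
    "fracture_status",
    "ecog",
    "asa",
    "primary_tumor",
    *LAB_COLUMNS,
    "survival_months",
    "death_observed",
]


class HorizonStatus(enum.Enum):
    """Survival status at a fixed month horizon."""

    ALIVE = "alive"
    DEAD = "dead"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PatientRecord:
    """A single patient's covariates, labs, and follow-up.

    ``labs`` maps the names in :data:`LAB_COLUMNS` to values; a missing lab is
    simply absent from the mapping (or NaN). If ``death_observed`` is False,
    ``survival_months`` is the censoring time.
    """

    patient_id: str
    age: float
    sex: str
    bmi: float
    charlson_comorbidity: bool
    prior_systemic_therapy: bool
    prior_local_radiation: bool
    visceral_mets: bool
    brain_mets: bool
    lymph_node_mets: bool
    n_bone_mets: str
    fracture_status: str
    ecog: int
    asa_class: int
    primary_tumor: str
    labs: Mapping[str, float]
    survival_months: float
    death_observed: bool

    def __post_init__(self) -> None:
        if self.survival_months < 0:
            raise ValueError(
                f"patient {self.patient_id}: survival_months must be >= 0"
            )
        if self.ecog not in range(5):
            raise ValueError(f"patient {self.patient_id}: ecog must be in 0..4")
        for name, value in self.labs.items():
            if value is not None and not np.isnan(value) and value < 0:
                raise ValueError(
                    f"patient {self.patient_id}: lab {name} must be non-negative"
                )


@dataclass
class CohortTable:
    """An ordered cohort of patients backed by a pandas DataFrame.

    Parameters
    ----------
    df : DataFrame with the columns in :data:`COHORT_COLUMNS`. Missing labs
        are NaN. Boolean columns are stored as booleans.
    provenance : one of ``real``, ``synthetic``, ``imputed``.
    """

    df: pd.DataFrame
    provenance: str = "real"

    def __post_init__(self) -> None:
        if self.provenance not in ("real", "synthetic", "imputed"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        missing = [c for c in COHORT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort missing columns: {missing}")
        ids = self.df["patient_id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate patient_id: {dup.iloc[0]!r}")
        if (self.df["survival_months"] < 0).any():
            bad = self.df.index[self.df["survival_months"] < 0][0]
            raise ValueError(f"negative survival_months at row {bad}")
        if (~self.df["ecog"].isin(range(5))).any():
            raise ValueError("ecog outside 0..4")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def patient_ids(self) -> pd.Series:
        return self.df["patient_id"]

    def records(self) -> Iterable[PatientRecord]:
        """Iterate patients as typed :class:`PatientRecord` objects."""
        for _, row in self.df.iterrows():
            labs = {k: row[k] for k in LAB_COLUMNS if pd.notna(row[k])}
            yield PatientRecord(
                patient_id=str(row["patient_id"]),
                age=float(row["age"]),
                sex=row["sex"],
                bmi=float(row["bmi"]),
                charlson_comorbidity=bool(row["charlson"]),
                prior_systemic_therapy=bool(row["prior_systemic"]),
                prior_local_radiation=bool(row["prior_radiation"]),
                visceral_mets=bool(row["visceral_mets"]),
                brain_mets=bool(row["brain_mets"]),
                lymph_node_mets=bool(row["lymph_node_mets"]),
                n_bone_mets=row["n_bone_mets"],
                fracture_status=row["fracture_status"],
                ecog=int(row["ecog"]),
                asa_class=int(row["asa"]),
                primary_tumor=row["primary_tumor"],
                labs=labs,
                survival_months=float(row["survival_months"]),
                death_observed=bool(row["death_observed"]),
            )


@dataclass(frozen=True)
class MetricEstimate:
    """Point estimate with a 95% confidence interval and effective n."""

    value: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_effective: int = 0
    method: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not (self.ci_low <= self.value + 1e-12 and self.value - 1e-12 <= self.ci_high):
                raise ValueError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not bracket {self.value}"
                )

    def as_dict(self) -> dict:
        return {
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_effective": self.n_effective,
            "method": self.method,
        }


@dataclass
class ScoreMap:
    """Per-horizon lookup from integer score to survival probability.

    ``direction`` declares whether a higher score means better prognosis
    (``"higher_better"``) or worse (``"higher_worse"``); the mapped
    probabilities must be monotone in the score accordingly.
    """

    model: str
    direction: str
    horizons: dict[float, dict[int, float]]

    def __post_init__(self) -> None:
        if self.direction not in ("higher_better", "higher_worse"):
            raise ValueError(f"unknown direction {self.direction!r}")
        for h, table in self.horizons.items():
            scores = sorted(table)
            probs = [table[s] for s in scores]
            if any(not (0.0 <= p <= 1.0) for p in probs):
                raise ValueError(f"score map at horizon {h}: probability outside [0,1]")
            diffs = np.diff(probs)
            ok = (diffs >= 0).all() if self.direction == "higher_better" else (diffs <= 0).all()
            if not ok:
                raise ValueError(
                    f"score map at horizon {h} is not monotone ({self.direction})"
                )

    def lookup(self, horizon: float, scores: np.ndarray) -> np.ndarray:
        if horizon not in self.horizons:
            raise KeyError(f"score map has no horizon {horizon}")
        table = self.horizons[horizon]
        out = np.empty(len(scores), dtype=float)
        for i, s in enumerate(scores):
            if np.isnan(s):
                out[i] = np.nan
                continue
            key = int(s)
            if key not in table:
                raise KeyError(f"unmapped score {key}")
            out[i] = table[key]
        return out


@dataclass
class PredictionSet:
    """Per-model survival predictions over patients and horizons.

    ``values`` is a DataFrame indexed by patient_id with one column per
    horizon (months, strictly increasing); NaN marks an unavailable cell
    (e.g. a model that only predicts at 3 and 12 months).
    """

    model_name: str
    mode: str
    values: pd.DataFrame
    score_map: ScoreMap | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("probability", "score"):
            raise ValueError(f"unknown mode {self.mode!r}")
        horizons = list(self.values.columns)
        if any(h2 <= h1 for h1, h2 in zip(horizons, horizons[1:])):
            raise ValueError("horizons must be strictly increasing")
        if self.mode == "probability":
            vals = self.values.to_numpy(dtype=float)
            bad = (vals < 0) | (vals > 1)
            if np.any(bad & ~np.isnan(vals)):
                i, j = np.argwhere(bad & ~np.isnan(vals))[0]
                raise ValueError(
                    f"model {self.model_name}: probability {vals[i, j]} outside [0,1] "
                    f"for patient {self.values.index[i]!r} at horizon {horizons[j]}"
                )

    @property
    def horizons(self) -> list[float]:
        return list(self.values.columns)

    def at_horizon(self, horizon: float) -> pd.Series:
        """Values at one horizon, dropping unavailable cells."""
        if horizon not in self.values.columns:
            raise KeyError(f"model {self.model_name} has no horizon {horizon}")
        return self.values[horizon].dropna()

    @property
    def supports_probability_metrics(self) -> bool:
        """Brier, calibration, DCA and MC need probabilities (or a score map)."""
        return self.mode == "probability" or self.score_map is not None


# ---------------------------------------------------------------------------
# Horizon status
# ---------------------------------------------------------------------------

def ascertain_status(
    survival_months: float,
    death_observed: bool,
    horizon: float,
    admin_censor: float = 24.0,
) -> HorizonStatus:
    """Survival status of one patient at a month horizon.

    A death at or before the horizon is DEAD; follow-up reaching the horizon
    alive (including censoring exactly at the horizon) is ALIVE; censoring
    alive strictly before the horizon is UNKNOWN.
    """
    if survival_months < 0:
        raise ValueError("survival_months must be >= 0")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if horizon > admin_censor:
        raise ValueError(f"horizon {horizon} exceeds administrative censoring {admin_censor}")
    if death_observed and survival_months <= horizon:
        return HorizonStatus.DEAD
    if survival_months >= horizon:
        return HorizonStatus.ALIVE
    return HorizonStatus.UNKNOWN


def ascertain_statuses(
    cohort: CohortTable, horizon: float, admin_censor: float = 24.0
) -> pd.Series:
    """Vectorised :func:`ascertain_status` over a cohort.

    Returns a Series of :class:`HorizonStatus` indexed by patient_id.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if horizon > admin_censor:
        raise ValueError(f"horizon {horizon} exceeds administrative censoring {admin_censor}")
    t = cohort.df["survival_months"].to_numpy(dtype=float)
    dead = cohort.df["death_observed"].to_numpy(dtype=bool)
    out = np.where(
        dead & (t <= horizon),
        HorizonStatus.DEAD,
        np.where(t >= horizon, HorizonStatus.ALIVE, HorizonStatus.UNKNOWN),
    )
    return pd.Series(out, index=cohort.df["patient_id"].to_numpy(), name=f"status_{horizon}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_cohort(path, provenance: str = "real") -> CohortTable:
    """Read a cohort CSV (header :data:`COHORT_COLUMNS`; booleans 0/1).

    Blank lab cells become missing values. Unknown columns warn and are
    dropped; malformed numerics and duplicate patient ids fail with the
    offending row.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown cohort columns: {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")

    numeric = ["age", "bmi", "ecog", "asa", "survival_months", *LAB_COLUMNS]
    for col in numeric + BOOL_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"malformed numeric in column {col!r} at row {row + 2}: {df[col].iloc[row]!r}"
            )
        if col in BOOL_COLUMNS:
            if coerced.isna().any():
                row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
                raise ValueError(f"missing boolean in column {col!r} at row {row + 2}")
            df[col] = coerced.astype(int).astype(bool)
        else:
            df[col] = coerced
    for col in ("ecog", "asa"):
        df[col] = df[col].astype(int)
    for col, levels in CATEGORICAL_LEVELS.items():
        bad = ~df[col].isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unknown level {df[col].iloc[row]!r} in column {col!r} at row {row + 2}"
            )
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate patient_id {dup.iloc[0]!r}")
    if len(df) == 0:
        raise ValueError("cohort file has no rows")
    return CohortTable(df[COHORT_COLUMNS], provenance=provenance)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort CSV; booleans as 0/1, missing labs as blank cells."""
    df = cohort.df[COHORT_COLUMNS].copy()
    for col in BOOL_COLUMNS:
        df[col] = df[col].astype(int)
    df.to_csv(path, index=False)


def read_predictions(
    path, score_maps: Mapping[str, ScoreMap] | None = None
) -> list[PredictionSet]:
    """Read a long-format predictions CSV into one PredictionSet per model.

    Expected header: ``patient_id,model,horizon_months,value,mode``. Mode is
    constant within a model. A score-mode model without a score map is
    allowed; its probability-scale metrics are simply flagged unavailable
    downstream.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "model": str, "mode": str})
    required = ["patient_id", "model", "horizon_months", "value", "mode"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"predictions file missing columns: {missing}")
    score_maps = score_maps or {}
    out: list[PredictionSet] = []
    for model, grp in df.groupby("model", sort=True):
        modes = grp["mode"].unique()
        if len(modes) != 1:
            raise ValueError(f"model {model!r} mixes modes {sorted(modes)}")
        mode = modes[0]
        if mode == "probability":
            bad = (grp["value"] < 0) | (grp["value"] > 1)
            if bad.any():
                row = grp[bad].iloc[0]
                raise ValueError(
                    f"model {model!r}: probability {row['value']} outside [0,1] for "
                    f"patient {row['patient_id']!r} at horizon {row['horizon_months']}"
                )
        wide = grp.pivot_table(
            index="patient_id", columns="horizon_months", values="value", aggfunc="first"
        )
        wide.columns = wide.columns.astype(float)
        wide.columns.name = None
        wide = wide.sort_index(axis=1)
        out.append(
            PredictionSet(
                model_name=model,
                mode=mode,
                values=wide,
                score_map=score_maps.get(model),
            )
        )
    return out


def write_predictions(preds: Sequence[PredictionSet], path) -> None:
    """Write prediction sets as a long-format CSV (inverse of read_predictions)."""
    rows = []
    for p in preds:
        long = p.values.stack().reset_index()
        long.columns = ["patient_id", "horizon_months", "value"]
        long.insert(1, "model", p.model_name)
        long["mode"] = p.mode
        rows.append(long)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_score_map(path) -> ScoreMap:
    """Read a score map JSON: ``{model, direction, horizons: {"12": {"0": 0.9}}}``."""
    with open(path) as fh:
        raw = json.load(fh)
    horizons = {
        float(h): {int(s): float(p) for s, p in table.items()}
        for h, table in raw["horizons"].items()
    }
    return ScoreMap(model=raw["model"], direction=raw["direction"], horizons=horizons)


def apply_score_map(pred: PredictionSet, score_map: ScoreMap) -> PredictionSet:
    """Convert a score-mode PredictionSet to probability mode via a ScoreMap.

    The map must cover every observed score at every available horizon;
    an unmapped score raises with the score value.
    """
    if pred.mode != "score":
        raise ValueError("apply_score_map expects a score-mode prediction set")
    cols = {}
    for h in pred.horizons:
        col = pred.values[h]
        mapped = score_map.lookup(h, col.to_numpy(dtype=float))
        cols[h] = pd.Series(mapped, index=col.index)
    values = pd.DataFrame(cols)
    return PredictionSet(model_name=pred.model_name, mode="probability", values=values)
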