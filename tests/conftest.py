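import numpy as np
import pandas as pd
import pytest

from pssval.data_model import COHORT_COLUMNS, CohortTable, HorizonStatus


def make_cohort_df(rows: list[dict]) -> pd.DataFrame:
    """Build a cohort DataFrame from sparse row dicts with sane defaults."""
    defaults = dict(
        age=60.0, sex="female", bmi=23.0, charlson=True, prior_systemic=False,
        prior_radiation=False, visceral_mets=False, brain_mets=False,
        lymph_node_mets=False, n_bone_mets="single", fracture_status="complete",
        ecog=1, asa=2, primary_tumor="lung", na=137.0, ca=9.3, alb=3.7,
        alp=110.0, bun=16.0, hgb=11.5, alc=1.3, anc=4.5, wbc=6.8, plt=230.0,
        survival_months=12.0, death_observed=False,
    )
    full = []
    for i, row in enumerate(rows):
        rec = {"patient_id": f"P{i}", **defaults, **row}
        full.append(rec)
    return pd.DataFrame(full)[COHORT_COLUMNS]


def statuses_from_string(spec: str) -> pd.Series:
    """'ada u' etc: a=ALIVE, d=DEAD, u=UNKNOWN, one patient per character."""
    lookup = {"a": HorizonStatus.ALIVE, "d": HorizonStatus.DEAD, "u": HorizonStatus.UNKNOWN}
    return pd.Series(
        [lookup[c] for c in spec], index=[f"P{i}" for i in range(len(spec))]
    )


def statuses_from_counts(n_dead: int, n_alive: int, n_unknown: int = 0) -> pd.Series:
    return statuses_from_string("d" * n_dead + "a" * n_alive + "u" * n_unknown)


def reference_count_cohort() -> CohortTable:
    """A cohort whose per-horizon death/ascertainment counts equal the
    emulated study's printed ones: deaths 17/63/108/167/191/204 among
    356/350/342/326/314/302 ascertained at 1/3/6/12/18/24 months."""
    horizons = [1.0, 3.0, 6.0, 12.0, 18.0, 24.0]
    death_increments = [17, 46, 45, 59, 24, 13]
    unknown_increments = [0, 6, 8, 16, 12, 12]
    rows = []
    prev = 0.0
    for h, d_inc, u_inc in zip(horizons, death_increments, unknown_increments):
        mid = (prev + h) / 2
        rows += [{"survival_months": mid, "death_observed": True}] * d_inc
        rows += [{"survival_months": mid, "death_observed": False}] * u_inc
        prev = h
    n_alive = 356 - sum(death_increments) - sum(unknown_increments)
    rows += [{"survival_months": 24.0, "death_observed": False}] * n_alive
    return CohortTable(make_cohort_df(rows))


@pytest.fixture
def small_cohort() -> CohortTable:
    return CohortTable(
        make_cohort_df(
            [
                {"survival_months": 2.0, "death_observed": True},
                {"survival_months": 5.0, "death_observed": False},
                {"survival_months": 24.0, "death_observed": False},
            ]
        )
    )


@pytest.fixture(scope="session")
def default_study():
    """One seeded default-config study shared by read-only tests."""
    import pssval as pv

    return pv.generate_cohort(
        pv.SimulationConfig(),
        [
            pv.PredictionSimSpec("good", target_auc=0.84, calibration_shift=0.45),
            pv.PredictionSimSpec("identity"),
        ],
        seed=20,
    )
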