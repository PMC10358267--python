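"""Iterative random-forest imputation of missing laboratory values.

Implements the missForest scheme: initialise gaps with column means, then
repeatedly visit variables in ascending order of missingness, fit a random
forest to the observed rows of each variable against all other (currently
completed) predictors, and re-predict the missing cells. Iteration stops the
first time the normalised squared difference between successive imputations
increases, returning the previous iteration's values, or at ``max_iter``.

Only the ten lab columns are imputation targets (they are the only variables
with missingness in the emulated study); every covariate enters as a
predictor, with categoricals one-hot encoded. Out-of-bag error per variable
comes from the forests' OOB predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .data_model import LAB_COLUMNS, CohortTable

__all__ = [
    "ImputationResult",
    "initialize_fill",
    "impute_missforest",
    "complete_case_subset",
]

_PREDICTOR_COVARIATES = [
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
]


@dataclass
class ImputationResult:
    cohort: CohortTable
    iterations_run: int
    oob_error: dict[str, float] = field(default_factory=dict)
    convergence_trace: list[float] = field(default_factory=list)


def initialize_fill(cohort: CohortTable) -> CohortTable:
    """Fill missing lab cells with the column mean (labs are continuous).

    A lab column with no observed values at all cannot be initialised and is
    rejected by name.
    """
    df = cohort.df.copy()
    for lab in LAB_COLUMNS:
        col = df[lab]
        if col.isna().all():
            raise ValueError(f"column {lab} has no observed values")
        if col.isna().any():
            df[lab] = col.fillna(col.mean())
    return CohortTable(df, provenance=cohort.provenance)


def _design_matrix(df: pd.DataFrame, exclude: str) -> np.ndarray:
    cols = [c for c in _PREDICTOR_COVARIATES + LAB_COLUMNS if c != exclude]
    X = pd.get_dummies(df[cols], columns=[c for c in cols if df[c].dtype == object])
    return X.to_numpy(dtype=float)


def impute_missforest(
    cohort: CohortTable,
    learner_params: dict | None = None,
    max_iter: int = 10,
    seed: int = 0,
) -> ImputationResult:
    """missForest imputation of the lab columns.

    Parameters
    ----------
    learner_params : forwarded to ``RandomForestRegressor`` (default 100
        trees); ``random_state`` is derived from ``seed``.
    max_iter : hard cap on sweeps; the difference-statistic stopping rule
        usually ends earlier.

    The convergence trace records, per sweep, the normalised squared
    difference ``sum((new - old)^2) / sum(new^2)`` over all imputed
    continuous cells. Originally observed values are never modified.
    """
    params = {"n_estimators": 100}
    params.update(learner_params or {})
    masks = {
        lab: cohort.df[lab].isna().to_numpy() for lab in LAB_COLUMNS
    }
    targets = [lab for lab in LAB_COLUMNS if masks[lab].any()]
    if not targets:
        return ImputationResult(cohort=cohort, iterations_run=1, convergence_trace=[0.0])
    # ascending missingness; ties broken by column position (list order)
    targets.sort(key=lambda lab: (masks[lab].sum(), LAB_COLUMNS.index(lab)))

    current = initialize_fill(cohort).df
    rng = np.random.default_rng(seed)
    trace: list[float] = []
    oob: dict[str, float] = {}
    best = current
    prev_stat = np.inf
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        new = current.copy()
        for lab in targets:
            miss = masks[lab]
            X = _design_matrix(new, exclude=lab)
            y = new[lab].to_numpy(dtype=float)
            forest = RandomForestRegressor(
                **params,
                oob_score=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            try:
                forest.fit(X[~miss], y[~miss])
            except Exception as exc:  # pragma: no cover - learner failure path
                raise RuntimeError(
                    f"learner failed on variable {lab} at iteration {it}: {exc}"
                ) from exc
            new.loc[miss, lab] = forest.predict(X[miss])
            oob[lab] = 1.0 - float(forest.oob_score_)
        num = 0.0
        den = 0.0
        for lab in targets:
            d = new.loc[masks[lab], lab].to_numpy() - current.loc[masks[lab], lab].to_numpy()
            num += float(np.sum(d**2))
            den += float(np.sum(new.loc[masks[lab], lab].to_numpy() ** 2))
        stat = num / den if den > 0 else 0.0
        trace.append(stat)
        if stat >= prev_stat:
            break  # diverged: keep the previous sweep's values
        best = new
        prev_stat = stat
        current = new
    result = CohortTable(best, provenance="imputed")
    for lab in LAB_COLUMNS:  # observed cells must be untouched
        obs = ~masks[lab]
        assert np.array_equal(
            result.df.loc[obs, lab].to_numpy(), cohort.df.loc[obs, lab].to_numpy()
        )
    return ImputationResult(
        cohort=result, iterations_run=iterations, oob_error=oob, convergence_trace=trace
    )


def complete_case_subset(cohort: CohortTable) -> CohortTable:
    """Rows with all ten labs observed, order preserved (sensitivity set)."""
    mask = cohort.df[LAB_COLUMNS].notna().all(axis=1)
    if not mask.any():
        import warnings

        warnings.warn("complete-case subset is empty", stacklevel=2)
    return CohortTable(cohort.df[mask].copy(), provenance=cohort.provenance)
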