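"""Two-step covariate adjustment producing the residuals all analyses consume.

Multi-cohort morphometry pools cohorts with very different age windows, so a
single mean model must absorb cohort offsets and non-linear age trends
simultaneously.  Stage 1 is an ordinary least squares fit of each measure on
cohort indicator contrasts plus a cubic age polynomial (age is divided by 100
before expansion to condition the design).  Stage 2 regresses the stage-1
residuals on the remaining categorical acquisition covariates (field
strength, segmentation-software version) with a random forest, which can
absorb interactions and non-linearities among those labels, and subtracts the
forest's prediction.  Both stages are fit on all subjects pooled — sex is
deliberately never a covariate, so sex-linked mean and variance structure
survives into the residuals.

Note that when each cohort uses a single scanner and software version (the
typical consortium design), those labels are nested in cohort and already
removed in stage 1; stage 2 then predicts approximately zero and is a no-op.
This is expected and surfaced in the out-of-bag summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.linalg import qr
from sklearn.ensemble import RandomForestRegressor

from .core_io import AdjustedTable, SubjectTable, GLOBAL_COV_COLUMN

__all__ = ["AdjustmentRecipe", "adjust_stage1", "adjust_stage2", "adjust"]

AGE_DIVISOR = 100.0


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable design matrix."""


@dataclass
class AdjustmentRecipe:
    """What the mean model removes, and how.

    Parameters
    ----------
    include_age : include a polynomial age trend (degree ``age_polynomial_degree``,
        default cubic) in the stage-1 linear model.
    include_cohort : include cohort indicator contrasts in stage 1.
    rf_covariates : categorical columns handled by the stage-2 random forest.
    global_covariate : optional extra linear stage-1 term (e.g. total brain
        volume), by column name.
    n_trees, min_leaf, rf_seed : random-forest hyperparameters.  The large
        default leaf size keeps the forest from absorbing sex-related variance
        through scanner-label overfitting.
    """

    include_age: bool = True
    age_polynomial_degree: int = 3
    include_cohort: bool = True
    rf_covariates: tuple[str, ...] = ("field_strength", "software_version")
    global_covariate: str | None = None
    n_trees: int = 500
    min_leaf: int = 50
    rf_seed: int = 0

    def __post_init__(self) -> None:
        if self.age_polynomial_degree < 1:
            raise ValueError("age_polynomial_degree must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rf_covariates"] = list(self.rf_covariates)
        return d


def _stage1_design(
    table: SubjectTable, recipe: AdjustmentRecipe
) -> tuple[np.ndarray, list[str]]:
    data = table.data
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["intercept"]
    if recipe.include_cohort:
        levels = sorted(data["cohort"].unique())
        for lev in levels[1:]:  # first level is the reference
            cols.append((data["cohort"] == lev).to_numpy(float))
            names.append(f"cohort[{lev}]")
    if recipe.include_age:
        a = data["age"].to_numpy(float) / AGE_DIVISOR
        for k in range(1, recipe.age_polynomial_degree + 1):
            cols.append(a**k)
            names.append(f"age^{k}")
    if recipe.global_covariate:
        gcol = recipe.global_covariate
        if gcol not in data.columns:
            raise DesignError(f"global covariate column {gcol!r} not present")
        cols.append(data[gcol].to_numpy(float))
        names.append(gcol)
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise DesignError(f"rank-deficient design; collinear columns: {bad}")


def adjust_stage1(
    table: SubjectTable, measure: str, recipe: AdjustmentRecipe
) -> tuple[pd.Series, dict]:
    """OLS residuals of one measure on cohort contrasts and the age polynomial.

    Returns the residual series (NaN where the measure is missing) and a fit
    summary dict (coefficients by design-column name, n used, R^2).  The fit
    uses the rows non-missing for this measure only (pairwise-complete).
    """
    X_full, names = _stage1_design(table, recipe)
    y_full = table.data[measure].to_numpy(float)
    mask = np.isfinite(y_full)
    if recipe.global_covariate:
        mask &= np.isfinite(table.data[recipe.global_covariate].to_numpy(float))
    X, y = X_full[mask], y_full[mask]
    if len(y) <= X.shape[1]:
        raise DesignError(
            f"measure {measure!r}: {len(y)} non-missing rows for {X.shape[1]} parameters"
        )
    _check_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = np.full_like(y_full, np.nan)
    resid[mask] = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum(resid[mask] ** 2))
    info = {
        "coef": dict(zip(names, beta.tolist())),
        "n": int(mask.sum()),
        "r2": (1.0 - rss / tss) if tss > 0 else 0.0,
    }
    return pd.Series(resid, index=table.data.index, name=measure), info


def adjust_stage2(
    table: SubjectTable, residuals: pd.Series, recipe: AdjustmentRecipe
) -> tuple[pd.Series, dict]:
    """Random-forest removal of categorical acquisition effects from residuals.

    One-hot encodes the recipe's rf_covariates (single-level covariates are
    dropped with a warning), fits a seeded RandomForestRegressor to the
    stage-1 residuals, and returns residual minus prediction together with an
    out-of-bag fit summary.
    """
    data = table.data
    usable = []
    for cov in recipe.rf_covariates:
        if data[cov].nunique() <= 1:
            warnings.warn(f"covariate {cov!r} has a single level; dropped from stage 2")
        else:
            usable.append(cov)
    y = residuals.to_numpy(float)
    mask = np.isfinite(y)
    if not usable:
        info = {"covariates": [], "oob_r2": None, "note": "no multi-level covariates; no-op"}
        return residuals.copy(), info
    X = pd.get_dummies(data[usable], dtype=float).to_numpy()
    rf = RandomForestRegressor(
        n_estimators=recipe.n_trees,
        min_samples_leaf=recipe.min_leaf,
        random_state=recipe.rf_seed,
        oob_score=True,
        bootstrap=True,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # small samples can leave some points never out-of-bag
        warnings.simplefilter("ignore")
        rf.fit(X[mask], y[mask])
        oob = float(rf.oob_score_) if hasattr(rf, "oob_score_") else None
    pred = np.full_like(y, np.nan)
    pred[mask] = rf.predict(X[mask])
    out = residuals.copy()
    out[mask] = y[mask] - pred[mask]
    info = {"covariates": usable, "oob_r2": oob, "rf_seed": recipe.rf_seed}
    return out, info


def adjust(
    table: SubjectTable,
    measures: list[str] | None = None,
    recipe: AdjustmentRecipe | None = None,
) -> AdjustedTable:
    """Full two-step adjustment over the requested measures.

    Returns an :class:`AdjustedTable` aligned row-for-row with ``table``; the
    recipe and per-measure fit summaries are recorded in ``meta``.
    """
    recipe = recipe or AdjustmentRecipe()
    if measures is None:
        measures = table.measures
    covariate_cols = [c for c in table.data.columns if c not in set(table.catalog.measure_ids())]
    out = table.data[covariate_cols].copy()
    fits: dict[str, dict] = {}
    for m in measures:
        resid, info1 = adjust_stage1(table, m, recipe)
        resid, info2 = adjust_stage2(table, resid, recipe)
        out[m] = resid
        fits[m] = {"stage1": info1, "stage2": info2}
    meta = dict(table.meta)
    meta["recipe"] = recipe.to_dict()
    meta["fits"] = fits
    return AdjustedTable(out, table.catalog, meta)
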