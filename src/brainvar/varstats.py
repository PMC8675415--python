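"""Mean- and variance-difference tests between the sexes.

Mean differences use pooled two-sample t-tests with Cohen's d (positive d =
male mean larger; negative = female larger).  Variance differences use the
variance ratio T = Var_males / Var_females of the adjusted residuals, log
transformed to symmetrize it around zero, with significance from a
permutation test that randomly reassigns sex labels among the residuals:

    p = (1/B) * sum_b I(T_b > T)            (one-sided, male > female)
    p = (1/B) * sum_b I(|ln T_b| >= |ln T|) (two-sided, the default)

B defaults to 10,000.  p-values are corrected with the Benjamini-Hochberg
step-up FDR procedure within each measure class.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cohens_d",
    "variance_ratio",
    "permutation_test_vr",
    "fdr_bh",
    "correlate_vr_with_d",
    "analyze_measures",
]

_PERM_CHUNK = 2000  # permutations held in memory at once


def _split_by_sex(values, sex) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    keep = np.isfinite(values)
    values, sex = values[keep], sex[keep]
    male = values[sex == "M"]
    female = values[sex == "F"]
    return male, female


def cohens_d(values, sex) -> dict:
    """Pooled-SD Cohen's d and Student two-sample t-test for one measure.

    Returns a dict with n_male, n_female, mean_m, mean_f, d, t, p.  The sign
    convention is d > 0 when the male mean is larger.
    """
    male, female = _split_by_sex(values, sex)
    if len(male) < 2 or len(female) < 2:
        raise ValueError("need at least 2 observations per sex")
    n_m, n_f = len(male), len(female)
    pooled_var = (
        (n_m - 1) * male.var(ddof=1) + (n_f - 1) * female.var(ddof=1)
    ) / (n_m + n_f - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD; Cohen's d undefined")
    d = (male.mean() - female.mean()) / np.sqrt(pooled_var)
    t, p = stats.ttest_ind(male, female, equal_var=True)
    return {
        "n_male": n_m,
        "n_female": n_f,
        "mean_m": float(male.mean()),
        "mean_f": float(female.mean()),
        "d": float(d),
        "t": float(t),
        "p_mean": float(p),
    }


def variance_ratio(values, sex) -> tuple[float, float]:
    """Variance ratio T = Var_males/Var_females and its log (n-1 variances)."""
    male, female = _split_by_sex(values, sex)
    if len(male) < 2 or len(female) < 2:
        raise ValueError("need at least 2 observations per sex")
    var_f = female.var(ddof=1)
    if var_f == 0:
        raise ValueError("female variance is zero; variance ratio undefined")
    T = male.var(ddof=1) / var_f
    return float(T), float(np.log(T))


def _log_t_for_masks(values: np.ndarray, male_masks: np.ndarray) -> np.ndarray:
    """log variance ratio for each boolean male-assignment row of male_masks."""
    n = values.shape[0]
    n_m = int(male_masks[0].sum())
    n_f = n - n_m
    s = values.sum()
    ss = (values**2).sum()
    sm = male_masks @ values
    ssm = male_masks @ (values**2)
    var_m = (ssm - sm**2 / n_m) / (n_m - 1)
    var_f = ((ss - ssm) - (s - sm) ** 2 / n_f) / (n_f - 1)
    return np.log(var_m) - np.log(var_f)


def permutation_test_vr(
    values,
    sex,
    B: int = 10_000,
    seed: int | None = None,
    sided: str = "two",
    exact: bool = False,
    smoothed: bool = False,
) -> dict:
    """Permutation test of equal male/female variances for one measure.

    For each of B random reassignments of the sex labels among the residuals,
    the variance ratio T_b is recomputed.  One-sided p is the proportion with
    T_b strictly greater than the observed T; two-sided (default) uses
    |ln T_b| >= |ln T|.  With ``exact=True`` all C(n, n_males) label
    assignments are enumerated instead of sampled (small n only).  With
    ``smoothed=True`` the add-one estimate (sum I + 1)/(B + 1) is returned to
    avoid p = 0.

    Returns dict with T, log_vr, p_perm, B (actual count), sided, seed.
    """
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    if not exact:
        if B <= 0:
            raise ValueError("B must be positive")
        if B < 100:
            warnings.warn(f"B={B} permutations is too small for stable p-values")

    male, female = _split_by_sex(values, sex)
    pooled = np.concatenate([male, female])
    n, n_m = len(pooled), len(male)
    if n_m < 2 or n - n_m < 2:
        raise ValueError("need at least 2 observations per sex")
    T_obs, log_T_obs = variance_ratio(values, sex)

    rng = np.random.default_rng(seed)
    count = 0
    total = 0
    if exact:
        n_assign = comb(n, n_m)
        if n_assign > 500_000:
            raise ValueError(f"exact enumeration infeasible: C({n},{n_m}) = {n_assign}")
        masks = np.zeros((n_assign, n), dtype=float)
        for row, idx in enumerate(combinations(range(n), n_m)):
            masks[row, list(idx)] = 1.0
        log_T = _log_t_for_masks(pooled, masks)
        count = _exceedances(log_T, log_T_obs, sided)
        total = n_assign
    else:
        remaining = B
        while remaining > 0:
            chunk = min(remaining, _PERM_CHUNK)
            order = np.argsort(rng.random((chunk, n)), axis=1)
            masks = np.zeros((chunk, n), dtype=float)
            np.put_along_axis(masks, order[:, :n_m], 1.0, axis=1)
            log_T = _log_t_for_masks(pooled, masks)
            count += _exceedances(log_T, log_T_obs, sided)
            total += chunk
            remaining -= chunk

    if smoothed:
        p = (count + 1) / (total + 1)
    else:
        p = count / total
    return {
        "var_m": float(male.var(ddof=1)),
        "var_f": float(female.var(ddof=1)),
        "T": T_obs,
        "log_vr": log_T_obs,
        "p_perm": float(p),
        "B": int(total),
        "sided": sided,
        "seed": seed,
        "exact": exact,
    }


def _exceedances(log_T: np.ndarray, log_T_obs: float, sided: str) -> int:
    # tolerance guards ties (e.g. the identity assignment under exact
    # enumeration) against floating-point jitter between variance formulas
    tol = 1e-9 * max(1.0, abs(log_T_obs))
    if sided == "one":
        return int(np.sum(log_T > log_T_obs + tol))  # strict, as defined
    return int(np.sum(np.abs(log_T) >= np.abs(log_T_obs) - tol))


def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and rejection flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or ~np.isfinite(p).all()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def correlate_vr_with_d(log_vr, d) -> dict:
    """Pearson correlation between per-measure log VR and Cohen's d vectors."""
    log_vr = np.asarray(log_vr, dtype=float)
    d = np.asarray(d, dtype=float)
    if log_vr.shape != d.shape:
        raise ValueError("log VR and d vectors must have matching length")
    if log_vr.size < 3:
        raise ValueError("need at least 3 measures")
    r, p = stats.pearsonr(log_vr, d)
    return {"r": float(r), "df": int(log_vr.size - 2), "p": float(p)}


def analyze_measures(
    adjusted,
    measures: list[str],
    B: int = 10_000,
    seed: int | None = None,
    sided: str = "two",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean and variance tests for a set of measures, FDR within the set.

    ``adjusted`` is an AdjustedTable (or SubjectTable of residuals).  Returns
    one row per measure with the documented result schema: measure_id,
    n_male, n_female, d, t, p_mean, q_mean, var_m, var_f, T, log_vr, p_perm,
    q_perm.  Each measure gets an independent substream of the seed.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(measures))
    sex = adjusted.data["sex"].to_numpy()
    rows = []
    for m, child in zip(measures, children):
        values = adjusted.data[m].to_numpy(float)
        mean_res = cohens_d(values, sex)
        child_seed = int(child.generate_state(1)[0] % (2**31))
        var_res = permutation_test_vr(values, sex, B=B, seed=child_seed, sided=sided)
        rows.append({"measure_id": m, **mean_res, **var_res})
    out = pd.DataFrame(rows)
    out["q_mean"], _ = fdr_bh(out["p_mean"].to_numpy(), alpha)
    out["q_perm"], out["sig_var"] = fdr_bh(out["p_perm"].to_numpy(), alpha)
    cols = [
        "measure_id", "n_male", "n_female", "mean_m", "mean_f", "d", "t",
        "p_mean", "q_mean", "var_m", "var_f", "T", "log_vr", "p_perm",
        "q_perm", "sig_var", "B", "sided",
    ]
    return out[cols]
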