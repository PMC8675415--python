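"""Does the sex difference in dispersion change across age?

The absolute adjusted residual |r_i| is a subject-level dispersion proxy
(for N(0, sigma^2) residuals, E|r| = sigma * sqrt(2/pi)), so regressing |r|
on age, sex, and their product models how the spread of each measure differs
by sex and how that gap moves across the lifespan:

    model 1 (linear):     |r| ~ 1 + age   + sex + age*sex
    model 2 (quadratic):  |r| ~ 1 + age^2 + sex + age^2*sex

Sex is coded male = 1, female = 0, so a positive sex coefficient means
greater male dispersion and a negative sex-by-age coefficient means the male
excess dispersion shrinks with age.  Age is z-scored over the analyzed
subjects by default (raw years optional).  The interaction p-values are FDR
corrected across the measures of a class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .varstats import fdr_bh

__all__ = ["absolute_residuals", "fit_interaction", "analyze_measures"]

_TERMS = ("intercept", "age_term", "sex", "sex_by_age")


def absolute_residuals(adjusted, measure: str) -> pd.Series:
    """Elementwise |r_i| for one measure, aligned with the table rows."""
    return adjusted.data[measure].abs()


def fit_interaction(
    abs_resid,
    age,
    sex,
    order: int = 1,
    age_scale: str = "zscore",
) -> dict:
    """OLS of |r| on {age term, sex, sex x age term} with intercept.

    ``order`` selects the age term: age itself (1) or age squared (2, used in
    both the main and the interaction term, exactly as the quadratic model is
    written).  ``sex`` may be 'M'/'F' labels or a 0/1 vector (1 = male).
    Returns coefficient/SE/p dicts keyed by term name.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 (linear) or 2 (quadratic)")
    y = np.asarray(abs_resid, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if sex.dtype.kind in "UO":
        sex_num = (sex == "M").astype(float)
    else:
        sex_num = sex.astype(float)
    keep = np.isfinite(y)
    y, age, sex_num = y[keep], age[keep], sex_num[keep]
    if len(y) < 10:
        raise ValueError("need at least 10 subjects")
    if len(np.unique(sex_num)) < 2:
        raise ValueError("both sexes required")
    if np.ptp(age) == 0:
        raise ValueError("age is constant; interaction model not identifiable")

    if age_scale == "zscore":
        a = (age - age.mean()) / age.std(ddof=0)
    elif age_scale == "raw":
        a = age
    else:
        raise ValueError("age_scale must be 'zscore' or 'raw'")
    age_term = a if order == 1 else a**2
    X = np.column_stack([np.ones_like(y), age_term, sex_num, age_term * sex_num])
    fit = sm.OLS(y, X).fit()
    out = {"n": int(len(y)), "order": order, "age_scale": age_scale}
    for j, term in enumerate(_TERMS):
        out[f"coef_{term}"] = float(fit.params[j])
        out[f"se_{term}"] = float(fit.bse[j])
        out[f"p_{term}"] = float(fit.pvalues[j])
    return out


def analyze_measures(
    adjusted,
    measures: list[str],
    orders=(1, 2),
    age_scale: str = "zscore",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dispersion-by-age models for a set of measures.

    One row per measure x order; the interaction term's FDR q is computed
    across measures separately within each order.
    """
    age = adjusted.data["age"].to_numpy(float)
    sex = adjusted.data["sex"].to_numpy()
    rows = []
    for order in orders:
        for m in measures:
            res = fit_interaction(
                absolute_residuals(adjusted, m), age, sex, order=order, age_scale=age_scale
            )
            rows.append({"measure_id": m, **res})
    out = pd.DataFrame(rows)
    out["q_sex_by_age"] = np.nan
    out["sig_interaction"] = False
    for order in orders:
        sel = out["order"] == order
        q, rej = fdr_bh(out.loc[sel, "p_sex_by_age"].to_numpy(), alpha)
        out.loc[sel, "q_sex_by_age"] = q
        out.loc[sel, "sig_interaction"] = rej
    return out
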