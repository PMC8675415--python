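"""Sex comparison of inter-regional anatomical correlation matrices.

Across-subject Pearson correlations between pairs of regional measures
("structural covariance") are computed separately for males and females
after sex-specific standardization (within each sex, every measure is
centered and scaled to unit variance, so sex differences in means and
variances cannot leak into the correlations).  The female matrix F_ij is
subtracted from the male matrix M_ij; per-edge significance of the
difference comes from the difference of Fisher z-transformed correlations
with a subject-level permutation null (sex labels shuffled across whole
rows, preserving each subject's cross-region profile).  The directional
counts of significant edges (male-stronger vs female-stronger) are compared
with a 1-df equal-proportions chi-square goodness-of-fit test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "standardize_by_sex",
    "correlation_difference",
    "permutation_edge_test",
    "chisq_directional",
    "compare_sexes",
    "HomogeneityResult",
]

_ATANH_CLIP = 1.0 - 1e-12


def standardize_by_sex(adjusted, measures: list[str] | None = None):
    """Within each sex, center and scale every measure to unit variance.

    Returns a copy of the table with standardized measure columns.  Raises if
    a measure has zero within-sex SD.
    """
    if measures is None:
        measures = adjusted.measures
    out = adjusted.data.copy()
    for sex in ("M", "F"):
        sel = out["sex"] == sex
        for m in measures:
            vals = out.loc[sel, m]
            sd = vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"measure {m!r} has zero within-sex SD for sex {sex}")
            out.loc[sel, m] = (vals - vals.mean()) / sd
    clone = type(adjusted)(out, adjusted.catalog, dict(adjusted.meta))
    return clone


def _corr(X: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix; pairwise-complete when NaNs are present."""
    if np.isfinite(X).all():
        with np.errstate(invalid="ignore"):
            return np.corrcoef(X, rowvar=False)
    return pd.DataFrame(X).corr(min_periods=3).to_numpy()


def _fisher_z(r: np.ndarray) -> np.ndarray:
    clipped = np.clip(r, -_ATANH_CLIP, _ATANH_CLIP)
    check = np.asarray(r)
    if check.ndim == 2 and check.shape[0] == check.shape[1]:
        check = check[~np.eye(check.shape[0], dtype=bool)]  # unit diagonal is expected
    if (np.abs(check) >= 1.0 - 1e-15).any():
        warnings.warn("correlation(s) at |r| = 1 clipped before Fisher z-transform")
    return np.arctanh(clipped)


@dataclass
class HomogeneityResult:
    """Sex-specific correlation matrices and their per-edge comparison."""

    regions: list[str]
    M: np.ndarray
    F: np.ndarray
    diff: np.ndarray  # M - F
    z_diff: np.ndarray  # atanh(M) - atanh(F)
    p: np.ndarray | None = None  # per-edge two-sided permutation p (matrix)
    sig: np.ndarray | None = None
    alpha: float | None = None
    n_male_stronger: int | None = None
    n_female_stronger: int | None = None
    chi2: float | None = None
    chi2_p: float | None = None
    B: int | None = None
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        n = len(self.regions)
        return n * (n - 1) // 2

    @property
    def n_significant(self) -> int | None:
        if self.n_male_stronger is None:
            return None
        return self.n_male_stronger + self.n_female_stronger

    def to_frame(self) -> pd.DataFrame:
        """Long-format edge list (upper triangle)."""
        rows = []
        n = len(self.regions)
        for i in range(n):
            for j in range(i + 1, n):
                row = {
                    "region_i": self.regions[i],
                    "region_j": self.regions[j],
                    "M": self.M[i, j],
                    "F": self.F[i, j],
                    "diff": self.diff[i, j],
                    "z": self.z_diff[i, j],
                }
                if self.p is not None:
                    row["p"] = self.p[i, j]
                    row["sig"] = bool(self.sig[i, j])
                    row["direction"] = (
                        ("male" if self.diff[i, j] > 0 else "female")
                        if self.sig[i, j]
                        else "ns"
                    )
                rows.append(row)
        return pd.DataFrame(rows)


def correlation_difference(standardized, measures: list[str]) -> HomogeneityResult:
    """M_ij, F_ij (pairwise-complete Pearson), their difference and z-difference."""
    if len(measures) < 2:
        raise ValueError("need at least 2 regions")
    data = standardized.data
    male = data.loc[data["sex"] == "M", measures].to_numpy(float)
    female = data.loc[data["sex"] == "F", measures].to_numpy(float)
    if len(male) < 3 or len(female) < 3:
        raise ValueError("need at least 3 subjects per sex")
    M = _corr(male)
    F = _corr(female)
    return HomogeneityResult(
        regions=list(measures),
        M=M,
        F=F,
        diff=M - F,
        z_diff=_fisher_z(M) - _fisher_z(F),
    )


def permutation_edge_test(
    standardized,
    measures: list[str],
    B: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> HomogeneityResult:
    """Two-sided subject-permutation test of M_ij - F_ij for every edge.

    For each of B permutations the sex labels are shuffled across subjects
    (whole rows), both correlation matrices recomputed, and the per-edge
    Fisher-z difference compared in absolute value with the observed one.
    Significant edges at ``alpha`` (raw p by default, BH-adjusted when
    ``fdr=True``) are counted by direction and summarized with the 1-df
    equal-proportions chi-square.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    obs = correlation_difference(standardized, measures)
    data = standardized.data
    X = data[measures].to_numpy(float)
    male = (data["sex"] == "M").to_numpy()
    n, n_m = len(male), int(male.sum())

    rng = np.random.default_rng(seed)
    abs_obs = np.abs(obs.z_diff)
    exceed = np.zeros_like(abs_obs)
    for _ in range(B):
        perm = rng.permutation(n)
        pm = np.zeros(n, dtype=bool)
        pm[perm[:n_m]] = True
        z_b = _fisher_z(_corr(X[pm])) - _fisher_z(_corr(X[~pm]))
        exceed += np.abs(z_b) >= abs_obs
    p = exceed / B
    np.fill_diagonal(p, 1.0)

    iu = np.triu_indices(len(measures), k=1)
    if fdr:
        from .varstats import fdr_bh

        _, rej = fdr_bh(p[iu], alpha)
        sig_edges = rej
    else:
        sig_edges = p[iu] < alpha
    sig = np.zeros_like(p, dtype=bool)
    sig[iu] = sig_edges
    sig |= sig.T

    d_edges = obs.diff[iu]
    n_male = int(np.sum(sig_edges & (d_edges > 0)))
    n_female = int(np.sum(sig_edges & (d_edges < 0)))
    chi2 = chisq_directional(n_male, n_female) if (n_male + n_female) else None

    obs.p = p
    obs.sig = sig
    obs.alpha = alpha
    obs.n_male_stronger = n_male
    obs.n_female_stronger = n_female
    obs.chi2 = chi2["chi2"] if chi2 else None
    obs.chi2_p = chi2["p"] if chi2 else None
    obs.B = B
    obs.seed = seed
    obs.metadata = {"fdr": fdr, "alpha": alpha, "B": B, "seed": seed}
    return obs


def chisq_directional(n_male_stronger: int, n_female_stronger: int) -> dict | None:
    """1-df goodness-of-fit of the two directional counts vs equal split.

    chi2 = sum (O - E)^2 / E with E = N/2 for both cells.  Returns None when
    both counts are zero (no significant edges: no test).
    """
    total = n_male_stronger + n_female_stronger
    if total == 0:
        return None
    expected = total / 2.0
    chi2 = (n_male_stronger - expected) ** 2 / expected + (
        n_female_stronger - expected
    ) ** 2 / expected
    return {
        "chi2": float(chi2),
        "df": 1,
        "N": int(total),
        "p": float(stats.chi2.sf(chi2, df=1)),
    }


def compare_sexes(
    adjusted,
    measures: list[str],
    B: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> HomogeneityResult:
    """Standardize by sex, then run the full edge-wise comparison."""
    std = standardize_by_sex(adjusted, measures)
    return permutation_edge_test(std, measures, B=B, seed=seed, alpha=alpha, fdr=fdr)
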