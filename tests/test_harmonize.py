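"""Two-step covariate adjustment: exactness, orthogonality, scanner removal."""

import numpy as np
import pandas as pd
import pytest

from brainvar.core_io import SubjectTable, default_catalog
from brainvar.harmonize import (
    AdjustmentRecipe,
    DesignError,
    adjust,
    adjust_stage1,
    adjust_stage2,
    _stage1_design,
)


def _table(n=600, seed=0, cohorts=("a", "b", "c"), scanner_by_cohort=None, noise_sd=1.0):
    rng = np.random.default_rng(seed)
    cohort = rng.choice(cohorts, size=n)
    age = rng.uniform(5, 85, size=n)
    offsets = {c: 10.0 * i for i, c in enumerate(cohorts)}
    a = age / 100.0
    y = (
        np.vectorize(offsets.get)(cohort)
        + 3.0 * a
        - 2.0 * a**2
        + 0.5 * a**3
        + rng.normal(0, noise_sd, n)
    )
    if scanner_by_cohort is None:
        scanner_by_cohort = {c: ("3T", "v6.0") for c in cohorts}
    fs = np.array([scanner_by_cohort[c][0] for c in cohort])
    sv = np.array([scanner_by_cohort[c][1] for c in cohort])
    data = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "cohort": cohort,
            "sex": rng.choice(["M", "F"], size=n),
            "age": age,
            "field_strength": fs,
            "software_version": sv,
            "lh_thalamus_vol": y,
        }
    )
    return SubjectTable(data, default_catalog())


FAST_RECIPE = AdjustmentRecipe(n_trees=50, min_leaf=30, rf_seed=1)


class TestStage1:
    def test_noise_free_data_fits_exactly(self):
        table = _table(noise_sd=0.0)
        resid, info = adjust_stage1(table, "lh_thalamus_vol", FAST_RECIPE)
        assert np.abs(resid).max() < 1e-8
        assert info["r2"] > 1.0 - 1e-12

    def test_residuals_orthogonal_to_design(self):
        table = _table(noise_sd=2.0)
        resid, _ = adjust_stage1(table, "lh_thalamus_vol", FAST_RECIPE)
        X, _names = _stage1_design(table, FAST_RECIPE)
        proj = X.T @ resid.to_numpy()
        scale = np.abs(table.data["lh_thalamus_vol"]).sum()
        assert np.abs(proj).max() < 1e-8 * scale

    def test_per_cohort_residual_means_vanish(self):
        table = _table(noise_sd=1.0)
        resid, _ = adjust_stage1(table, "lh_thalamus_vol", FAST_RECIPE)
        for _, grp in resid.groupby(table.data["cohort"]):
            assert abs(grp.mean()) < 1e-10

    def test_omitting_age_leaves_age_signal(self):
        table = _table(noise_sd=0.1)
        recipe = AdjustmentRecipe(include_age=False, n_trees=10, min_leaf=30)
        resid, _ = adjust_stage1(table, "lh_thalamus_vol", recipe)
        r = np.corrcoef(resid, table.data["age"])[0, 1]
        assert abs(r) > 0.5

    def test_rank_deficient_design_names_columns(self):
        table = _table()
        table.data["global_cov"] = 1.0  # collinear with the intercept
        recipe = AdjustmentRecipe(global_covariate="global_cov")
        with pytest.raises(DesignError, match="global_cov|intercept"):
            adjust_stage1(table, "lh_thalamus_vol", recipe)

    def test_missing_values_pairwise_masked(self):
        table = _table(noise_sd=1.0)
        table.data.loc[:10, "lh_thalamus_vol"] = np.nan
        resid, info = adjust_stage1(table, "lh_thalamus_vol", FAST_RECIPE)
        assert resid.isna().sum() == 11
        assert info["n"] == table.n_subjects - 11


class TestStage2:
    def test_no_scanner_effect_is_near_identity(self):
        table = _table(
            n=2000,
            scanner_by_cohort={"a": ("1.5T", "v5.3"), "b": ("3T", "v6.0"), "c": ("3T", "v5.3")},
        )
        s1, _ = adjust_stage1(table, "lh_thalamus_vol", FAST_RECIPE)
        s2, _ = adjust_stage2(table, s1, FAST_RECIPE)
        assert np.corrcoef(s1, s2)[0, 1] > 0.95

    def test_software_shift_removed(self):
        rng = np.random.default_rng(42)
        n = 2000
        sv = rng.choice(["v5.3", "v6.0"], size=n)
        y = rng.normal(0, 1, n) + np.where(sv == "v6.0", 10.0, 0.0)
        data = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "cohort": "a",
                "sex": rng.choice(["M", "F"], size=n),
                "age": rng.uniform(5, 85, n),
                "field_strength": "3T",
                "software_version": sv,
                "lh_thalamus_vol": y,
            }
        )
        table = SubjectTable(data, default_catalog())
        resid = data["lh_thalamus_vol"] - data["lh_thalamus_vol"].mean()
        out, info = adjust_stage2(table, resid, FAST_RECIPE)
        assert "software_version" in info["covariates"]
        assert abs(out[sv == "v6.0"].mean()) < 0.5

    def test_single_level_covariates_warn_and_noop(self):
        table = _table()
        s1, _ = adjust_stage1(table, "lh_thalamus_vol", FAST_RECIPE)
        with pytest.warns(UserWarning, match="single level"):
            out, info = adjust_stage2(table, s1, FAST_RECIPE)
        assert info["covariates"] == []
        assert out.equals(s1)

    def test_constant_residuals_stay_constant_zero(self):
        table = _table(
            scanner_by_cohort={"a": ("1.5T", "v5.3"), "b": ("3T", "v6.0"), "c": ("3T", "v6.0")}
        )
        zeros = pd.Series(np.zeros(table.n_subjects))
        out, _ = adjust_stage2(table, zeros, FAST_RECIPE)
        assert np.abs(out).max() < 1e-12


class TestFullAdjust:
    def test_empty_measure_list_gives_empty_table(self):
        table = _table()
        adj = adjust(table, [], FAST_RECIPE)
        assert adj.measures == []
        assert adj.n_subjects == table.n_subjects

    def test_recipe_recorded_and_deterministic(self):
        table = _table(
            scanner_by_cohort={"a": ("1.5T", "v5.3"), "b": ("3T", "v6.0"), "c": ("3T", "v5.3")}
        )
        a1 = adjust(table, ["lh_thalamus_vol"], FAST_RECIPE)
        a2 = adjust(table, ["lh_thalamus_vol"], FAST_RECIPE)
        assert a1.meta["recipe"]["n_trees"] == 50
        assert a1.data["lh_thalamus_vol"].equals(a2.data["lh_thalamus_vol"])

    def test_adjustment_reduces_design_r2(self):
        table = _table(noise_sd=1.0)
        adj = adjust(table, ["lh_thalamus_vol"], FAST_RECIPE)
        X, _ = _stage1_design(table, FAST_RECIPE)

        def r2(y):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            return 1 - resid.var() / y.var()

        raw = table.data["lh_thalamus_vol"].to_numpy()
        cleaned = adj.data["lh_thalamus_vol"].to_numpy()
        assert r2(cleaned) <= r2(raw) + 1e-12

    def test_global_covariate_enters_stage1(self):
        table = _table(noise_sd=0.5)
        rng = np.random.default_rng(7)
        gc = rng.normal(size=table.n_subjects)
        table.data["global_cov"] = gc
        table.data["lh_thalamus_vol"] += 5.0 * gc
        recipe = AdjustmentRecipe(global_covariate="global_cov", n_trees=10, min_leaf=30)
        resid, info = adjust_stage1(table, "lh_thalamus_vol", recipe)
        assert abs(info["coef"]["global_cov"] - 5.0) < 0.1
        assert abs(np.corrcoef(resid, gc)[0, 1]) < 1e-8
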