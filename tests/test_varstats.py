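"""Effect sizes, variance-ratio permutation inference, and FDR."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainvar import varstats as vs


class TestCohensD:
    def test_identical_groups_null(self):
        v = np.r_[np.arange(10.0), np.arange(10.0)]
        sex = np.array(["M"] * 10 + ["F"] * 10)
        res = vs.cohens_d(v, sex)
        assert res["d"] == 0.0
        assert res["p_mean"] == pytest.approx(1.0)

    def test_unit_shift_unit_sd(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 5000)
        base = (base - base.mean()) / base.std(ddof=1)
        v = np.r_[base + 1.0, base]
        sex = np.array(["M"] * 5000 + ["F"] * 5000)
        assert vs.cohens_d(v, sex)["d"] == pytest.approx(1.0)

    def test_recovers_simulated_shift(self):
        rng = np.random.default_rng(1)
        v = np.r_[rng.normal(0.5, 1, 10_000), rng.normal(0, 1, 10_000)]
        sex = np.array(["M"] * 10_000 + ["F"] * 10_000)
        assert abs(vs.cohens_d(v, sex)["d"] - 0.5) < 0.05

    def test_zero_pooled_sd_errors(self):
        v = np.array([1.0, 1.0, 2.0, 2.0])
        sex = np.array(["M", "M", "F", "F"])
        with pytest.raises(ValueError, match="pooled SD"):
            vs.cohens_d(v, sex)


class TestVarianceRatio:
    def test_scaling_law(self):
        f = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        v = np.r_[2.0 * f, f]
        sex = np.array(["M"] * 5 + ["F"] * 5)
        T, lvr = vs.variance_ratio(v, sex)
        assert T == pytest.approx(4.0)
        assert lvr == pytest.approx(np.log(4.0))

    def test_identical_groups(self):
        f = np.arange(6.0)
        v = np.r_[f, f]
        sex = np.array(["M"] * 6 + ["F"] * 6)
        assert vs.variance_ratio(v, sex) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_closed_form_large_sample(self):
        rng = np.random.default_rng(2)
        v = np.r_[rng.normal(0, 1.2, 100_000), rng.normal(0, 1.0, 100_000)]
        sex = np.array(["M"] * 100_000 + ["F"] * 100_000)
        _, lvr = vs.variance_ratio(v, sex)
        assert abs(lvr - 2 * np.log(1.2)) < 0.02

    def test_zero_female_variance_errors(self):
        v = np.array([1.0, 2.0, 3.0, 3.0])
        sex = np.array(["M", "M", "F", "F"])
        with pytest.raises(ValueError, match="female variance"):
            vs.variance_ratio(v, sex)


def _brute_force_p(values, sex, sided="two"):
    """Independent enumeration oracle over all male-label assignments."""
    values = np.asarray(values, float)
    n_m = int(np.sum(sex == "M"))
    obs_lvr = np.log(
        values[sex == "M"].var(ddof=1) / values[sex == "F"].var(ddof=1)
    )
    count = total = 0
    for idx in combinations(range(len(values)), n_m):
        male = np.zeros(len(values), bool)
        male[list(idx)] = True
        lvr = np.log(values[male].var(ddof=1) / values[~male].var(ddof=1))
        if sided == "one":
            count += lvr > obs_lvr
        else:
            count += abs(lvr) >= abs(obs_lvr)
        total += 1
    return count / total


class TestPermutationTest:
    def test_exact_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=8)
        values[:4] *= 2.5
        sex = np.array(["M"] * 4 + ["F"] * 4)
        for sided in ("one", "two"):
            res = vs.permutation_test_vr(values, sex, sided=sided, exact=True)
            assert res["p_perm"] == pytest.approx(_brute_force_p(values, sex, sided))

    def test_monte_carlo_converges_to_exact(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=12)
        sex = np.array(["M"] * 6 + ["F"] * 6)
        exact = vs.permutation_test_vr(values, sex, exact=True)["p_perm"]
        mc = vs.permutation_test_vr(values, sex, B=20_000, seed=9)["p_perm"]
        assert abs(mc - exact) < 0.02

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=16)
        values[:8] *= 1.5
        sex = np.array(["M"] * 8 + ["F"] * 8)
        swapped = np.where(sex == "M", "F", "M")
        a = vs.permutation_test_vr(values, sex, exact=True)
        b = vs.permutation_test_vr(values, swapped, exact=True)
        assert a["log_vr"] == pytest.approx(-b["log_vr"])
        assert a["p_perm"] == pytest.approx(b["p_perm"])

    def test_seed_reproducible(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=60)
        sex = np.array(["M", "F"] * 30)
        p1 = vs.permutation_test_vr(values, sex, B=500, seed=11)["p_perm"]
        p2 = vs.permutation_test_vr(values, sex, B=500, seed=11)["p_perm"]
        assert p1 == p2

    def test_smoothed_p_never_zero(self):
        v = np.r_[np.array([-30.0, -10.0, 10.0, 30.0]), np.array([-0.1, 0.0, 0.05, 0.1])]
        sex = np.array(["M"] * 4 + ["F"] * 4)
        res = vs.permutation_test_vr(v, sex, exact=True, smoothed=True)
        assert res["p_perm"] > 0

    def test_bad_B_rejected(self):
        v = np.arange(8.0)
        sex = np.array(["M", "F"] * 4)
        with pytest.raises(ValueError):
            vs.permutation_test_vr(v, sex, B=0)
        with pytest.warns(UserWarning, match="too small"):
            vs.permutation_test_vr(v, sex, B=50, seed=0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.5, 3.0))
    def test_scale_equivariance_property(self, seed, c):
        """Scaling male deviations by c multiplies T by c^2, shifts log VR by 2 ln c."""
        rng = np.random.default_rng(seed)
        values = rng.normal(size=30)
        sex = np.array(["M"] * 15 + ["F"] * 15)
        T0, lvr0 = vs.variance_ratio(values, sex)
        scaled = values.copy()
        male = sex == "M"
        scaled[male] = scaled[male].mean() + c * (scaled[male] - scaled[male].mean())
        T1, lvr1 = vs.variance_ratio(scaled, sex)
        assert T1 == pytest.approx(c**2 * T0, rel=1e-9)
        assert lvr1 == pytest.approx(lvr0 + 2 * np.log(c), rel=1e-9)


class TestFdrBH:
    def test_step_up_example(self):
        q, reject = vs.fdr_bh([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert reject.all()
        assert q.max() <= 0.05

    def test_all_ones(self):
        q, reject = vs.fdr_bh([1.0, 1.0, 1.0])
        assert not reject.any()
        assert (q == 1.0).all()

    def test_single_p_identity(self):
        q, reject = vs.fdr_bh([0.04], alpha=0.05)
        assert q[0] == pytest.approx(0.04)
        assert reject[0]

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        q, _ = vs.fdr_bh(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            vs.fdr_bh([0.5, 1.5])


class TestCorrelateVrWithD:
    def test_identical_vectors(self):
        v = np.array([0.1, 0.2, 0.3, 0.15])
        assert vs.correlate_vr_with_d(v, v)["r"] == pytest.approx(1.0)

    def test_df_contract_for_14_measures(self):
        rng = np.random.default_rng(9)
        res = vs.correlate_vr_with_d(rng.normal(size=14), rng.normal(size=14))
        assert res["df"] == 12

    def test_orthogonal_vectors_zero_r(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert abs(vs.correlate_vr_with_d(a, b)["r"]) < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            vs.correlate_vr_with_d([0.1, 0.2, 0.3], [0.1, 0.2])
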