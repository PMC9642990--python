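"""Preprocessing computations: beta values, age acceleration, outlier
screening, PDS scoring, covariate adjustment, and twin ICCs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twinlca as t
from twinlca.biometrics import simulate_twin_pairs


class TestBetaValue:
    @pytest.mark.parametrize(
        "M,U,expected",
        [(0.0, 0.0, 0.0), (100.0, 0.0, 0.5), (900.0, 0.0, 0.9), (0.0, 900.0, 0.0)],
    )
    def test_known_values(self, M, U, expected):
        assert t.beta_value(M, U) == pytest.approx(expected)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            t.beta_value(-1.0, 5.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        M=st.floats(0.01, 1e6), U=st.floats(0, 1e6),
        dM=st.floats(1e-3, 1e3), dU=st.floats(1e-3, 1e3),
    )
    def test_monotone_in_intensities(self, M, U, dM, dU):
        b = t.beta_value(M, U)
        assert 0.0 <= b < 1.0
        assert t.beta_value(M + dM, U) > b
        assert t.beta_value(M, U + dU) < b  # strict for M > 0


class TestAgeAcceleration:
    def test_perfect_linear_fit_gives_zero_residuals(self):
        age = np.array([20.0, 21.0, 23.0, 26.0])
        assert np.allclose(t.age_acceleration(2 * age + 5, age), 0.0)
        assert np.allclose(t.age_acceleration(age, age), 0.0)

    def test_matches_normal_equations_oracle(self):
        # x=(20,22,24), y=(25,20,30): slope=10/8=1.25, intercept=-2.5,
        # residuals (2.5, -5, 2.5) by hand
        resid = t.age_acceleration([25.0, 20.0, 30.0], [20.0, 22.0, 24.0])
        assert np.allclose(resid, [2.5, -5.0, 2.5])

    def test_residual_properties(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(20, 25, 50)
        epi = 1.3 * age + rng.standard_normal(50)
        resid = t.age_acceleration(epi, age)
        assert abs(resid.sum()) < 1e-8
        assert abs(np.corrcoef(resid, age)[0, 1]) < 1e-8

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            t.age_acceleration([1.0, 2.0, 3.0], [22.0, 22.0, 22.0])


class TestScreenOutliers:
    def test_ten_sd_outlier_recoded(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(500)
        v[100] = 10 * v.std()
        out, n = t.screen_outliers(v, k=5)
        assert n == 1 and np.isnan(out[100])
        assert np.isfinite(np.delete(out, 100)).all()

    def test_identical_values_no_recode(self):
        out, n = t.screen_outliers(np.full(10, 3.0))
        assert n == 0 and np.isfinite(out).all()

    def test_hand_arithmetic_case(self):
        # (0,0,0,0,100), k=1: mean 20, SD sqrt(2000)=44.7 -> only 100 exceeds
        out, n = t.screen_outliers([0.0, 0, 0, 0, 100.0], k=1)
        assert n == 1 and np.isnan(out[-1]) and np.all(out[:4] == 0)

    def test_single_pass_semantics(self):
        # a second pass over the survivors of the hand case finds nothing
        out, _ = t.screen_outliers([0.0, 0, 0, 0, 100.0], k=1)
        out2, n2 = t.screen_outliers(out, k=1)
        assert n2 == 0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            t.screen_outliers([np.nan, np.nan])


class TestPDS:
    @pytest.mark.parametrize(
        "items,expected",
        [((1, 1, 1, 1, 1), 1.0), ((3, 3, 3, 3, 3), 3.0), ((1, 2, 3, 3, 1), 2.0)],
    )
    def test_mean_scoring(self, items, expected):
        assert t.pds_score(items) == pytest.approx(expected)

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            t.pds_score((1, 2, 3, 4, 1))
        with pytest.raises(ValueError):
            t.pds_score((1, 2, 3))


class TestAdjustOutcome:
    def test_orthogonal_covariate_only_centers(self):
        rng = np.random.default_rng(11)
        y = rng.standard_normal(40)
        yc = y - y.mean()
        x = rng.standard_normal(40)
        x -= x.mean()
        x -= (x @ yc) / (yc @ yc) * yc  # centered and orthogonal to y
        resid = t.adjust_outcome(y, x)
        assert np.allclose(resid, yc, atol=1e-10)

    def test_exact_linear_outcome_gives_zero(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 3))
        y = 2 + X @ np.array([1.0, -2.0, 0.5])
        assert np.allclose(t.adjust_outcome(y, X), 0.0, atol=1e-10)

    def test_matches_hat_matrix_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((6, 2))
        y = rng.standard_normal(6)
        D = np.column_stack([np.ones(6), X])
        H = D @ np.linalg.inv(D.T @ D) @ D.T
        assert np.allclose(t.adjust_outcome(y, X), (np.eye(6) - H) @ y)

    def test_affine_covariate_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        r1 = t.adjust_outcome(y, X)
        r2 = t.adjust_outcome(y, 3.0 * X + 7.0)
        assert np.allclose(r1, r2, atol=1e-8)

    def test_missing_rows_propagate(self):
        y = np.array([1.0, 2, np.nan, 4, 5, 6, 7])
        X = np.arange(7.0)
        resid = t.adjust_outcome(y, X)
        assert np.isnan(resid[2]) and np.isfinite(np.delete(resid, 2)).all()

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank"):
            t.adjust_outcome(np.arange(6.0), X)


class TestTwinICC:
    def test_identical_members_give_one(self):
        v = np.arange(10.0)
        assert t.twin_icc(np.column_stack([v, v])).icc == pytest.approx(1.0)

    def test_independent_members_give_zero(self):
        rng = np.random.default_rng(5)
        res = t.twin_icc(rng.standard_normal((4000, 2)))
        assert abs(res.icc) < 0.05

    def test_ae_generating_correlation_recovered(self):
        # MZ correlation equals the additive-genetic share by construction
        rng = np.random.default_rng(6)
        pairs = simulate_twin_pairs(10_000, 10, {"a2": 0.73, "e2": 0.27}, rng=rng)
        res = t.twin_icc(pairs["MZ"])
        assert abs(res.icc - 0.73) < 0.02
        assert res.ci_low < 0.73 < res.ci_high

    def test_mz_exceeds_dz_under_genetic_variance(self):
        rng = np.random.default_rng(7)
        pairs = simulate_twin_pairs(3000, 3000, {"a2": 0.6, "e2": 0.4}, rng=rng)
        assert t.twin_icc(pairs["MZ"]).icc > t.twin_icc(pairs["DZ"]).icc

    def test_incomplete_pairs_dropped_and_min_pairs_enforced(self):
        pairs = np.array([[1.0, 1.0], [2.0, np.nan], [3.0, 3.0]])
        with pytest.raises(ValueError, match="3 complete"):
            t.twin_icc(pairs)

    def test_anova_estimator_agrees_on_balanced_data(self):
        rng = np.random.default_rng(8)
        pairs = simulate_twin_pairs(2000, 10, {"a2": 0.5, "e2": 0.5}, rng=rng)["MZ"]
        de = t.twin_icc(pairs, method="double_entry").icc
        an = t.twin_icc(pairs, method="anova").icc
        assert abs(de - an) < 0.01

    def test_cohort_level_iccs(self, default_cohort_small):
        _, cohort, _ = default_cohort_small
        res = t.icc_by_zygosity(cohort, "AA_Grim")
        assert set(res) == {"MZ", "DZ"}
        assert -1 <= res["DZ"].icc <= res["MZ"].icc <= 1
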