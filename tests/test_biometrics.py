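"""Twin variance-component models: likelihood, FIML, fit indices,
model comparison."""

import numpy as np
import pytest

from twinlca.biometrics import (
    TwinBiometricModel,
    compare_models,
    fit_indices,
    pairs_from_cohort,
    simulate_twin_pairs,
)


def _exact_moment_pairs(n, var, cov, rng):
    """Complete pairs whose ML (denominator-n) moments are exactly (0, var, cov)."""
    z = rng.standard_normal((n, 2))
    z -= z.mean(axis=0)
    S = z.T @ z / n
    z = z @ np.linalg.inv(np.linalg.cholesky(S)).T
    target = np.array([[var, cov], [cov, var]])
    return z @ np.linalg.cholesky(target).T


class TestLikelihoodAndFits:
    def test_e_model_equals_pooled_variance(self):
        rng = np.random.default_rng(0)
        mz = _exact_moment_pairs(100, 1.0, 0.6, rng)
        dz = _exact_moment_pairs(100, 1.0, 0.3, rng)
        fit = TwinBiometricModel(mz, dz, "E").fit(seed=0)
        assert fit.total_variance == pytest.approx(1.0, abs=1e-4)
        assert fit.mean == pytest.approx(0.0, abs=1e-4)

    def test_ae_recovers_falconer_solution_on_consistent_moments(self):
        # rMZ=0.8, rDZ=0.4, unit variances: exactly AE with a2=0.8
        rng = np.random.default_rng(1)
        mz = _exact_moment_pairs(200, 1.0, 0.8, rng)
        dz = _exact_moment_pairs(200, 1.0, 0.4, rng)
        fit = TwinBiometricModel(mz, dz, "AE").fit(seed=0)
        assert fit.raw_components["a2"] == pytest.approx(0.8, abs=1e-3)
        assert fit.standardized["a2"] == pytest.approx(0.8, abs=1e-3)

    def test_ml_matches_grid_search_oracle(self):
        """Dense grid over (a2, e2) agrees with the optimizer within the
        grid resolution on balanced complete toy data."""
        rng = np.random.default_rng(2)
        pairs = simulate_twin_pairs(80, 80, {"a2": 0.6, "e2": 0.4}, rng=rng)
        model = TwinBiometricModel(pairs["MZ"], pairs["DZ"], "AE")
        fit = model.fit(seed=0)
        grid = np.arange(0.05, 1.5, 0.005)
        best = (-np.inf, None)
        m = fit.mean
        for a2 in grid:
            for e2 in grid:
                ll = model.loglik(np.array([m, a2, e2]))
                if ll > best[0]:
                    best = (ll, (a2, e2))
        assert abs(fit.raw_components["a2"] - best[1][0]) <= 0.005 + 1e-9
        assert abs(fit.raw_components["e2"] - best[1][1]) <= 0.005 + 1e-9
        assert fit.loglik >= best[0] - 1e-6

    def test_loglik_nesting_across_models(self):
        rng = np.random.default_rng(3)
        pairs = simulate_twin_pairs(120, 150, {"a2": 0.5, "c2": 0.2, "e2": 0.3},
                                    rng=rng, model="ACE")
        mz, dz = pairs["MZ"], pairs["DZ"]
        ll = {
            m: TwinBiometricModel(mz, dz, m).fit(seed=0).loglik
            for m in ("ACE", "AE", "E")
        }
        assert ll["ACE"] >= ll["AE"] - 1e-6 >= ll["E"] - 2e-6

    def test_fiml_uses_incomplete_pairs(self):
        rng = np.random.default_rng(4)
        pairs = simulate_twin_pairs(60, 60, {"a2": 0.6, "e2": 0.4}, rng=rng)
        mz = pairs["MZ"].copy()
        mz[:20, 1] = np.nan  # 20 singleton co-twins
        fit_full = TwinBiometricModel(mz, pairs["DZ"], "AE").fit(seed=0)
        fit_drop = TwinBiometricModel(mz[20:], pairs["DZ"], "AE").fit(seed=0)
        assert fit_full.loglik != pytest.approx(fit_drop.loglik)
        # singles shift the grand mean toward their own average
        singles_mean = mz[:20, 0].mean()
        if singles_mean > fit_drop.mean:
            assert fit_full.mean > fit_drop.mean - 1e-9
        else:
            assert fit_full.mean < fit_drop.mean + 1e-9

    def test_standardized_shares_sum_to_one(self):
        rng = np.random.default_rng(5)
        pairs = simulate_twin_pairs(100, 100, {"a2": 0.4, "d2": 0.2, "e2": 0.4},
                                    rng=rng, model="ADE")
        fit = TwinBiometricModel(pairs["MZ"], pairs["DZ"], "ADE").fit(seed=0)
        assert sum(fit.standardized.values()) == pytest.approx(1.0, abs=1e-8)
        ci = fit.standardized_ci()
        for name, share in fit.standardized.items():
            lo, hi = ci[name]
            assert lo <= share <= hi

    def test_input_validation(self):
        with pytest.raises(ValueError, match="model"):
            TwinBiometricModel(np.zeros((20, 2)), np.zeros((20, 2)), "DE")
        with pytest.raises(ValueError, match="at least"):
            TwinBiometricModel(np.zeros((3, 2)), np.zeros((20, 2)), "AE")


class TestFitIndices:
    def test_well_specified_model_fits_cleanly(self):
        rng = np.random.default_rng(6)
        mz = _exact_moment_pairs(150, 1.0, 0.7, rng)
        dz = _exact_moment_pairs(150, 1.0, 0.35, rng)
        fit = TwinBiometricModel(mz, dz, "AE").fit(seed=0)
        idx = fit_indices(fit)
        # the AE structure reproduces these moments almost exactly
        # (common-mean saturated model differs only through the mean)
        assert idx.chi2 < 1.0
        assert idx.cfi > 0.99 and idx.rmsea < 0.02 and idx.srmr < 0.02
        assert idx.df == 4

    def test_e_model_fails_on_twin_correlated_data(self):
        rng = np.random.default_rng(7)
        pairs = simulate_twin_pairs(150, 200, {"a2": 0.7, "e2": 0.3}, rng=rng)
        fit = TwinBiometricModel(pairs["MZ"], pairs["DZ"], "E").fit(seed=0)
        idx = fit_indices(fit)
        assert idx.p < 0.001 and idx.cfi < 0.95 and idx.df == 5

    def test_degrees_of_freedom_progression(self):
        rng = np.random.default_rng(8)
        pairs = simulate_twin_pairs(60, 60, {"a2": 0.5, "e2": 0.5}, rng=rng)
        dfs = {}
        for m in ("ACE", "ADE", "AE", "CE", "E"):
            fit = TwinBiometricModel(pairs["MZ"], pairs["DZ"], m).fit(n_starts=1)
            dfs[m] = fit_indices(fit).df
        assert dfs == {"ACE": 3, "ADE": 3, "AE": 4, "CE": 4, "E": 5}


class TestModelComparison:
    def test_ae_selected_under_ae_truth(self):
        rng = np.random.default_rng(9)
        pairs = simulate_twin_pairs(154, 211, {"a2": 0.73, "e2": 0.27}, rng=rng)
        fits = [
            TwinBiometricModel(pairs["MZ"], pairs["DZ"], m).fit(seed=0)
            for m in ("ACE", "ADE", "AE", "CE", "E")
        ]
        table = compare_models(fits)
        assert table.loc[table["selected"], "model"].iloc[0] == "AE"
        assert table.loc[table.model == "AE", "BIC"].iloc[0] < table.loc[
            table.model == "ACE", "BIC"
        ].iloc[0]

    def test_ae_preferred_over_ace_by_bic_in_majority(self):
        rng = np.random.default_rng(10)
        wins = 0
        reps = 30
        for _ in range(reps):
            pairs = simulate_twin_pairs(120, 160, {"a2": 0.6, "e2": 0.4}, rng=rng)
            ace = TwinBiometricModel(pairs["MZ"], pairs["DZ"], "ACE").fit(n_starts=1)
            ae = TwinBiometricModel(pairs["MZ"], pairs["DZ"], "AE").fit(n_starts=1)
            n = ace.model_obj.n_individuals
            bic_ace = -2 * ace.loglik + ace.n_params * np.log(n)
            bic_ae = -2 * ae.loglik + ae.n_params * np.log(n)
            wins += bic_ae < bic_ace
        assert wins / reps > 0.8


def test_pairs_from_cohort_pools_dz(default_cohort_small):
    _, cohort, _ = default_cohort_small
    pairs = pairs_from_cohort(cohort, "AA_Grim")
    zyg = cohort.groupby("family_id")["zygosity"].first()
    assert pairs["MZ"].shape[0] == (zyg == "MZ").sum()
    assert pairs["DZ"].shape[0] == zyg.str.startswith("DZ").sum()
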