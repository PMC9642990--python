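"""Latent class engine: EM correctness, FIML under MAR, selection
statistics, classification diagnostics, and the enumeration tests."""

import numpy as np
import pandas as pd
import pytest

import twinlca as t
from twinlca.lca import (
    LatentClassModel,
    _e_step,
    _m_step,
    _prepare,
    avepp,
    information_criteria,
    lmr_tests,
    n_free_parameters,
)

BIN_SPECS = [t.IndicatorSpec(f"b{j}", "ordinal", 2) for j in range(4)]


def _binary_frame(rng, n, p1, p0, prop=0.5):
    """Two-class binary-indicator data with known parameters."""
    cls = (rng.random(n) > prop).astype(int)
    cols = {}
    for j in range(4):
        p = np.where(cls == 1, p1[j], p0[j])
        cols[f"b{j}"] = (rng.random(n) < p).astype(float)
    return pd.DataFrame(cols), cls


class TestSingleClass:
    def test_closed_form_solution(self, default_cohort_small):
        cfg, cohort, _ = default_cohort_small
        fit = LatentClassModel(cohort, cfg.indicator_specs, 1).fit()
        assert fit.pi == pytest.approx([1.0])
        obs = cohort["smoke17"].dropna()
        freqs = obs.value_counts(normalize=True).sort_index().to_numpy()
        assert np.allclose(fit.ordinal_params["smoke17"][0], freqs, atol=1e-10)
        bmi = cohort["bmi17"].dropna().to_numpy()
        mu, var = fit.cont_params["bmi17"]
        assert mu[0] == pytest.approx(bmi.mean())
        assert var[0] == pytest.approx(bmi.var())
        # loglik is the sum of independent marginal log-likelihoods
        ll = 0.0
        for spec in cfg.indicator_specs:
            col = cohort[spec.name].dropna().to_numpy()
            if spec.kind == "ordinal":
                p = np.bincount(col.astype(int), minlength=spec.n_categories) / len(col)
                ll += np.sum(np.log(p[col.astype(int)]))
            else:
                v = col.var()
                ll += -0.5 * len(col) * np.log(2 * np.pi * v) - 0.5 * len(col)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)


class TestPosterior:
    def test_all_missing_individual_gets_prior(self, fitted_compact):
        cfg, cohort, fit = fitted_compact
        blank = cohort.head(3).copy()
        for s in cfg.indicator_specs:
            blank[s.name] = np.nan
        post = fit.posterior(blank)
        assert np.allclose(post, np.tile(fit.pi, (3, 1)))

    def test_rows_sum_to_one(self, fitted_compact):
        _, _, fit = fitted_compact
        assert np.allclose(fit.posterior().sum(axis=1), 1.0)

    def test_matches_hand_bayes_computation(self):
        # 2 classes, 2 binary indicators, 3 individuals; posteriors computed
        # directly from pi_k * prod p via explicit arithmetic
        data = pd.DataFrame({"b0": [1.0, 0.0, np.nan], "b1": [1.0, 1.0, 0.0]})
        specs = [t.IndicatorSpec("b0", "ordinal", 2), t.IndicatorSpec("b1", "ordinal", 2)]
        model = LatentClassModel(data, specs, 2)
        fit = model.fit(n_starts=1, seed=0)
        pi = np.array([0.6, 0.4])
        p0 = np.array([[0.8, 0.2], [0.3, 0.7]])  # P(b0 = 0|k), P(b0 = 1|k)... rows k
        p1 = np.array([[0.5, 0.5], [0.1, 0.9]])
        fit.pi = pi
        fit.ordinal_params = {"b0": p0, "b1": p1}
        post = fit.posterior(data)
        lik = np.array([
            [pi[0] * p0[0, 1] * p1[0, 1], pi[1] * p0[1, 1] * p1[1, 1]],
            [pi[0] * p0[0, 0] * p1[0, 1], pi[1] * p0[1, 0] * p1[1, 1]],
            [pi[0] * p1[0, 0], pi[1] * p1[1, 0]],
        ])
        assert np.allclose(post, lik / lik.sum(axis=1, keepdims=True))


class TestEMProperties:
    def test_loglik_nondecreasing_every_iteration(self):
        rng = np.random.default_rng(0)
        data, _ = _binary_frame(rng, 300, [0.8, 0.7, 0.9, 0.6], [0.2, 0.3, 0.1, 0.4])
        prep = _prepare(data, BIN_SPECS)
        resp0 = rng.dirichlet(np.ones(2), size=prep.n)
        params, _ = _m_step(prep, resp0, {})
        last = -np.inf
        for _ in range(60):
            resp, ll = _e_step(prep, params)
            assert ll >= last - 1e-9
            last = ll
            params, _ = _m_step(prep, resp, {})

    def test_label_permutation_leaves_fit_statistics_unchanged(self, fitted_compact):
        _, cohort, fit = fitted_compact
        perm = fit.posterior()[:, ::-1]
        assert np.allclose(sorted(avepp(perm)), sorted(fit.avepp()), atol=1e-12)
        # canonical ordering: descending mixing proportions
        assert np.all(np.diff(np.round(fit.pi, 10)) <= 0)

    def test_fiml_parameter_recovery_under_mar(self):
        """With MAR missingness injected, the EM recovers the generating
        category probabilities and class sizes."""
        cfg = t.compact_two_class_config(n_pairs=2500, seed=5)
        cfg.missing_rates = {s.name: 0.15 for s in cfg.indicator_specs}
        cohort = t.generate_cohort(cfg)
        fit = LatentClassModel(cohort, cfg.indicator_specs, 2).fit(
            n_starts=5, seed=1, tol=1e-8
        )
        assert np.allclose(np.sort(fit.pi), [0.5, 0.5], atol=0.03)
        target = np.asarray(cfg.indicator_params["ind1"]["probs"])
        est = fit.ordinal_params["ind1"]
        err = min(
            np.abs(est - target).max(), np.abs(est[::-1] - target).max()
        )
        assert err < 0.04

    def test_degenerate_inputs_rejected(self):
        data = pd.DataFrame({"b0": [np.nan, np.nan], "b1": [np.nan, np.nan]})
        specs = [t.IndicatorSpec("b0", "ordinal", 2), t.IndicatorSpec("b1", "ordinal", 2)]
        with pytest.raises(ValueError, match="observed"):
            LatentClassModel(data, specs, 2)
        with pytest.raises(ValueError, match="n_classes"):
            LatentClassModel(data, specs, 0)


class TestInformationCriteria:
    def test_arithmetic(self):
        fit = _FakeFit(loglik=-1000.0, n_params=10)
        aic, bic, abic = information_criteria(fit, n=100)
        assert aic == pytest.approx(2020.0)
        assert bic == pytest.approx(2000 + 10 * np.log(100))
        assert abic == pytest.approx(2000 + 10 * np.log(102 / 24))

    def test_free_parameter_accounting(self):
        specs = t.default_indicator_specs()
        # each added class contributes 1 + sum(C_j - 1) + 2 * n_continuous
        per_class = sum(s.n_categories - 1 for s in specs if s.kind == "ordinal") + 2 * 3
        for K in range(1, 6):
            assert n_free_parameters(specs, K) == (K - 1) + K * per_class


class _FakeFit:
    def __init__(self, loglik, n_params, n_classes=2, n_effective=100):
        self.loglik = loglik
        self.n_params = n_params
        self.n_classes = n_classes
        self.n_effective = n_effective


class TestEnumerationTests:
    def test_zero_gain_gives_p_near_one(self):
        f2 = _FakeFit(-500.0, 9, n_classes=2)
        f1 = _FakeFit(-500.0, 4, n_classes=1)
        pv, pl = lmr_tests(f2, f1, n=500)
        assert pv > 0.99 and pl > 0.99

    def test_inadequate_starts_detected(self):
        f2 = _FakeFit(-510.0, 9, n_classes=2)
        f1 = _FakeFit(-500.0, 4, n_classes=1)
        with pytest.raises(ValueError, match="starts"):
            lmr_tests(f2, f1, n=500)

    def test_class_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="one class fewer"):
            lmr_tests(_FakeFit(-1, 9, 3), _FakeFit(-2, 4, 1), n=100)

    def test_null_rejection_rate_bounded(self):
        """Testing 2 vs 1 classes on one-class data: the enumeration test
        rejects at 5% at most about 5% of the time (the chi-square
        reference is conservative under the mixture null)."""
        rng = np.random.default_rng(7)
        rej = 0
        reps = 200
        for rep in range(reps):
            df = pd.DataFrame(
                {f"b{j}": rng.integers(0, 2, 1000).astype(float) for j in range(4)}
            )
            f1 = LatentClassModel(df, BIN_SPECS, 1).fit()
            f2 = LatentClassModel(df, BIN_SPECS, 2).fit(
                n_starts=4, seed=rep, max_iter=300, stage1_iter=20, stage1_keep=2
            )
            pv, _ = lmr_tests(f2, f1)
            rej += pv < 0.05
        assert rej / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_true_extra_class_detected(self):
        """4 vs 5 classes on five-class data: the test rejects the smaller
        model decisively."""
        cfg = t.default_config(n_pairs=2557, seed=3)
        cohort = t.generate_cohort(cfg)
        f4 = LatentClassModel(cohort, cfg.indicator_specs, 4).fit(
            n_starts=12, seed=0, tol=1e-7, stage1_iter=40
        )
        f5 = LatentClassModel(cohort, cfg.indicator_specs, 5).fit(
            n_starts=12, seed=0, tol=1e-7, stage1_iter=40
        )
        pv, pl = lmr_tests(f5, f4)
        assert pv < 0.001 and pl < 0.001


class TestAvePP:
    def test_one_hot_posteriors(self):
        post = np.eye(3)[np.array([0, 1, 2, 0])]
        assert np.allclose(avepp(post), 1.0)

    def test_uniform_posteriors(self):
        # deterministic first-index tie-break assigns everyone to class 1,
        # whose AvePP is then 0.5; the unpopulated class is flagged NaN
        post = np.full((6, 2), 0.5)
        res = avepp(post)
        assert res[0] == pytest.approx(0.5) and np.isnan(res[1])

    def test_hand_computed_toy(self):
        post = np.array([
            [0.9, 0.1], [0.6, 0.4], [0.2, 0.8], [0.3, 0.7],
        ])
        # modal class 1: rows 0,1 -> mean(0.9, 0.6); class 2: rows 2,3
        assert np.allclose(avepp(post), [0.75, 0.75])

    def test_empty_modal_class_flagged_nan(self):
        post = np.array([[0.9, 0.1], [0.8, 0.2]])
        res = avepp(post)
        assert res[0] == pytest.approx(0.85) and np.isnan(res[1])


def test_selection_table_shape(fitted_compact):
    cfg, cohort, _ = fitted_compact
    table = t.select_classes(cohort, cfg.indicator_specs, k_min=1, k_max=2,
                             n_starts=3, seed=0)
    assert list(table["K"]) == [1, 2]
    assert np.isnan(table.loc[0, "VLMR_p"]) and table.loc[1, "VLMR_p"] <= 1.0
    assert (table["AIC"].diff().dropna() < 0).all()  # 2 classes fit better


def test_cluster_robust_proportion_se(fitted_compact):
    _, cohort, fit = fitted_compact
    se = fit.class_proportion_se(cohort["family_id"].to_numpy())
    assert se.shape == (2,) and np.all(se > 0) and np.all(se < 0.1)
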