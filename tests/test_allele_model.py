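import math

import numpy as np
import pytest

from magefit.allele_model import (
    PenaltyConfig,
    build_feature_matrix,
    fit_penalized,
    fit_penalized_cv,
    ols_fit,
    repeated_weighted_fit,
    selected_features,
    sklearn_penalties_to_quoted_loss,
    two_round_selection,
    univariate_scan,
)
from magefit.mage_sim import MageSimConfig, experiment_to_genotype_table, simulate_population

from conftest import make_genotype_table


def closed_form_ols(X, y):
    """Independent oracle: normal-equation OLS with intercept."""
    A = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)[1:]


class TestBuildFeatureMatrix:
    def test_singleton_feature_dropped(self):
        X = np.zeros((10, 2))
        X[0, 0] = 1  # allele seen once
        X[:5, 1] = 1
        gt = make_genotype_table(X, np.full(10, 40.0))
        fm = build_feature_matrix(gt)
        assert fm.feature_ids == ["a1"]

    def test_constant_column_flagged_non_identifiable(self):
        X = np.ones((6, 2))
        X[:3, 1] = 0
        gt = make_genotype_table(X, np.full(6, 40.0))
        fm = build_feature_matrix(gt)
        assert fm.non_identifiable == ["a0"]
        assert "a0" in fm.feature_ids  # retained

    def test_impute_zero_policy(self, caplog):
        X = np.array([[1.0, np.nan], [1.0, 1.0], [0.0, 1.0], [0.0, 0.0]])
        gt = make_genotype_table(X, np.full(4, 40.0))
        with caplog.at_level("WARNING"):
            fm = build_feature_matrix(gt)
        assert "imputing 1" in caplog.text
        assert fm.X[0, 1] == 0.0

    def test_drop_clone_policy(self):
        X = np.array([[1.0, np.nan], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        gt = make_genotype_table(X, np.full(4, 40.0))
        fm = build_feature_matrix(gt, missing_policy="drop_clone")
        assert fm.n_clones == 3

    def test_y_is_natural_log_of_doubling_time(self, toy_genotype_table):
        fm = build_feature_matrix(toy_genotype_table, min_clone_occurrence=1)
        np.testing.assert_allclose(
            fm.y_log, np.log(toy_genotype_table.meta["doubling_time_min"])
        )

    def test_non_positive_time_rejected(self):
        gt = make_genotype_table(np.ones((3, 1)), [40.0, -1.0, 30.0])
        with pytest.raises(ValueError, match="non-positive"):
            build_feature_matrix(gt, min_clone_occurrence=1)


class TestPenalizedFit:
    def test_zero_penalty_limit_equals_ols(self, toy_genotype_table):
        fm = build_feature_matrix(toy_genotype_table, min_clone_occurrence=1)
        fit = fit_penalized(fm, alpha=1e-12, l1_ratio=0.5)
        np.testing.assert_allclose(
            fit.coefficients, closed_form_ols(fm.X, fm.y_log), atol=1e-6
        )

    def test_total_shrinkage_at_huge_alpha(self, toy_genotype_table):
        fm = build_feature_matrix(toy_genotype_table, min_clone_occurrence=1)
        fit = fit_penalized(fm, alpha=1e6, l1_ratio=1.0)
        assert np.all(fit.coefficients == 0.0)

    @pytest.mark.parametrize("alpha,l1_ratio", [(0.01, 1.0), (0.05, 0.5), (0.02, 0.1)])
    def test_stationarity_of_quoted_loss(self, alpha, l1_ratio):
        """The returned coefficients satisfy the subgradient conditions of
        |y - Xb|^2 + lambda1 |b|_1 + lambda2 |b|^2 at the mapped penalties."""
        rng = np.random.default_rng(42)
        X = (rng.random((40, 6)) < 0.4).astype(float)
        y = X @ np.array([-0.3, -0.1, 0, 0, 0.05, 0]) + rng.normal(0, 0.05, 40)
        gt = make_genotype_table(X, np.exp(y) * 40.0)
        fm = build_feature_matrix(gt, min_clone_occurrence=1)
        fit = fit_penalized(fm, alpha=alpha, l1_ratio=l1_ratio)
        lam1, lam2 = sklearn_penalties_to_quoted_loss(alpha, l1_ratio, fm.n_clones)
        # intercept is unpenalized: check on centered data
        Xc = fm.X - fm.X.mean(axis=0)
        yc = fm.y_log - fm.y_log.mean()
        grad_smooth = -2.0 * Xc.T @ (yc - Xc @ fit.coefficients) + 2.0 * lam2 * fit.coefficients
        for j, b in enumerate(fit.coefficients):
            if b != 0:
                assert abs(grad_smooth[j] + lam1 * np.sign(b)) < 1e-4 * max(1, lam1)
            else:
                assert abs(grad_smooth[j]) <= lam1 * (1 + 1e-6) + 1e-4

    def test_l1_path_support_monotone_on_orthogonal_toy(self):
        """Pure-L1 support never grows as alpha increases (orthogonal design,
        where the lasso path is exact soft thresholding)."""
        X = np.kron(np.eye(4), np.ones((5, 1)))
        beta = np.array([-0.4, -0.2, -0.05, 0.0])
        gt = make_genotype_table(X, 40.0 * np.exp(X @ beta))
        fm = build_feature_matrix(gt, min_clone_occurrence=1)
        supports = []
        for alpha in [1e-4, 1e-3, 1e-2, 5e-2, 1e-1]:
            fit = fit_penalized(fm, alpha=alpha, l1_ratio=1.0)
            supports.append(frozenset(np.nonzero(fit.coefficients)[0]))
        for small, big in zip(supports[1:], supports):
            assert small <= big

    def test_cv_requires_enough_clones(self, toy_genotype_table, light_penalty):
        fm = build_feature_matrix(toy_genotype_table, min_clone_occurrence=1)
        fm.X, fm.y_log = fm.X[:3], fm.y_log[:3]
        fm.clone_ids = fm.clone_ids[:3]
        with pytest.raises(ValueError, match="folds"):
            fit_penalized_cv(fm, light_penalty, seed=0)


def _single_causal_table(n=60, p=8, beta=math.log(0.8), seed=0):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, p)) < 0.5).astype(float)
    t = 40.0 * np.exp(X[:, 0] * beta)  # noiseless
    return make_genotype_table(X, t)


class TestRepeatedWeightedFit:
    def test_noiseless_single_causal_recovered_exactly(self, deep_penalty):
        gt = _single_causal_table()
        fm = build_feature_matrix(gt, min_clone_occurrence=1)
        effects = repeated_weighted_fit(
            fm, deep_penalty, n_reps=8, n_holdout=15, seed=4
        )
        by_id = {e.feature_id: e.mean_coefficient for e in effects}
        assert by_id["a0"] == pytest.approx(math.log(0.8), abs=1e-6)
        for fid, coef in by_id.items():
            if fid != "a0":
                assert abs(coef) < 1e-6

    def test_deterministic_given_seed(self, light_penalty):
        gt = _single_causal_table(seed=3)
        fm = build_feature_matrix(gt, min_clone_occurrence=1)
        a = repeated_weighted_fit(fm, light_penalty, n_reps=5, seed=9)
        b = repeated_weighted_fit(fm, light_penalty, n_reps=5, seed=9)
        for ea, eb in zip(a, b):
            assert ea.feature_id == eb.feature_id
            assert ea.mean_coefficient == eb.mean_coefficient
            assert np.array_equal(ea.per_rep_coefficients, eb.per_rep_coefficients)
            assert np.array_equal(ea.per_rep_weights, eb.per_rep_weights)

    def test_weighted_mean_identity(self, light_penalty):
        gt = _single_causal_table(seed=6)
        fm = build_feature_matrix(gt, min_clone_occurrence=1)
        (e, *_) = repeated_weighted_fit(fm, light_penalty, n_reps=6, seed=1)
        w, c = e.per_rep_weights, e.per_rep_coefficients
        assert e.mean_coefficient == pytest.approx(
            float((w * c).sum() / w.sum()), rel=1e-12
        )


class TestTwoRoundSelection:
    def test_single_strong_causal_ranks_first(self, light_penalty):
        gt = _single_causal_table(beta=math.log(0.7), seed=8)
        fm = build_feature_matrix(gt, min_clone_occurrence=1)
        effects = two_round_selection(fm, light_penalty, n_reps=8, seed=2)
        assert effects[0].feature_id == "a0"
        assert effects[0].survived_round == 2
        assert effects[0].mean_coefficient < 0
        assert "a0" in selected_features(effects)

    def test_three_causal_occupy_most_negative_ranks(self, light_penalty):
        """Simulated MAGE experiment, 3 causal + 20 neutral targeted alleles."""
        cfg = MageSimConfig(
            n_oligos=23,
            causal_reversion_effects={
                "rev000": -0.25, "rev001": -0.15, "rev002": -0.10,
            },
            de_novo_rate_per_cycle=0.0,
            n_cycles=30,
            population_size=800,
            sample_cycles=[5, 10, 15, 20, 25, 30],
            clones_per_sample=15,
            seed=1,
        )
        exp = simulate_population(cfg)
        fm = build_feature_matrix(experiment_to_genotype_table(exp))
        effects = two_round_selection(fm, light_penalty, n_reps=10, seed=1)
        top3 = {e.feature_id for e in effects[:3]}
        assert top3 == {"rev000", "rev001", "rev002"}
        # cross-check against OLS restricted to the true causal set
        idx = [fm.feature_ids.index(a) for a in ("rev000", "rev001", "rev002")]
        ols = closed_form_ols(fm.X[:, idx], fm.y_log)
        assert np.all(ols < 0)

    def test_pure_noise_selection_below_permutation_floor(self, light_penalty):
        """On phenotypes independent of genotype, no weighted-mean coefficient
        should exceed the noise floor estimated by refitting on permuted y."""
        rng = np.random.default_rng(12)
        X = (rng.random((40, 10)) < 0.5).astype(float)
        t = 40.0 * np.exp(rng.normal(0, 0.05, 40))
        gt = make_genotype_table(X, t)
        fm = build_feature_matrix(gt, min_clone_occurrence=1)
        effects = repeated_weighted_fit(fm, light_penalty, n_reps=6, seed=0)
        observed = max(abs(e.mean_coefficient) for e in effects)
        null_max = []
        for k in range(5):
            fm_perm = build_feature_matrix(gt, min_clone_occurrence=1)
            fm_perm.y_log = np.random.default_rng(100 + k).permutation(fm.y_log)
            null = repeated_weighted_fit(fm_perm, light_penalty, n_reps=6, seed=k)
            null_max.append(max(abs(e.mean_coefficient) for e in null))
        assert observed <= 3 * max(max(null_max), 1e-4)

    def test_additive_and_multiplicative_agree_on_small_effects(self, light_penalty):
        cfg = MageSimConfig(
            n_oligos=12,
            causal_reversion_effects={"rev000": -0.12, "rev001": -0.08},
            de_novo_rate_per_cycle=0.0,
            n_cycles=20,
            population_size=600,
            sample_cycles=[5, 10, 15, 20],
            clones_per_sample=20,
            seed=7,
        )
        fm = build_feature_matrix(
            experiment_to_genotype_table(simulate_population(cfg))
        )
        log_eff = two_round_selection(fm, light_penalty, n_reps=8, seed=3)
        fm_add = build_feature_matrix(
            experiment_to_genotype_table(simulate_population(cfg))
        )
        fm_add.y_log = np.exp(fm_add.y_log)  # raw doubling time response
        add_eff = two_round_selection(fm_add, light_penalty, n_reps=8, seed=3)
        top_log = {e.feature_id for e in log_eff[:2]}
        top_add = {e.feature_id for e in add_eff[:2]}
        assert top_log == top_add == {"rev000", "rev001"}


class TestOLS:
    def test_matches_simple_regression_closed_form(self):
        rng = np.random.default_rng(5)
        x = (rng.random(30) < 0.5).astype(float)
        y = -0.2 * x + rng.normal(0, 0.03, 30)
        gt = make_genotype_table(x[:, None], 40.0 * np.exp(y))
        fm = build_feature_matrix(gt, min_clone_occurrence=1)
        res = ols_fit(fm)
        # hand-computed slope and SE for simple regression
        xc, yc = x - x.mean(), fm.y_log - fm.y_log.mean()
        slope = float(xc @ yc / (xc @ xc))
        resid = yc - slope * xc
        se = math.sqrt(resid @ resid / (30 - 2) / (xc @ xc))
        assert res.loc["a0", "coefficient"] == pytest.approx(slope, rel=1e-10)
        assert res.loc["a0", "stderr"] == pytest.approx(se, rel=1e-10)

    def test_noiseless_orthogonal_exact(self):
        # three groups (baseline, a0-only, a1-only): full rank with intercept
        X = np.vstack([np.tile(r, (4, 1)) for r in ([0, 0], [1, 0], [0, 1])]).astype(float)
        gt = make_genotype_table(X, 40.0 * np.exp(X @ np.array([-0.3, -0.1])))
        fm = build_feature_matrix(gt, min_clone_occurrence=1)
        res = ols_fit(fm)
        np.testing.assert_allclose(res["coefficient"], [-0.3, -0.1], atol=1e-12)
        assert (res["pvalue"] < 1e-10).all()

    def test_collinear_columns_rejected(self):
        x = np.array([0, 1, 0, 1, 1, 0, 1, 0, 0, 1, 1, 0], dtype=float)
        gt = make_genotype_table(np.column_stack([x, x]), np.full(12, 40.0))
        fm = build_feature_matrix(gt, min_clone_occurrence=1)
        with pytest.raises(np.linalg.LinAlgError, match="a0.*a1"):
            ols_fit(fm)

    def test_overparameterised_guard(self):
        rng = np.random.default_rng(0)
        X = (rng.random((12, 6)) < 0.5).astype(float)
        gt = make_genotype_table(X, np.full(12, 40.0))
        fm = build_feature_matrix(gt, min_clone_occurrence=1)
        with pytest.raises(ValueError, match="clones/3"):
            ols_fit(fm)


class TestUnivariateScan:
    def test_hitchhiker_gets_same_slope_as_causal(self):
        x = np.array([0, 0, 0, 1, 1, 1, 0, 1, 0, 1], dtype=float)
        X = np.column_stack([x, x.copy()])  # perfectly correlated pair
        gt = make_genotype_table(X, 40.0 * np.exp(-0.2 * x))
        fm = build_feature_matrix(gt, min_clone_occurrence=1)
        res = univariate_scan(fm)
        assert res.loc["a0", "slope"] == pytest.approx(res.loc["a1", "slope"])

    def test_neutral_feature_near_zero_slope(self):
        rng = np.random.default_rng(21)
        x = (rng.random(200) < 0.5).astype(float)
        t = 40.0 * np.exp(rng.normal(0, 0.05, 200))
        gt = make_genotype_table(x[:, None], t)
        fm = build_feature_matrix(gt, min_clone_occurrence=1)
        res = univariate_scan(fm)
        assert abs(res.loc["a0", "slope"]) < 0.03

    def test_agrees_with_ols_for_single_feature(self):
        rng = np.random.default_rng(3)
        x = (rng.random(30) < 0.5).astype(float)
        gt = make_genotype_table(x[:, None], 40.0 * np.exp(-0.1 * x + rng.normal(0, 0.02, 30)))
        fm = build_feature_matrix(gt, min_clone_occurrence=1)
        uni = univariate_scan(fm)
        multi = ols_fit(fm)
        assert uni.loc["a0", "slope"] == pytest.approx(
            multi.loc["a0", "coefficient"], rel=1e-10
        )
        assert uni.loc["a0", "pvalue"] == pytest.approx(
            multi.loc["a0", "pvalue"], rel=1e-8
        )
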