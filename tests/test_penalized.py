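import itertools

import numpy as np
import pytest

from sncsig import penalized
from sncsig.penalized import (
    EnetConfig,
    clogit_enet,
    clogit_lambda_max,
    clogit_smooth_grad,
    cox_enet,
    cox_lambda_max,
    cox_smooth_grad,
    kkt_violation,
    make_ad_data,
    make_atn_data,
    stability_select,
    tune_hyperparameters,
)


def clogit_objective(beta, D, alpha, lam):
    n = D.shape[0]
    loss = np.mean(np.logaddexp(0.0, -(D @ beta)))
    return loss + lam * (alpha * np.abs(beta).sum() + (1 - alpha) / 2 * beta @ beta)


def cox_objective(beta, X, t, e, alpha, lam):
    from sncsig.assoc import cox_loglik_grad_hess

    ll, _ = cox_loglik_grad_hess(beta, X, t, e, ties="breslow", want_hess=False)
    return -ll / X.shape[0] + lam * (
        alpha * np.abs(beta).sum() + (1 - alpha) / 2 * beta @ beta
    )


def grid_search(objective, p, lo=-4.0, hi=4.0, steps=41, refinements=9):
    """Dense grid minimizer with iterative refinement — independent oracle.

    Each refinement re-grids a window of +-width around the incumbent with
    13 points and shrinks the window 6-fold, so the final resolution is
    ~width_0 * 6**-refinements (far below 1e-4 for the defaults); for a
    convex objective the incumbent always stays within half a grid spacing
    of the minimizer, so the shrinking window never loses it.
    """
    axes = [np.linspace(lo, hi, steps)] * p
    best, best_val = None, np.inf
    for point in itertools.product(*axes):
        v = objective(np.array(point))
        if v < best_val:
            best, best_val = np.array(point), v
    width = (hi - lo) / (steps - 1)
    for _ in range(refinements):
        axes = [np.linspace(b - width, b + width, 13) for b in best]
        for point in itertools.product(*axes):
            v = objective(np.array(point))
            if v < best_val:
                best, best_val = np.array(point), v
        width = width / 6.0
    return best


class TestEnetConfig:
    def test_defaults_valid(self):
        cfg = EnetConfig()
        cfg.validate()
        assert min(cfg.alpha_grid) == pytest.approx(0.10)
        assert max(cfg.alpha_grid) == pytest.approx(1.0)
        assert len(cfg.alpha_grid) == 19  # 0.10 .. 1.00 in 0.05 steps

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha_grid": (0.0, 0.5)},  # pure ridge excluded
            {"alpha_grid": (1.2,)},
            {"train_fraction": 1.0},
            {"occurrence_threshold": 200},
            {"cv_folds": 1},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            EnetConfig(**kwargs).validate()


class TestClogitEnet:
    def test_lambda_max_gives_null_solution(self):
        rng = np.random.default_rng(0)
        D = rng.normal(size=(40, 12)) + 0.3
        for alpha in (0.1, 0.65, 1.0):
            lmax = clogit_lambda_max(D, alpha)
            assert np.all(clogit_enet(D, alpha, lmax * 1.0001) == 0.0)
            assert np.any(clogit_enet(D, alpha, lmax * 0.95) != 0.0)

    def test_two_feature_lasso_matches_grid_search(self):
        rng = np.random.default_rng(1)
        D = rng.normal(size=(10, 2)) + np.array([0.8, -0.4])
        alpha, lam = 1.0, 0.05
        beta = clogit_enet(D, alpha, lam)
        oracle = grid_search(lambda b: clogit_objective(b, D, alpha, lam), 2)
        np.testing.assert_allclose(beta, oracle, atol=1e-4)

    def test_duplicated_feature_equal_coefficients(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20) + 0.5
        D = np.column_stack([x, x, rng.normal(size=20)])
        beta = clogit_enet(D, 0.5, 0.05)
        assert beta[0] == pytest.approx(beta[1], abs=1e-6)

    def test_kkt_conditions(self):
        rng = np.random.default_rng(3)
        D = rng.normal(size=(60, 30)) + 0.1
        for alpha, frac in ((0.9, 0.3), (0.5, 0.1), (1.0, 0.5)):
            lam = clogit_lambda_max(D, alpha) * frac
            beta = clogit_enet(D, alpha, lam)
            assert kkt_violation(clogit_smooth_grad(D, beta), beta, alpha, lam) < 1e-5

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            clogit_enet(np.ones((5, 2)), 0.0, 0.1)


@pytest.fixture(scope="module")
def survdata():
    rng = np.random.default_rng(4)
    n = 60
    X = rng.normal(size=(n, 10))
    t = rng.exponential(1 / np.exp(0.7 * X[:, 0] - 0.5 * X[:, 1]))
    e = (rng.random(n) < 0.75).astype(int)
    e[:2] = 1
    return X, t, e


class TestCoxEnet:
    def test_lambda_max_gives_null_solution(self, survdata):
        X, t, e = survdata
        for alpha in (0.2, 0.65, 1.0):
            lmax = cox_lambda_max(X, t, e, alpha)
            assert np.all(cox_enet(X, t, e, alpha, lmax * 1.0001) == 0.0)
            assert np.any(cox_enet(X, t, e, alpha, lmax * 0.95) != 0.0)

    def test_small_lambda_matches_unpenalized(self, survdata):
        from sncsig.assoc import fit_cox

        X, t, e = survdata
        x1 = X[:, [0]]
        beta = cox_enet(x1, t, e, 1.0, 1e-10)
        ref = fit_cox(x1, t, e, ties="breslow")
        assert beta[0] == pytest.approx(ref.beta[0], abs=1e-3)

    def test_kkt_conditions(self, survdata):
        X, t, e = survdata
        for alpha, frac in ((0.65, 0.3), (1.0, 0.15), (0.3, 0.5)):
            lam = cox_lambda_max(X, t, e, alpha) * frac
            beta = cox_enet(X, t, e, alpha, lam)
            assert (
                kkt_violation(cox_smooth_grad(X, t, e, beta), beta, alpha, lam) < 1e-5
            )

    def test_two_feature_oracle(self, survdata):
        X, t, e = survdata
        X2 = X[:, :2]
        alpha, lam = 0.65, 0.08
        beta = cox_enet(X2, t, e, alpha, lam)
        oracle = grid_search(lambda b: cox_objective(b, X2, t, e, alpha, lam), 2)
        np.testing.assert_allclose(beta, oracle, atol=1e-4)

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            cox_enet(np.ones((4, 2)), np.ones(4), np.zeros(4), 0.5, 0.1)


class TestTuning:
    def test_degenerate_single_pair_grid_returned_unchanged(self, preprocessed):
        em, _, pheno, _ = preprocessed
        data = make_atn_data(em, pheno)
        cfg = EnetConfig(
            alpha_grid=(0.65,), lambda_path=(0.08,), tuning_reps=2,
            cv_folds=3, seed=0,
        )
        res = tune_hyperparameters(data, cfg)
        assert res.alpha_star == 0.65
        assert res.lambda_star == pytest.approx(0.08)

    def test_trace_is_complete(self, preprocessed):
        em, _, pheno, _ = preprocessed
        data = make_ad_data(em, pheno)
        cfg = EnetConfig(
            alpha_grid=(0.3, 0.9), n_lambda=8, tuning_reps=2, cv_folds=4, seed=1
        )
        res = tune_hyperparameters(data, cfg)
        assert len(res.trace) == 2 * 2
        assert set(res.trace.columns) >= {
            "rep", "alpha", "lambda_selected", "heldout_score"
        }
        assert res.alpha_star in (0.3, 0.9)
        assert res.lambda_star > 0


class TestStabilitySelect:
    def test_zero_threshold_keeps_every_selected_feature(self, preprocessed):
        em, _, pheno, _ = preprocessed
        data = make_atn_data(em, pheno)
        cfg = EnetConfig(
            stability_iters=10, occurrence_threshold=0, bootstrap_reps=100, seed=0
        )
        sig = stability_select(data, 0.9, 0.15, cfg)
        occ = np.asarray(sig.occurrences)
        assert set(sig.selected_features) == set(
            np.asarray(sig.feature_ids)[occ > 0]
        ) or len(sig.selected_features) == len(sig.feature_ids)
        assert np.all(np.asarray(sig.mean_coef) != 0.0)

    def test_selected_subset_and_threshold_invariants(self, preprocessed):
        em, _, pheno, _ = preprocessed
        data = make_atn_data(em, pheno)
        cfg = EnetConfig(
            stability_iters=30, occurrence_threshold=27, bootstrap_reps=100, seed=3
        )
        sig = stability_select(data, 0.9, 0.12, cfg)
        occ = dict(zip(sig.feature_ids, np.asarray(sig.occurrences)))
        for f in sig.selected_features:
            assert occ[f] >= 27
        assert set(sig.selected_features) <= set(sig.feature_ids)

    def test_planted_features_dominate_null(self, preprocessed):
        from scipy.stats import mannwhitneyu

        em, _, pheno, truth = preprocessed
        data = make_atn_data(em, pheno)
        cfg = EnetConfig(stability_iters=50, occurrence_threshold=45,
                         bootstrap_reps=100, seed=4)
        sig = stability_select(data, 0.9, 0.15, cfg)
        occ = np.asarray(sig.occurrences, dtype=float)
        planted = np.isin(np.asarray(sig.feature_ids), truth.atn_feature_ids)
        res = mannwhitneyu(occ[planted], occ[~planted], alternative="greater")
        assert res.pvalue < 0.01

    def test_empty_signature_warns(self, preprocessed):
        em, _, pheno, _ = preprocessed
        data = make_atn_data(em, pheno)
        cfg = EnetConfig(stability_iters=10, occurrence_threshold=9,
                         bootstrap_reps=100, seed=5)
        lmax = 10.0  # absurdly strong penalty: nothing survives
        with pytest.warns(RuntimeWarning):
            sig = stability_select(data, 0.9, lmax, cfg)
        assert sig.selected_features == []

    def test_json_roundtrip(self, preprocessed, tmp_path):
        em, _, pheno, _ = preprocessed
        data = make_atn_data(em, pheno)
        cfg = EnetConfig(stability_iters=10, occurrence_threshold=5,
                         bootstrap_reps=100, seed=6)
        sig = stability_select(data, 0.9, 0.2, cfg)
        path = tmp_path / "sig.json"
        sig.to_json(path)
        back = penalized.SignatureResult.from_json(path)
        assert back.selected_features == sig.selected_features
        np.testing.assert_allclose(back.mean_coef, sig.mean_coef)
        assert back.alpha_star == sig.alpha_star
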