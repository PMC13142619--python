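"""Weight-estimation methods: oracles, calibration, planted recovery."""

import warnings

import numpy as np
import pandas as pd
import pytest

from psomics.data import FeatureMatrix, OrdinalOutcome
from psomics.ordinal import OrderedLogit
from psomics.selection import (WeightSet, compose, cross_leverage_screen,
                               fit_ordinal_boosting, fit_ordinal_elasticnet,
                               fit_rf_vim, prune, threshold_select)


def fm(data, layer="dnam", ids=None):
    df = pd.DataFrame(np.asarray(data, dtype=float),
                      index=[f"s{i}" for i in range(len(data))],
                      columns=ids or [f"f{j:03d}" for j in
                                      range(np.asarray(data).shape[1])])
    return FeatureMatrix(df, layer)


def outcome_from_latent(lat, probs=(0.25, 0.25, 0.25, 0.25)):
    th = np.quantile(lat, np.cumsum(probs)[:-1])
    codes = (np.asarray(lat)[:, None] > th[None, :]).sum(1)
    return OrdinalOutcome([f"l{i}" for i in range(len(probs))],
                          pd.Series(codes, index=[f"s{i}" for i in
                                                  range(len(lat))]))


def empty_design(n):
    return pd.DataFrame(index=[f"s{i}" for i in range(n)])


class TestPrune:
    def test_identical_features_collapse_to_one_cluster(self):
        x = np.random.default_rng(0).normal(size=20)
        m = fm(np.column_stack([x, x, x]), ids=["b", "a", "c"])
        pr = prune(m, 1)
        assert pr.n_clusters == 1
        assert pr.representatives == ["a"]  # lexicographic tie-break

    def test_n_clusters_equal_p_is_identity(self):
        m = fm(np.random.default_rng(1).normal(size=(30, 6)))
        pr = prune(m, 6)
        assert sorted(pr.representatives) == sorted(m.feature_ids)

    def test_two_block_structure_recovered(self):
        rng = np.random.default_rng(2)
        n = 200
        a, b = rng.normal(size=n), rng.normal(size=n)
        block_a = a[:, None] + rng.normal(0, 0.23, size=(n, 5))  # rho ~ 0.95
        block_b = b[:, None] + rng.normal(0, 0.23, size=(n, 5))
        m = fm(np.column_stack([block_a, block_b]))
        pr = prune(m, 2)
        labels = pr.assignment.to_numpy()
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_anticorrelated_features_merge_under_abs_distance(self):
        x = np.random.default_rng(3).normal(size=50)
        m = fm(np.column_stack([x, -x]))
        assert prune(m, 1).n_clusters == 1
        # signed distance keeps them apart at 2 clusters
        pr = prune(m, 2, distance="one-minus-cor")
        assert pr.n_clusters == 2

    def test_errors(self):
        m = fm(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError):
            prune(m, 4)
        bad = fm(np.column_stack([np.ones(10), np.arange(10.0)]))
        with pytest.raises(ValueError, match="zero-variance"):
            prune(bad, 1)


class TestThreshold:
    def test_alpha_zero_selects_nothing(self, planted_train):
        ws = threshold_select(planted_train["X"].subset_features(
            planted_train["X"].feature_ids[:10]), planted_train["y"],
            planted_train["design"], alpha=0.0)
        assert ws.k == 0

    def test_null_selection_rate_close_to_alpha(self, rng):
        """Under a global null the per-feature selection rate is ~alpha."""
        n, p = 150, 400
        X = rng.normal(size=(n, p))
        y = outcome_from_latent(rng.logistic(size=n))
        ws = threshold_select(fm(X), y, empty_design(n), alpha=0.05)
        rate = ws.k / p
        se = np.sqrt(0.05 * 0.95 / p)
        assert abs(rate - 0.05) < 3.5 * se

    def test_liability_copy_gets_large_positive_weight(self, rng):
        n = 200
        lat = rng.logistic(size=n)
        X = np.column_stack([lat + rng.normal(0, 0.3, n), rng.normal(size=n)])
        X = (X - X.mean(0)) / X.std(0)
        y = outcome_from_latent(lat)
        ws = threshold_select(fm(X), y, empty_design(n))
        assert "f000" in ws.weights.index
        assert ws.weights["f000"] > 0.5


class TestElasticNet:
    def test_lambda_above_max_shrinks_everything(self, rng):
        n, p = 60, 8
        X = rng.normal(size=(n, p))
        y = outcome_from_latent(X[:, 0] + rng.logistic(size=n))
        ws = fit_ordinal_elasticnet(fm(X), y, empty_design(n),
                                    lambda_path=np.array([50.0, 10.0]),
                                    cv_folds=3, seed=0)
        assert ws.provenance["lambda"] in (50.0, 10.0)
        ws_big = fit_ordinal_elasticnet(fm(X), y, empty_design(n),
                                        lambda_path=np.array([1e3, 999.0]),
                                        cv_folds=3, seed=0)
        assert ws_big.k == 0

    def test_unpenalized_limit_matches_mle(self, rng):
        """At lambda ~ 0 the elastic-net slopes equal the unpenalized MLE."""
        n, p = 40, 5
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = outcome_from_latent(X[:, 0] * 0.8 + rng.logistic(size=n),
                                probs=(0.3, 0.4, 0.3))
        ws = fit_ordinal_elasticnet(fm(X), y, empty_design(n),
                                    lambda_path=np.array([1e-7, 1e-8]),
                                    cv_folds=2, seed=0, maxiter=3000)
        mle = OrderedLogit(y.codes.to_numpy(), X, ridge_eps=0.0).fit()
        full = pd.Series(0.0, index=[f"f{j:03d}" for j in range(p)])
        full[ws.weights.index] = ws.weights
        np.testing.assert_allclose(full.to_numpy(), mle.params, atol=1e-4)

    def test_solution_is_local_minimum_of_penalized_objective(self, rng):
        n, p = 40, 5
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        codes = outcome_from_latent(X[:, 0] + rng.logistic(size=n))
        lam, mix = 0.05, 0.5
        from psomics.selection import _prox_fit
        from psomics.ordinal import null_thresholds
        model = OrderedLogit(codes.codes.to_numpy(), X, ridge_eps=0.0)
        L = model.n_levels
        thr0 = null_thresholds(np.bincount(model.endog))
        t0 = np.concatenate([[thr0[0]], np.log(np.diff(thr0)), np.zeros(p)])
        t_hat = _prox_fit(model, p, lam, mix, t0, maxiter=2000)

        def objective(t):
            ll, _ = model.loglike_grad_t(t)
            b = t[L - 1:]
            return (-ll / model.nobs + lam * (mix * np.abs(b).sum()
                                              + (1 - mix) / 2 * b @ b))

        base = objective(t_hat)
        for _ in range(200):
            assert objective(t_hat + rng.normal(scale=1e-3,
                                                size=t_hat.size)) >= base - 1e-9

    def test_nondecreasing_path_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        y = outcome_from_latent(rng.logistic(size=30))
        with pytest.raises(ValueError, match="decreasing"):
            fit_ordinal_elasticnet(fm(X), y, empty_design(30),
                                   lambda_path=np.array([0.1, 0.2]))


class TestBoosting:
    def test_mstop_zero_gives_empty_weights(self, rng):
        X = rng.normal(size=(40, 4))
        y = outcome_from_latent(rng.logistic(size=40))
        ws = fit_ordinal_boosting(fm(X), y, empty_design(40), mstop=0)
        assert ws.k == 0

    def test_training_loss_non_increasing(self, rng):
        n, p = 80, 10
        X = rng.normal(size=(n, p))
        y = outcome_from_latent(X[:, 0] + rng.logistic(size=n))
        ws = fit_ordinal_boosting(fm(X), y, empty_design(n), mstop=150,
                                  val_fraction=0.25, seed=3)
        losses = ws.provenance["train_losses"]
        assert np.all(np.diff(losses) <= 1e-9)

    def test_converges_to_mle_in_low_dimension(self, rng):
        """With mstop large and no early stopping, componentwise boosting
        approaches the unpenalized proportional-odds MLE (within 5%)."""
        n, p = 60, 3
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = outcome_from_latent(0.9 * X[:, 0] - 0.5 * X[:, 1]
                                + rng.logistic(size=n), probs=(0.3, 0.4, 0.3))
        ws = fit_ordinal_boosting(fm(X), y, empty_design(n), nu=0.1,
                                  mstop=5000, val_fraction=0.0, seed=0)
        mle = OrderedLogit(y.codes.to_numpy(), X, ridge_eps=0.0).fit()
        est = pd.Series(0.0, index=[f"f{j:03d}" for j in range(p)])
        est[ws.weights.index] = ws.weights
        scale = np.abs(mle.params).max()
        np.testing.assert_allclose(est.to_numpy(), mle.params,
                                   atol=0.05 * scale)

    def test_negative_mstop_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        y = outcome_from_latent(rng.logistic(size=20))
        with pytest.raises(ValueError):
            fit_ordinal_boosting(fm(X), y, empty_design(20), mstop=-1)


class TestRandomForest:
    def test_null_importances_small_and_unstable(self, rng):
        """With the outcome independent of all features, positive-VIM
        selections are unstable across seeds (chance-level overlap) and the
        importance magnitudes are tiny compared to a planted signal."""
        n, p = 80, 60
        X = rng.normal(size=(n, p))
        y = outcome_from_latent(rng.logistic(size=n))
        sels, max_null = [], 0.0
        for seed in range(6):
            ws = fit_rf_vim(fm(X), y, empty_design(n), n_trees=100, seed=seed)
            sels.append(set(ws.weights.index))
            max_null = max(max_null, ws.weights.abs().max())
        stable = set.intersection(*sels)
        assert len(stable) < 0.2 * p  # no consistently "important" feature
        # a planted outcome copy dwarfs every null importance
        Xs = X.copy()
        Xs[:, 0] = y.codes.to_numpy() + rng.normal(0, 0.05, n)
        ws_sig = fit_rf_vim(fm(Xs), y, empty_design(n), n_trees=100, seed=0)
        assert ws_sig.weights["f000"] > 5 * max_null

    def test_outcome_copy_dominates_importance(self, rng):
        n, p = 100, 10
        X = rng.normal(size=(n, p))
        y = outcome_from_latent(rng.logistic(size=n))
        X[:, 3] = y.codes.to_numpy() + rng.normal(0, 0.05, n)
        ws = fit_rf_vim(fm(X), y, empty_design(n), n_trees=200, seed=1)
        assert ws.weights.abs().idxmax() == "f003"
        assert ws.weights["f003"] > 0

    def test_weights_carry_marginal_spearman_sign(self, rng):
        from scipy.stats import spearmanr
        n, p = 90, 8
        X = rng.normal(size=(n, p))
        lat = X[:, 0] - X[:, 1] + rng.logistic(size=n)
        y = outcome_from_latent(lat)
        ws = fit_rf_vim(fm(X), y, empty_design(n), n_trees=200, seed=2)
        codes = y.codes.to_numpy()
        for fid, w in ws.weights.items():
            j = int(fid[1:])
            rho = spearmanr(X[:, j], codes).statistic
            assert np.sign(w) == np.sign(rho)

    def test_deterministic_given_seed(self, rng):
        n, p = 60, 12
        X = rng.normal(size=(n, p))
        y = outcome_from_latent(X[:, 0] + rng.logistic(size=n))
        a = fit_rf_vim(fm(X), y, empty_design(n), n_trees=50, seed=7)
        b = fit_rf_vim(fm(X), y, empty_design(n), n_trees=50, seed=7)
        pd.testing.assert_series_equal(a.weights, b.weights)


class TestCrossLeverage:
    def test_matches_bruteforce_svd_on_five_features(self, rng):
        n, p = 30, 5
        X = rng.normal(size=(n, p))
        lat = X[:, 2] + 0.1 * rng.logistic(size=n)
        y = outcome_from_latent(lat)
        ws = cross_leverage_screen(fm(X), y, window=5, q=5, rank_r=3)
        # brute-force oracle
        Z = np.column_stack([X, y.codes.to_numpy().astype(float)])
        Z = (Z - Z.mean(0)) / Z.std(0)
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        V = Vt[:3].T
        c = V[:-1] @ V[-1]
        for j in range(p):
            fid = f"f{j:03d}"
            if fid in ws.weights.index:
                assert ws.weights[fid] == pytest.approx(c[j], abs=1e-10)
        # the feature proportional to the outcome attains the largest |c|
        assert ws.weights.abs().idxmax() == "f002"

    def test_invariant_to_feature_rescaling(self, rng):
        n, p = 40, 8
        X = rng.normal(size=(n, p))
        y = outcome_from_latent(X[:, 1] + rng.logistic(size=n))
        a = cross_leverage_screen(fm(X), y, window=8, q=8, rank_r=4)
        X2 = X.copy()
        X2[:, 1] *= 10.0
        b = cross_leverage_screen(fm(X2), y, window=8, q=8, rank_r=4)
        pd.testing.assert_series_equal(a.weights, b.weights, atol=1e-10)

    def test_cauchy_schwarz_bound_on_scores(self, rng):
        n, p = 35, 12
        X = rng.normal(size=(n, p))
        y = outcome_from_latent(rng.logistic(size=n))
        r = 5
        ws = cross_leverage_screen(fm(X), y, window=12, q=12, rank_r=r)
        Z = np.column_stack([(X - X.mean(0)) / X.std(0),
                             _std(y.codes.to_numpy())])
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        V = Vt[:r].T
        proj = V @ V.T
        for fid, c in ws.weights.items():
            j = int(fid[1:])
            assert abs(c) <= np.sqrt(proj[j, j] * proj[-1, -1]) + 1e-12

    def test_full_rank_configuration_rejected(self, rng):
        X = rng.normal(size=(50, 10))
        y = outcome_from_latent(rng.logistic(size=50))
        with pytest.raises(ValueError, match="identity"):
            cross_leverage_screen(fm(X), y, window=10, q=3)

    def test_null_scores_below_signal_scores(self, rng):
        """Orthogonal outcome: all |c_j| stay below the score of a planted
        exact copy of the outcome."""
        n = 60
        Xn = rng.normal(size=(n, 6))
        yc = rng.logistic(size=n)
        y = outcome_from_latent(yc)
        null_ws = cross_leverage_screen(fm(Xn), y, window=6, q=6, rank_r=3)
        Xs = np.column_stack([Xn[:, :5], y.codes.to_numpy()
                              + rng.normal(0, 1e-6, n)])
        sig_ws = cross_leverage_screen(fm(Xs), y, window=6, q=6, rank_r=3)
        assert sig_ws.weights.abs().max() > null_ws.weights.abs().max()


def _std(v):
    v = np.asarray(v, dtype=float)
    return (v - v.mean()) / v.std()


class TestCompose:
    def test_prune_identity_then_en_equals_en(self, rng):
        n, p = 50, 6
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = outcome_from_latent(X[:, 0] + rng.logistic(size=n))
        direct = fit_ordinal_elasticnet(fm(X), y, empty_design(n), seed=4,
                                        n_lambda=20, cv_folds=3)
        composed = compose(("PT", "EN"), fm(X), y, empty_design(n), seed=4,
                           config={"n_clusters": p, "n_lambda": 20,
                                   "cv_folds": 3})
        joint = direct.weights.align(composed.weights, fill_value=0.0)
        np.testing.assert_allclose(joint[0].sort_index().to_numpy(),
                                   joint[1].sort_index().to_numpy(), atol=1e-3)

    def test_planted_block_yields_single_representative(self, rng):
        """Two equicorrelated blocks, one causal: PT selects exactly one
        representative of the causal block."""
        n = 300
        a, b = rng.normal(size=n), rng.normal(size=n)
        causal_block = a[:, None] + rng.normal(0, 0.1, size=(n, 5))
        null_block = b[:, None] + rng.normal(0, 0.1, size=(n, 5))
        X = np.column_stack([causal_block, null_block])
        X = (X - X.mean(0)) / X.std(0)
        y = outcome_from_latent(1.5 * a + rng.logistic(size=n))
        ws = compose(("PT",), fm(X), y, empty_design(n), config={"n_clusters": 2})
        assert ws.k == 1
        assert int(ws.weights.index[0][1:]) < 5  # from the causal block

    def test_empty_intermediate_set_warns_and_returns_empty(self, rng):
        n = 40
        X = rng.normal(size=(n, 6))
        y = outcome_from_latent(rng.logistic(size=n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ws = compose(("WA", "EN"), fm(X), y, empty_design(n),
                         config={"q": 1, "window": 6, "rank_r": 3})
        assert ws.method == "WA+EN"

    def test_unknown_chain_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = outcome_from_latent(rng.logistic(size=20))
        with pytest.raises(ValueError, match="chain"):
            compose(("EN", "PT"), fm(X), y, empty_design(20))


def test_weightset_drops_zero_weights_and_validates():
    w = pd.Series([0.5, 0.0, -1.0], index=["a", "b", "c"])
    ws = WeightSet("PT", "dnam", w)
    assert ws.k == 2 and "b" not in ws.weights.index
    with pytest.raises(ValueError, match="duplicate"):
        WeightSet("PT", "dnam", pd.Series([1.0, 2.0], index=["a", "a"]))
    with pytest.raises(ValueError, match="finite"):
        WeightSet("PT", "dnam", pd.Series([np.inf], index=["a"]))


def test_methods_are_pure_functions_of_seed(planted_train):
    """Repeated calls with identical inputs give bit-identical weights."""
    X = planted_train["X"].subset_features(planted_train["X"].feature_ids[:40])
    y, Z = planted_train["y"], planted_train["design"]
    for maker in (lambda: fit_rf_vim(X, y, Z, n_trees=60, seed=5),
                  lambda: fit_ordinal_boosting(X, y, Z, mstop=60, seed=5),
                  lambda: threshold_select(X, y, Z)):
        a, b = maker(), maker()
        pd.testing.assert_series_equal(a.weights, b.weights)
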