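"""From-scratch boosted trees: derivatives, greedy splits, boosting, tuning."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ptosiskit import gbm
from ptosiskit.errors import ConfigurationError, FitError, PredictError
from ptosiskit.gbm import BoostConfig, HyperGrid


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_tree(X, g, h, lam, max_depth, min_gain=0.0, depth=0):
    """Exhaustive-enumeration CART oracle (no prefix sums, no sorting tricks).

    Scans every (feature, observed midpoint) pair with direct masked sums;
    same tie rule as the implementation: first feature, lowest threshold,
    strict improvement.
    """
    G, H = g.sum(), h.sum()
    leaf = ("leaf", -G / (H + lam))
    if depth >= max_depth or len(X) < 2:
        return leaf

    def gain_of(GL, HL, GR, HR):
        return 0.5 * (
            GL**2 / (HL + lam) + GR**2 / (HR + lam) - (GL + GR) ** 2 / (HL + HR + lam)
        )

    best = (0.0, None, None)
    for j in range(X.shape[1]):
        for thr in sorted({0.5 * (a + b) for a, b in zip(sorted(set(X[:, j]))[:-1], sorted(set(X[:, j]))[1:])}):
            mask = X[:, j] <= thr
            gain = gain_of(g[mask].sum(), h[mask].sum(), g[~mask].sum(), h[~mask].sum())
            if gain > best[0] + 1e-12:
                best = (gain, j, thr)
    if best[1] is None or best[0] <= min_gain:
        return leaf
    mask = X[:, best[1]] <= best[2]
    return (
        "split",
        best[1],
        best[2],
        brute_force_tree(X[mask], g[mask], h[mask], lam, max_depth, min_gain, depth + 1),
        brute_force_tree(X[~mask], g[~mask], h[~mask], lam, max_depth, min_gain, depth + 1),
    )


def oracle_predict(node, row):
    if node[0] == "leaf":
        return node[1]
    _, j, thr, left, right = node
    return oracle_predict(left if row[j] <= thr else right, row)


def pairwise_auc(labels, scores):
    """O(n^2) pairwise-ranking AUC with ties counted half."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# loss derivatives


class TestLogisticGradHess:
    def test_midpoint(self):
        g, h = gbm.logistic_grad_hess(np.array([1]), np.array([0.0]))
        assert g[0] == pytest.approx(-0.5) and h[0] == pytest.approx(0.25)

    def test_saturation(self):
        g, h = gbm.logistic_grad_hess(np.array([0]), np.array([30.0]))
        assert g[0] == pytest.approx(1.0, abs=1e-9)
        assert h[0] == pytest.approx(0.0, abs=1e-9)

    def test_balanced_labels_zero_mean_gradient(self):
        y = np.array([0, 1] * 10)
        g, _ = gbm.logistic_grad_hess(y, np.zeros(20))
        assert g.sum() == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# tree fitting


class TestFitCart:
    def test_zero_gradients_single_leaf(self):
        X = np.arange(8, dtype=float).reshape(-1, 1)
        tree = gbm.fit_cart(X, np.zeros(8), np.ones(8), BoostConfig(lambda_reg=0.0))
        assert tree.root.is_leaf and tree.root.weight == pytest.approx(0.0)

    def test_depth_zero_newton_leaf(self):
        X = np.arange(4, dtype=float).reshape(-1, 1)
        g = np.array([1.0, 1.0, -1.0, 3.0])
        h = np.full(4, 2.0)
        tree = gbm.fit_cart(X, g, h, BoostConfig(max_depth=0, lambda_reg=1.0))
        assert tree.root.is_leaf
        assert tree.root.weight == pytest.approx(-g.sum() / (h.sum() + 1.0))

    def test_toy_split_between_groups(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        g = np.array([-1.0, -1.0, 1.0, 1.0])
        h = np.ones(4)
        tree = gbm.fit_cart(X, g, h, BoostConfig(max_depth=1, lambda_reg=0.0))
        assert tree.root.threshold == pytest.approx(1.5)
        assert tree.root.left.weight == pytest.approx(1.0)
        assert tree.root.right.weight == pytest.approx(-1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(FitError):
            gbm.fit_cart(np.empty((0, 2)), np.array([]), np.array([]))

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_exhaustive_enumeration_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = rng.integers(2, 51)
        d = rng.integers(1, 4)
        X = np.round(rng.normal(size=(n, d)), 3)
        g = rng.normal(size=n)
        h = rng.uniform(0.1, 2.0, size=n)
        lam = float(rng.choice([0.0, 1.0]))
        depth = int(rng.integers(1, 4))
        cfg = BoostConfig(max_depth=depth, lambda_reg=lam)
        tree = gbm.fit_cart(X, g, h, cfg)
        oracle = brute_force_tree(X, g, h, lam, depth)
        pred = tree.predict(X)
        expected = np.array([oracle_predict(oracle, row) for row in X])
        np.testing.assert_allclose(pred, expected, atol=1e-9)

    @given(lams=st.tuples(st.floats(0.0, 10.0), st.floats(0.0, 10.0)))
    def test_leaf_weight_shrinks_with_regularization(self, lams):
        """|w| = |G|/(H + lambda) is non-increasing in lambda."""
        G, H = 3.0, 2.0
        lo, hi = sorted(lams)
        assert abs(-G / (H + hi)) <= abs(-G / (H + lo)) + 1e-12


# ---------------------------------------------------------------------------
# boosting


def _toy_task(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = (X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.normal(size=n) > 0).astype(int)
    return X, y


class TestBoostFit:
    def test_eta_zero_not_allowed_but_empty_rounds_constant(self):
        X, y = _toy_task()
        model = gbm.boost_fit(X, y, BoostConfig(n_rounds=0, base_score=0.5))
        np.testing.assert_allclose(gbm.predict_proba(model, X), 0.5)

    def test_single_newton_stump_matches_brute_force(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        cfg = BoostConfig(eta=1.0, n_rounds=1, max_depth=1, lambda_reg=0.0, base_score=0.5)
        model = gbm.boost_fit(X, y, cfg)
        g, h = gbm.logistic_grad_hess(y, np.zeros(4))
        oracle = brute_force_tree(X, g, h, 0.0, 1)
        expected = gbm.sigmoid(np.array([oracle_predict(oracle, row) for row in X]))
        np.testing.assert_allclose(gbm.predict_proba(model, X), expected, atol=1e-12)

    def test_training_logloss_non_increasing(self):
        X, y = _toy_task(seed=3)
        model = gbm.boost_fit(X, y, BoostConfig(eta=0.3, n_rounds=40, max_depth=3))
        losses = np.array(model.train_loss)
        assert np.all(np.diff(losses) <= 1e-12)

    def test_single_class_warns(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.warns(UserWarning, match="single-class"):
            model = gbm.boost_fit(X, np.ones(10), BoostConfig(n_rounds=3))
        assert np.all(gbm.predict_proba(model, X) > 0.5)

    def test_margin_update_scales_linearly_with_eta(self):
        """Per-round margin updates are exactly eta times the tree output."""
        X, y = _toy_task(seed=5)
        updates = {}
        for eta in (0.1, 0.2):
            model = gbm.boost_fit(X, y, BoostConfig(eta=eta, n_rounds=1, max_depth=2))
            tree, used_eta = model.trees[0]
            assert used_eta == eta
            updates[eta] = used_eta * tree.predict(X)
        np.testing.assert_allclose(2.0 * updates[0.1], updates[0.2], atol=1e-12)


class TestPredictProba:
    def test_empty_ensemble_returns_base_score(self):
        model = gbm.BoostedEnsemble(base_score=0.5, n_features=2)
        np.testing.assert_allclose(gbm.predict_proba(model, np.zeros((5, 2))), 0.5)

    def test_probabilities_monotone_on_sorted_input(self):
        X = np.linspace(-2, 2, 50).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(int)
        model = gbm.boost_fit(X, y, BoostConfig(eta=0.3, n_rounds=20, max_depth=2))
        p = gbm.predict_proba(model, X)
        assert np.all(np.diff(p) >= -1e-12)

    def test_feature_count_mismatch(self):
        X, y = _toy_task()
        model = gbm.boost_fit(X, y, BoostConfig(n_rounds=2))
        with pytest.raises(PredictError):
            gbm.predict_proba(model, np.zeros((3, 5)))

    def test_matches_reference_xgboost(self):
        """Cross-implementation check against xgboost at matched settings."""
        xgboost = pytest.importorskip("xgboost")
        X, y = _toy_task(n=120, seed=7)
        cfg = BoostConfig(eta=0.3, n_rounds=25, max_depth=3, lambda_reg=1.0, base_score=0.5)
        ours = gbm.predict_proba(gbm.boost_fit(X, y, cfg), X)
        booster = xgboost.train(
            {
                "objective": "binary:logistic",
                "eta": cfg.eta,
                "max_depth": cfg.max_depth,
                "lambda": cfg.lambda_reg,
                "base_score": cfg.base_score,
                "tree_method": "exact",
                "min_child_weight": 0.0,
                "gamma": 0.0,
            },
            xgboost.DMatrix(X, label=y),
            num_boost_round=cfg.n_rounds,
        )
        theirs = booster.predict(xgboost.DMatrix(X))
        assert np.mean(np.abs(ours - theirs)) < 0.05

    def test_serialization_roundtrip(self):
        X, y = _toy_task()
        model = gbm.boost_fit(X, y, BoostConfig(n_rounds=5))
        back = gbm.BoostedEnsemble.from_json(model.to_json())
        np.testing.assert_allclose(gbm.predict_proba(back, X), gbm.predict_proba(model, X))


# ---------------------------------------------------------------------------
# grid search


class TestGridSearch:
    def test_singleton_grid(self):
        X, y = _toy_task()
        grid = HyperGrid(params={"eta": [0.2]})
        cfg = gbm.grid_search(X, y, grid, seed=0)
        assert cfg.eta == 0.2

    def test_picks_lower_validation_loss_and_matches_exhaustive(self):
        X, y = _toy_task(n=100, seed=2)
        grid = HyperGrid(params={"eta": [0.1], "n_rounds": [2, 60]})
        best = gbm.grid_search(X, y, grid, seed=1)
        # exhaustive evaluation with the same carve-out
        losses = {}
        rng = np.random.default_rng(1)
        val_idx = []
        for cls in np.unique(y):
            idx = np.nonzero(y == cls)[0]
            k = max(1, int(round(0.25 * len(idx))))
            val_idx.extend(rng.permutation(idx)[:k].tolist())
        mask = np.zeros(len(y), dtype=bool)
        mask[val_idx] = True
        for cfg in grid.configs():
            m = gbm.boost_fit(X[~mask], y[~mask], cfg)
            losses[cfg.n_rounds] = gbm.log_loss(y[mask], gbm.predict_margin(m, X[mask]))
        assert best.n_rounds == min(losses, key=losses.get)
        assert losses[60] < losses[2]

    def test_deterministic_selection(self):
        X, y = _toy_task(n=80, seed=4)
        grid = HyperGrid(params={"eta": [0.05, 0.3], "max_depth": [2, 3]})
        assert gbm.grid_search(X, y, grid, seed=5) == gbm.grid_search(X, y, grid, seed=5)

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            gbm.grid_search(*_toy_task(), HyperGrid(params={}))
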