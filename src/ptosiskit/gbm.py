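"""Gradient-boosted CART binary classifier, written from first principles.

The model is the additive ensemble F(x) = f0 + sum_m eta * h_m(x), where
f0 is the log-odds of ``base_score``, each h_m is a regression tree
fitted to the first- and second-order derivatives (g, h) of the logistic
loss at the current margins, and eta is a constant per-round shrinkage
("learning rate") that damps every leaf weight.  Trees are grown greedily:
at each node the split maximizing the second-order gain

    gain = 1/2 * [ G_L^2/(H_L + lambda) + G_R^2/(H_R + lambda)
                   - (G_L + G_R)^2 / (H_L + H_R + lambda) ]

over all features and observed midpoints is taken (ties broken by lowest
feature index, then lowest threshold), subject to a minimum gain and a
depth bound; leaf weights are the regularized Newton step -G/(H + lambda).
There is no row/column subsampling and no early stopping; the number of
rounds is fixed (and grid-searched).  Hyperparameters are tuned by
exhaustive grid search against log-loss on a validation subset carved
from the training rows.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import ConfigurationError, FitError, PredictError

_MARGIN_CLAMP = 30.0


@dataclass(frozen=True)
class BoostConfig:
    """Hyperparameters of the boosted ensemble.

    eta: per-round shrinkage in (0, 1]; n_rounds: number of trees;
    max_depth: tree depth bound (0 = a single leaf); lambda_reg: L2
    regularizer on leaf weights; min_split_gain: minimum gain to accept a
    split; base_score: prior positive probability in (0, 1).
    """

    eta: float = 0.1
    n_rounds: int = 100
    max_depth: int = 3
    lambda_reg: float = 1.0
    min_split_gain: float = 0.0
    base_score: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.eta <= 1.0):
            raise ConfigurationError(f"eta must be in (0, 1], got {self.eta}")
        if self.n_rounds < 0 or self.max_depth < 0:
            raise ConfigurationError("n_rounds and max_depth must be >= 0")
        if self.lambda_reg < 0 or self.min_split_gain < 0:
            raise ConfigurationError("lambda_reg and min_split_gain must be >= 0")
        if not (0.0 < self.base_score < 1.0):
            raise ConfigurationError(f"base_score must be in (0, 1), got {self.base_score}")


@dataclass
class TreeNode:
    """One node of a regression tree: an internal split or a leaf."""

    weight: float = 0.0
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.weight}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "leaf" in d:
            return cls(weight=float(d["leaf"]))
        return cls(
            feature=int(d["feature"]),
            threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class RegressionTree:
    """A CART regressor predicting a leaf weight per row (x <= t goes left)."""

    root: TreeNode

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.weight
        return out


@dataclass
class BoostedEnsemble:
    """Fitted additive model: base score, shrunken trees, loss trace."""

    base_score: float
    trees: list[tuple[RegressionTree, float]] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    n_features: int | None = None

    @property
    def base_margin(self) -> float:
        return float(np.log(self.base_score / (1.0 - self.base_score)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "base_score": self.base_score,
                "n_features": self.n_features,
                "train_loss": self.train_loss,
                "trees": [{"eta": eta, "root": t.root.to_dict()} for t, eta in self.trees],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "BoostedEnsemble":
        d = json.loads(text)
        return cls(
            base_score=float(d["base_score"]),
            trees=[
                (RegressionTree(TreeNode.from_dict(t["root"])), float(t["eta"]))
                for t in d["trees"]
            ],
            train_loss=[float(v) for v in d["train_loss"]],
            n_features=d.get("n_features"),
        )


@dataclass
class HyperGrid:
    """Candidate hyperparameter values for exhaustive grid search.

    ``params`` maps :class:`BoostConfig` field names to candidate lists;
    combinations are enumerated in insertion/product order, which also
    defines tie-breaking.  ``validation_fraction`` of the training rows
    is held out for selection by log-loss.
    """

    params: dict[str, list] = field(
        default_factory=lambda: {
            "eta": [0.05, 0.1, 0.3],
            "max_depth": [2, 3, 4],
            "n_rounds": [50, 100, 200],
            "lambda_reg": [0.0, 1.0],
        }
    )
    validation_fraction: float = 0.25
    base: BoostConfig = field(default_factory=BoostConfig)

    def validate(self) -> None:
        if not self.params or any(len(v) == 0 for v in self.params.values()):
            raise ConfigurationError("hyperparameter grid must be non-empty")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ConfigurationError("validation_fraction must be in (0, 1)")
        unknown = set(self.params) - set(asdict(self.base))
        if unknown:
            raise ConfigurationError(f"unknown BoostConfig fields in grid: {sorted(unknown)}")

    def configs(self) -> Iterator[BoostConfig]:
        keys = list(self.params)
        for combo in itertools.product(*(self.params[k] for k in keys)):
            yield replace(self.base, **dict(zip(keys, combo)))


# ---------------------------------------------------------------------------
# loss derivatives


def sigmoid(f: np.ndarray) -> np.ndarray:
    f = np.clip(f, -_MARGIN_CLAMP, _MARGIN_CLAMP)
    return 1.0 / (1.0 + np.exp(-f))


def logistic_grad_hess(y: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivatives of the logistic loss at margins f.

    With p = sigmoid(f): g = p - y, h = p(1 - p).  Margins are clamped to
    +/-30 before exponentiation.
    """
    y = np.asarray(y, dtype=float)
    p = sigmoid(np.asarray(f, dtype=float))
    return p - y, p * (1.0 - p)


def log_loss(y: np.ndarray, f: np.ndarray) -> float:
    """Mean logistic loss of labels y at margins f."""
    p = sigmoid(np.asarray(f, dtype=float))
    p = np.clip(p, 1e-15, 1 - 1e-15)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# tree growing


def _split_gain(GL: float, HL: float, GR: float, HR: float, lam: float) -> float:
    tot = (GL + GR) ** 2 / (HL + HR + lam)
    return 0.5 * (GL * GL / (HL + lam) + GR * GR / (HR + lam) - tot)


def _best_split(
    X: np.ndarray, g: np.ndarray, h: np.ndarray, lam: float
) -> tuple[float, int | None, float | None]:
    """Scan all features and observed midpoints for the max-gain split.

    Ties are broken by lowest feature index, then lowest threshold
    (features scanned in order, thresholds ascending, strict improvement
    required).
    """
    best_gain, best_feat, best_thr = 0.0, None, None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs, gs, hs = X[order, j], g[order], h[order]
        Gc, Hc = np.cumsum(gs), np.cumsum(hs)
        G, H = Gc[-1], Hc[-1]
        boundary = np.nonzero(np.diff(xs) > 0)[0]  # split after position i
        for i in boundary:
            gain = _split_gain(Gc[i], Hc[i], G - Gc[i], H - Hc[i], lam)
            if gain > best_gain + 1e-12:
                best_gain = gain
                best_feat = j
                best_thr = 0.5 * (xs[i] + xs[i + 1])
    return best_gain, best_feat, best_thr


def _grow(
    X: np.ndarray, g: np.ndarray, h: np.ndarray, config: BoostConfig, depth: int
) -> TreeNode:
    lam = config.lambda_reg
    G, H = float(g.sum()), float(h.sum())
    leaf = TreeNode(weight=-G / (H + lam) if (H + lam) > 0 else 0.0)
    if depth >= config.max_depth or len(X) < 2:
        return leaf
    gain, feat, thr = _best_split(X, g, h, lam)
    if feat is None or gain <= config.min_split_gain:
        return leaf
    mask = X[:, feat] <= thr
    return TreeNode(
        weight=leaf.weight,
        feature=feat,
        threshold=thr,
        left=_grow(X[mask], g[mask], h[mask], config, depth + 1),
        right=_grow(X[~mask], g[~mask], h[~mask], config, depth + 1),
    )


def fit_cart(
    X: np.ndarray, g: np.ndarray, h: np.ndarray, config: BoostConfig = BoostConfig()
) -> RegressionTree:
    """Grow one greedy second-order regression tree on gradients (g, h)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    g = np.asarray(g, dtype=float).ravel()
    h = np.asarray(h, dtype=float).ravel()
    if len(X) == 0:
        raise FitError("cannot fit a tree on zero rows")
    if not (len(X) == len(g) == len(h)):
        raise FitError("X, g, h row counts differ")
    config.validate()
    return RegressionTree(_grow(X, g, h, config, depth=0))


# ---------------------------------------------------------------------------
# boosting


def boost_fit(
    X: np.ndarray, y: np.ndarray, config: BoostConfig = BoostConfig()
) -> BoostedEnsemble:
    """Fit the boosted ensemble by sequential Newton-step trees.

    Each round fits a tree to (g, h) at the current margins and advances
    the margins by ``eta`` times its predictions; the training log-loss
    is recorded per round.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != len(y):
        raise FitError("X and y row counts differ")
    if len(X) == 0:
        raise FitError("cannot boost on zero rows")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise FitError("labels must be 0/1")
    config.validate()
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: the fit yields a near-constant model", stacklevel=2)

    model = BoostedEnsemble(base_score=config.base_score, n_features=X.shape[1])
    margins = np.full(len(y), model.base_margin)
    for _ in range(config.n_rounds):
        g, h = logistic_grad_hess(y, margins)
        tree = fit_cart(X, g, h, config)
        margins = margins + config.eta * tree.predict(X)
        model.trees.append((tree, config.eta))
        model.train_loss.append(log_loss(y, margins))
    return model


def predict_margin(model: BoostedEnsemble, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.n_features is not None and X.shape[1] != model.n_features:
        raise PredictError(
            f"feature count {X.shape[1]} does not match training ({model.n_features})"
        )
    f = np.full(len(X), model.base_margin)
    for tree, eta in model.trees:
        f += eta * tree.predict(X)
    return f


def predict_proba(model: BoostedEnsemble, X: np.ndarray) -> np.ndarray:
    """Positive-class probability sigmoid(F(x)), strictly inside (0, 1)."""
    return sigmoid(predict_margin(model, X))


# ---------------------------------------------------------------------------
# hyperparameter search


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperGrid = HyperGrid(),
    seed: int = 0,
) -> BoostConfig:
    """Pick the grid point minimizing validation log-loss.

    A stratified validation subset is carved from the provided training
    rows with the given seed; every configuration in the grid is fitted
    on the remainder and scored on it.  Ties keep the earliest
    configuration in enumeration order.
    """
    grid.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)

    val_idx: list[int] = []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        k = max(1, int(round(grid.validation_fraction * len(idx))))
        k = min(k, len(idx) - 1) if len(idx) > 1 else 0
        val_idx.extend(rng.permutation(idx)[:k].tolist())
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True
    if not val_mask.any() or val_mask.all():
        raise ConfigurationError("too few rows to carve a validation subset")

    best_cfg, best_loss = None, np.inf
    for cfg in grid.configs():
        model = boost_fit(X[~val_mask], y[~val_mask], cfg)
        loss = log_loss(y[val_mask], predict_margin(model, X[val_mask]))
        if loss < best_loss - 1e-12:
            best_loss, best_cfg = loss, cfg
    assert best_cfg is not None
    return best_cfg


def save_model(model: BoostedEnsemble, path: str | Path) -> None:
    Path(path).write_text(model.to_json())


def load_model(path: str | Path) -> BoostedEnsemble:
    return BoostedEnsemble.from_json(Path(path).read_text())
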