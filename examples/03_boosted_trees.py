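"""Fit the from-scratch boosted-tree classifier on a toy task.

Each round fits a CART tree to the logistic-loss gradients at the
current margins and shrinks its leaf weights by the learning rate eta;
the training log-loss therefore decreases monotonically.
"""

import numpy as np

from ptosiskit.gbm import BoostConfig, HyperGrid, boost_fit, grid_search, predict_proba

rng = np.random.default_rng(0)
X = rng.normal(size=(200, 3))
y = (X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.normal(size=200) > 0).astype(int)

config = BoostConfig(eta=0.3, n_rounds=30, max_depth=3)
model = boost_fit(X, y, config)
p = predict_proba(model, X)
print(f"training log-loss: round 1 = {model.train_loss[0]:.4f}, "
      f"round 30 = {model.train_loss[-1]:.4f} (non-increasing)")
print(f"training accuracy: {np.mean((p >= 0.5) == y):.3f}")

grid = HyperGrid(params={"eta": [0.1, 0.3], "max_depth": [2, 3], "n_rounds": [20, 50]})
best = grid_search(X, y, grid, seed=1)
print(f"grid search picked eta={best.eta}, depth={best.max_depth}, "
      f"rounds={best.n_rounds} by validation log-loss")
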