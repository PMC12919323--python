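"""Feedforward neural baseline for the growth relations.

A single-hidden-layer network (10 tanh units, linear output) regresses
height on DBH, or DBH on age, optionally with the screened environmental
covariates as extra inputs.  Training is full-batch Levenberg–Marquardt on
the L2-penalized squared loss (weight decay 0.001 on weights, not biases),
with the damping parameter initialized from the configured learning rate
and adapted multiplicatively.  Inputs and the response are z-scored with
training-split statistics; predictions are returned on the original scale.
Early stopping monitors the validation split and the weight snapshot with
the best validation loss is retained.  A damped Gauss–Newton variant
(fixed damping) and a first-order fallback (scikit-learn's Adam-trained
MLP) are provided for comparison.

Identical seed, data and config give bitwise-identical trained weights:
initialization is the only random element and the optimizer is
deterministic full-batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import _largest_remainder_sizes
from .errors import ConvergenceError, SchemaError


@dataclass(frozen=True)
class NNConfig:
    hidden_units: int = 10
    l2_weight_decay: float = 0.001
    learning_rate: float = 0.01
    optimizer: str = "levenberg_marquardt"
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    early_stopping_patience: int = 20
    max_epochs: int = 1000
    seed: int = 0


@dataclass
class Network:
    """Trained network plus its standardization constants."""

    W1: np.ndarray  # (hidden, d)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: float
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    feature_names: tuple[str, ...] | None = None
    config: NNConfig | None = None

    def _forward_std(self, Xs: np.ndarray) -> np.ndarray:
        a = np.tanh(Xs @ self.W1.T + self.b1)
        return a @ self.W2 + self.b2

    def predict(self, features) -> np.ndarray:
        Xs = (_coerce_features(features, self.feature_names) - self.x_mean) / self.x_std
        return self._forward_std(Xs) * self.y_std + self.y_mean

    def to_dict(self) -> dict:
        return {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": float(self.b2),
            "x_mean": self.x_mean.tolist(), "x_std": self.x_std.tolist(),
            "y_mean": float(self.y_mean), "y_std": float(self.y_std),
            "feature_names": list(self.feature_names or []),
        }


def _coerce_features(features, expected_names=None) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        if expected_names:
            missing = [c for c in expected_names if c not in features.columns]
            if missing:
                raise SchemaError(f"missing features: {missing}")
            features = features[list(expected_names)]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if expected_names and X.shape[1] != len(expected_names):
            raise SchemaError(
                f"expected {len(expected_names)} features, got {X.shape[1]}"
            )
    return X


def nn_predict(network: Network, features) -> np.ndarray:
    """Apply the stored standardization, then the network. Deterministic."""
    return network.predict(features)


def _r2(y, yhat) -> float:
    sstot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum((y - yhat) ** 2) / sstot) if sstot > 0 else float("nan")


def _pearson(y, yhat) -> float:
    if np.std(y) == 0 or np.std(yhat) == 0:
        return float("nan")
    return float(np.corrcoef(y, yhat)[0, 1])


class _LMState:
    """Flat parameter vector <-> network weights, with analytic Jacobian."""

    def __init__(self, d: int, h: int):
        self.d, self.h = d, h
        self.n_params = h * d + h + h + 1
        # decay mask: weights yes, biases no
        mask = np.zeros(self.n_params)
        mask[: h * d] = 1.0
        mask[h * d + h: h * d + h + h] = 1.0
        self.decay_mask = mask

    def unpack(self, w):
        d, h = self.d, self.h
        W1 = w[: h * d].reshape(h, d)
        b1 = w[h * d: h * d + h]
        W2 = w[h * d + h: h * d + 2 * h]
        b2 = w[-1]
        return W1, b1, W2, b2

    def forward(self, w, X):
        W1, b1, W2, b2 = self.unpack(w)
        a = np.tanh(X @ W1.T + b1)
        return a @ W2 + b2, a

    def jacobian(self, w, X, a):
        """d yhat_i / d w_j, shape (n, n_params)."""
        W1, b1, W2, b2 = self.unpack(w)
        n = X.shape[0]
        da = 1.0 - a**2                      # (n, h)
        g_W1 = (W2 * da)[:, :, None] * X[:, None, :]   # (n, h, d)
        g_b1 = W2 * da                        # (n, h)
        g_W2 = a                              # (n, h)
        g_b2 = np.ones((n, 1))
        return np.concatenate(
            [g_W1.reshape(n, -1), g_b1, g_W2, g_b2], axis=1
        )


def _penalized_loss(resid, w, lam, mask) -> float:
    return float(np.sum(resid**2) + lam * np.sum((mask * w) ** 2))


def _train_lm(Xtr, ytr, Xval, yval, config: NNConfig):
    """Full-batch LM / damped Gauss-Newton with validation early stopping."""
    h, d = config.hidden_units, Xtr.shape[1]
    state = _LMState(d, h)
    rng = np.random.default_rng(config.seed)
    w = rng.uniform(-0.5, 0.5, state.n_params) / np.sqrt(d)
    lam = config.l2_weight_decay
    adaptive = config.optimizer == "levenberg_marquardt"
    mu = config.learning_rate  # damping, seeded from the stated learning rate
    sqrt_lam = np.sqrt(lam)

    def val_loss(wv):
        pred, _ = state.forward(wv, Xval)
        return float(np.mean((pred - yval) ** 2)) if yval.size else float("inf")

    pred, a = state.forward(w, Xtr)
    resid = pred - ytr
    loss = _penalized_loss(resid, w, lam, state.decay_mask)
    best_w, best_val, best_epoch = w.copy(), val_loss(w), 0
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        if not np.isfinite(loss):
            raise ConvergenceError(f"non-finite loss at epoch {epoch}")
        J = state.jacobian(w, Xtr, a)
        # augmented system: residuals + sqrt(lam)*masked weights
        g = J.T @ resid + lam * state.decay_mask * w
        if np.linalg.norm(g) < 1e-12:
            break
        JtJ = J.T @ J + lam * np.diag(state.decay_mask)
        accepted = False
        for _ in range(25):
            try:
                delta = np.linalg.solve(JtJ + mu * np.eye(state.n_params), -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            w_try = w + delta
            pred_t, a_t = state.forward(w_try, Xtr)
            resid_t = pred_t - ytr
            loss_t = _penalized_loss(resid_t, w_try, lam, state.decay_mask)
            if np.isfinite(loss_t) and loss_t < loss:
                w, resid, a, loss = w_try, resid_t, a_t, loss_t
                if adaptive:
                    mu = max(mu / 10.0, 1e-12)
                accepted = True
                break
            if not adaptive:
                break
            mu *= 10.0
        if not accepted:
            break  # no descent direction left
        vl = val_loss(w)
        if vl < best_val - 1e-15:
            best_w, best_val, best_epoch = w.copy(), vl, epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stopping_patience:
                break
    final_val = val_loss(w)
    if best_val <= final_val:
        w = best_w
    return w, state, {"best_val_loss": min(best_val, final_val),
                      "final_val_loss": final_val, "best_epoch": best_epoch}


def _split_indices(n: int, fractions, seed: int):
    perm = np.random.default_rng(seed).permutation(n)
    sizes = _largest_remainder_sizes(n, fractions)
    out, start = [], 0
    for s in sizes:
        out.append(np.sort(perm[start:start + s]))
        start += s
    return out


def train_nn(features, response, config: NNConfig = None):
    """Train the network and report per-split R².

    Returns
    -------
    (Network, dict)
        The trained network and a metrics dict with R² on the train,
        validation and test splits plus the test-set Pearson r (the two
        accuracy conventions in circulation for such baselines), and the
        early-stopping trace.
    """
    config = config or NNConfig()
    names = tuple(features.columns) if isinstance(features, pd.DataFrame) else None
    X = _coerce_features(features)
    y = np.asarray(response, dtype=float)
    n = X.shape[0]
    if n < 30:
        raise ValueError("need n >= 30 to support a 70/15/15 split")
    idx = _split_indices(n, config.split, config.seed)
    if any(len(i) == 0 for i in idx):
        raise ValueError("a split partition is empty; n too small")
    itr, ival, ite = idx[0], idx[1], idx[2]
    x_mean, x_std = X[itr].mean(axis=0), X[itr].std(axis=0)
    x_std = np.where(x_std > 0, x_std, 1.0)
    y_mean, y_std = float(y[itr].mean()), float(y[itr].std())
    y_std = y_std if y_std > 0 else 1.0
    Xs = (X - x_mean) / x_std
    ys = (y - y_mean) / y_std

    if config.optimizer == "adam_fallback":
        from sklearn.neural_network import MLPRegressor

        sk = MLPRegressor(
            hidden_layer_sizes=(config.hidden_units,), activation="tanh",
            alpha=config.l2_weight_decay,
            learning_rate_init=config.learning_rate,
            max_iter=config.max_epochs, random_state=config.seed,
            n_iter_no_change=config.early_stopping_patience,
        )
        sk.fit(Xs[itr], ys[itr])
        net = Network(
            W1=sk.coefs_[0].T, b1=sk.intercepts_[0],
            W2=sk.coefs_[1].ravel(), b2=float(sk.intercepts_[1][0]),
            x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
            feature_names=names, config=config,
        )
        trace = {}
    elif config.optimizer in ("levenberg_marquardt", "damped_gauss_newton"):
        w, state, trace = _train_lm(Xs[itr], ys[itr], Xs[ival], ys[ival], config)
        W1, b1, W2, b2 = state.unpack(w)
        net = Network(
            W1=W1, b1=b1, W2=W2, b2=float(b2),
            x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
            feature_names=names, config=config,
        )
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    yhat = net._forward_std(Xs) * y_std + y_mean
    metrics = {
        "train_r2": _r2(y[itr], yhat[itr]),
        "validation_r2": _r2(y[ival], yhat[ival]),
        "test_r2": _r2(y[ite], yhat[ite]),
        "test_r": _pearson(y[ite], yhat[ite]),
        **trace,
    }
    return net, metrics
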