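"""Minimal feed-forward residual network for tabular regression, in numpy.

The regression target throughout the package is log reaction time, so
the network is a scalar-output MLP: a linear input projection to a fixed
width, a stack of pre-activation residual blocks (two fully connected
layers with a skip connection each), and a linear head.  Training is
plain minibatch Adam on mean squared error with early stopping on a
held-out validation split.  Everything is float64 and single-threaded,
so runs are bit-reproducible given the seeds.

Targets are standardised internally (zero mean, unit variance on the
training split) and de-standardised at prediction time; this makes
training exactly equivariant under affine changes of the target's unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TrainingConfig", "ResidualMLP", "TrainingDivergenceError"]


class TrainingDivergenceError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass(frozen=True)
class TrainingConfig:
    width: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 20  # early-stopping patience, in epochs
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class ResidualMLP:
    """Scalar-output residual MLP.

    Parameters are He-initialised from ``init_seed``.  ``n_blocks`` is
    the number of residual blocks; the model-selection candidates used
    elsewhere are {2, 4, 6}.
    """

    def __init__(
        self,
        input_dim: int,
        n_blocks: int,
        init_seed: int,
        config: TrainingConfig | None = None,
    ) -> None:
        self.input_dim = input_dim
        self.n_blocks = n_blocks
        self.config = config or TrainingConfig()
        self.init_seed = init_seed
        w = self.config.width
        rng = np.random.default_rng(init_seed)

        def he(n_in, n_out):
            return rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))

        self.params: dict[str, np.ndarray] = {"W_in": he(input_dim, w), "b_in": np.zeros(w)}
        for i in range(n_blocks):
            self.params[f"W{i}_1"] = he(w, w)
            self.params[f"b{i}_1"] = np.zeros(w)
            self.params[f"W{i}_2"] = he(w, w)
            self.params[f"b{i}_2"] = np.zeros(w)
        self.params["W_out"] = he(w, 1)
        self.params["b_out"] = np.zeros(1)
        # target standardisation, set by fit()
        self.y_mean = 0.0
        self.y_std = 1.0
        self.history: dict[str, list[float]] = {"train_mse": [], "val_mse": []}
        self.best_val_mse = np.inf

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, cache: bool = False):
        p = self.params
        acts = {"h": X @ p["W_in"] + p["b_in"]}
        h = acts["h"]
        store = {"X": X, "h0": h} if cache else None
        for i in range(self.n_blocks):
            a1 = _relu(h)
            z1 = a1 @ p[f"W{i}_1"] + p[f"b{i}_1"]
            a2 = _relu(z1)
            z2 = a2 @ p[f"W{i}_2"] + p[f"b{i}_2"]
            if cache:
                store[f"a1_{i}"] = a1
                store[f"z1_{i}"] = z1
                store[f"a2_{i}"] = a2
                store[f"hin_{i}"] = h
            h = h + z2
        out = (h @ p["W_out"] + p["b_out"])[:, 0]
        if cache:
            store["h_final"] = h
            return out, store
        return out

    def _backward(self, store, d_out: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        grads: dict[str, np.ndarray] = {}
        h_final = store["h_final"]
        grads["W_out"] = h_final.T @ d_out[:, None]
        grads["b_out"] = np.array([d_out.sum()])
        dh = d_out[:, None] @ p["W_out"].T
        for i in reversed(range(self.n_blocks)):
            a1 = store[f"a1_{i}"]
            z1 = store[f"z1_{i}"]
            a2 = store[f"a2_{i}"]
            dz2 = dh  # skip connection passes dh through unchanged as well
            grads[f"W{i}_2"] = a2.T @ dz2
            grads[f"b{i}_2"] = dz2.sum(axis=0)
            da2 = dz2 @ p[f"W{i}_2"].T
            dz1 = da2 * (z1 > 0)
            grads[f"W{i}_1"] = a1.T @ dz1
            grads[f"b{i}_1"] = dz1.sum(axis=0)
            da1 = dz1 @ p[f"W{i}_1"].T
            dh = dh + da1 * (store[f"hin_{i}"] > 0)
        grads["W_in"] = store["X"].T @ dh
        grads["b_in"] = dh.sum(axis=0)
        return grads

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        split_seed: int,
        shuffle_seed: int | None = None,
        val_fraction: float = 0.10,
    ) -> "ResidualMLP":
        """Train with a random 90/10 train/validation split and early
        stopping on validation MSE; restores the best parameters."""
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        split_rng = np.random.default_rng(split_seed)
        perm = split_rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        self.y_mean = float(ytr.mean())
        self.y_std = float(ytr.std()) or 1.0
        ytr_s = (ytr - self.y_mean) / self.y_std
        yval_s = (yval - self.y_mean) / self.y_std

        rng = np.random.default_rng(
            self.init_seed + 1 if shuffle_seed is None else shuffle_seed
        )
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(val) for k, val in self.params.items()}
        t = 0
        best_params = {k: p.copy() for k, p in self.params.items()}
        best_val = np.inf
        stale = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(Xtr.shape[0])
            ep_loss = 0.0
            for start in range(0, Xtr.shape[0], cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = Xtr[idx], ytr_s[idx]
                pred, store = self._forward(xb, cache=True)
                err = pred - yb
                ep_loss += float((err ** 2).sum())
                d_out = (2.0 / xb.shape[0]) * err
                grads = self._backward(store, d_out)
                t += 1
                lr_t = cfg.learning_rate * np.sqrt(
                    1 - cfg.adam_beta2 ** t
                ) / (1 - cfg.adam_beta1 ** t)
                for k, g in grads.items():
                    m[k] = cfg.adam_beta1 * m[k] + (1 - cfg.adam_beta1) * g
                    v[k] = cfg.adam_beta2 * v[k] + (1 - cfg.adam_beta2) * g * g
                    self.params[k] -= lr_t * m[k] / (np.sqrt(v[k]) + cfg.adam_eps)
            train_mse = ep_loss / Xtr.shape[0]
            val_mse = float(np.mean((self._forward(Xval) - yval_s) ** 2))
            if not np.isfinite(train_mse) or not np.isfinite(val_mse):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch}: train={train_mse}, val={val_mse}"
                )
            self.history["train_mse"].append(train_mse)
            self.history["val_mse"].append(val_mse)
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_params = {k: p.copy() for k, p in self.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        self.params = best_params
        self.best_val_mse = best_val
        return self

    def predict(self, X: np.ndarray, batch: int = 1 << 16) -> np.ndarray:
        """De-standardised predictions (same units as the training target)."""
        X = np.asarray(X, dtype=float)
        outs = [
            self._forward(X[i : i + batch]) for i in range(0, X.shape[0], batch)
        ]
        raw = np.concatenate(outs) if outs else np.empty(0)
        return raw * self.y_std + self.y_mean
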