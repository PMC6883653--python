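"""Minimal feed-forward / 1-D convolutional network core (numpy, CPU).

Just enough machinery for the two small orientation classifiers: Dense,
Conv1D (valid cross-correlation via im2col), MaxPool1D, ReLU, inverted
Dropout, sigmoid/softmax cross-entropy heads, Adam, and early stopping on a
validation split.  All arithmetic is float32; a single ``numpy`` Generator
drives initialization, shuffling and dropout so training is reproducible
for a given seed on a given BLAS.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, scale: str = "he"):
        super().__init__()
        std = np.sqrt(2.0 / n_in) if scale == "he" else np.sqrt(1.0 / n_in)
        self.W = rng.normal(0.0, std, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return np.where(self._mask, g, 0.0)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Conv1D(Layer):
    """Valid cross-correlation over (batch, channels, length) input."""

    def __init__(self, c_in: int, c_out: int, width: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * width
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out, self.width = c_in, c_out, width
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    @property
    def filters(self) -> np.ndarray:
        """Filter tensor of shape (c_out, c_in, width)."""
        return self.W.reshape(self.c_in, self.width, self.c_out).transpose(2, 0, 1)

    def forward(self, x, train):
        B, C, L = x.shape
        L_out = L - self.width + 1
        cols = np.lib.stride_tricks.sliding_window_view(x, self.width, axis=2)
        # (B, C, L_out, width) -> (B, L_out, C*width), contiguous copy
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            B, L_out, C * self.width
        )
        self._cols, self._in_len = cols, L
        out = cols @ self.W + self.b  # (B, L_out, c_out)
        return out.transpose(0, 2, 1)

    def backward(self, g):
        B = g.shape[0]
        gt = np.ascontiguousarray(g.transpose(0, 2, 1))  # (B, L_out, c_out)
        L_out = gt.shape[1]
        cw = self.c_in * self.width
        self.grads[0][...] = self._cols.reshape(-1, cw).T @ gt.reshape(-1, self.c_out)
        self.grads[1][...] = gt.sum(axis=(0, 1))
        dcols = gt @ self.W.T  # (B, L_out, C*width)
        dcols = dcols.reshape(B, L_out, self.c_in, self.width).transpose(0, 2, 3, 1)
        dx = np.zeros((B, self.c_in, self._in_len), dtype=np.float32)
        for j in range(self.width):
            dx[:, :, j : j + L_out] += dcols[:, :, j, :]
        return dx


class MaxPool1D(Layer):
    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x, train):
        B, C, L = x.shape
        L_out = L // self.pool
        xr = x[:, :, : L_out * self.pool].reshape(B, C, L_out, self.pool)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, g):
        B, C, L = self._shape
        L_out = L // self.pool
        dxr = np.zeros((B, C, L_out, self.pool), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], g[..., None], axis=-1)
        dx = np.zeros((B, C, L), dtype=np.float32)
        dx[:, :, : L_out * self.pool] = dxr.reshape(B, C, L_out * self.pool)
        return dx


def _sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A layer stack with a ``sigmoid`` (binary) or ``softmax`` loss head."""

    def __init__(self, layers: list[Layer], head: str):
        if head not in ("sigmoid", "softmax"):
            raise ValueError(f"unknown head {head!r}")
        self.layers = layers
        self.head = head

    # -- forward / predict -------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class probabilities: shape (n,) for sigmoid, (n, K) for softmax."""
        outs = []
        for i in range(0, len(X), batch_size):
            z = self._forward(np.asarray(X[i : i + batch_size], dtype=np.float32), False)
            outs.append(_sigmoid(z)[:, 0] if self.head == "sigmoid" else _softmax(z))
        return np.concatenate(outs) if outs else np.zeros(
            (0,) if self.head == "sigmoid" else (0, 2), dtype=np.float32
        )

    # -- training ----------------------------------------------------------
    def _loss_and_grad(self, z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        n = len(y)
        eps = 1e-12
        if self.head == "sigmoid":
            p = _sigmoid(z)[:, 0]
            loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
            dz = ((p - y) / n).astype(np.float32)[:, None]
        else:
            p = _softmax(z)
            loss = -np.mean(np.log(p[np.arange(n), y.astype(int)] + eps))
            dz = p.copy()
            dz[np.arange(n), y.astype(int)] -= 1.0
            dz = (dz / n).astype(np.float32)
        return float(loss), dz

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(flat, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape {w.shape} != expected {p.shape}")
            p[...] = w

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int,
        batch_size: int,
        learning_rate: float,
        rng: np.random.Generator,
        validation_fraction: float = 0.1,
        patience: int = 5,
        log: list | None = None,
    ) -> "Network":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        n = len(X)
        idx = rng.permutation(n)
        n_val = max(1, int(round(n * validation_fraction))) if n > 10 else 0
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]

        params = [p for layer in self.layers for p in layer.params]
        grads = [g for layer in self.layers for g in layer.grads]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_val, best_weights, stale = np.inf, None, 0

        for epoch in range(epochs):
            order = rng.permutation(len(Xtr))
            epoch_loss, n_batches = 0.0, 0
            for i in range(0, len(Xtr), batch_size):
                batch = order[i : i + batch_size]
                z = self._forward(Xtr[batch], train=True)
                loss, dz = self._loss_and_grad(z, ytr[batch])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}: {loss}"
                    )
                g = dz
                for layer in reversed(self.layers):
                    g = layer.backward(g)
                t += 1
                lr_t = learning_rate * np.sqrt(1 - b2**t) / (1 - b1**t)
                for p, gr, mi, vi in zip(params, grads, m, v):
                    mi *= b1
                    mi += (1 - b1) * gr
                    vi *= b2
                    vi += (1 - b2) * gr * gr
                    p -= lr_t * mi / (np.sqrt(vi) + eps)
                epoch_loss += loss
                n_batches += 1
            entry = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
            if n_val:
                zv = self._forward(X[val_idx], train=False)
                val_loss, _ = self._loss_and_grad(zv, y[val_idx])
                entry["val_loss"] = val_loss
                if val_loss < best_val - 1e-5:
                    best_val, best_weights, stale = val_loss, self.get_weights(), 0
                else:
                    stale += 1
            if log is not None:
                log.append(entry)
            if n_val and stale > patience:
                break
        if best_weights is not None:
            self.set_weights(best_weights)
        return self
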