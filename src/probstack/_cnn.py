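"""Minimal seeded 1-D convolutional network for tabular rows.

A row of n features is treated as a length-n single-channel sequence.
Architecture: conv(32, k=3) -> conv(32, k=3) -> conv(64, k=3), all
same-padded with ReLU, then dense(128, ReLU) -> dense(2) -> softmax,
trained with Adam on cross-entropy.  Pure numpy: the networks are tiny
and must run identically on any 1-CPU host.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConvNet1D"]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ConvNet1D:
    """Binary classifier; sklearn-ish fit/predict_proba surface."""

    def __init__(
        self,
        filters: tuple[int, int, int] = (32, 32, 64),
        kernel_sizes: tuple[int, int, int] = (3, 3, 3),
        fc_size: int = 128,
        learning_rate: float = 0.01,
        epochs: int = 200,
        batch_size: int = 32,
        validation_fraction: float = 0.1,
        patience: int = 20,
        early_stopping: bool = True,
        seed: int = 0,
    ):
        self.filters = filters
        self.kernel_sizes = kernel_sizes
        self.fc_size = fc_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.early_stopping = early_stopping
        self.seed = seed
        self._params: list[np.ndarray] | None = None

    # -- parameter init -----------------------------------------------------
    def _init_params(self, length: int, rng: np.random.Generator) -> None:
        chans = (1,) + self.filters
        self._conv_w, self._conv_b = [], []
        for i, k in enumerate(self.kernel_sizes):
            fan_in = k * chans[i]
            w = rng.normal(0, np.sqrt(2.0 / fan_in), size=(k, chans[i], chans[i + 1]))
            self._conv_w.append(w)
            self._conv_b.append(np.zeros(chans[i + 1]))
        flat = length * self.filters[-1]
        self._w1 = rng.normal(0, np.sqrt(2.0 / flat), size=(flat, self.fc_size))
        self._b1 = np.zeros(self.fc_size)
        self._w2 = rng.normal(0, np.sqrt(2.0 / self.fc_size), size=(self.fc_size, 2))
        self._b2 = np.zeros(2)
        self._params = [*self._conv_w, *self._conv_b, self._w1, self._b1, self._w2, self._b2]
        self._length = length

    # -- forward / backward -------------------------------------------------
    @staticmethod
    def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple:
        """Same-padded 1-D convolution. x: (n, L, ci), w: (k, ci, co)."""
        k = w.shape[0]
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, k - 1 - pad), (0, 0)))
        L = x.shape[1]
        out = np.tile(b, (x.shape[0], L, 1))
        for j in range(k):
            out += xp[:, j : j + L, :] @ w[j]
        return out, xp

    @staticmethod
    def _conv_backward(dout: np.ndarray, xp: np.ndarray, w: np.ndarray) -> tuple:
        k, L = w.shape[0], dout.shape[1]
        dw = np.empty_like(w)
        dxp = np.zeros_like(xp)
        for j in range(k):
            dw[j] = np.einsum("nlc,nld->cd", xp[:, j : j + L, :], dout)
            dxp[:, j : j + L, :] += dout @ w[j].T
        db = dout.sum(axis=(0, 1))
        pad = k // 2
        return dw, db, dxp[:, pad : pad + L, :]

    def _forward(self, X: np.ndarray, cache: bool = False):
        a = X[:, :, None]
        caches = []
        for w, b in zip(self._conv_w, self._conv_b):
            z, xp = self._conv_forward(a, w, b)
            a_next = np.maximum(z, 0)
            if cache:
                caches.append((xp, z))
            a = a_next
        flat = a.reshape(a.shape[0], -1)
        h = np.maximum(flat @ self._w1 + self._b1, 0)
        logits = h @ self._w2 + self._b2
        if cache:
            return logits, (caches, flat, h)
        return logits

    def _backward(self, X, y_onehot, logits, fw_cache):
        caches, flat, h = fw_cache
        n = X.shape[0]
        probs = _softmax(logits)
        dlogits = (probs - y_onehot) / n
        dw2 = h.T @ dlogits
        db2 = dlogits.sum(axis=0)
        dh = dlogits @ self._w2.T
        dh[h <= 0] = 0
        dw1 = flat.T @ dh
        db1 = dh.sum(axis=0)
        dflat = dh @ self._w1.T
        da = dflat.reshape(n, self._length, self.filters[-1])
        conv_grads = []
        for (xp, z), w in zip(reversed(caches), reversed(self._conv_w)):
            dz = da * (z > 0)
            dw, db, da = self._conv_backward(dz, xp, w)
            conv_grads.append((dw, db))
        conv_grads.reverse()
        dws = [g[0] for g in conv_grads]
        dbs = [g[1] for g in conv_grads]
        return [*dws, *dbs, dw1, db1, dw2, db2]

    # -- public surface -----------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "ConvNet1D":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[1], rng)

        n = len(X)
        use_val = self.early_stopping and n >= 40
        if use_val:
            perm = rng.permutation(n)
            n_val = max(1, int(round(self.validation_fraction * n)))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_tr, y_tr, X_val, y_val = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
        else:
            X_tr, y_tr = X, y

        onehot = np.eye(2)[y_tr]
        opt = _Adam(self._params, lr=self.learning_rate)
        best_loss, best_params, stale = np.inf, None, 0
        for _ in range(self.epochs):
            order = rng.permutation(len(X_tr))
            for start in range(0, len(X_tr), self.batch_size):
                idx = order[start : start + self.batch_size]
                logits, fw = self._forward(X_tr[idx], cache=True)
                grads = self._backward(X_tr[idx], onehot[idx], logits, fw)
                opt.step(grads)
            if use_val:
                p = _softmax(self._forward(X_val))
                loss = -np.log(p[np.arange(len(y_val)), y_val] + 1e-12).mean()
                if loss < best_loss - 1e-5:
                    best_loss, stale = loss, 0
                    best_params = [p_.copy() for p_ in self._params]
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if use_val and best_params is not None:
            for p_, b_ in zip(self._params, best_params):
                p_[...] = b_
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self._params is None:
            raise RuntimeError("model not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._length:
            raise ValueError(
                f"expected {self._length} features, got {X.shape[1]}"
            )
        return _softmax(self._forward(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def get_params(self, deep: bool = True) -> dict:
        return {
            "filters": self.filters,
            "kernel_sizes": self.kernel_sizes,
            "fc_size": self.fc_size,
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "validation_fraction": self.validation_fraction,
            "patience": self.patience,
            "early_stopping": self.early_stopping,
            "seed": self.seed,
        }
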