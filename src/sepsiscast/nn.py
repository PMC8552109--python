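"""Minimal feed-forward / recurrent neural-network engine on numpy.

Implements exactly the layer vocabulary the surrogate architectures need —
dense layers (optionally applied per time step), flattening, inverted
dropout, and stacked LSTM cells — together with reverse-mode gradients,
the Adam optimizer, MAE/MSE losses, and an early-stopping training loop.

All arithmetic is float64 and single-threaded numpy, so training is
bit-reproducible given the initialization, shuffling and dropout seeds.

Conventions
-----------
* Batch-first shapes: dense input ``(N, d)``, sequence input ``(N, T, d)``.
* ``forward(x, rng=None)``: when ``rng`` is ``None`` dropout layers are the
  identity; when a :class:`numpy.random.Generator` is supplied, dropout
  draws an independent mask row per sample (this is what makes a batched
  Monte-Carlo-dropout ensemble work: each row of the batch is a member).
* A layer owns its parameter arrays; gradients accumulate in parallel
  arrays zeroed by the trainer before each backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "TimeDistributedDense",
    "Flatten",
    "Dropout",
    "LSTM",
    "Sequential",
    "Adam",
    "mse_loss",
    "mae_loss",
]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class; stateless layers only override forward/backward."""

    def params(self):
        return []

    def grads(self):
        return []

    def zero_grads(self):
        for g in self.grads():
            g[...] = 0.0

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def forward(self, x, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer ``y = act(x W + b)``.

    ``activation`` is ``"relu"`` or ``"linear"``. Weights use He
    initialization for relu and Glorot for linear output layers.
    """

    def __init__(self, n_in: int, n_out: int, activation: str = "relu", *,
                 rng: np.random.Generator | None = None):
        if activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation: {activation}")
        rng = rng or np.random.default_rng(0)
        if activation == "relu":
            scale = np.sqrt(2.0 / n_in)
            self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        else:
            limit = np.sqrt(6.0 / (n_in + n_out))
            self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.activation = activation
        self.n_in, self.n_out = n_in, n_out

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, rng=None):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._mask
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T


class TimeDistributedDense(Layer):
    """Apply one shared :class:`Dense` to every time step of ``(N, T, d)``."""

    def __init__(self, n_in: int, n_out: int, activation: str = "relu", *,
                 rng: np.random.Generator | None = None):
        self.inner = Dense(n_in, n_out, activation, rng=rng)
        self.n_in, self.n_out = n_in, n_out

    def params(self):
        return self.inner.params()

    def grads(self):
        return self.inner.grads()

    def forward(self, x, rng=None):
        self._shape = x.shape
        n, t, d = x.shape
        y = self.inner.forward(x.reshape(n * t, d))
        return y.reshape(n, t, self.n_out)

    def backward(self, dy):
        n, t, _ = self._shape
        dx = self.inner.backward(dy.reshape(n * t, self.n_out))
        return dx.reshape(self._shape)


class Flatten(Layer):
    """Collapse all non-batch axes: ``(N, T, d) -> (N, T*d)``."""

    def forward(self, x, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout with rate ``p``.

    Identity when no generator is supplied (deterministic prediction);
    with a generator, each sample in the batch gets an independent mask,
    so a batch of M identical inputs yields an M-member dropout ensemble.
    """

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1): {p}")
        self.p = p

    def forward(self, x, rng=None):
        if rng is None or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class LSTM(Layer):
    """Single LSTM layer with sigmoid gates and tanh candidate/output.

    Parameters follow the standard cell: input kernel ``W (d, 4u)``,
    recurrent kernel ``U (u, 4u)``, bias ``b (4u,)`` with gate order
    [input, forget, candidate, output]; the forget-gate bias starts at 1.
    Parameter count is ``4*((d + u)*u + u)``.
    """

    def __init__(self, n_in: int, units: int, return_sequences: bool, *,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(6.0 / (n_in + 4 * units))
        self.W = rng.uniform(-limit, limit, size=(n_in, 4 * units))
        rlimit = np.sqrt(6.0 / (units + 4 * units))
        self.U = rng.uniform(-rlimit, rlimit, size=(units, 4 * units))
        self.b = np.zeros(4 * units)
        self.b[units:2 * units] = 1.0
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)
        self.units = units
        self.n_in = n_in
        self.return_sequences = return_sequences

    def params(self):
        return [self.W, self.U, self.b]

    def grads(self):
        return [self.dW, self.dU, self.db]

    def forward(self, x, rng=None):
        n, t, d = x.shape
        u = self.units
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        self._x = x
        self._cache = []
        hs = np.empty((n, t, u))
        for k in range(t):
            z = x[:, k, :] @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, k, :] = h
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, dy):
        x = self._x
        n, t, d = x.shape
        u = self.units
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, u))
        dc_next = np.zeros((n, u))
        if not self.return_sequences:
            dy_steps = [np.zeros((n, u))] * (t - 1) + [dy]
        else:
            dy_steps = [dy[:, k, :] for k in range(t)]
        for k in reversed(range(t)):
            h_prev, c_prev, i, f, g, o, tc = self._cache[k]
            dh = dy_steps[k] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            self.dW += x[:, k, :].T @ dz
            self.dU += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, k, :] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return dx


def mse_loss(pred, target):
    """Mean squared error and its gradient wrt ``pred``."""
    diff = pred - target
    return float(np.mean(diff * diff)), 2.0 * diff / diff.size


def mae_loss(pred, target):
    """Mean absolute error and its gradient wrt ``pred``."""
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


_LOSSES = {"MSE": mse_loss, "MAE": mae_loss}


class Adam:
    """Adam with the customary defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Sequential:
    """An ordered stack of layers with a seeded training loop."""

    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def forward(self, x, rng=None):
        for layer in self.layers:
            x = layer.forward(x, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights):
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w

    def fit(self, X, y, X_val=None, y_val=None, *, loss="MSE", epochs=200,
            batch_size=128, lr=1e-3, seed=0, patience=10,
            min_delta_frac=1e-4):
        """Minibatch Adam training with early stopping.

        Early stopping watches validation loss (training loss when no
        validation set is given): improvement smaller than
        ``min_delta_frac`` times the initial loss, ``patience`` epochs in a
        row, ends training; the best weights seen are restored.

        Returns a history dict with per-epoch ``train`` and ``val`` losses.
        """
        if loss not in _LOSSES:
            raise ValueError(f"unknown loss: {loss}")
        loss_fn = _LOSSES[loss]
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if y_val is not None and np.ndim(y_val) == 1:
            y_val = np.asarray(y_val, dtype=float)[:, None]
        ss = np.random.SeedSequence(seed)
        shuffle_rng, drop_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
        opt = Adam(self.params(), lr=lr)
        n = X.shape[0]
        history = {"train": [], "val": []}
        best_val = np.inf
        best_weights = None
        min_delta = None
        stale = 0
        for _ in range(epochs):
            order = shuffle_rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb = X[idx], y[idx]
                pred = self.forward(xb, rng=drop_rng)
                batch_loss, dpred = loss_fn(pred, yb)
                for layer in self.layers:
                    layer.zero_grads()
                self.backward(dpred)
                opt.step(self.grads())
                ep_loss += batch_loss * len(idx)
            ep_loss /= n
            history["train"].append(ep_loss)
            if X_val is not None and len(X_val):
                val_pred = self.forward(X_val)
                val_loss, _ = loss_fn(val_pred, y_val)
            else:
                val_loss = ep_loss
            history["val"].append(val_loss)
            if min_delta is None:
                min_delta = min_delta_frac * max(val_loss, 1e-300)
            if val_loss < best_val - min_delta:
                best_val = val_loss
                best_weights = self.get_weights()
                stale = 0
            else:
                if val_loss < best_val:
                    best_val = val_loss
                    best_weights = self.get_weights()
                stale += 1
                if stale >= patience:
                    break
        if best_weights is not None:
            self.set_weights(best_weights)
        return history
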