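"""Minimal neural-network core used by the network decoders.

Implements exactly the pieces the decoders need — dense, ReLU, dropout,
batch normalization, a per-channel temporal convolution, a single-layer
LSTM — with hand-written gradients and an Adam optimizer whose weight
decay is coupled into the gradient (classic Adam + L2).  Everything runs
in float32; all randomness (init, shuffling, dropout, noise) flows through
explicit numpy generators.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base layer: holds aligned lists of parameters and gradients."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        # He initialization (ReLU stacks).
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(DTYPE)
        b = np.zeros(n_out, dtype=DTYPE)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, gout):
        self.grads[0][...] = self._x.T @ gout
        self.grads[1][...] = gout.sum(axis=0)
        return gout @ self.params[0].T


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class BatchNorm(Layer):
    """1-D batch normalization with running statistics for inference."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        gamma = np.ones(n_features, dtype=DTYPE)
        beta = np.zeros(n_features, dtype=DTYPE)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.params[0] * self._xhat + self.params[1]

    def backward(self, gout):
        gamma = self.params[0]
        xhat = self._xhat
        self.grads[0][...] = (gout * xhat).sum(axis=0)
        self.grads[1][...] = gout.sum(axis=0)
        if not self._training:
            return gout * gamma / self._std
        n = gout.shape[0]
        gx_hat = gout * gamma
        return (
            gx_hat
            - gx_hat.mean(axis=0)
            - xhat * (gx_hat * xhat).mean(axis=0)
        ) / self._std


class ChannelTemporalConv(Layer):
    """Time-wise convolution applied to each channel independently.

    Input (N, C, H); each of F filters (kernel length exactly H, shared
    across channels) produces one value per channel, giving (N, C*F).
    """

    def __init__(self, n_history_bins: int, n_filters: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(n_history_bins)
        w = rng.uniform(-bound, bound, (n_filters, n_history_bins)).astype(DTYPE)
        b = np.zeros(n_filters, dtype=DTYPE)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, training):
        self._x = x  # (N, C, H)
        out = np.einsum("nch,fh->ncf", x, self.params[0]) + self.params[1]
        return out.reshape(x.shape[0], -1)

    def backward(self, gout):
        n, c, _ = self._x.shape
        g = gout.reshape(n, c, -1)  # (N, C, F)
        self.grads[0][...] = np.einsum("ncf,nch->fh", g, self._x)
        self.grads[1][...] = g.sum(axis=(0, 1))
        return np.einsum("ncf,fh->nch", g, self.params[0])


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def state(self) -> list[np.ndarray]:
        extra = []
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                extra += [layer.running_mean, layer.running_var]
        return [p.copy() for p in self.params] + [e.copy() for e in extra]

    def load_state(self, state: list[np.ndarray]) -> None:
        n = len(self.params)
        for p, s in zip(self.params, state[:n]):
            p[...] = s
        extra = state[n:]
        i = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = extra[i].copy()
                layer.running_var = extra[i + 1].copy()
                i += 2


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class LSTM:
    """Single-layer LSTM with a linear head on the final hidden state.

    Gate order i, f, g, o; one bias vector, so the parameter count is
    4 * ((n_in + n_hidden) * n_hidden + n_hidden) plus the head.
    """

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_hidden)
        u = lambda shape: rng.uniform(-bound, bound, shape).astype(DTYPE)
        self.w = u((n_in, 4 * n_hidden))
        self.u = u((n_hidden, 4 * n_hidden))
        self.b = np.zeros(4 * n_hidden, dtype=DTYPE)
        self.w_out = u((n_hidden, n_out))
        self.b_out = np.zeros(n_out, dtype=DTYPE)
        self.n_hidden = n_hidden
        self.params = [self.w, self.u, self.b, self.w_out, self.b_out]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (N, T, C) -> (N, n_out) from the final time step.

        Hidden and cell states start at zero.
        """
        n, t_len, _ = x.shape
        hdim = self.n_hidden
        h = np.zeros((n, hdim), dtype=DTYPE)
        c = np.zeros((n, hdim), dtype=DTYPE)
        self._cache = []
        self._x = x
        for t in range(t_len):
            z = x[:, t, :] @ self.w + h @ self.u + self.b
            i = _sigmoid(z[:, :hdim])
            f = _sigmoid(z[:, hdim : 2 * hdim])
            g = np.tanh(z[:, 2 * hdim : 3 * hdim])
            o = _sigmoid(z[:, 3 * hdim :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, tanh_c))
            h = o * tanh_c
            c = c_new
        self._h_final = h
        return h @ self.w_out + self.b_out

    def backward(self, gout: np.ndarray) -> None:
        hdim = self.n_hidden
        x = self._x
        for gr in self.grads:
            gr[...] = 0.0
        self.grads[3][...] = self._h_final.T @ gout
        self.grads[4][...] = gout.sum(axis=0)
        dh = gout @ self.w_out.T
        dc = np.zeros_like(dh)
        for t in range(x.shape[1] - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.grads[0] += x[:, t, :].T @ dz
            self.grads[1] += h_prev.T @ dz
            self.grads[2] += dz.sum(axis=0)
            dh = dz @ self.u.T
            dc = dc * f

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


class Adam:
    """Adam with L2-coupled weight decay (decay added to the gradient)."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
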