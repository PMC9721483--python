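"""Minimal neural-network toolkit used by the learning agents.

Dense/ReLU multilayer perceptrons and two-layer GRU encoders with manual
backpropagation, trained with the adaptive-moment (Adam) optimiser.  The
networks here are small (hidden layers of 64-128 units, horizons of ten
steps), so plain numpy matrix arithmetic is adequate and keeps the package
free of a deep-learning framework dependency.

Conventions: batches are leading axes; sequences are (batch, time, features)
with a (batch, time) mask whose zeros freeze the hidden state, so histories of
different lengths can share a padded batch.  All parameters are float32.
Every initialiser takes a ``numpy.random.Generator`` so runs are reproducible
bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "MLP", "GRU", "GRUStack", "Adam", "sigmoid"]

DTYPE = np.float32


def sigmoid(x):
    """Numerically safe logistic function (vectorised)."""
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _uniform_init(rng, shape, fan_in):
    k = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-k, k, size=shape).astype(DTYPE)


class Dense:
    """Affine layer with optional activation ('relu', 'sigmoid', 'tanh', None)."""

    def __init__(self, n_in: int, n_out: int, activation: str | None, rng):
        self.W = _uniform_init(rng, (n_in, n_out), n_in)
        self.b = _uniform_init(rng, (n_out,), n_in)
        self.activation = activation
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._z = z
            return np.maximum(z, 0.0)
        if self.activation == "sigmoid":
            self._out = sigmoid(z)
            return self._out
        if self.activation == "tanh":
            self._out = np.tanh(z)
            return self._out
        return z

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * (self._z > 0)
        elif self.activation == "sigmoid":
            dout = dout * self._out * (1.0 - self._out)
        elif self.activation == "tanh":
            dout = dout * (1.0 - self._out**2)
        self.gW += self._x.T @ dout
        self.gb += dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


class MLP:
    """Feed-forward network; hidden activations ReLU, configurable output."""

    def __init__(self, sizes, rng, out_activation: str | None = None):
        self.layers = []
        for i in range(len(sizes) - 1):
            act = "relu" if i < len(sizes) - 2 else out_activation
            self.layers.append(Dense(sizes[i], sizes[i + 1], act, rng))

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]


class GRU:
    """Single GRU layer over padded sequences.

    Gate order in the packed weight matrices is (reset, update, candidate):
        r = sigmoid(x Wx[:, :H]   + bx[:H]   + h Wh[:, :H]   + bh[:H])
        z = sigmoid(x Wx[:, H:2H] + bx[H:2H] + h Wh[:, H:2H] + bh[H:2H])
        n = tanh(x Wx[:, 2H:] + bx[2H:] + r * (h Wh[:, 2H:] + bh[2H:]))
        h' = (1 - z) * n + z * h
    Masked steps carry the hidden state through unchanged.
    """

    def __init__(self, n_in: int, n_units: int, rng):
        H = n_units
        self.H = H
        self.Wx = _uniform_init(rng, (n_in, 3 * H), H)
        self.Wh = _uniform_init(rng, (H, 3 * H), H)
        self.bx = _uniform_init(rng, (3 * H,), H)
        self.bh = _uniform_init(rng, (3 * H,), H)
        for name in ("Wx", "Wh", "bx", "bh"):
            setattr(self, "g" + name, np.zeros_like(getattr(self, name)))

    def forward(self, seq, mask):
        """seq: (B, T, D); mask: (B, T). Returns hidden states (B, T, H)."""
        B, T, D = seq.shape
        H = self.H
        h = np.zeros((B, H), dtype=DTYPE)
        self._cache = []
        hs = np.zeros((B, T, H), dtype=DTYPE)
        # input projections for every step in one matmul
        gx_all = (seq.reshape(B * T, D) @ self.Wx + self.bx).reshape(B, T, 3 * H)
        for t in range(T):
            gx = gx_all[:, t, :]
            gh = h @ self.Wh + self.bh
            r = sigmoid(gx[:, :H] + gh[:, :H])
            z = sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H])
            a = gh[:, 2 * H :]
            n = np.tanh(gx[:, 2 * H :] + r * a)
            m = mask[:, t : t + 1]
            self._cache.append((h, r, z, n, a, m))
            h = m * ((1.0 - z) * n + z * h) + (1.0 - m) * h
            hs[:, t, :] = h
        self._seq = seq
        return hs

    def backward(self, dhs):
        """dhs: (B, T, H) gradient w.r.t. each output step. Returns dseq."""
        B, T, D = self._seq.shape
        H = self.H
        dgx_all = np.empty((B, T, 3 * H), dtype=DTYPE)
        dh = np.zeros((B, H), dtype=DTYPE)
        dgh = np.empty((B, 3 * H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            h_prev, r, z, n, a, m = self._cache[t]
            dh = dh + dhs[:, t, :]
            dh_new = dh * m
            dn_pre = dh_new * (1.0 - z) * (1.0 - n**2)
            dgx = dgx_all[:, t, :]
            dgx[:, :H] = dn_pre * a * r * (1.0 - r)  # reset gate pre-act
            dgx[:, H : 2 * H] = dh_new * (h_prev - n) * z * (1.0 - z)
            dgx[:, 2 * H :] = dn_pre
            dgh[:, : 2 * H] = dgx[:, : 2 * H]
            dgh[:, 2 * H :] = dn_pre * r
            self.gWh += h_prev.T @ dgh
            self.gbh += dgh.sum(axis=0)
            dh = dh_new * z + dh * (1.0 - m) + dgh @ self.Wh.T
        flat = dgx_all.reshape(B * T, 3 * H)
        self.gWx += self._seq.reshape(B * T, D).T @ flat
        self.gbx += flat.sum(axis=0)
        return (flat @ self.Wx.T).reshape(B, T, D)

    def params(self):
        return [self.Wx, self.Wh, self.bx, self.bh]

    def grads(self):
        return [self.gWx, self.gWh, self.gbx, self.gbh]


class GRUStack:
    """Two stacked GRU layers; exposes the top layer's final hidden state."""

    def __init__(self, n_in: int, n_units: int, n_layers: int, rng):
        self.layers = []
        d = n_in
        for _ in range(n_layers):
            self.layers.append(GRU(d, n_units, rng))
            d = n_units

    def forward(self, seq, mask):
        """Returns the final (post-mask) hidden state of the top layer (B, H)."""
        hs = seq
        for layer in self.layers:
            hs = layer.forward(hs, mask)
        self._T = seq.shape[1]
        return hs[:, -1, :] if self._T > 0 else np.zeros(
            (seq.shape[0], self.layers[-1].H), dtype=DTYPE
        )

    def backward(self, dh_final):
        if self._T == 0:
            return None
        B, H = dh_final.shape
        dhs = np.zeros((B, self._T, H), dtype=DTYPE)
        dhs[:, -1, :] = dh_final
        for layer in reversed(self.layers):
            dhs = layer.backward(dhs)
        return dhs

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]


class Adam:
    """Adaptive-moment optimiser over a list of parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def zero_grads(net):
    for g in net.grads():
        g[...] = 0.0


def get_params(net):
    return [p.copy() for p in net.params()]


def set_params(net, values):
    for p, v in zip(net.params(), values):
        p[...] = v


def polyak_update(net, target, rho: float):
    """theta_targ <- rho * theta_targ + (1 - rho) * theta, elementwise."""
    for p, pt in zip(net.params(), target.params()):
        if p.shape != pt.shape:
            raise ValueError("network and target parameter shapes differ")
        pt *= rho
        pt += (1.0 - rho) * p
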