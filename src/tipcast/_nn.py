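"""Minimal NumPy neural-network core for the tipping-point regressor.

Implements exactly the two architectures the package needs:

* a two-row convolution (kernel spans both input channels, width d) sliding
  along the 500-sample axis, ReLU, local max pooling, an LSTM over the
  pooled feature sequence, and a dense scalar head;
* the ablation variant that feeds the raw two-channel sequence straight
  into the LSTM.

Everything is float32, trained with Adam on mean squared error, and fully
deterministic given the construction seed.  Written against NumPy only so
the package has no deep-learning-framework dependency; matmul-heavy
formulations (im2col convolution, batched gate projections) keep it fast
enough for the corpus sizes used here.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _glorot(rng, shape, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(DTYPE)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class CNNLSTM:
    """2-D CNN + LSTM regressor (or LSTM-only ablation) on 2 x L inputs."""

    def __init__(self, kernel_len: int = 10, n_filters: int = 50,
                 pool_size: int = 2, lstm_units: int = 64,
                 use_cnn: bool = True, seed: int = 0, n_input: int = 500,
                 out_bias: float = 1.5):
        if kernel_len < 3:
            raise ValueError("kernel_len must be >= 3")
        rng = np.random.default_rng(seed)
        self.use_cnn = use_cnn
        self.d = kernel_len
        self.F = n_filters
        self.P = pool_size
        self.H = lstm_units
        self.n_input = n_input
        H = lstm_units
        p = {}
        if use_cnn:
            p["Wc"] = _glorot(rng, (2 * self.d, self.F), 2 * self.d, self.F)
            p["bc"] = np.zeros(self.F, DTYPE)
            self.Lc = n_input - self.d + 1          # valid convolution
            self.T = self.Lc // self.P              # pooled sequence length
            in_dim = self.F
        else:
            self.Lc = n_input
            self.T = n_input
            in_dim = 2
        self.in_dim = in_dim
        p["Wx"] = _glorot(rng, (in_dim, 4 * H), in_dim, 4 * H)
        p["Wh"] = _glorot(rng, (H, 4 * H), H, 4 * H)
        b = np.zeros(4 * H, DTYPE)
        b[H:2 * H] = 1.0                            # forget-gate bias
        p["b"] = b
        p["Wd"] = _glorot(rng, (H, 1), H, 1)
        p["bd"] = np.full(1, out_bias, DTYPE)
        self.params = p

    # -- forward -------------------------------------------------------------

    def _conv_forward(self, X):
        # X: (B, 2, L) -> windows (B, Lc, 2*d) -> features (B, Lc, F)
        win = np.lib.stride_tricks.sliding_window_view(X, self.d, axis=2)
        col = win.transpose(0, 2, 1, 3).reshape(X.shape[0], self.Lc, 2 * self.d)
        col = np.ascontiguousarray(col, dtype=DTYPE)
        Z = col @ self.params["Wc"] + self.params["bc"]
        A = np.maximum(Z, 0.0)
        # max pooling along the sequence
        B, Lc, F = A.shape
        T = self.T
        Ap = A[:, :T * self.P].reshape(B, T, self.P, F)
        amax = Ap.argmax(axis=2)
        pooled = np.take_along_axis(Ap, amax[:, :, None, :], axis=2)[:, :, 0, :]
        return col, Z, amax, pooled

    def _lstm_forward(self, seq):
        # seq: (B, T, in_dim)
        B, T, _ = seq.shape
        H = self.H
        Xp = seq.reshape(B * T, self.in_dim) @ self.params["Wx"]
        Xp = Xp.reshape(B, T, 4 * H) + self.params["b"]
        Wh = self.params["Wh"]
        h = np.zeros((B, H), DTYPE)
        c = np.zeros((B, H), DTYPE)
        cache = []
        for t in range(T):
            z = Xp[:, t] + h @ Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            cache.append((i, f, g, o, c_prev, tc, h_prev))
        return h, cache

    def forward(self, X, want_cache: bool = False):
        """X: (B, 2, n_input) -> predictions (B,)."""
        X = np.ascontiguousarray(X, dtype=DTYPE)
        if self.use_cnn:
            col, Z, amax, seq = self._conv_forward(X)
        else:
            col = Z = amax = None
            seq = np.ascontiguousarray(X.transpose(0, 2, 1), dtype=DTYPE)
        h, cache = self._lstm_forward(seq)
        y = (h @ self.params["Wd"] + self.params["bd"])[:, 0]
        if want_cache:
            return y, (X, col, Z, amax, seq, cache, h)
        return y

    # -- backward ------------------------------------------------------------

    def backward(self, dy, ctx):
        """Gradients of the summed loss wrt parameters; dy: (B,)."""
        X, col, Z, amax, seq, cache, h_last = ctx
        p = self.params
        B, T, _ = seq.shape
        H = self.H
        g = {k: np.zeros_like(v) for k, v in p.items()}

        g["Wd"] = h_last.T @ dy[:, None]
        g["bd"] = np.array([dy.sum()], DTYPE)
        dh = dy[:, None] @ p["Wd"].T
        dc = np.zeros((B, H), DTYPE)
        dXp = np.empty((B, T, 4 * H), DTYPE)
        Wh = p["Wh"]
        dWh = g["Wh"]
        for t in range(T - 1, -1, -1):
            i, f, gg, o, c_prev, tc, h_prev = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * gg
            df = dc * c_prev
            dg = dc * i
            dz = np.empty((B, 4 * H), DTYPE)
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H:2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H:3 * H] = dg * (1.0 - gg * gg)
            dz[:, 3 * H:] = do * o * (1.0 - o)
            dXp[:, t] = dz
            dWh += h_prev.T @ dz
            dh = dz @ Wh.T
            dc = dc * f
        g["b"] = dXp.sum(axis=(0, 1))
        flat = dXp.reshape(B * T, 4 * H)
        g["Wx"] = seq.reshape(B * T, self.in_dim).T @ flat
        if self.use_cnn:
            dseq = (flat @ p["Wx"].T).reshape(B, T, self.in_dim)
            dA = np.zeros_like(Z)
            dAp = dA[:, :T * self.P].reshape(B, T, self.P, self.F)
            np.put_along_axis(dAp, amax[:, :, None, :], dseq[:, :, None, :],
                              axis=2)
            dZ = dA * (Z > 0)
            g["Wc"] = col.reshape(B * self.Lc, 2 * self.d).T @ \
                dZ.reshape(B * self.Lc, self.F)
            g["bc"] = dZ.sum(axis=(0, 1))
        return g

    def loss_and_grads(self, X, y):
        """Mean squared error and parameter gradients on one batch."""
        yhat, ctx = self.forward(X, want_cache=True)
        err = yhat - np.asarray(y, DTYPE)
        loss = float(np.mean(err ** 2))
        dy = (2.0 / len(err)) * err
        return loss, self.backward(dy, ctx)

    # -- parameter I/O -------------------------------------------------------

    def get_weights(self):
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights):
        for k in self.params:
            self.params[k] = np.asarray(weights[k], DTYPE).reshape(
                self.params[k].shape)

    @property
    def n_layers(self) -> int:
        """Trainable stages: conv (if present) + lstm + dense."""
        return (1 if self.use_cnn else 0) + 2


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 clip_norm=5.0):
        self.lr = lr
        self.b1 = beta1
        self.b2 = beta2
        self.eps = eps
        self.clip = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
        scale = 1.0
        if self.clip and norm > self.clip:
            scale = self.clip / (norm + 1e-12)
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            g = g * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
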