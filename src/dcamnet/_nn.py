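"""Minimal numpy layer framework used by the fatigue-detection network.

Each layer exposes ``forward(x, train)`` / ``backward(dy)`` with explicit
caches, and publishes its learnable arrays as :class:`Parameter` objects so a
single Adam optimizer can drive any layer stack.  Convolutions along the time
axis run in the frequency domain (zero 'same' padding, stride 1); their
gradients are frequency-domain correlations and are verified against
brute-force loops and finite differences in the test suite.

Nothing here is specific to EEG; the network topology lives in
:mod:`dcamnet.model`.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

__all__ = [
    "Parameter",
    "Layer",
    "SEDynamicConv",
    "BatchNorm",
    "ELU",
    "SpatialConv",
    "WindowVariance",
    "TemporalAttention",
    "PoolChannels",
    "PoolTime",
    "PoolTimeFlatten",
    "Dropout",
    "Linear",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Parameter:
    """A learnable array and its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


# ---------------------------------------------------------------------------
# frequency-domain time-axis convolution ('same' zero padding, stride 1)
# ---------------------------------------------------------------------------


def _corr_bank_forward(x: np.ndarray, w: np.ndarray, padding: str = "same"):
    """Cross-correlate ``x (B,V,C,T)`` with a kernel bank ``w (M,V,L)``.

    Returns ``y (B,M,C,T1)`` with
    ``y[b,m,c,t] = sum_{v,l} x[b,v,c,t+l-p] w[m,v,l]`` (zero outside), where
    ``p = (L-1)//2`` and ``T1 = T`` for 'same' padding, or ``p = 0`` and
    ``T1 = T - L + 1`` for 'valid'; plus the cached spectrum of ``x``.
    """
    B, V, C, T = x.shape
    M, V2, L = w.shape
    if V2 != V:
        raise ValueError(f"kernel band axis {V2} != input band axis {V}")
    if padding == "same":
        p, out_len = (L - 1) // 2, T
    elif padding == "valid":
        if L > T:
            raise ValueError(f"kernel length {L} exceeds series length {T}")
        p, out_len = 0, T - L + 1
    else:
        raise ValueError(f"unknown padding {padding!r}")
    nfft = next_fast_len(T + L - 1)
    X = rfft(x, nfft, axis=-1)
    Wf = rfft(w[:, :, ::-1], nfft, axis=-1)
    y_full = irfft(np.einsum("bvcf,mvf->bmcf", X, Wf, optimize=True), nfft, axis=-1)
    return y_full[..., L - 1 - p : L - 1 - p + out_len], (X, nfft, p, L, T)


def _corr_bank_weight_grad(dy: np.ndarray, cache) -> np.ndarray:
    """Gradient of :func:`_corr_bank_forward` w.r.t. the kernel bank."""
    X, nfft, p, L, T = cache
    DY = rfft(dy, nfft, axis=-1)
    G = irfft(np.einsum("bmcf,bvcf->mvf", np.conj(DY), X, optimize=True), nfft, axis=-1)
    idx = (np.arange(L) - p) % nfft
    return G[:, :, idx]


def corr_time_same(x: np.ndarray, w: np.ndarray, padding: str = "same") -> np.ndarray:
    """Public helper: time-axis cross-correlation, summing the band axis."""
    y, _ = _corr_bank_forward(x, w, padding)
    return y


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class SEDynamicConv(Layer):
    """Dynamic convolution with squeeze-and-excitation kernel attention.

    ``K`` parallel time-axis kernels ``(N, Nb, L)`` are mixed per sample with
    weights ``pi = softmax(z / tau)`` where ``z = W2 relu(W1 g)`` and ``g`` is
    the band-wise global average of the input.  With ``K == 1`` the SE branch
    is omitted and the layer is an ordinary static convolution.
    """

    def __init__(
        self,
        n_bands: int,
        K: int,
        n_maps: int,
        kernel_len: int,
        reduction: int = 4,
        tau: float = 1.0,
        padding: str = "same",
        rng: np.random.Generator | None = None,
    ):
        if K < 1:
            raise ValueError("K must be >= 1")
        if tau <= 0:
            raise ValueError("softmax temperature must be positive")
        rng = rng or np.random.default_rng(0)
        self.padding = padding
        self.K, self.N, self.Nb, self.L, self.tau = K, n_maps, n_bands, kernel_len, tau
        self.bottleneck = max(1, n_bands // reduction)
        fan = n_bands * kernel_len
        self.W = Parameter("dynconv.W", _uniform(rng, (K, n_maps, n_bands, kernel_len), fan))
        self.b = Parameter("dynconv.b", np.zeros((K, n_maps)))
        if K > 1:
            self.W1 = Parameter("se.W1", _uniform(rng, (self.bottleneck, n_bands), n_bands))
            self.W2 = Parameter("se.W2", _uniform(rng, (K, self.bottleneck), self.bottleneck))
        else:
            self.W1 = self.W2 = None
        self.last_pi: np.ndarray | None = None

    def params(self):
        ps = [self.W, self.b]
        if self.K > 1:
            ps += [self.W1, self.W2]
        return ps

    def attention(self, x: np.ndarray) -> np.ndarray:
        """Kernel attention weights ``pi (B, K)`` for a batch (no caching)."""
        B = x.shape[0]
        if self.K == 1:
            return np.ones((B, 1))
        g = x.mean(axis=(2, 3))
        a = np.maximum(g @ self.W1.value.T, 0.0)
        z = a @ self.W2.value.T
        return softmax(z / self.tau, axis=1)

    def forward(self, x, train=False):
        B, _, _, T = x.shape
        if self.K > 1:
            self._g = x.mean(axis=(2, 3))
            self._a = np.maximum(self._g @ self.W1.value.T, 0.0)
            z = self._a @ self.W2.value.T
            pi = softmax(z / self.tau, axis=1)
        else:
            pi = np.ones((B, 1))
        self.last_pi = pi
        L = self.L
        if self.padding == "same":
            p, out_len = (L - 1) // 2, T
        else:
            p, out_len = 0, T - L + 1
        nfft = next_fast_len(T + L - 1)
        X = rfft(x, nfft, axis=-1)  # (B, Nb, C, F)
        # per-sample effective kernel: convex combination of the K basis kernels
        w_eff = np.einsum("bk,knvl->bnvl", pi, self.W.value, optimize=True)
        Wf = rfft(w_eff[..., ::-1], nfft, axis=-1)  # (B, N, Nb, F)
        Y = np.einsum("bvcf,bnvf->bncf", X, Wf, optimize=True)
        y = irfft(Y, nfft, axis=-1)[..., L - 1 - p : L - 1 - p + out_len]
        self._cache = (X, nfft, p)
        eff_bias = pi @ self.b.value  # (B, N)
        return y + eff_bias[:, :, None, None]

    def backward(self, dy):
        pi = self.last_pi
        X, nfft, p = self._cache
        dy_sum = dy.sum(axis=(2, 3))  # (B, N)
        # per-sample weight-grad correlations G[b,n,v,l] = sum_{c,t} dy x[t+l-p]
        DY = rfft(dy, nfft, axis=-1)
        Gf = np.einsum("bncf,bvcf->bnvf", np.conj(DY), X, optimize=True)
        G = irfft(Gf, nfft, axis=-1)[..., (np.arange(self.L) - p) % nfft]
        self.W.grad += np.einsum("bk,bnvl->knvl", pi, G, optimize=True)
        self.b.grad += pi.T @ dy_sum
        if self.K > 1:
            dpi = (
                np.einsum("knvl,bnvl->bk", self.W.value, G, optimize=True)
                + dy_sum @ self.b.value.T
            )
            dz = pi * (dpi - (dpi * pi).sum(axis=1, keepdims=True)) / self.tau
            self.W2.grad += dz.T @ self._a
            da = (dz @ self.W2.value) * (self._a > 0)
            self.W1.grad += da.T @ self._g
        return None  # input is data; no upstream gradient needed


class BatchNorm(Layer):
    """Per-feature batch normalization over all axes except axis 1.

    Inference uses the running statistics accumulated during training.  With
    ``probe_mode`` set, the statistics of the current batch are used instead
    (without updating the running ones) — used by analyses that feed the
    trained network inputs whose overall scale differs from the training
    distribution, such as single-band masking.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter("bn.gamma", np.ones(n_features))
        self.beta = Parameter("bn.beta", np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum, self.eps = momentum, eps
        self.probe_mode = False

    def params(self):
        return [self.gamma, self.beta]

    @staticmethod
    def _shape(x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train=False):
        axes = (0,) + tuple(range(2, x.ndim))
        sh = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        elif self.probe_mode:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(sh)) / self._std.reshape(sh)
        self._train_axes = axes
        self._m = x.size // x.shape[1]
        self._train_mode = train or self.probe_mode
        return self.gamma.value.reshape(sh) * self._xhat + self.beta.value.reshape(sh)

    def backward(self, dy):
        axes, sh = self._train_axes, self._shape(dy)
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value.reshape(sh)
        if not self._train_mode:
            return dxhat / self._std.reshape(sh)
        m = self._m
        term = (
            dxhat
            - dxhat.mean(axis=axes).reshape(sh)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes).reshape(sh) / m
        )
        return term / self._std.reshape(sh)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train=False):
        self._y = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._pos = x > 0
        return self._y

    def backward(self, dy):
        return dy * np.where(self._pos, 1.0, self._y + self.alpha)


class SpatialConv(Layer):
    """``m`` bias-free filters contracting the (map, electrode) axes per time point."""

    def __init__(self, m: int, n_maps: int, n_channels: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.S = Parameter(
            "spatial.S", _uniform(rng, (m, n_maps, n_channels), n_maps * n_channels)
        )

    def params(self):
        return [self.S]

    def forward(self, x, train=False):
        self._x = x
        return np.einsum("bnct,mnc->bmt", x, self.S.value, optimize=True)

    def backward(self, dy):
        self.S.grad += np.einsum("bmt,bnct->mnc", dy, self._x, optimize=True)
        return np.einsum("bmt,mnc->bnct", dy, self.S.value, optimize=True)


class WindowVariance(Layer):
    """Population variance over non-overlapping windows of length ``w``.

    ``(B, m, T1) -> (B, m, n)`` with ``n = floor(T1 / w)``; trailing samples
    beyond ``n * w`` are discarded.
    """

    def __init__(self, w: int):
        if w < 1:
            raise ValueError("window length must be >= 1")
        self.w = w

    def forward(self, x, train=False):
        T1 = x.shape[-1]
        if self.w > T1:
            raise ValueError(f"window length {self.w} exceeds series length {T1}")
        n = T1 // self.w
        xw = x[..., : n * self.w].reshape(*x.shape[:-1], n, self.w)
        mu = xw.mean(axis=-1, keepdims=True)
        self._dev = xw - mu
        self._T1 = T1
        return (self._dev**2).mean(axis=-1)

    def backward(self, dv):
        dxw = 2.0 * self._dev * dv[..., None] / self.w
        dx = np.zeros(dxw.shape[:-2] + (self._T1,))
        dx[..., : dxw.shape[-2] * self.w] = dxw.reshape(*dxw.shape[:-2], -1)
        return dx


class TemporalAttention(Layer):
    """Group-wise attention over window variances.

    A shared matrix ``U (h, n)`` is row-softmaxed over the window axis (unless
    ``apply_softmax`` is disabled for the raw-weight form) and channel ``c``
    uses row ``c mod h``: ``xout[c] = sum_q A[c mod h, q] v[c, q]``.
    """

    def __init__(self, h: int, n_windows: int, m: int, apply_softmax: bool = True, rng=None):
        if m % h != 0:
            raise ValueError(f"group size h={h} must divide m={m}")
        rng = rng or np.random.default_rng(0)
        self.h, self.n, self.m = h, n_windows, m
        self.apply_softmax = apply_softmax
        self.U = Parameter("temporal.U", _uniform(rng, (h, n_windows), n_windows))
        self._rows = np.arange(m) % h

    def params(self):
        return [self.U]

    def attention_matrix(self) -> np.ndarray:
        return softmax(self.U.value, axis=1) if self.apply_softmax else self.U.value

    def forward(self, v, train=False):
        if v.shape[1] != self.m or v.shape[2] != self.n:
            raise ValueError(f"expected (B, {self.m}, {self.n}), got {v.shape}")
        self._A = self.attention_matrix()
        self._v = v
        return np.einsum("bmn,mn->bm", v, self._A[self._rows], optimize=True)

    def backward(self, dy):
        dA_per_chan = np.einsum("bm,bmn->mn", dy, self._v, optimize=True)
        dA = np.zeros_like(self.U.value)
        np.add.at(dA, self._rows, dA_per_chan)
        if self.apply_softmax:
            A = self._A
            self.U.grad += A * (dA - (dA * A).sum(axis=1, keepdims=True))
        else:
            self.U.grad += dA
        return dy[:, :, None] * self._A[self._rows]


class PoolChannels(Layer):
    """Mean over the electrode axis: ``(B, N, C, T) -> (B, N, T)``."""

    def forward(self, x, train=False):
        self._C = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None, :], self._C, axis=2) / self._C


class PoolTime(Layer):
    """Mean over time: ``(B, m, T) -> (B, m)``."""

    def forward(self, x, train=False):
        self._T = x.shape[-1]
        return x.mean(axis=-1)

    def backward(self, dy):
        return np.repeat(dy[..., None], self._T, axis=-1) / self._T


class PoolTimeFlatten(Layer):
    """Mean over time then flatten maps x electrodes: ``(B, N, C, T) -> (B, N*C)``."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=-1).reshape(x.shape[0], -1)

    def backward(self, dy):
        B, N, C, T = self._shape
        return np.repeat(dy.reshape(B, N, C)[..., None], T, axis=-1) / T


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Linear(Layer):
    def __init__(self, n_out: int, n_in: int, bias: bool = False, rng=None):
        rng = rng or np.random.default_rng(0)
        self.Wl = Parameter("linear.W", _uniform(rng, (n_out, n_in), n_in))
        self.bl = Parameter("linear.b", np.zeros(n_out)) if bias else None

    def params(self):
        return [self.Wl] + ([self.bl] if self.bl is not None else [])

    def forward(self, x, train=False):
        self._x = x
        y = x @ self.Wl.value.T
        if self.bl is not None:
            y = y + self.bl.value
        return y

    def backward(self, dy):
        self.Wl.grad += dy.T @ self._x
        if self.bl is not None:
            self.bl.grad += dy.sum(axis=0)
        return dy @ self.Wl.value


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, probabilities, dlogits)."""
    p = softmax(logits, axis=1)
    B = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(B), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    return loss, p, dlogits / B


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.weight_decay * p.value
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
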