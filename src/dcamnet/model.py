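"""The fatigue-detection network and its scikit-learn estimator wrapper.

Architecture (per sample, input is the ``(Nb, C, T)`` filter-bank tensor):

1. **Dynamic convolution block** — ``K`` parallel time-axis kernels
   ``(N, Nb, 1, L)`` are aggregated into one effective kernel with
   input-dependent weights ``pi`` produced by a squeeze-and-excitation branch
   (band-wise global average pooling, bottlenecked two-layer map, temperature
   softmax).  Batch normalization + ELU follow, yielding ``(N, C, T1)``.
2. **Spatial convolution block** — ``m`` bias-free filters contract the
   (map, electrode) axes per time point; batch normalization + ELU give
   ``(m, T1)`` single-channel series.
3. **Temporal attention block** — each series is cut into ``n = floor(T1/w)``
   non-overlapping windows; the per-window population variance is a local
   energy descriptor, and a shared row-softmaxed matrix ``U (h, n)`` scores
   the windows group-wise, producing an ``m``-vector.
4. Dropout and a bias-free fully connected layer map to ``Nc`` class logits.

Ablation variants (single static kernel, no spatial block, pooled temporal
block, minimal conv+classifier), band masking, channel dropping, and the
closed-form parameter accounting live here as well.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .filterbank import FilterBankSpec, filter_bank_transform

__all__ = [
    "DCAMNetConfig",
    "DCAMNet",
    "DCAMNetClassifier",
    "ABLATION_VARIANTS",
    "count_parameters",
    "aggregate_kernels",
    "make_ablation_variant",
    "dense_layer_params",
    "mask_bands",
    "drop_channels",
]

ABLATION_VARIANTS = ("full", "static_K1", "no_spatial", "no_temporal", "minimal")


@dataclass
class DCAMNetConfig:
    """Hyperparameters of the network.

    Defaults follow the reference configuration: ``K=4`` kernels of length
    ``L=64`` producing ``N=16`` maps, SE reduction ``r=4`` (bottleneck
    ``max(1, floor(Nb/r))``), temperature 1, ``m=16`` spatial filters, window
    ``w=25`` samples with ``h=4`` group channels, dropout 0.5.
    """

    C: int = 17
    T: int = 800
    n_bands: int = 9
    K: int = 4
    N: int = 16
    L: int = 64
    r: int = 4
    tau_d: float = 1.0
    m: int = 16
    w: int = 25
    h: int = 4
    n_classes: int = 2
    dropout: float = 0.5
    padding: str = "same"  # 'same' keeps T1 = T; 'valid' gives T1 = T - L + 1
    softmax_temporal: bool = True

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_classes < 2 or self.w < 1:
            raise ValueError("invalid config: require K >= 1, Nc >= 2, w >= 1")
        if self.m % self.h != 0:
            raise ValueError(f"h={self.h} must divide m={self.m}")
        if self.tau_d <= 0:
            raise ValueError("tau_d must be positive")
        if self.padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {self.padding!r}")

    @property
    def bottleneck(self) -> int:
        return max(1, self.n_bands // self.r)

    @property
    def T1(self) -> int:
        return self.T if self.padding == "same" else self.T - self.L + 1

    @property
    def n_windows(self) -> int:
        return self.T1 // self.w


class DCAMNet:
    """The assembled layer stack for one ablation variant."""

    def __init__(self, cfg: DCAMNetConfig, variant: str = "full", seed: int = 0):
        if variant not in ABLATION_VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {ABLATION_VARIANTS}")
        self.cfg = cfg
        self.variant = variant
        rng = np.random.default_rng(seed)
        c = cfg
        K = 1 if variant in ("static_K1", "minimal") else c.K
        self.conv = _nn.SEDynamicConv(
            c.n_bands, K, c.N, c.L, reduction=c.r, tau=c.tau_d, padding=c.padding, rng=rng
        )
        self.dropout = _nn.Dropout(c.dropout, rng=np.random.default_rng(seed + 1))

        if variant == "minimal":
            self.layers = [
                self.conv,
                _nn.ELU(),
                _nn.PoolTimeFlatten(),
                self.dropout,
                _nn.Linear(c.n_classes, c.N * c.C, rng=rng),
            ]
            return

        head_width = c.m
        layers: list[_nn.Layer] = [self.conv, _nn.BatchNorm(c.N), _nn.ELU()]
        if variant == "no_spatial":
            layers.append(_nn.PoolChannels())
            head_width = c.N
        else:
            layers += [
                _nn.SpatialConv(c.m, c.N, c.C, rng=rng),
                _nn.BatchNorm(c.m),
                _nn.ELU(),
            ]
        if variant == "no_temporal":
            layers.append(_nn.PoolTime())
        else:
            if head_width % c.h != 0:
                raise ValueError(f"h={c.h} must divide the attention width {head_width}")
            layers += [
                _nn.WindowVariance(c.w),
                _nn.TemporalAttention(
                    c.h, c.n_windows, head_width, apply_softmax=c.softmax_temporal, rng=rng
                ),
            ]
        layers += [self.dropout, _nn.Linear(c.n_classes, head_width, rng=rng)]
        self.layers = layers

    # -- forward / backward --------------------------------------------------
    def params(self) -> list[_nn.Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._validate(x)
        for layer in self.layers:
            x = layer.forward(x, train=train)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite activations in forward pass")
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
            if g is None:
                break

    def predict_proba(self, x: np.ndarray, probe_batch_stats: bool = False) -> np.ndarray:
        """Class probabilities; softmax of the forward logits.

        With `probe_batch_stats`, batch normalization uses the statistics of
        this batch rather than the frozen running statistics.  This is the
        mode used when probing the trained network with inputs whose overall
        scale lies outside the training distribution (e.g. band-masked
        tensors, where the frozen statistics would push activations into the
        ELU saturation region); pass the whole probe set as one batch.
        """
        if not probe_batch_stats:
            return _nn.softmax(self.forward(x, train=False), axis=1)
        bns = [l for l in self.layers if isinstance(l, _nn.BatchNorm)]
        for l in bns:
            l.probe_mode = True
        try:
            return _nn.softmax(self.forward(x, train=False), axis=1)
        finally:
            for l in bns:
                l.probe_mode = False

    def kernel_attention(self, x: np.ndarray) -> np.ndarray:
        self._validate(x)
        return self.conv.attention(x)

    def _validate(self, x: np.ndarray) -> None:
        c = self.cfg
        expect = (c.n_bands, c.C, c.T)
        if x.ndim != 4 or x.shape[1:] != expect:
            raise ValueError(f"expected input (batch, {expect[0]}, {expect[1]}, {expect[2]}), got {x.shape}")

    # -- state ----------------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param/{i}/{p.name}": p.value for i, p in enumerate(self.params())}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, _nn.BatchNorm):
                state[f"bn/{i}/mean"] = layer.running_mean
                state[f"bn/{i}/var"] = layer.running_var
        return state

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.state_arrays().items():
            v[...] = state[k]

    def save(self, path) -> None:
        """Single-file checkpoint: config JSON + weight arrays (zip archive)."""
        meta = {"config": asdict(self.cfg), "variant": self.variant}
        buf = io.BytesIO()
        np.savez(buf, **self.get_state())
        with zipfile.ZipFile(path, "w") as z:
            z.writestr("meta.json", json.dumps(meta))
            z.writestr("state.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "DCAMNet":
        with zipfile.ZipFile(path) as z:
            meta = json.loads(z.read("meta.json"))
            with np.load(io.BytesIO(z.read("state.npz"))) as st:
                state = {k: st[k] for k in st.files}
        net = cls(DCAMNetConfig(**meta["config"]), variant=meta["variant"])
        net.set_state(state)
        return net


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------


def aggregate_kernels(weights: np.ndarray, biases: np.ndarray, pi) -> tuple[np.ndarray, np.ndarray]:
    """Convex combination of ``K`` basis kernels and biases with weights `pi`.

    `weights` is ``(K, N, Nb, L)``, `biases` ``(K, N)``, and `pi` a length-K
    vector on the probability simplex; returns the effective kernel
    ``(N, Nb, L)`` and bias ``(N,)``.
    """
    pi = np.asarray(pi, dtype=np.float64)
    if pi.ndim != 1 or len(pi) != weights.shape[0]:
        raise ValueError(f"pi must be a length-{weights.shape[0]} vector")
    if pi.min() < -1e-9 or abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError("pi must lie on the probability simplex")
    return np.einsum("k,knvl->nvl", pi, weights), pi @ biases


def dense_layer_params(n_in: int, n_out: int, bias: bool = False) -> int:
    """Weight count of one dense layer (used for baseline bookkeeping)."""
    return n_in * n_out + (n_out if bias else 0)


def count_parameters(cfg: DCAMNetConfig, variant: str = "full") -> dict:
    """Closed-form per-layer parameter counts.

    ``table_rows`` follows the layer-table convention (dynamic convolution
    ``K*N*(Nb*L+1)``, spatial ``m*N*C``, temporal attention ``h*floor(T1/w)``,
    fully connected ``Nc*m``), with the SE branch
    (``bottleneck*Nb + K*bottleneck``) listed separately.  ``full_total``
    additionally includes the batch-normalization affine parameters and the SE
    branch, and matches the number of learnable scalars in :class:`DCAMNet`.
    """
    c = cfg
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    K = 1 if variant in ("static_K1", "minimal") else c.K
    rows: dict[str, int] = {"dynamic_conv": K * c.N * (c.n_bands * c.L + 1)}
    se = 0 if K == 1 else c.bottleneck * c.n_bands + K * c.bottleneck
    bn = 0
    if variant == "minimal":
        rows["fully_connected"] = c.n_classes * c.N * c.C
    else:
        bn += 2 * c.N
        head_width = c.m
        if variant == "no_spatial":
            head_width = c.N
        else:
            rows["spatial_conv"] = c.m * c.N * c.C
            bn += 2 * c.m
        if variant != "no_temporal":
            rows["temporal_attention"] = c.h * c.n_windows
        rows["fully_connected"] = c.n_classes * head_width
    table_total = sum(rows.values())
    return {
        "table_rows": rows,
        "se_branch": se,
        "batch_norm": bn,
        "table_total": table_total,
        "full_total": table_total + se + bn,
    }


# ---------------------------------------------------------------------------
# masking / channel analyses
# ---------------------------------------------------------------------------


def mask_bands(xfb: np.ndarray, keep) -> np.ndarray:
    """Zero all band slices except those in `keep` (band axis = -3).

    Works on a single ``(Nb, C, T)`` tensor or a batch ``(n, Nb, C, T)``; the
    kept slices are copied bit-identically.  Intended for probing an
    already-trained network without retraining.
    """
    keep = sorted(set(int(k) for k in np.atleast_1d(keep)))
    if not keep:
        raise ValueError("keep set must be non-empty")
    n_bands = xfb.shape[-3]
    if any(k < 0 or k >= n_bands for k in keep):
        raise ValueError(f"band indices {keep} outside [0, {n_bands})")
    out = np.zeros_like(xfb)
    out[..., keep, :, :] = xfb[..., keep, :, :]
    return out


def drop_channels(X: np.ndarray, channel_names: list[str], drop) -> tuple[np.ndarray, list[str]]:
    """Remove electrodes by name or index from epochs ``(..., C, T)``."""
    names = list(channel_names)
    idx = []
    for d in drop:
        if isinstance(d, (int, np.integer)):
            if not 0 <= d < len(names):
                raise KeyError(f"channel index {d} out of range; available: {names}")
            idx.append(int(d))
        else:
            if d not in names:
                raise KeyError(f"unknown channel {d!r}; available: {names}")
            idx.append(names.index(d))
    keep = [i for i in range(len(names)) if i not in set(idx)]
    return X[..., keep, :], [names[i] for i in keep]


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------


class DCAMNetClassifier(BaseEstimator, ClassifierMixin):
    """Binary EEG fatigue classifier with SE-driven dynamic convolution.

    Accepts either pre-expanded multi-band tensors ``(n, Nb, C, T)`` or raw
    epochs ``(n, C, T)``; in the latter case set `fs` so the nine-band filter
    bank can be applied internally.

    Parameters mirror :class:`DCAMNetConfig` plus the training protocol
    (Adam, step learning-rate decay, early stopping on a stratified
    validation split).  All randomness (weight init, batching, dropout,
    validation split) derives from `seed`.

    Attributes
    ----------
    classes_ : ndarray
        Class labels (index 1 is the fatigued/positive class).
    network_ : DCAMNet
        The fitted layer stack.
    history_ : dict
        Per-epoch training/validation losses and learning rates.
    """

    def __init__(
        self,
        K: int = 4,
        N: int = 16,
        L: int = 64,
        r: int = 4,
        tau_d: float = 1.0,
        m: int = 16,
        w: int = 25,
        h: int = 4,
        dropout: float = 0.5,
        padding: str = "same",
        softmax_temporal: bool = True,
        variant: str = "full",
        fs: float | None = None,
        band_spec: FilterBankSpec | None = None,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        weight_decay: float = 1e-4,
        lr_step: int = 50,
        lr_factor: float = 0.5,
        max_epochs: int = 300,
        batch_size: int = 64,
        patience: int = 30,
        val_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.K = K
        self.N = N
        self.L = L
        self.r = r
        self.tau_d = tau_d
        self.m = m
        self.w = w
        self.h = h
        self.dropout = dropout
        self.padding = padding
        self.softmax_temporal = softmax_temporal
        self.variant = variant
        self.fs = fs
        self.band_spec = band_spec
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.weight_decay = weight_decay
        self.lr_step = lr_step
        self.lr_factor = lr_factor
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    # -- helpers --------------------------------------------------------------
    def _expand(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            if self.fs is None:
                raise ValueError("raw (n, C, T) input requires fs for the filter bank")
            X = filter_bank_transform(X, self.fs, self.band_spec)
        if X.ndim != 4:
            raise ValueError(f"expected (n, Nb, C, T) or (n, C, T), got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("input contains non-finite values")
        return X

    def _config(self, n_bands: int, C: int, T: int) -> DCAMNetConfig:
        return DCAMNetConfig(
            C=C,
            T=T,
            n_bands=n_bands,
            K=self.K,
            N=self.N,
            L=self.L,
            r=self.r,
            tau_d=self.tau_d,
            m=self.m,
            w=self.w,
            h=self.h,
            dropout=self.dropout,
            padding=self.padding,
            softmax_temporal=self.softmax_temporal,
        )

    # -- estimator API ---------------------------------------------------------
    def fit(self, X, y, val=None):
        """Fit on epochs X with binary labels y.

        `val` optionally supplies an explicit ``(X_val, y_val)`` pair;
        otherwise `val_fraction` of the training data is held out, stratified.
        """
        from .training import TrainConfig, train_network

        X = self._expand(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError(f"expected 2 classes, got {len(self.classes_)}")
        cfg = self._config(*X.shape[1:])
        self.config_ = cfg
        net = DCAMNet(cfg, variant=self.variant, seed=self.seed)
        tc = TrainConfig(
            lr=self.lr,
            beta1=self.beta1,
            beta2=self.beta2,
            weight_decay=self.weight_decay,
            lr_step=self.lr_step,
            lr_factor=self.lr_factor,
            max_epochs=self.max_epochs,
            batch=self.batch_size,
            patience=self.patience,
            val_fraction=self.val_fraction,
            seed=self.seed,
        )
        if val is not None:
            Xv, yv = val
            Xv = self._expand(Xv)
            yv = np.searchsorted(self.classes_, np.asarray(yv))
            val = (Xv, yv)
        self.history_ = train_network(net, X, y_idx, tc, val=val)
        self.network_ = net
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = self._expand(X)
        out = []
        for start in range(0, len(X), self.batch_size):
            out.append(self.network_.predict_proba(X[start : start + self.batch_size]))
        return np.vstack(out)

    def predict(self, X):
        proba = self.predict_proba(X)
        # exact ties at the decision threshold resolve to the first (alert) class
        return self.classes_[(proba[:, 1] > proba[:, 0]).astype(int)]

    def kernel_attention(self, X):
        """Per-sample kernel attention weights ``pi (n, K)``."""
        check_is_fitted(self, "network_")
        X = self._expand(X)
        out = []
        for start in range(0, len(X), self.batch_size):
            out.append(self.network_.kernel_attention(X[start : start + self.batch_size]))
        return np.vstack(out)

    def count_parameters(self):
        check_is_fitted(self, "network_")
        return count_parameters(self.config_, variant=self.variant)

    def clone_variant(self, variant: str) -> "DCAMNetClassifier":
        """Unfitted copy configured as a different ablation variant."""
        params = self.get_params()
        params["variant"] = variant
        return DCAMNetClassifier(**params)


def make_ablation_variant(cfg: DCAMNetConfig, variant: str, seed: int = 0) -> DCAMNet:
    """Construct the requested ablation variant of the network."""
    return DCAMNet(cfg, variant=variant, seed=seed)
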