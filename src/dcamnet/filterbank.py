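"""Preprocessing of continuous EEG into epochs and multi-band tensors.

The pipeline mirrors standard fatigue-EEG practice: a zero-phase Butterworth
bandpass (0.5-45 Hz) removes drift and high-frequency noise, the continuous
record is cut into fixed-length epochs, and each epoch is expanded through a
nine-band filter bank (delta, theta, alpha1, alpha2, beta1, beta2, gamma1,
gamma2, broadband) into the ``(Nb, C, T)`` tensor the network consumes.

All filters are fourth-order Butterworth designs applied forward and backward
(zero phase, effective magnitude order 8).  Edge transients are bounded by
reflection padding of length ``3 * order``.  Time windows are half-open
``[start, end)`` in seconds; sample indices are 0-based; amplitudes are
microvolts throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BandDefinition",
    "FilterBankSpec",
    "EEGEpoch",
    "MultiBandTensor",
    "apply_zero_phase_bandpass",
    "segment_epochs",
    "filter_bank_decompose",
    "filter_bank_transform",
    "FilterBank",
]

#: Canonical nine-band decomposition (Hz).  Index 0 = delta ... index 8 = broadband.
DEFAULT_BANDS = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha1", 8.0, 10.0),
    ("alpha2", 10.0, 13.0),
    ("beta1", 13.0, 20.0),
    ("beta2", 20.0, 30.0),
    ("gamma1", 30.0, 36.0),
    ("gamma2", 36.0, 42.0),
    ("broadband", 0.5, 45.0),
)


@dataclass(frozen=True)
class BandDefinition:
    """One bandpass edge pair in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0.0 < self.low < self.high:
            raise ValueError(
                f"band {self.name!r}: require 0 < low < high, got ({self.low}, {self.high})"
            )


@dataclass(frozen=True)
class FilterBankSpec:
    """Ordered set of bands plus the shared filter realization."""

    bands: tuple[BandDefinition, ...] = field(
        default_factory=lambda: tuple(BandDefinition(*b) for b in DEFAULT_BANDS)
    )
    order: int = 4
    zero_phase: bool = True

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def validate_against_fs(self, fs: float) -> None:
        nyq = fs / 2.0
        for band in self.bands:
            if band.high >= nyq:
                raise ValueError(
                    f"band {band.name!r} high edge {band.high} Hz >= Nyquist {nyq} Hz"
                )

    @classmethod
    def default(cls) -> "FilterBankSpec":
        return cls()


@dataclass
class EEGEpoch:
    """A preprocessed ``C x T`` epoch in microvolts."""

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or min(self.samples.shape) < 1:
            raise ValueError("epoch samples must be a non-empty C x T matrix")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("epoch contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]


@dataclass
class MultiBandTensor:
    """``(Nb, C, T)`` filter-bank expansion of a single epoch."""

    values: np.ndarray
    band_spec: FilterBankSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("multi-band tensor must be (Nb, C, T)")
        if self.values.shape[0] != self.band_spec.n_bands:
            raise ValueError(
                f"first axis {self.values.shape[0]} != number of bands "
                f"{self.band_spec.n_bands}"
            )


def _design_sos(fs: float, low: float, high: float, order: int) -> np.ndarray:
    nyq = fs / 2.0
    if not 0.0 < low < high:
        raise ValueError(f"invalid band edges ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def apply_zero_phase_bandpass(
    x: np.ndarray,
    fs: float,
    low: float,
    high: float,
    order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Forward-backward Butterworth bandpass (zero phase distortion).

    Parameters
    ----------
    x : array
        Signal(s); filtering runs along `axis` (time).
    fs, low, high : float
        Sampling rate and band edges in Hz; requires ``0 < low < high < fs/2``.
    order : int
        Order of the underlying one-way Butterworth design (default 4; the
        forward-backward pass doubles the effective magnitude order).
    """
    x = np.asarray(x, dtype=np.float64)
    sos = _design_sos(fs, low, high, order)
    padlen = 3 * order
    if x.shape[axis] <= padlen:
        raise ValueError(
            f"signal length {x.shape[axis]} too short for stable filtering "
            f"(need > {padlen} samples)"
        )
    return sps.sosfiltfilt(sos, x, axis=axis, padtype="even", padlen=padlen)


def zero_phase_magnitude(
    fs: float, low: float, high: float, freq: float, order: int = 4
) -> float:
    """Magnitude response of the forward-backward filter at `freq` Hz."""
    sos = _design_sos(fs, low, high, order)
    _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
    return float(np.abs(h[0]) ** 2)  # applied twice


def segment_epochs(
    continuous: np.ndarray,
    fs: float,
    epoch_seconds: float,
    anchors: np.ndarray | list[float] | None = None,
    subject_id: str = "",
) -> list[EEGEpoch]:
    """Cut a continuous ``C x T`` record into fixed-length epochs.

    Without `anchors`: contiguous non-overlapping windows from the start, the
    trailing remainder discarded.  With `anchors` (event-locked mode): each
    epoch covers ``[anchor - epoch_seconds, anchor)`` — the window immediately
    preceding the event; anchors too close to the recording start are skipped
    with a warning.
    """
    continuous = np.asarray(continuous, dtype=np.float64)
    if continuous.ndim != 2:
        raise ValueError("continuous recording must be C x T")
    n_samp = epoch_seconds * fs
    if abs(n_samp - round(n_samp)) > 1e-9:
        raise ValueError(
            f"epoch_seconds * fs = {n_samp} is not a whole number of samples"
        )
    n_samp = int(round(n_samp))
    total = continuous.shape[1]

    epochs: list[EEGEpoch] = []
    if anchors is None:
        for start in range(0, total - n_samp + 1, n_samp):
            epochs.append(
                EEGEpoch(continuous[:, start : start + n_samp], fs, subject_id)
            )
        return epochs

    for anchor in np.asarray(anchors, dtype=np.float64):
        end = int(round(anchor * fs))
        start = end - n_samp
        if start < 0 or end > total:
            warnings.warn(
                f"anchor at {anchor:.3f} s lacks a full {epoch_seconds} s "
                "pre-anchor window; epoch skipped",
                stacklevel=2,
            )
            continue
        epochs.append(EEGEpoch(continuous[:, start:end], fs, subject_id))
    return epochs


def filter_bank_decompose(
    epoch: EEGEpoch | np.ndarray,
    fs: float | None = None,
    spec: FilterBankSpec | None = None,
) -> MultiBandTensor:
    """Expand one epoch into its ``(Nb, C, T)`` multi-band tensor."""
    if isinstance(epoch, EEGEpoch):
        samples, fs = epoch.samples, epoch.fs
    else:
        if fs is None:
            raise ValueError("fs required when passing a raw array")
        samples = np.asarray(epoch, dtype=np.float64)
    spec = spec or FilterBankSpec.default()
    values = filter_bank_transform(samples[None], fs, spec)[0]
    return MultiBandTensor(values, spec)


def filter_bank_transform(
    X: np.ndarray, fs: float, spec: FilterBankSpec | None = None
) -> np.ndarray:
    """Vectorized filter bank: ``(n, C, T) -> (n, Nb, C, T)``."""
    spec = spec or FilterBankSpec.default()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError("expected (n_epochs, C, T)")
    spec.validate_against_fs(fs)
    out = np.empty((X.shape[0], spec.n_bands) + X.shape[1:], dtype=np.float64)
    for b, band in enumerate(spec.bands):
        out[:, b] = apply_zero_phase_bandpass(
            X, fs, band.low, band.high, order=spec.order, axis=-1
        )
    return out


class FilterBank(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer wrapping :func:`filter_bank_transform`.

    Transforms raw epochs ``(n, C, T)`` into multi-band tensors
    ``(n, Nb, C, T)``; stateless apart from parameter validation.
    """

    def __init__(self, fs: float = 200.0, spec: FilterBankSpec | None = None):
        self.fs = fs
        self.spec = spec

    def fit(self, X, y=None):
        spec = self.spec or FilterBankSpec.default()
        spec.validate_against_fs(self.fs)
        self.n_bands_ = spec.n_bands
        return self

    def transform(self, X):
        return filter_bank_transform(X, self.fs, self.spec)
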