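"""Synthetic multi-subject fatigue EEG, deviation sessions, and eye tracking.

The EEG model is deliberately simple but carries the statistical structure
the detector exploits: each epoch is 1/f^gamma background noise plus
amplitude-modulated narrowband oscillations in the theta, alpha, and beta
ranges.  Fatigued epochs raise theta and alpha power and suppress beta power
by configurable dB effects; each subject carries fixed band-power offsets
(and an individual alpha peak frequency), which is what makes held-out
subjects genuinely harder than held-out segments.

Deviation sessions and eye-closure streams carry the generator's *intended*
state per event/epoch, so the label-derivation rules can be tested against
ground truth rather than against themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfftfreq

from .labeling import DeviationEvent, EyeEpochDurations, SessionEvents

__all__ = [
    "SubjectProfile",
    "SimConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_deviation_session",
    "simulate_eye_epochs",
]

_BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}


@dataclass
class SubjectProfile:
    """Per-subject spectral idiosyncrasies (log-power offsets in dB)."""

    band_power_offsets: dict = field(default_factory=dict)  # band -> dB, |dB| <= 6
    alpha_peak_shift: float = 0.0  # Hz relative to 10 Hz; peak stays in 8-13
    noise_scale: float = 1.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        for band, db in self.band_power_offsets.items():
            if abs(db) > 6.0:
                raise ValueError(f"offset for {band} ({db} dB) outside +/-6 dB")
        if not 8.0 <= 10.0 + self.alpha_peak_shift <= 13.0:
            raise ValueError("alpha peak must stay inside 8-13 Hz")


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults: 6 subjects x 40 epochs per class, 8 channels, 4 s epochs at
    200 Hz (T=800), class effects +3 dB theta / +2 dB alpha / -2 dB beta,
    pink-noise exponent 1, subject offsets drawn with sd 2 dB (clipped at
    +/-6 dB).
    """

    n_subjects: int = 6
    epochs_per_class_per_subject: int = 40
    C: int = 8
    fs: float = 200.0
    T: int = 800
    theta_effect_db: float = 3.0
    alpha_effect_db: float = 2.0
    beta_effect_db: float = -2.0
    subject_offset_sd_db: float = 2.0
    osc_amplitude: float = 1.0
    modulation_depth: float = 0.5
    pink_noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.epochs_per_class_per_subject, self.C, self.T) < 1:
            raise ValueError("counts must be >= 1")
        for eff in (self.theta_effect_db, self.alpha_effect_db, self.beta_effect_db):
            if not np.isfinite(eff):
                raise ValueError("effects must be finite")


@dataclass
class SimulatedDataset:
    X: np.ndarray  # (n_epochs, C, T)
    y: np.ndarray  # 0 = alert, 1 = fatigued
    subjects: np.ndarray  # subject label per epoch
    fs: float
    profiles: list[SubjectProfile]
    channel_names: list[str]


def _pink_noise(rng, shape, T, fs, exponent):
    """1/f^gamma noise synthesized in the frequency domain, unit variance."""
    freqs = rfftfreq(T, 1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    coef = (rng.normal(size=shape + (len(freqs),)) + 1j * rng.normal(size=shape + (len(freqs),))) * scale
    x = irfft(coef, T, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _narrowband(rng, shape, T, fs, low, high, modulation_depth):
    """Amplitude-modulated band-limited Gaussian process, unit RMS."""
    freqs = rfftfreq(T, 1.0 / fs)
    mask = ((freqs >= low) & (freqs <= high)).astype(float)
    coef = (rng.normal(size=shape + (len(freqs),)) + 1j * rng.normal(size=shape + (len(freqs),))) * mask
    x = irfft(coef, T, axis=-1)
    x = x / (x.std(axis=-1, keepdims=True) + 1e-30)
    if modulation_depth > 0:
        t = np.arange(T) / fs
        f_mod = rng.uniform(0.1, 0.5, size=shape)[..., None]
        phase = rng.uniform(0, 2 * np.pi, size=shape)[..., None]
        env = 1.0 + modulation_depth * np.sin(2 * np.pi * f_mod * t + phase)
        x = x * env
        x = x / x.std(axis=-1, keepdims=True)
    return x


def _draw_profile(rng, cfg: SimConfig, subject_id: str) -> SubjectProfile:
    offsets = {
        band: float(np.clip(rng.normal(0.0, cfg.subject_offset_sd_db), -6.0, 6.0))
        for band in _BANDS
    }
    shift = float(np.clip(rng.normal(0.0, 1.0), -1.5, 2.5))
    return SubjectProfile(offsets, shift, float(rng.lognormal(0.0, 0.1)), subject_id)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate the labeled multi-subject epoch collection.

    Per epoch: pink background noise per channel plus theta/alpha/beta
    oscillations shared across channels through fixed random channel gains.
    Band oscillation power is ``osc_amplitude^2`` scaled by
    ``10^((subject_offset + class_effect)/10)``, with the class effect applied
    only to fatigued epochs.  Classes are balanced per subject; everything is
    driven by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    effects = {
        "theta": cfg.theta_effect_db,
        "alpha": cfg.alpha_effect_db,
        "beta": cfg.beta_effect_db,
    }
    n_per_subj = 2 * cfg.epochs_per_class_per_subject
    X = np.empty((cfg.n_subjects * n_per_subj, cfg.C, cfg.T))
    y = np.empty(len(X), dtype=np.int64)
    subjects = np.empty(len(X), dtype=object)
    profiles = []
    row = 0
    for s in range(cfg.n_subjects):
        sid = f"S{s + 1:02d}"
        profile = _draw_profile(rng, cfg, sid)
        profiles.append(profile)
        gains = {band: rng.uniform(0.5, 1.5, size=cfg.C) for band in _BANDS}
        for label in (0, 1):
            for _ in range(cfg.epochs_per_class_per_subject):
                epoch = profile.noise_scale * _pink_noise(
                    rng, (cfg.C,), cfg.T, cfg.fs, cfg.pink_noise_exponent
                )
                for band, (low, high) in _BANDS.items():
                    if band == "alpha":
                        center = 10.0 + profile.alpha_peak_shift
                        low, high = center - 1.5, center + 1.5
                    db = profile.band_power_offsets[band] + (effects[band] if label else 0.0)
                    amp = cfg.osc_amplitude * 10.0 ** (db / 20.0)
                    osc = _narrowband(
                        rng, (), cfg.T, cfg.fs, low, high, cfg.modulation_depth
                    )
                    epoch += amp * gains[band][:, None] * osc[None, :]
                X[row] = epoch
                y[row] = label
                subjects[row] = sid
                row += 1
    names = [f"CH{i + 1}" for i in range(cfg.C)]
    return SimulatedDataset(X, y, subjects.astype(str), cfg.fs, profiles, names)


def simulate_deviation_session(
    n_events: int,
    fatigue_trajectory,
    seed: int = 0,
    spacing_s: tuple[float, float] = (5.0, 15.0),
    alert_rt: tuple[float, float] = (0.7, 0.08),
    fatigued_rt: tuple[float, float] = (5.0, 0.4),
    subject_id: str = "",
) -> tuple[SessionEvents, np.ndarray]:
    """Deviation-event stream with known intended states.

    `fatigue_trajectory` gives the intended state (0/1) per event, or a
    scalar applied to all events.  Onsets are spaced uniformly within
    `spacing_s`; reaction times are Gaussian draws around the alert or
    inflated fatigued mean (truncated at 50 ms).

    Note the downstream labeling rule sets its alert threshold at the 95th
    percentile of *all* local reaction times, so trajectories with more than
    about 5% strongly inflated events push that threshold into the inflated
    range and suppress FATIGUED labels; ground-truth recovery tests should
    use sparse contiguous fatigued blocks.
    """
    if n_events < 2:
        raise ValueError("need at least 2 events")
    states = np.broadcast_to(np.asarray(fatigue_trajectory, dtype=int), (n_events,)).copy()
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(*spacing_s, size=n_events)
    deps = np.cumsum(gaps)
    events = []
    for i in range(n_events):
        mean, sd = fatigued_rt if states[i] else alert_rt
        rt = max(0.05, rng.normal(mean, sd))
        events.append(DeviationEvent(dep=float(deps[i]), act=float(deps[i] + rt)))
    return SessionEvents(events, subject_id=subject_id), states


def simulate_eye_epochs(
    n_epochs: int,
    closure_level_trajectory,
    seed: int = 0,
    epoch_seconds: float = 4.0,
    coverage: float = 1.0,
    noise: float = 0.0,
) -> list[EyeEpochDurations]:
    """Eye-tracking duration streams whose expected PERCLOS follows the trajectory.

    `closure_level_trajectory` is a scalar or per-epoch array in [0, 1];
    `coverage` shrinks the observable interval below the epoch length;
    `noise` adds truncated Gaussian jitter to the closure fraction.
    """
    levels = np.broadcast_to(
        np.asarray(closure_level_trajectory, dtype=float), (n_epochs,)
    ).copy()
    if levels.min() < 0 or levels.max() > 1:
        raise ValueError("closure levels must lie in [0, 1]")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    epochs = []
    for s in range(n_epochs):
        interval = epoch_seconds * coverage
        frac = float(np.clip(levels[s] + (rng.normal(0.0, noise) if noise else 0.0), 0.0, 1.0))
        closure = frac * interval
        rest = interval - closure
        # split the open-eye remainder among blink/fixation/saccade
        shares = rng.dirichlet([1.0, 6.0, 2.0]) if rest > 0 else np.zeros(3)
        epochs.append(
            EyeEpochDurations(
                t_blink=float(rest * shares[0]),
                t_fixation=float(rest * shares[1]),
                t_saccade=float(rest * shares[2]),
                t_closure=float(closure),
                epoch_index=s,
            )
        )
    return epochs
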