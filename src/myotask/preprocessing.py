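"""EMG envelope extraction.

Raw EMG is turned into the nonnegative amplitude envelopes the coupling
estimators consume, using the standard recipe: full-wave rectification,
zero-phase low-pass Butterworth filtering (20 Hz cut-off), cubic-spline
time-normalisation to 1000 samples, and integration over consecutive
20-sample windows, yielding a ~50-step waveform per trial and muscle.

The chain is order-sensitive and the validator enforces it: rectifying
after filtering would re-introduce high-frequency content and change the
envelope, so a provenance list records the applied steps.  Amplitude
normalisation is deliberately absent — the downstream estimators are
rank-based and invariant to monotone amplitude rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from ._exceptions import ValidationError

__all__ = [
    "ProcessedEMG",
    "full_wave_rectify",
    "lowpass_zero_phase",
    "time_normalize",
    "integrate_windows",
    "resample_task_signal",
    "preprocess_emg",
]

#: canonical chain order; the pipeline validator rejects any other order
CHAIN_ORDER = ("rectify", "filter", "normalise", "integrate")


@dataclass
class ProcessedEMG:
    """Envelopes of shape (n_trials, n_muscles, T) with step provenance."""

    envelope: np.ndarray
    muscle_names: list = field(default_factory=list)
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.envelope = np.asarray(self.envelope, dtype=float)
        if self.envelope.ndim != 3:
            raise ValidationError("envelope must be (n_trials, n_muscles, T)")
        if (self.envelope < 0).any():
            raise ValidationError("envelope must be nonnegative")
        if not self.muscle_names:
            self.muscle_names = [f"m{i}" for i in range(self.envelope.shape[1])]

    @property
    def n_trials(self) -> int:
        return self.envelope.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.envelope.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.envelope.shape[2]


def full_wave_rectify(signal) -> np.ndarray:
    """Elementwise absolute value; idempotent."""
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite values")
    return np.abs(x)


def lowpass_zero_phase(signal, cutoff_hz: float = 20.0, sampling_rate: float = 1000.0,
                       order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass along the last axis.

    DC gain is unity and the forward-backward pass cancels the phase shift,
    squaring the magnitude response (an order-4 design acts as order 8 in
    magnitude).
    """
    x = np.asarray(signal, dtype=float)
    if sampling_rate <= 2.0 * cutoff_hz:
        raise ValidationError("sampling_rate must exceed twice the cut-off")
    padlen = 3 * max(order, 1) * 2 + 1
    if x.shape[-1] <= padlen:
        raise ValidationError(f"signal too short to filter (need > {padlen} samples)")
    b, a = butter(order, cutoff_hz, btype="low", fs=sampling_rate)
    return filtfilt(b, a, x, axis=-1)


def time_normalize(signal, n_samples: int = 1000) -> np.ndarray:
    """Cubic-spline resampling onto a uniform grid spanning the original support.

    Endpoints are preserved; splines reproduce polynomials up to cubic
    exactly, so linear ramps and quadratics pass through unchanged.
    """
    x = np.asarray(signal, dtype=float)
    if x.shape[-1] < 4:
        raise ValidationError("need at least 4 samples for cubic-spline resampling")
    src = np.linspace(0.0, 1.0, x.shape[-1])
    dst = np.linspace(0.0, 1.0, int(n_samples))
    return CubicSpline(src, x, axis=-1)(dst)


def resample_task_signal(series, target_length: int) -> np.ndarray:
    """Cubic-spline resampling of kinematic/dynamic/IMU traces to match the EMG base."""
    return time_normalize(series, target_length)


def integrate_windows(signal, window: int = 20) -> np.ndarray:
    """Sum consecutive non-overlapping windows along the last axis.

    A trailing remainder shorter than ``window`` is dropped (1000/20 is
    exact, so this only matters for nonstandard configurations).
    """
    x = np.asarray(signal, dtype=float)
    if window <= 0:
        raise ValidationError("window must be positive")
    length = x.shape[-1]
    if length < window:
        raise ValidationError("signal shorter than one window")
    n_out = length // window
    trimmed = x[..., : n_out * window]
    return trimmed.reshape(*x.shape[:-1], n_out, window).sum(axis=-1)


def preprocess_emg(raw, sampling_rate: float, cutoff_hz: float = 20.0,
                   n_samples: int = 1000, window: int = 20,
                   order: int = 4, muscle_names: list | None = None) -> ProcessedEMG:
    """Full envelope chain: rectify -> filter -> normalise -> integrate.

    raw : array (n_trials, n_muscles, n_raw_samples), no NaN.
    Returns envelopes of length ``n_samples // window`` (50 at defaults).
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 3:
        raise ValidationError("raw EMG must be (n_trials, n_muscles, samples)")
    if np.isnan(x).any():
        raise ValidationError("raw EMG contains NaN")
    if sampling_rate <= 2.0 * cutoff_hz:
        raise ValidationError("sampling rate must exceed twice the filter cut-off")
    x = full_wave_rectify(x)
    x = lowpass_zero_phase(x, cutoff_hz, sampling_rate, order)
    x = time_normalize(x, n_samples)
    # filtering can produce small negative lobes; the envelope is an
    # amplitude, so clip before integration
    x = np.clip(x, 0.0, None)
    env = integrate_windows(x, window)
    return ProcessedEMG(
        env,
        muscle_names=list(muscle_names or []),
        provenance=list(CHAIN_ORDER),
    )


def validate_chain(provenance) -> None:
    """Reject envelope products whose steps deviate from the canonical order."""
    if tuple(provenance) != CHAIN_ORDER:
        raise ValidationError(
            f"preprocessing chain {tuple(provenance)} violates required order {CHAIN_ORDER}"
        )
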