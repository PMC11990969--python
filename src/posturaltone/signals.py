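"""Uniformly sampled signals and the conditioning steps applied to them.

EMG is band-pass filtered (4th-order zero-phase Butterworth, 20-500 Hz) and
converted to a moving-window RMS envelope; COP traces are low-pass filtered
at 20 Hz; task excerpts are time-normalised to a fixed number of samples.
All filters are applied forward-backward (``scipy.signal.filtfilt``) so the
net phase shift is zero; each pass is 4th order, so the effective magnitude
response is squared (8th order).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .errors import SignalLengthError

__all__ = [
    "SampledSignal",
    "bandpass_emg",
    "lowpass_cop",
    "rms_envelope",
    "time_normalize",
    "check_emg_quiescence",
    "QuiescenceReport",
]

#: Resting-muscle EMG amplitude ceiling (uV); trials exceeding it are excluded.
EMG_QUIESCENCE_THRESHOLD_UV = 5.0

#: EMG band-pass corners (Hz) and COP low-pass corner (Hz).
EMG_BAND_HZ = (20.0, 500.0)
COP_LOWPASS_HZ = 20.0
FILTER_ORDER = 4

#: Moving-RMS window length in samples.
RMS_WINDOW_SAMPLES = 100


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled single-channel time series.

    Parameters
    ----------
    values
        Sample values, ordered in time.
    fs
        Sampling rate in Hz (> 0).
    units
        Physical units of the samples (e.g. ``"uV"``, ``"mm"``, ``"Nm"``).
    label
        Channel name (e.g. ``"TA"``, ``"cop_ap"``).
    """

    values: np.ndarray
    fs: float
    units: str = ""
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.values.ndim != 1:
            raise ValueError("SampledSignal values must be one-dimensional")
        if self.values.size < 2:
            raise SignalLengthError("SampledSignal needs at least 2 samples")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record duration in seconds (N / fs)."""
        return self.values.size / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.values.size) / self.fs

    def with_values(self, values: np.ndarray, **changes) -> "SampledSignal":
        """Copy of this signal with new sample values (rate/units kept)."""
        return replace(self, values=np.asarray(values, dtype=float), **changes)

    def slice_time(self, start: float, end: float) -> "SampledSignal":
        """Excerpt between two times (seconds, inclusive start, exclusive end)."""
        i0 = max(int(round(start * self.fs)), 0)
        i1 = min(int(round(end * self.fs)), self.values.size)
        if i1 - i0 < 2:
            raise SignalLengthError(
                f"slice [{start}, {end}) s keeps fewer than 2 samples"
            )
        return self.with_values(self.values[i0:i1])


@lru_cache(maxsize=64)
def _butter_sos_cached(order: int, corners: tuple[float, ...], btype: str) -> np.ndarray:
    return sps.butter(order, corners if len(corners) > 1 else corners[0], btype=btype, output="sos")


def _butter_sos(order: int, corners: tuple[float, ...], btype: str) -> np.ndarray:
    # sosfilt needs a writable buffer; hand out a copy of the cached design
    return _butter_sos_cached(order, corners, btype).copy()


def _check_filter_length(sig: SampledSignal, order: int) -> None:
    # filtfilt default pad length is 3 * max(len(a), len(b)); shorter signals
    # cannot be filtered meaningfully.
    if len(sig) <= 3 * (2 * order + 1):
        raise SignalLengthError(
            f"signal of {len(sig)} samples too short for order-{order} zero-phase filter"
        )


def bandpass_emg(
    sig: SampledSignal,
    low_hz: float = EMG_BAND_HZ[0],
    high_hz: float = EMG_BAND_HZ[1],
    order: int = FILTER_ORDER,
) -> SampledSignal:
    """Zero-phase Butterworth band-pass for raw EMG (default 20-500 Hz).

    When the upper corner sits at or above ~Nyquist (the standard case at
    fs = 1000 Hz, where 500 Hz *is* Nyquist) the low-pass branch is
    inoperative and the filter degenerates to the 20 Hz high-pass alone.
    """
    _check_filter_length(sig, order)
    nyq = sig.fs / 2.0
    if high_hz >= 0.98 * nyq:
        sos = _butter_sos(order, (low_hz / nyq,), "highpass")
    else:
        sos = _butter_sos(order, (low_hz / nyq, high_hz / nyq), "bandpass")
    out = sps.sosfiltfilt(sos, sig.values)
    return sig.with_values(out)


def lowpass_cop(
    sig: SampledSignal, corner_hz: float = COP_LOWPASS_HZ, order: int = FILTER_ORDER
) -> SampledSignal:
    """Zero-phase Butterworth low-pass for COP/force traces (default 20 Hz)."""
    _check_filter_length(sig, order)
    sos = _butter_sos(order, (corner_hz / (sig.fs / 2.0),), "lowpass")
    out = sps.sosfiltfilt(sos, sig.values)
    return sig.with_values(out)


def rms_envelope(sig: SampledSignal, window: int = RMS_WINDOW_SAMPLES) -> SampledSignal:
    """Moving-window RMS envelope.

    Sample ``i`` is the RMS over a window centred on ``i``; at the edges the
    window shrinks to the available samples.  Output length equals input
    length and every sample is non-negative.
    """
    if window < 1:
        raise ValueError("window must be >= 1 sample")
    n = len(sig)
    if window > n:
        raise SignalLengthError(f"window of {window} exceeds signal length {n}")
    sq = np.concatenate(([0.0], np.cumsum(sig.values**2)))
    half_lo = window // 2
    half_hi = window - half_lo  # window = half_lo + half_hi, centred
    idx = np.arange(n)
    lo = np.clip(idx - half_lo, 0, n)
    hi = np.clip(idx + half_hi, 0, n)
    mean_sq = (sq[hi] - sq[lo]) / (hi - lo)
    return sig.with_values(np.sqrt(np.maximum(mean_sq, 0.0)))


def time_normalize(sig: SampledSignal, n_out: int = 1000) -> SampledSignal:
    """Resample to exactly ``n_out`` samples by linear interpolation.

    The first and last samples are preserved; monotone inputs stay monotone
    (linear interpolation cannot overshoot).  The nominal rate of the output
    is set so the resampled excerpt spans 1 s, matching the convention of
    normalising task phases to a unit window.
    """
    if len(sig) < 2:
        raise SignalLengthError("time_normalize needs at least 2 samples")
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    x_old = np.linspace(0.0, 1.0, len(sig))
    x_new = np.linspace(0.0, 1.0, n_out)
    out = np.interp(x_new, x_old, sig.values)
    return replace(sig, values=out, fs=float(n_out))


@dataclass(frozen=True)
class QuiescenceReport:
    """Outcome of the resting-EMG validity check."""

    valid: bool
    offending_channel: str | None = None
    offending_time: float | None = None
    peak_uv: float | None = None


def check_emg_quiescence(
    envelopes: dict[str, SampledSignal] | list[SampledSignal],
    threshold_uv: float = EMG_QUIESCENCE_THRESHOLD_UV,
) -> QuiescenceReport:
    """Flag a passive trial invalid if any EMG envelope exceeds ``threshold_uv``.

    Returns the first offending channel (in iteration order) and the time of
    its first supra-threshold sample.
    """
    if isinstance(envelopes, dict):
        items = list(envelopes.items())
    else:
        items = [(e.label or f"ch{i}", e) for i, e in enumerate(envelopes)]
    if not items:
        raise ValueError("no envelopes supplied")
    first: tuple[float, str, float, float] | None = None
    for name, env in items:
        over = np.flatnonzero(env.values > threshold_uv)
        if over.size:
            t = over[0] / env.fs
            if first is None or t < first[0]:
                first = (t, name, float(env.values[over[0]]), t)
    if first is None:
        return QuiescenceReport(valid=True)
    t, name, peak, _ = first
    return QuiescenceReport(valid=False, offending_channel=name, offending_time=t, peak_uv=peak)
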