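"""Functional (postural) ankle stiffness from quiet-standing sway.

Under the single-link inverted-pendulum model of quiet standing, the body
rotates about the ankles; the sway angle is theta_sw = COM_AP / h (COM
excursion over COM height, small-angle) and the summed ankle moment is
AM = R * COP_AP with the vertical reaction R equal to body weight.
Functional stiffness Ka is the slope of the ordinary least-squares
regression of AM on theta_sw over a stable analysis window (the middle 15 s
of a 30 s stance), averaged over three repetitions.  Ka has units Nm/rad.

When the COM trajectory was not measured directly it is estimated as the
low-frequency image of the COP (zero-phase 0.5 Hz low-pass), which is the
standard COP-to-COM relation in the pendulum model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError, SignalLengthError
from .signals import SampledSignal

__all__ = [
    "StanceRecording",
    "FunctionalStiffnessResult",
    "middle_window",
    "sway_angle",
    "ankle_moment",
    "estimate_com",
    "functional_stiffness",
]

STANCE_DURATION_S = 30.0
ANALYSIS_WINDOW_S = 15.0
COM_LOWPASS_HZ = 0.5


@dataclass
class StanceRecording:
    """Force-plate recording of one stance/task trial.

    COP channels in mm (anterior / rightward positive), vertical force in N.
    ``com_ap`` (mm) is present when the centre of mass was simulated or
    measured directly; otherwise it is estimated from the COP.
    """

    cop_ap: SampledSignal
    cop_ml: SampledSignal
    fz: SampledSignal
    body_weight: float
    h: float
    com_ap: SampledSignal | None = None
    task: str = "standing"
    single_plate: bool = True

    def __post_init__(self):
        n, fs = len(self.cop_ap), self.cop_ap.fs
        chans = [self.cop_ml, self.fz] + ([self.com_ap] if self.com_ap is not None else [])
        for ch in chans:
            if len(ch) != n or ch.fs != fs:
                raise ValueError("all recording channels must share fs and length")
        if self.body_weight <= 0 or self.h <= 0:
            raise ValueError("body_weight and h must be positive")

    @property
    def fs(self) -> float:
        return self.cop_ap.fs


@dataclass(frozen=True)
class FunctionalStiffnessResult:
    """Per-repetition Ka (Nm/rad) with regression r2, and their mean."""

    per_rep: tuple[float, ...]
    r2_per_rep: tuple[float, ...]
    mean: float
    window: tuple[float, float]


def middle_window(sig: SampledSignal, keep_s: float = ANALYSIS_WINDOW_S) -> SampledSignal:
    """Centred ``keep_s``-second excerpt of a signal (the stable interval)."""
    if sig.duration < keep_s - 0.5 / sig.fs:
        raise SignalLengthError(
            f"signal of {sig.duration:.2f} s shorter than analysis window {keep_s} s"
        )
    start = (sig.duration - keep_s) / 2.0
    i0 = int(round(start * sig.fs))
    i1 = i0 + int(round(keep_s * sig.fs))
    return sig.with_values(sig.values[i0:i1])


def sway_angle(com_ap_mm: np.ndarray, h_m: float) -> np.ndarray:
    """Sway angle theta_sw = COM_AP / h in radians (small-angle linearisation)."""
    if h_m <= 0:
        raise ValueError("COM height h must be positive")
    return np.asarray(com_ap_mm, dtype=float) / 1000.0 / h_m


def ankle_moment(cop_ap_mm: np.ndarray, body_weight_n: float) -> np.ndarray:
    """Summed ankle moment AM = R * COP_AP (Nm), with R = body weight."""
    if body_weight_n <= 0:
        raise ValueError("body weight must be positive")
    return body_weight_n * np.asarray(cop_ap_mm, dtype=float) / 1000.0


def estimate_com(cop_ap: SampledSignal, corner_hz: float = COM_LOWPASS_HZ) -> SampledSignal:
    """Estimate the COM-AP trajectory as the 0.5 Hz zero-phase low-pass of COP-AP.

    The COM is the heavily smoothed image of the COP in the pendulum model:
    the COP oscillates about the COM to accelerate it, and COM motion itself
    is confined well below 1 Hz in quiet stance.
    """
    sos = sps.butter(2, corner_hz / (cop_ap.fs / 2.0), btype="lowpass", output="sos")
    out = sps.sosfiltfilt(sos, cop_ap.values)
    return cop_ap.with_values(out, label="com_ap_est")


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    vx = np.var(x)
    if vx < 1e-30:
        raise DegenerateSignalError("no sway variance; stiffness regression degenerate")
    slope = float(np.cov(x, y, bias=True)[0, 1] / vx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return slope, r2


def functional_stiffness(
    reps: list[StanceRecording],
    keep_s: float = ANALYSIS_WINDOW_S,
) -> FunctionalStiffnessResult:
    """Ka = dAM/d(theta_sw) per repetition (middle ``keep_s`` seconds), then mean.

    Uses the recorded COM when present, the COP-derived estimate otherwise.
    """
    slopes: list[float] = []
    r2s: list[float] = []
    window = (0.0, keep_s)
    for rec in reps:
        cop = middle_window(rec.cop_ap, keep_s)
        com_src = rec.com_ap if rec.com_ap is not None else estimate_com(rec.cop_ap)
        com = middle_window(com_src, keep_s)
        theta = sway_angle(com.values, rec.h)
        am = ankle_moment(cop.values, rec.body_weight)
        slope, r2 = _ols_slope(theta, am)
        slopes.append(slope)
        r2s.append(r2)
        start = (rec.cop_ap.duration - keep_s) / 2.0
        window = (start, start + keep_s)
    return FunctionalStiffnessResult(
        per_rep=tuple(slopes),
        r2_per_rep=tuple(r2s),
        mean=float(np.mean(slopes)),
        window=window,
    )
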