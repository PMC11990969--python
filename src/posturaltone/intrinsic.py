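"""Ankle intrinsic stiffness from slow passive dorsiflexion trials.

The passive torque-angle relation of the ankle, stretched well below the
reflex threshold (5 deg/s), is modelled as a 4th-order polynomial

    F(x) = a x^4 + b x^3 + c x^2 + d x + e          (torque, Nm; angle, deg)

and intrinsic stiffness at an angular position is its first derivative

    F'(x) = 4 a x^3 + 3 b x^2 + 2 c x + d           (Nm/deg).

Stiffness is reported at the ankle angle closest to quiet standing (0 deg
dorsiflexion) and averaged over the three valid repetitions.  A repetition
is valid only if all three monitored muscles (TA, SOL, GM) stay below the
5 uV resting-EMG ceiling and the dorsiflexion sweep is at constant velocity;
the first and last degree of the sweep are discarded to remove the
acceleration transients of the dynamometer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DomainError,
    InsufficientDataError,
    SegmentationError,
    ValidityError,
)
from .signals import SampledSignal, check_emg_quiescence

__all__ = [
    "DynamometerTrial",
    "PolynomialTorqueModel",
    "StiffnessResult",
    "extract_df_segment",
    "gravity_correct",
    "fit_torque_angle",
    "stiffness_at",
    "intrinsic_stiffness",
]

#: Protocol stretch velocity (deg/s) and tolerance on its constancy.
NOMINAL_VELOCITY_DEG_S = 5.0
VELOCITY_TOLERANCE_FRAC = 0.10

#: Degrees trimmed from the start and end of the dorsiflexion sweep.
EDGE_TRIM_DEG = 1.0

REQUIRED_VALID_REPS = 3


@dataclass
class DynamometerTrial:
    """One passive dorsiflexion repetition: synchronized angle/torque/EMG.

    ``angle`` is in degrees with dorsiflexion positive, ``torque`` in Nm,
    ``velocity`` in deg/s, and ``emg`` maps muscle name (TA/SOL/GM) to its
    RMS envelope in uV.  All channels share sampling rate and length.
    """

    angle: SampledSignal
    torque: SampledSignal
    velocity: SampledSignal
    emg: dict[str, SampledSignal]
    side: str = ""

    def __post_init__(self):
        n, fs = len(self.angle), self.angle.fs
        for ch in (self.torque, self.velocity, *self.emg.values()):
            if len(ch) != n or ch.fs != fs:
                raise ValueError("all trial channels must share fs and length")


@dataclass(frozen=True)
class PolynomialTorqueModel:
    """Least-squares quartic torque-angle model with its fit quality.

    ``coeffs`` is (a, b, c, d, e) in Nm/deg^k; ``fit_domain`` the angle
    interval (deg) the data covered — stiffness evaluation outside it is an
    extrapolation and is refused.
    """

    coeffs: tuple[float, float, float, float, float]
    r2: float
    fit_domain: tuple[float, float]

    def torque(self, angle_deg: float | np.ndarray) -> float | np.ndarray:
        """Modelled torque F(x) at ``angle_deg``."""
        return np.polyval(self.coeffs, angle_deg)


@dataclass(frozen=True)
class StiffnessResult:
    """Per-repetition and averaged intrinsic stiffness at ``eval_angle``."""

    per_rep: tuple[float, ...]
    mean: float
    eval_angle: float
    n_valid: int
    r2_per_rep: tuple[float, ...] = ()
    side: str = ""


def extract_df_segment(
    trial: DynamometerTrial,
    nominal_velocity: float = NOMINAL_VELOCITY_DEG_S,
    trim_deg: float = EDGE_TRIM_DEG,
    velocity_tolerance: float = VELOCITY_TOLERANCE_FRAC,
) -> DynamometerTrial:
    """Keep only the constant-velocity dorsiflexion portion of a sweep.

    The dorsiflexion phase is the longest contiguous run of positive angular
    velocity; the first and last ``trim_deg`` degrees are discarded.  Raises
    :class:`SegmentationError` if no dorsiflexion phase exists and
    :class:`ValidityError` if velocity deviates from ``nominal_velocity`` by
    more than ``velocity_tolerance`` anywhere in the kept segment.
    """
    v = trial.velocity.values
    pos = v > 0
    if not pos.any():
        raise SegmentationError("trial contains no dorsiflexion (positive-velocity) phase")
    # longest contiguous positive-velocity run
    edges = np.diff(pos.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if pos[0]:
        starts.insert(0, 0)
    if pos[-1]:
        ends.append(pos.size)
    i0, i1 = max(zip(starts, ends), key=lambda se: se[1] - se[0])

    ang = trial.angle.values[i0:i1]
    lo, hi = ang[0] + trim_deg, ang[-1] - trim_deg
    if hi <= lo:
        raise SegmentationError(
            f"dorsiflexion sweep of {ang[-1] - ang[0]:.2f} deg too short to trim {trim_deg} deg per side"
        )
    keep = np.flatnonzero((ang >= lo) & (ang <= hi))
    j0, j1 = i0 + keep[0], i0 + keep[-1] + 1

    seg_v = trial.velocity.values[j0:j1]
    dev = np.abs(seg_v - nominal_velocity)
    if dev.max() > velocity_tolerance * nominal_velocity:
        k = int(np.argmax(dev))
        raise ValidityError(
            f"velocity deviates {dev.max():.3f} deg/s from nominal {nominal_velocity} "
            f"deg/s at t={(j0 + k) / trial.velocity.fs:.3f} s"
        )

    cut = slice(j0, j1)
    return DynamometerTrial(
        angle=trial.angle.with_values(trial.angle.values[cut]),
        torque=trial.torque.with_values(trial.torque.values[cut]),
        velocity=trial.velocity.with_values(seg_v),
        emg={k: s.with_values(s.values[cut]) for k, s in trial.emg.items()},
        side=trial.side,
    )


def gravity_correct(
    torque: SampledSignal,
    angle: SampledSignal,
    reference_torque_at_neutral: float,
) -> SampledSignal:
    """Remove the gravitational component of the foot/footplate torque.

    ``reference_torque_at_neutral`` is the resting torque measured at the
    neutral ankle angle (0 deg); the gravitational torque at angle theta is
    modelled as reference * cos(theta), so the correction equals the
    reference exactly at 0 deg.
    """
    theta = np.deg2rad(angle.values)
    return torque.with_values(torque.values - reference_torque_at_neutral * np.cos(theta))


def fit_torque_angle(angle_deg: np.ndarray, torque_nm: np.ndarray) -> PolynomialTorqueModel:
    """Least-squares quartic fit of torque on angle.

    Requires at least 10 samples spanning at least 5 degrees (a quartic on a
    narrower support is ill-conditioned and physiologically meaningless).
    """
    x = np.asarray(angle_deg, dtype=float)
    y = np.asarray(torque_nm, dtype=float)
    if x.size < 10:
        raise ValidityError(f"need >= 10 samples for a quartic fit, got {x.size}")
    span = x.max() - x.min()
    if span < 5.0:
        raise ValidityError(f"angle span {span:.2f} deg < 5 deg; fit not identifiable")
    coeffs = np.polyfit(x, y, 4)
    yhat = np.polyval(coeffs, x)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return PolynomialTorqueModel(
        coeffs=tuple(coeffs), r2=min(r2, 1.0), fit_domain=(float(x.min()), float(x.max()))
    )


def stiffness_at(model: PolynomialTorqueModel, angle_deg: float) -> float:
    """Intrinsic stiffness F'(x) = 4a x^3 + 3b x^2 + 2c x + d at ``angle_deg``."""
    lo, hi = model.fit_domain
    if not (lo <= angle_deg <= hi):
        raise DomainError(
            f"angle {angle_deg} deg outside fitted domain [{lo:.2f}, {hi:.2f}]"
        )
    a, b, c, d, _ = model.coeffs
    x = angle_deg
    return float(4 * a * x**3 + 3 * b * x**2 + 2 * c * x + d)


def _closest_in_domain(model: PolynomialTorqueModel, angle_deg: float) -> float:
    lo, hi = model.fit_domain
    return float(np.clip(angle_deg, lo, hi))


def intrinsic_stiffness(
    trials: list[DynamometerTrial],
    eval_angle: float = 0.0,
    reference_torque_at_neutral: float = 0.0,
    nominal_velocity: float = NOMINAL_VELOCITY_DEG_S,
) -> StiffnessResult:
    """Intrinsic stiffness at ``eval_angle`` averaged over three valid repetitions.

    Each repetition is screened (EMG quiescence, dorsiflexion segmentation,
    velocity constancy), gravity-corrected, fitted with the quartic model and
    differentiated at ``eval_angle`` (or the closest angle inside the fitted
    domain, when the trim removed the target).  The first three valid
    repetitions enter the arithmetic mean; fewer than three raises
    :class:`InsufficientDataError` listing every exclusion and its rule.
    """
    per_rep: list[float] = []
    r2s: list[float] = []
    exclusions: list[str] = []
    side = trials[0].side if trials else ""
    for i, trial in enumerate(trials):
        if len(per_rep) >= REQUIRED_VALID_REPS:
            break
        rep = f"rep {i}"
        quiet = check_emg_quiescence(trial.emg)
        if not quiet.valid:
            exclusions.append(
                f"{rep}: EMG activity {quiet.peak_uv:.1f} uV > 5 uV in "
                f"{quiet.offending_channel} at t={quiet.offending_time:.3f} s"
            )
            continue
        try:
            seg = extract_df_segment(trial, nominal_velocity=nominal_velocity)
            corrected = gravity_correct(seg.torque, seg.angle, reference_torque_at_neutral)
            model = fit_torque_angle(seg.angle.values, corrected.values)
            k = stiffness_at(model, _closest_in_domain(model, eval_angle))
        except (SegmentationError, ValidityError) as exc:
            exclusions.append(f"{rep}: {exc}")
            continue
        per_rep.append(k)
        r2s.append(model.r2)
    if len(per_rep) < REQUIRED_VALID_REPS:
        raise InsufficientDataError(
            f"only {len(per_rep)} valid repetitions (3 required); "
            f"exclusions: {exclusions or 'none — too few trials supplied'}",
            exclusions=exclusions,
        )
    return StiffnessResult(
        per_rep=tuple(per_rep),
        mean=float(np.mean(per_rep)),
        eval_angle=eval_angle,
        n_valid=len(per_rep),
        r2_per_rep=tuple(r2s),
        side=side,
    )
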