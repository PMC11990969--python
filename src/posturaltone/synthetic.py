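"""Seeded generators for every recording type the analysis pipeline consumes.

The study's human recordings are not public, so each acquisition is
emulated from explicit ground truth:

* **Passive dynamometry** — a constant-velocity (5 deg/s) dorsiflexion ramp
  whose torque follows a known quartic of angle plus Gaussian noise, with
  quiescent EMG channels (optionally contaminated by a burst, to exercise
  the 5 uV validity gate).
* **Quiet standing** — a stiffness-controlled inverted pendulum,
  I theta'' = mgh sin(theta) - K theta - B theta' + w(t), integrated with
  fixed-step RK4 at the recording rate; COM_AP = h sin(theta), ankle moment
  AM = K theta + B theta', COP_AP = AM / mg.  Configurations with
  K <= mgh topple and are rejected.
* **Transition tasks** — quiet baseline noise plus a raised-cosine COP
  excursion.  The programmed onset time is made physically meaningful by
  shifting the ramp so that its analytic crossing of the detection
  threshold (3 SD of the 20 Hz low-pass-filtered baseline) falls exactly at
  the programmed onset; the excursion peaks (and therefore inverts) at the
  programmed reversal time.  Gait-initiation trials add a mediolateral
  pulse peaking at the programmed T0.  EMG envelopes switch from baseline
  to phase amplitude at onset.
* **Cohorts** — two groups of participants (healthy: DOM/NDOM limbs;
  stroke: IPSI/CONTRA) with lognormal between-participant variation and
  programmed stroke effects applied multiplicatively to the underlying
  ground-truth parameters.

Everything is reproducible: identical ground truth + seed gives identical
output, sample for sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import brentq

from .coactivation import EMGSet
from .errors import ConfigurationError, InstabilityError
from .functional import StanceRecording
from .intrinsic import DynamometerTrial
from .signals import SampledSignal, bandpass_emg, rms_envelope

__all__ = [
    "DynamoGroundTruth",
    "PendulumGroundTruth",
    "TaskGroundTruth",
    "CohortSpec",
    "ParticipantDataset",
    "generate_dynamometer_trial",
    "simulate_quiet_standing",
    "generate_task_trial",
    "generate_cohort",
]

DEFAULT_FS = 1000.0
GRAVITY = 9.81


# ------------------------------------------------------------ dynamometer

@dataclass(frozen=True)
class DynamoGroundTruth:
    """Ground truth for one passive dorsiflexion repetition.

    ``coeffs`` are the quartic torque-angle coefficients (a, b, c, d, e) in
    Nm/deg^k; ``angle_range`` the sweep in degrees (plantarflexion negative
    to dorsiflexion positive, spanning 0); ``contamination`` optionally
    injects a (time_s, amplitude_uV) burst into the SOL channel.
    """

    coeffs: tuple[float, float, float, float, float] = (2e-5, 5e-4, 0.01, 0.42, 1.0)
    angle_range: tuple[float, float] = (-20.0, 15.0)
    velocity: float = 5.0
    torque_noise_sd: float = 0.15
    emg_noise_sd: float = 1.0
    contamination: tuple[float, float] | None = None
    fs: float = DEFAULT_FS
    seed: int = 0

    def __post_init__(self):
        if self.velocity <= 0:
            raise ConfigurationError("stretch velocity must be positive")
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        lo, hi = self.angle_range
        if not (lo < 0.0 < hi):
            raise ConfigurationError(
                f"angle range {self.angle_range} must span the neutral angle 0 deg"
            )


def generate_dynamometer_trial(truth: DynamoGroundTruth) -> DynamometerTrial:
    """Simulate one dorsiflexion sweep with EMG envelopes.

    The raw EMG channels are zero-mean Gaussian noise (plus the optional
    contamination burst) passed through the standard conditioning chain
    (band-pass, 100-sample RMS), so the trial carries envelopes exactly as
    the analysis expects them.
    """
    rng = np.random.default_rng(truth.seed)
    lo, hi = truth.angle_range
    duration = (hi - lo) / truth.velocity
    n = int(round(duration * truth.fs)) + 1
    t = np.arange(n) / truth.fs
    angle = lo + truth.velocity * t
    torque = np.polyval(truth.coeffs, angle)
    if truth.torque_noise_sd > 0:
        torque = torque + rng.normal(0.0, truth.torque_noise_sd, n)
    velocity = np.full(n, truth.velocity)

    emg: dict[str, SampledSignal] = {}
    for muscle in ("TA", "SOL", "GM"):
        raw = rng.normal(0.0, truth.emg_noise_sd, n) if truth.emg_noise_sd > 0 else np.zeros(n)
        if truth.contamination is not None and muscle == "SOL":
            t_burst, amp = truth.contamination
            burst = (t >= t_burst) & (t < t_burst + 0.2)
            raw = raw + amp * burst
        sig = SampledSignal(raw, truth.fs, units="uV", label=muscle)
        if truth.emg_noise_sd > 0 or truth.contamination is not None:
            sig = bandpass_emg(sig)
        emg[muscle] = rms_envelope(sig)
    return DynamometerTrial(
        angle=SampledSignal(angle, truth.fs, units="deg", label="angle"),
        torque=SampledSignal(torque, truth.fs, units="Nm", label="torque"),
        velocity=SampledSignal(velocity, truth.fs, units="deg/s", label="velocity"),
        emg=emg,
    )


# ---------------------------------------------------------------- pendulum

@dataclass(frozen=True)
class PendulumGroundTruth:
    """Ground truth for a stiffness-controlled inverted-pendulum stance.

    ``K`` (Nm/rad) and ``B`` (Nm s/rad) are the ankle rotational stiffness
    and damping; stability requires K > mass * g * h.  ``noise_torque_sd``
    is the SD of the per-sample motor-torque disturbance in Nm (held
    constant within each integration step, so for a fixed sampling rate it
    directly sets the sway amplitude).
    """

    mass: float = 70.0
    g: float = GRAVITY
    h: float = 0.9
    K: float = 927.0  # ~1.5 * m g h for the defaults
    B: float = 50.0
    noise_torque_sd: float = 15.0
    theta0: float = 0.0
    duration: float = 30.0
    fs: float = DEFAULT_FS
    seed: int = 0

    def __post_init__(self):
        if self.mass <= 0 or self.h <= 0 or self.g <= 0:
            raise ConfigurationError("mass, g and h must be positive")
        if self.duration < 30.0:
            raise ConfigurationError("standing trials last at least 30 s")
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")

    @property
    def mgh(self) -> float:
        return self.mass * self.g * self.h


def simulate_quiet_standing(truth: PendulumGroundTruth) -> StanceRecording:
    """Integrate the sagittal inverted pendulum and emit a stance recording.

    Fixed-step RK4 at the recording rate; the disturbance torque is held
    constant across each step.  Raises :class:`InstabilityError` when the
    stiffness cannot counter gravity (K <= mgh).
    """
    if truth.K <= truth.mgh:
        raise InstabilityError(
            f"K = {truth.K:.1f} Nm/rad does not exceed mgh = {truth.mgh:.1f} Nm/rad; "
            "the pendulum topples"
        )
    rng = np.random.default_rng(truth.seed)
    n = int(round(truth.duration * truth.fs))
    dt = 1.0 / truth.fs
    inertia = truth.mass * truth.h**2
    mgh, K, B = truth.mgh, truth.K, truth.B
    noise = (
        rng.normal(0.0, truth.noise_torque_sd, n)
        if truth.noise_torque_sd > 0
        else np.zeros(n)
    )

    theta = np.empty(n)
    omega = np.empty(n)
    th, om = truth.theta0, 0.0
    sin = math.sin
    for i in range(n):
        theta[i], omega[i] = th, om
        w = noise[i]

        def acc(th_, om_):
            return (mgh * sin(th_) - K * th_ - B * om_ + w) / inertia

        k1t, k1o = om, acc(th, om)
        k2t, k2o = om + 0.5 * dt * k1o, acc(th + 0.5 * dt * k1t, om + 0.5 * dt * k1o)
        k3t, k3o = om + 0.5 * dt * k2o, acc(th + 0.5 * dt * k2t, om + 0.5 * dt * k2o)
        k4t, k4o = om + dt * k3o, acc(th + dt * k3t, om + dt * k3o)
        th = th + dt / 6.0 * (k1t + 2 * k2t + 2 * k3t + k4t)
        om = om + dt / 6.0 * (k1o + 2 * k2o + 2 * k3o + k4o)

    body_weight = truth.mass * truth.g
    am = K * theta + B * omega
    com_ap_mm = truth.h * np.sin(theta) * 1000.0
    cop_ap_mm = am / body_weight * 1000.0
    fs = truth.fs
    return StanceRecording(
        cop_ap=SampledSignal(cop_ap_mm, fs, units="mm", label="cop_ap"),
        cop_ml=SampledSignal(np.zeros(n), fs, units="mm", label="cop_ml"),
        fz=SampledSignal(np.full(n, body_weight), fs, units="N", label="fz"),
        com_ap=SampledSignal(com_ap_mm, fs, units="mm", label="com_ap"),
        body_weight=body_weight,
        h=truth.h,
        task="standing",
    )


# ------------------------------------------------------------- task trials

@dataclass(frozen=True)
class TaskGroundTruth:
    """Ground truth for a transition (or steady-standing) task trial.

    ``onset_time`` is the true M0: the generator shifts the raised-cosine
    excursion so its analytic crossing of the 3 SD detection threshold falls
    there.  ``reversal_time`` is the true M1 (the excursion peak);
    ``ml_peak_time`` the true T0 for gait initiation.  ``emg_profiles``
    maps side -> muscle -> (baseline_uV, phase_uV).
    """

    task: str = "stand_to_sit"
    onset_time: float = 16.0
    reversal_time: float = 16.25
    ml_peak_time: float | None = None
    cop_step_amplitude: float = 20.0
    ml_pulse_amplitude: float | None = None
    baseline_sd: float = 1.0
    emg_profiles: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            side: {"TA": (3.0, 15.0), "SOL": (3.0, 6.0), "GM": (3.0, 6.0)}
            for side in ("DOM", "NDOM")
        }
    )
    duration: float | None = None
    body_weight: float = 70.0 * GRAVITY
    h: float = 0.9
    fs: float = DEFAULT_FS
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("standing", "stand_to_sit", "gait_initiation"):
            raise ConfigurationError(f"unknown task {self.task!r}")
        if self.task != "standing":
            if not self.onset_time < self.reversal_time:
                raise ConfigurationError("onset_time must precede reversal_time")
            if self.onset_time < 15.0:
                raise ConfigurationError("at least 15 s of pre-onset baseline is required")
        if self.task == "gait_initiation":
            tp = self.ml_peak_time if self.ml_peak_time is not None else self.onset_time + 0.2
            if not (self.onset_time - 0.05 <= tp <= self.onset_time + 0.45):
                raise ConfigurationError(
                    f"ml_peak_time {tp} outside [onset - 0.05 s, onset + 0.45 s]"
                )
        if self.baseline_sd < 0 or self.cop_step_amplitude < 0:
            raise ConfigurationError("amplitudes must be non-negative")


def _filtered_noise_sd_ratio(fs: float, corner_hz: float = 20.0, order: int = 4) -> float:
    """SD gain of the zero-phase COP low-pass on white noise (|H|^4 average)."""
    sos = sps.butter(order, corner_hz / (fs / 2.0), btype="lowpass", output="sos")
    _, h = sps.sosfreqz(sos, worN=4096)
    return float(np.sqrt(np.mean(np.abs(h) ** 4)))


def _raised_cosine_excursion(
    t: np.ndarray, t_start: float, t_peak: float, amplitude: float
) -> np.ndarray:
    """Smooth excursion: cosine rise t_start->t_peak, symmetric return after."""
    rise = t_peak - t_start
    out = np.zeros_like(t)
    up = (t >= t_start) & (t <= t_peak)
    out[up] = amplitude / 2.0 * (1.0 - np.cos(np.pi * (t[up] - t_start) / rise))
    down = (t > t_peak) & (t <= t_peak + rise)
    out[down] = amplitude / 2.0 * (1.0 + np.cos(np.pi * (t[down] - t_peak) / rise))
    return out


def _calibrated_start(
    onset: float, reversal: float, amplitude: float, threshold: float, earliest: float
) -> float:
    """Ramp start such that the noise-free excursion crosses ``threshold`` at onset."""
    if amplitude <= 2.0 * threshold or threshold <= 0:
        return onset

    def crossing_gap(delta: float) -> float:
        rise = reversal - onset + delta
        return amplitude / 2.0 * (1.0 - math.cos(math.pi * delta / rise)) - threshold

    hi = max(onset - earliest - 1e-3, 1e-4)
    if crossing_gap(hi) < 0:
        return onset
    delta = brentq(crossing_gap, 0.0, hi, xtol=1e-9)
    return onset - delta


def generate_task_trial(truth: TaskGroundTruth) -> tuple[StanceRecording, EMGSet]:
    """Simulate one task trial: COP trace plus per-side EMG envelopes.

    COP noise is white at the recording rate with SD ``baseline_sd``; the
    detection pipeline low-pass filters at 20 Hz, so the generator
    calibrates the excursion against 3 x (filtered-baseline SD), which is
    known analytically for white noise.  EMG envelopes are generated
    directly at envelope level (baseline amplitude, switching to the phase
    amplitude at onset over a 50 ms cosine transition).
    """
    fs = truth.fs
    duration = truth.duration
    if duration is None:
        duration = 30.0 if truth.task == "standing" else truth.onset_time + 4.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(truth.seed)

    cop_ap = rng.normal(0.0, truth.baseline_sd, n) if truth.baseline_sd > 0 else np.zeros(n)
    cop_ml = rng.normal(0.0, truth.baseline_sd, n) if truth.baseline_sd > 0 else np.zeros(n)

    if truth.task != "standing" and truth.cop_step_amplitude > 0:
        kappa = _filtered_noise_sd_ratio(fs)
        threshold = 3.0 * kappa * truth.baseline_sd
        t_start = _calibrated_start(
            truth.onset_time,
            truth.reversal_time,
            truth.cop_step_amplitude,
            threshold,
            earliest=15.0,
        )
        cop_ap = cop_ap + _raised_cosine_excursion(
            t, t_start, truth.reversal_time, truth.cop_step_amplitude
        )
        if truth.task == "gait_initiation":
            ml_peak = truth.ml_peak_time if truth.ml_peak_time is not None else truth.onset_time + 0.2
            ml_amp = (
                truth.ml_pulse_amplitude
                if truth.ml_pulse_amplitude is not None
                else 0.6 * truth.cop_step_amplitude
            )
            # the ML pulse crosses its own 3 SD threshold at the programmed
            # onset as well, so neither direction pre-empts the true M0
            ml_start = _calibrated_start(truth.onset_time, ml_peak, ml_amp, threshold, earliest=15.0)
            cop_ml = cop_ml + _raised_cosine_excursion(t, ml_start, ml_peak, ml_amp)

    envelopes: dict[str, dict[str, SampledSignal]] = {}
    onset = truth.onset_time if truth.task != "standing" else duration + 1.0
    transition = np.clip((t - onset) / 0.05, 0.0, 1.0)
    gate = 0.5 * (1.0 - np.cos(np.pi * transition))  # 0 before onset, 1 after +50 ms
    for side, muscles in truth.emg_profiles.items():
        envelopes[side] = {}
        for muscle, (base_uv, phase_uv) in muscles.items():
            level = base_uv + (phase_uv - base_uv) * gate
            envelopes[side][muscle] = SampledSignal(level, fs, units="uV", label=muscle)

    rec = StanceRecording(
        cop_ap=SampledSignal(cop_ap, fs, units="mm", label="cop_ap"),
        cop_ml=SampledSignal(cop_ml, fs, units="mm", label="cop_ml"),
        fz=SampledSignal(np.full(n, truth.body_weight), fs, units="N", label="fz"),
        body_weight=truth.body_weight,
        h=truth.h,
        task=truth.task,
    )
    return rec, EMGSet(envelopes=envelopes)


# ------------------------------------------------------------------ cohort

#: Stroke-effect keys understood by :func:`generate_cohort`; values are
#: multiplicative factors applied to the stroke group's ground truth.
SUPPORTED_EFFECTS = (
    "contra_istiff_ratio",
    "ipsi_istiff_ratio",
    "fstiff_ratio",
    "standing_ta_ratio",
    "transition_ta_ratio",
    "cop_amplitude_ratio",
)


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort layout with programmed stroke-vs-healthy effects.

    ``effects`` maps an effect key (see :data:`SUPPORTED_EFFECTS`) to a
    multiplicative factor applied to the stroke group; an empty dict gives
    a null cohort in which the groups differ only by sampling noise.
    ``within_group_cv`` is the between-participant coefficient of variation
    of the underlying physiological parameters.
    """

    n_per_group: int = 12
    effects: dict[str, float] = field(default_factory=dict)
    within_group_cv: float = 0.2
    n_reps: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 3:
            raise ConfigurationError("need at least 3 participants per group")
        if self.within_group_cv < 0:
            raise ConfigurationError("within_group_cv must be non-negative")
        unknown = set(self.effects) - set(SUPPORTED_EFFECTS)
        if unknown:
            raise ConfigurationError(f"unknown effect keys: {sorted(unknown)}")


@dataclass
class ParticipantDataset:
    """All synthetic recordings of one participant."""

    participant_id: str
    group: str  # "healthy" | "stroke"
    limbs: tuple[str, str]  # (reference, affected-analogue) e.g. ("DOM","NDOM")
    dynamometer: dict[str, list[DynamometerTrial]] = field(default_factory=dict)
    standing: list[StanceRecording] = field(default_factory=list)
    standing_emg: list[EMGSet] = field(default_factory=list)
    transitions: dict[str, list[tuple[StanceRecording, EMGSet]]] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)


ALL_COMPONENTS = ("dynamometer", "standing", "stand_to_sit", "gait_initiation")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


def generate_cohort(
    spec: CohortSpec, components: tuple[str, ...] = ALL_COMPONENTS
) -> list[ParticipantDataset]:
    """Generate a healthy and a stroke group of synthetic participants.

    Each participant carries ``spec.n_reps`` dynamometer repetitions per
    limb, standing trials, stand-to-sit trials and gait-initiation trials
    (restricted to ``components`` when only part of the battery is needed).
    Stroke parameters are the healthy-population parameters scaled by
    ``spec.effects``.  Fully reproducible from ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    participants: list[ParticipantDataset] = []
    eff = spec.effects
    for g_idx, group in enumerate(("healthy", "stroke")):
        limbs = ("DOM", "NDOM") if group == "healthy" else ("IPSI", "CONTRA")
        for p_idx in range(spec.n_per_group):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            pid = f"{group[0].upper()}{p_idx:02d}"
            ds = ParticipantDataset(participant_id=pid, group=group, limbs=limbs)

            mass = 70.0 * _lognormal_factor(rng, 0.1)
            h = 0.9 * _lognormal_factor(rng, 0.05)
            mgh = mass * GRAVITY * h
            k_ratio = max(1.15, 1.5 * _lognormal_factor(rng, spec.within_group_cv / 2))
            if group == "stroke":
                k_ratio = max(1.15, k_ratio * eff.get("fstiff_ratio", 1.0))
            stiff_scale = {limb: _lognormal_factor(rng, spec.within_group_cv) for limb in limbs}
            if group == "stroke":
                stiff_scale["CONTRA"] *= eff.get("contra_istiff_ratio", 1.0)
                stiff_scale["IPSI"] *= eff.get("ipsi_istiff_ratio", 1.0)
            emg_scale = {
                side: {m: _lognormal_factor(rng, spec.within_group_cv) for m in ("TA", "SOL", "GM")}
                for side in limbs
            }
            ta_standing = 1.0
            ta_transition = 1.0
            cop_amp = 20.0 * _lognormal_factor(rng, spec.within_group_cv / 2)
            if group == "stroke":
                ta_standing = eff.get("standing_ta_ratio", 1.0)
                ta_transition = eff.get("transition_ta_ratio", 1.0)
                cop_amp *= eff.get("cop_amplitude_ratio", 1.0)
            ds.truth = {
                "mass": mass,
                "h": h,
                "K": k_ratio * mgh,
                "stiff_scale": stiff_scale,
                "cop_amplitude": cop_amp,
            }

            base = (2e-5, 5e-4, 0.01, 0.42, 1.0)
            if "dynamometer" in components:
                for limb in limbs:
                    s = stiff_scale[limb]
                    coeffs = tuple(c * s for c in base[:4]) + (base[4],)
                    reps = []
                    for _ in range(spec.n_reps):
                        truth = DynamoGroundTruth(
                            coeffs=coeffs,
                            seed=int(rng.integers(0, 2**31 - 1)),
                        )
                        trial = generate_dynamometer_trial(truth)
                        trial.side = limb
                        reps.append(trial)
                    ds.dynamometer[limb] = reps

            if "standing" in components:
                for _ in range(spec.n_reps):
                    truth = PendulumGroundTruth(
                        mass=mass,
                        h=h,
                        K=k_ratio * mgh,
                        B=50.0 * _lognormal_factor(rng, spec.within_group_cv / 2),
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    ds.standing.append(simulate_quiet_standing(truth))
                    profiles = {
                        side: {
                            muscle: (level, level)
                            for muscle, level in (
                                ("TA", 3.0 * emg_scale[side]["TA"]
                                 * (ta_standing if group == "stroke" else 1.0)),
                                ("SOL", 3.0 * emg_scale[side]["SOL"]),
                                ("GM", 3.0 * emg_scale[side]["GM"]),
                            )
                        }
                        for side in limbs
                    }
                    _, emg = generate_task_trial(
                        TaskGroundTruth(
                            task="standing",
                            emg_profiles=profiles,
                            seed=int(rng.integers(0, 2**31 - 1)),
                        )
                    )
                    ds.standing_emg.append(emg)

            for task in ("stand_to_sit", "gait_initiation"):
                if task not in components:
                    continue
                trials = []
                for _ in range(spec.n_reps):
                    ta_f = ta_transition if group == "stroke" else 1.0
                    profiles = {
                        side: {
                            "TA": (3.0, 15.0 * ta_f * emg_scale[side]["TA"]),
                            "SOL": (3.0, 6.0 * emg_scale[side]["SOL"]),
                            "GM": (3.0, 6.0 * emg_scale[side]["GM"]),
                        }
                        for side in limbs
                    }
                    truth = TaskGroundTruth(
                        task=task,
                        cop_step_amplitude=cop_amp,
                        ml_peak_time=16.2 if task == "gait_initiation" else None,
                        emg_profiles=profiles,
                        body_weight=mass * GRAVITY,
                        h=h,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    trials.append(generate_task_trial(truth))
                ds.transitions[task] = trials
            participants.append(ds)
    return participants
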