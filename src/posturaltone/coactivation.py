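"""Antagonist coactivation (CoA) over the postural phase.

CoA expresses the antagonist's share of the total agonist + antagonist
activity:

    CoA(%) = antagonist / (agonist + antagonist) * 100

Muscle roles are task-dependent: in quiet standing the plantarflexors (SOL,
GM) are the agonists and TA the antagonist; in stand-to-sit and gait
initiation TA is the agonist and the plantarflexors are the antagonists.
The muscle pairs follow the study convention:

    standing:        TA/SOL, TA/GM, Ve/Do  (Ve = TA, Do = SOL + GM)
    transitions:     SOL/TA, GM/TA, Do/Ve

For the transition tasks, envelopes are first normalised to the RMS of the
15 s quiet-standing baseline preceding the task (activities become
dimensionless multiples of resting stance activity), the phase excerpt
[M0, M1] is time-normalised to a 1 s window, and the RMS of that excerpt
is the activity entering the index.  For standing, where no M0/M1 exist
and the trial *is* the baseline, activities are the raw envelope RMS (uV)
over the middle 15 s — normalising standing by itself would fix every
index at 50%.  Composite dorsal activity is the sum of the SOL and GM
activities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ConfigurationError,
    NormalizationError,
    PosturalToneError,
    UndefinedIndexError,
)
from .events import TaskEvents
from .functional import middle_window
from .signals import SampledSignal, time_normalize

__all__ = [
    "EMGSet",
    "CoAResult",
    "normalize_to_baseline",
    "phase_rms",
    "coa_index",
    "task_coactivation",
]

MUSCLES = ("TA", "SOL", "GM")

#: (pair label, antagonist spec, agonist spec) per task family; "DO" = SOL+GM.
STANDING_PAIRS = (("TA/SOL", "TA", "SOL"), ("TA/GM", "TA", "GM"), ("Ve/Do", "TA", "DO"))
TRANSITION_PAIRS = (("SOL/TA", "SOL", "TA"), ("GM/TA", "GM", "TA"), ("Do/Ve", "DO", "TA"))


@dataclass
class EMGSet:
    """Per-side, per-muscle EMG envelopes sharing one sampling rate.

    ``envelopes`` maps side label (e.g. "IPSI") to {muscle: envelope}.
    """

    envelopes: dict[str, dict[str, SampledSignal]]

    def sides(self) -> list[str]:
        return list(self.envelopes)

    def muscle(self, side: str, name: str) -> SampledSignal:
        try:
            return self.envelopes[side][name]
        except KeyError as exc:
            raise ConfigurationError(f"missing EMG channel {name} for side {side}") from exc


@dataclass(frozen=True)
class CoAResult:
    """One antagonist-coactivation index for a (task, side, pair)."""

    task: str
    pair: str
    side: str
    antagonist_rms: float
    agonist_rms: float
    coa: float  # percent


def normalize_to_baseline(
    envelope: SampledSignal, baseline_window: tuple[float, float]
) -> SampledSignal:
    """Divide an envelope by the RMS of its own baseline window.

    The result is a dimensionless activity with baseline level ~= 1.
    """
    base = envelope.slice_time(*baseline_window).values
    rms = float(np.sqrt(np.mean(base**2)))
    if rms <= 0:
        raise NormalizationError(
            f"baseline RMS of channel {envelope.label!r} is zero; cannot normalise"
        )
    return envelope.with_values(envelope.values / rms, units="")


def phase_rms(envelope: SampledSignal, events: TaskEvents, n_norm: int = 1000) -> float:
    """RMS of an envelope over [M0, M1], after time-normalising to a 1 s window."""
    if events.m1 <= events.m0:
        raise PosturalToneError("empty postural phase: m1 <= m0")
    fs = envelope.fs
    i0 = int(round(events.m0 * fs))
    i1 = int(round(events.m1 * fs))
    if i1 - i0 < 2:
        raise PosturalToneError("postural phase shorter than 2 samples")
    excerpt = envelope.with_values(envelope.values[i0:i1])
    norm = time_normalize(excerpt, n_out=n_norm)
    return float(np.sqrt(np.mean(norm.values**2)))


def coa_index(antagonist: float, agonist: float) -> float:
    """CoA(%) = 100 * antagonist / (agonist + antagonist)."""
    if antagonist < 0 or agonist < 0:
        raise ValueError("activities must be non-negative")
    total = antagonist + agonist
    if total == 0:
        raise UndefinedIndexError("agonist and antagonist activities are both zero")
    return 100.0 * antagonist / total


def _activity(activities: dict[str, float], spec: str) -> float:
    if spec == "DO":
        return activities["SOL"] + activities["GM"]
    return activities[spec]


def task_coactivation(
    emg: EMGSet,
    events: TaskEvents | None,
    task: str,
    baseline_window: tuple[float, float] = (0.0, 15.0),
    printed_dove_denominator: bool = False,
) -> list[CoAResult]:
    """All muscle-pair CoA indices for one task trial, per side.

    Transition envelopes are baseline-normalised and reduced to the RMS of
    the time-normalised [M0, M1] excerpt; standing envelopes are used raw
    over the middle 15 s.  Activities are combined per the task's pair
    table.

    ``printed_dove_denominator`` switches the transition Do/Ve index to the
    variant whose denominator adds SOL to both terms (as sometimes printed),
    instead of the default agonist + antagonist form.
    """
    if task == "standing":
        pairs = STANDING_PAIRS
    elif task in ("stand_to_sit", "gait_initiation"):
        if events is None:
            raise ConfigurationError(f"task {task!r} requires detected M0/M1 events")
        pairs = TRANSITION_PAIRS
    else:
        raise ConfigurationError(f"unknown task {task!r}")

    results: list[CoAResult] = []
    for side in emg.sides():
        activities: dict[str, float] = {}
        for muscle in MUSCLES:
            if task == "standing":
                win = middle_window(emg.muscle(side, muscle))
                activities[muscle] = float(np.sqrt(np.mean(win.values**2)))
            else:
                env = normalize_to_baseline(emg.muscle(side, muscle), baseline_window)
                activities[muscle] = phase_rms(env, events)
        for label, antagonist_spec, agonist_spec in pairs:
            ant = _activity(activities, antagonist_spec)
            ago = _activity(activities, agonist_spec)
            if label == "Do/Ve" and printed_dove_denominator:
                # denominator as printed: EMG(SOL+TA) + EMG(SOL+GM)
                denom = (activities["SOL"] + activities["TA"]) + ant
                if denom == 0:
                    raise UndefinedIndexError("all activities zero in Do/Ve index")
                coa = 100.0 * ant / denom
            else:
                coa = coa_index(ant, ago)
            results.append(
                CoAResult(
                    task=task,
                    pair=label,
                    side=side,
                    antagonist_rms=ant,
                    agonist_rms=ago,
                    coa=coa,
                )
            )
    return results
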