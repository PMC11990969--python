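"""Delimited-text serialization of trials and cohort manifests.

Each trial is one CSV (column ``time_s`` plus one column per channel,
named ``<label>_<units>``) with a YAML sidecar (``<file>.meta.yaml``)
carrying task, side, seed and ground-truth metadata.  A cohort is a
directory of trial files plus ``manifest.yaml`` listing every participant
and trial.  Numbers are written with ``%.10g``, so identical data always
serialises to identical bytes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coactivation import EMGSet
from .functional import StanceRecording
from .intrinsic import DynamometerTrial
from .signals import SampledSignal
from .synthetic import ParticipantDataset

__all__ = [
    "save_signals",
    "load_signals",
    "save_cohort",
    "load_cohort",
]

FLOAT_FMT = "%.10g"


def save_signals(path: str | Path, channels: dict[str, SampledSignal], meta: dict | None = None) -> None:
    """Write named channels (shared fs) as CSV plus a YAML metadata sidecar."""
    path = Path(path)
    sigs = list(channels.values())
    fs = sigs[0].fs
    n = len(sigs[0])
    if any(len(s) != n or s.fs != fs for s in sigs):
        raise ValueError("all channels must share fs and length")
    cols = {"time_s": np.arange(n) / fs}
    for name, sig in channels.items():
        suffix = f"_{sig.units}" if sig.units else ""
        cols[f"{name}{suffix}"] = sig.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FMT)
    sidecar = dict(meta or {})
    sidecar["fs"] = float(fs)
    with open(f"{path}.meta.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)


def load_signals(path: str | Path) -> tuple[dict[str, SampledSignal], dict]:
    """Inverse of :func:`save_signals`: channels dict plus metadata."""
    path = Path(path)
    df = pd.read_csv(path)
    with open(f"{path}.meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    fs = float(meta["fs"])
    channels: dict[str, SampledSignal] = {}
    for col in df.columns:
        if col == "time_s":
            continue
        name, units = (col.rsplit("_", 1) + [""])[:2] if "_" in col else (col, "")
        channels[name] = SampledSignal(df[col].to_numpy(), fs, units=units, label=name)
    return channels, meta


def _dynamo_channels(trial: DynamometerTrial) -> dict[str, SampledSignal]:
    chans = {"angle": trial.angle, "torque": trial.torque, "velocity": trial.velocity}
    for muscle, env in trial.emg.items():
        chans[f"emg_{muscle}"] = env
    return chans


def _dynamo_from_channels(channels: dict[str, SampledSignal], side: str) -> DynamometerTrial:
    emg = {k.removeprefix("emg_"): v for k, v in channels.items() if k.startswith("emg_")}
    return DynamometerTrial(
        angle=channels["angle"], torque=channels["torque"],
        velocity=channels["velocity"], emg=emg, side=side,
    )


def _stance_channels(rec: StanceRecording) -> dict[str, SampledSignal]:
    chans = {"cop_ap": rec.cop_ap, "cop_ml": rec.cop_ml, "fz": rec.fz}
    if rec.com_ap is not None:
        chans["com_ap"] = rec.com_ap
    return chans


def _stance_from_channels(channels: dict[str, SampledSignal], meta: dict) -> StanceRecording:
    return StanceRecording(
        cop_ap=channels["cop_ap"], cop_ml=channels["cop_ml"], fz=channels["fz"],
        com_ap=channels.get("com_ap"),
        body_weight=float(meta["body_weight"]), h=float(meta["h"]),
        task=meta.get("task", "standing"),
    )


def _emgset_channels(emg: EMGSet) -> dict[str, SampledSignal]:
    return {
        f"{side}_{muscle}": sig
        for side, muscles in emg.envelopes.items()
        for muscle, sig in muscles.items()
    }


def _emgset_from_channels(channels: dict[str, SampledSignal]) -> EMGSet:
    envelopes: dict[str, dict[str, SampledSignal]] = {}
    for name, sig in channels.items():
        side, muscle = name.rsplit("_", 1)
        envelopes.setdefault(side, {})[muscle] = sig
    return EMGSet(envelopes=envelopes)


def save_cohort(cohort: list[ParticipantDataset], out_dir: str | Path) -> Path:
    """Write every trial of a cohort as text plus a manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"participants": []}
    for ds in cohort:
        entry: dict = {
            "id": ds.participant_id, "group": ds.group, "limbs": list(ds.limbs),
            "dynamometer": {}, "standing": [], "standing_emg": [], "transitions": {},
        }
        pdir = out / ds.participant_id
        pdir.mkdir(exist_ok=True)
        for limb, trials in ds.dynamometer.items():
            files = []
            for i, trial in enumerate(trials):
                f = pdir / f"dynamo_{limb}_{i}.csv"
                save_signals(f, _dynamo_channels(trial), {"side": limb, "kind": "dynamometer"})
                files.append(str(f.relative_to(out)))
            entry["dynamometer"][limb] = files
        for i, rec in enumerate(ds.standing):
            f = pdir / f"standing_{i}.csv"
            save_signals(
                f, _stance_channels(rec),
                {"kind": "stance", "task": rec.task, "body_weight": rec.body_weight, "h": rec.h},
            )
            entry["standing"].append(str(f.relative_to(out)))
        for i, emg in enumerate(ds.standing_emg):
            f = pdir / f"standing_emg_{i}.csv"
            save_signals(f, _emgset_channels(emg), {"kind": "emg"})
            entry["standing_emg"].append(str(f.relative_to(out)))
        for task, trials in ds.transitions.items():
            files = []
            for i, (rec, emg) in enumerate(trials):
                f_rec = pdir / f"{task}_{i}.csv"
                f_emg = pdir / f"{task}_emg_{i}.csv"
                save_signals(
                    f_rec, _stance_channels(rec),
                    {"kind": "stance", "task": task, "body_weight": rec.body_weight, "h": rec.h},
                )
                save_signals(f_emg, _emgset_channels(emg), {"kind": "emg"})
                files.append([str(f_rec.relative_to(out)), str(f_emg.relative_to(out))])
            entry["transitions"][task] = files
        manifest["participants"].append(entry)
    mpath = out / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return mpath


def load_cohort(manifest_path: str | Path) -> list[ParticipantDataset]:
    """Load a cohort written by :func:`save_cohort`."""
    mpath = Path(manifest_path)
    root = mpath.parent
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    cohort: list[ParticipantDataset] = []
    for entry in manifest["participants"]:
        ds = ParticipantDataset(
            participant_id=entry["id"], group=entry["group"], limbs=tuple(entry["limbs"])
        )
        for limb, files in entry.get("dynamometer", {}).items():
            ds.dynamometer[limb] = [
                _dynamo_from_channels(load_signals(root / f)[0], limb) for f in files
            ]
        for f in entry.get("standing", []):
            channels, meta = load_signals(root / f)
            ds.standing.append(_stance_from_channels(channels, meta))
        for f in entry.get("standing_emg", []):
            ds.standing_emg.append(_emgset_from_channels(load_signals(root / f)[0]))
        for task, files in entry.get("transitions", {}).items():
            trials = []
            for f_rec, f_emg in files:
                channels, meta = load_signals(root / f_rec)
                rec = _stance_from_channels(channels, meta)
                emg = _emgset_from_channels(load_signals(root / f_emg)[0])
                trials.append((rec, emg))
            ds.transitions[task] = trials
        cohort.append(ds)
    return cohort
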