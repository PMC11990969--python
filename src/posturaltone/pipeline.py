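"""Cohort-level orchestration and non-parametric statistics.

Runs the full analysis battery over a cohort — signal conditioning,
intrinsic and functional stiffness, postural events, coactivation, linear
COP metrics and non-linear dynamics — then summarises per-metric group
contrasts the way small clinical cohorts are analysed: medians with 25th
and 75th percentiles, Mann-Whitney U group comparisons, and Spearman rank
correlations classified by the conventional strength bands (very weak
0-0.19, weak 0.2-0.39, moderate 0.4-0.59, strong 0.6-0.79, very strong
0.8-1.0).  Shapiro-Wilk normality is recorded per metric, but the analysis
always proceeds non-parametrically.  No multiple-testing correction is
applied across the comparison families.

Limbs are paired across groups by role: DOM with IPSI (less-affected
analogue) and NDOM with CONTRA (more-affected analogue); the neutral labels
``limb1`` and ``limb2`` name those roles in the output tables.  Every
per-trial failure (EMG contamination, undetectable events, ...) is logged
with its rule and the affected metric left missing; missing values are
dropped pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .coactivation import task_coactivation
from .cop_metrics import cop_linear_metrics
from .errors import PosturalToneError
from .events import compute_baseline, detect_events
from .functional import functional_stiffness, middle_window
from .intrinsic import intrinsic_stiffness
from .nonlinear import EntropyConfig, LyapunovConfig, lyapunov_wolf, multiscale_entropy
from .signals import lowpass_cop
from .synthetic import ParticipantDataset

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "describe",
    "mann_whitney",
    "spearman",
    "classify_strength",
    "participant_metrics",
    "run_pipeline",
]

logger = logging.getLogger("posturaltone")

ALPHA = 0.05

STRENGTH_BANDS = (
    (0.2, "very weak"),
    (0.4, "weak"),
    (0.6, "moderate"),
    (0.8, "strong"),
    (1.0 + 1e-12, "very strong"),
)


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    median_a: float
    p25_a: float
    p75_a: float
    median_b: float
    p25_b: float
    p75_b: float
    u: float
    p: float
    significant: bool
    n_a: int
    n_b: int


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    p: float
    strength: str
    n: int


def describe(values) -> tuple[float, float, float]:
    """(median, P25, P75) with linear interpolation between order statistics."""
    v = np.asarray([x for x in np.ravel(values) if np.isfinite(x)], dtype=float)
    if v.size == 0:
        raise ValueError("describe needs at least one finite value")
    q = np.percentile(v, [50, 25, 75])
    return float(q[0]), float(q[1]), float(q[2])


def mann_whitney(a, b, metric: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    Exact p for small samples without ties, tie-corrected normal
    approximation otherwise.  The reported U is the smaller of the two
    one-sided statistics (the tabled convention).
    """
    a = np.asarray([x for x in np.ravel(a) if np.isfinite(x)], dtype=float)
    b = np.asarray([x for x in np.ravel(b) if np.isfinite(x)], dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 20) else "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)
    med_a, p25_a, p75_a = describe(a)
    med_b, p25_b, p75_b = describe(b)
    return GroupComparison(
        metric=metric,
        median_a=med_a, p25_a=p25_a, p75_a=p75_a,
        median_b=med_b, p25_b=p25_b, p75_b=p75_b,
        u=u, p=float(res.pvalue), significant=bool(res.pvalue < ALPHA),
        n_a=int(a.size), n_b=int(b.size),
    )


def classify_strength(r: float) -> str:
    """Correlation-strength band for |r| (very weak ... very strong)."""
    a = abs(r)
    if a > 1:
        raise ValueError(f"|r| = {a} exceeds 1")
    for upper, label in STRENGTH_BANDS:
        if a < upper:
            return label
    return "very strong"


def spearman(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties, plus its band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise PosturalToneError("constant input; rank correlation undefined")
    res = sstats.spearmanr(x, y)
    r = float(res.statistic)
    return CorrelationResult(
        pair=pair, r=r, p=float(res.pvalue), strength=classify_strength(r), n=int(x.size)
    )


# ------------------------------------------------------------ orchestration

def _coa_label(pair: str) -> str:
    return pair.replace("/", "_")


def participant_metrics(
    ds: ParticipantDataset,
    entropy_config: EntropyConfig | None = None,
    lyapunov_config: LyapunovConfig | None = None,
    log: list[str] | None = None,
) -> dict[str, float]:
    """All scalar metrics of one participant, keyed by canonical metric name.

    Limb roles: ``limb1`` = DOM/IPSI, ``limb2`` = NDOM/CONTRA.  Failures are
    appended to ``log`` and the metric left out (missing).
    """
    if entropy_config is None:
        entropy_config = EntropyConfig()
    if lyapunov_config is None:
        lyapunov_config = LyapunovConfig()
    log = log if log is not None else []
    out: dict[str, float] = {}
    pid = ds.participant_id
    roles = dict(zip(ds.limbs, ("limb1", "limb2")))

    for limb, trials in ds.dynamometer.items():
        try:
            res = intrinsic_stiffness(trials)
            out[f"istiff_{roles[limb]}"] = res.mean
        except PosturalToneError as exc:
            log.append(f"{pid}: istiff {limb}: {exc}")

    if ds.standing:
        try:
            recs = [
                type(r)(
                    cop_ap=lowpass_cop(r.cop_ap), cop_ml=r.cop_ml, fz=r.fz,
                    com_ap=r.com_ap, body_weight=r.body_weight, h=r.h, task=r.task,
                )
                for r in ds.standing
            ]
            out["fstiff"] = functional_stiffness(recs).mean
        except PosturalToneError as exc:
            log.append(f"{pid}: fstiff: {exc}")
        # linear + non-linear dynamics of standing COP (first repetition)
        try:
            cop = lowpass_cop(ds.standing[0].cop_ap)
            mid = middle_window(cop)
            start = (cop.duration - 15.0) / 2.0
            m = cop_linear_metrics(cop, None, (start, start + 15.0))
            out.update(
                pcop_standing=m.pcop, acop_standing=m.acop,
                mdcop_standing=m.mdcop, tdcop_standing=m.tdcop,
            )
            pos = mid.values
            dpos = np.diff(pos)
            out["ci_pcop"] = multiscale_entropy(pos, entropy_config).ci
            out["ci_dcop"] = multiscale_entropy(dpos, entropy_config).ci
            out["lye_pcop"] = lyapunov_wolf(
                pos[: entropy_config.n], lyapunov_config, fs=cop.fs
            ).lam
            out["lye_dcop"] = lyapunov_wolf(
                dpos[: entropy_config.n], lyapunov_config, fs=cop.fs
            ).lam
        except PosturalToneError as exc:
            log.append(f"{pid}: standing COP dynamics: {exc}")

    for emg in ds.standing_emg[:1]:
        try:
            for r in task_coactivation(emg, None, "standing"):
                out[f"coa_standing_{_coa_label(r.pair)}_{roles[r.side]}"] = r.coa
        except PosturalToneError as exc:
            log.append(f"{pid}: standing CoA: {exc}")

    for task, trials in ds.transitions.items():
        per_pair: dict[str, list[float]] = {}
        per_cop: dict[str, list[float]] = {}
        for i, (rec, emg) in enumerate(trials):
            try:
                filt = type(rec)(
                    cop_ap=lowpass_cop(rec.cop_ap), cop_ml=lowpass_cop(rec.cop_ml),
                    fz=rec.fz, com_ap=rec.com_ap, body_weight=rec.body_weight,
                    h=rec.h, task=rec.task,
                )
                baseline = compute_baseline(filt)
                ev = detect_events(filt, baseline, task=task)
                for r in task_coactivation(emg, ev, task):
                    per_pair.setdefault(f"{_coa_label(r.pair)}_{roles[r.side]}", []).append(r.coa)
                cm = cop_linear_metrics(filt.cop_ap, baseline, (ev.m0, ev.m1))
                for name, val in (
                    ("pcop", cm.pcop), ("acop", cm.acop),
                    ("mdcop", cm.mdcop), ("tdcop", cm.tdcop),
                ):
                    per_cop.setdefault(name, []).append(val)
            except PosturalToneError as exc:
                log.append(f"{pid}: {task} trial {i}: {exc}")
        for key, vals in per_pair.items():
            out[f"coa_{task}_{key}"] = float(np.mean(vals))
        for key, vals in per_cop.items():
            out[f"{key}_{task}"] = float(np.mean(vals))
    return out


#: Correlation pairs examined across the pooled cohort (where present).
CORRELATION_PAIRS = (
    ("istiff_limb2", "fstiff"),
    ("istiff_limb2", "coa_standing_Ve_Do_limb2"),
    ("istiff_limb2", "coa_stand_to_sit_Do_Ve_limb2"),
    ("fstiff", "coa_gait_initiation_Do_Ve_limb2"),
    ("ci_pcop", "lye_pcop"),
)


def run_pipeline(
    cohort: list[ParticipantDataset],
    entropy_config: EntropyConfig | None = None,
    lyapunov_config: LyapunovConfig | None = None,
) -> dict:
    """Full analysis of a cohort: per-participant metrics and group statistics.

    Returns a bundle with ``participants`` (wide DataFrame, one row per
    participant), ``comparisons`` (healthy-vs-stroke Mann-Whitney per
    metric), ``normality`` (Shapiro-Wilk per metric and group, recorded but
    not acted on), ``correlations`` (Spearman over the pooled cohort) and
    ``log`` (every exclusion with its rule).
    """
    log: list[str] = []
    rows = []
    for ds in cohort:
        metrics = participant_metrics(ds, entropy_config, lyapunov_config, log)
        rows.append({"participant": ds.participant_id, "group": ds.group, **metrics})
    participants = pd.DataFrame(rows).set_index("participant")

    metric_cols = [c for c in participants.columns if c != "group"]
    healthy = participants[participants["group"] == "healthy"]
    stroke = participants[participants["group"] == "stroke"]

    comparisons = []
    normality = []
    for col in metric_cols:
        a = healthy[col].dropna().to_numpy()
        b = stroke[col].dropna().to_numpy()
        for gname, vals in (("healthy", a), ("stroke", b)):
            if vals.size >= 3 and np.ptp(vals) > 0:
                w, p = sstats.shapiro(vals)
                normality.append(
                    {"metric": col, "group": gname, "W": float(w), "p": float(p),
                     "normal": bool(p >= ALPHA)}
                )
        if a.size < 3 or b.size < 3:
            log.append(f"comparison {col}: insufficient data ({a.size} vs {b.size})")
            continue
        try:
            c = mann_whitney(a, b, metric=col)
        except ValueError as exc:
            log.append(f"comparison {col}: {exc}")
            continue
        comparisons.append(
            {
                "metric": col,
                "healthy_median": c.median_a, "healthy_p25": c.p25_a, "healthy_p75": c.p75_a,
                "stroke_median": c.median_b, "stroke_p25": c.p25_b, "stroke_p75": c.p75_b,
                "U": c.u, "p": c.p, "significant": c.significant,
            }
        )

    correlations = []
    for x_name, y_name in CORRELATION_PAIRS:
        if x_name not in participants.columns or y_name not in participants.columns:
            continue
        try:
            r = spearman(
                participants[x_name].to_numpy(dtype=float),
                participants[y_name].to_numpy(dtype=float),
                pair=(x_name, y_name),
            )
        except (ValueError, PosturalToneError) as exc:
            log.append(f"correlation {x_name} vs {y_name}: {exc}")
            continue
        correlations.append(
            {"x": x_name, "y": y_name, "r": r.r, "p": r.p, "strength": r.strength, "n": r.n}
        )

    return {
        "participants": participants,
        "comparisons": pd.DataFrame(comparisons),
        "normality": pd.DataFrame(normality),
        "correlations": pd.DataFrame(correlations),
        "log": log,
    }
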