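"""Linear centre-of-pressure descriptors over an analysis window.

Four conventional stabilometric summaries of the anteroposterior COP:

* pCOP — mean position relative to the quiet-standing baseline mean (mm);
* aCOP — amplitude, i.e. range max - min (mm);
* mdCOP — mean absolute deviation from the window mean (mm);
* tdCOP — total displacement, the cumulative path length (mm).

For transition tasks the window is the detected postural phase [M0, M1];
for quiet standing it is the middle 15 s of the trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PosturalToneError
from .events import BaselineStats
from .signals import SampledSignal

__all__ = ["CopLinearMetrics", "cop_linear_metrics"]


@dataclass(frozen=True)
class CopLinearMetrics:
    pcop: float
    acop: float
    mdcop: float
    tdcop: float
    window: tuple[float, float]

    def __post_init__(self):
        assert self.acop >= 0 and self.mdcop >= 0 and self.tdcop >= 0


def cop_linear_metrics(
    cop_ap: SampledSignal,
    baseline: BaselineStats | None,
    window: tuple[float, float],
) -> CopLinearMetrics:
    """pCOP/aCOP/mdCOP/tdCOP of the AP trace over ``window`` (seconds).

    ``baseline`` supplies the reference mean for pCOP; when absent, pCOP is
    the window mean itself (absolute plate coordinates).
    """
    start, end = window
    if end <= start:
        raise PosturalToneError(f"empty analysis window [{start}, {end}]")
    x = cop_ap.slice_time(start, end).values
    ref = baseline.mean_ap if baseline is not None else 0.0
    mean = float(x.mean())
    return CopLinearMetrics(
        pcop=mean - ref,
        acop=float(x.max() - x.min()),
        mdcop=float(np.mean(np.abs(x - mean))),
        tdcop=float(np.sum(np.abs(np.diff(x)))),
        window=(float(start), float(end)),
    )
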