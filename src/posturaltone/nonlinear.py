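"""Non-linear dynamics of COP and coactivation series.

Two families of measures quantify the temporal structure of postural
signals beyond variance:

**Multiscale entropy.**  Sample entropy,

    SE(m, r, N) = -ln( U^{m+1}(r) / U^m(r) ),

is the negative log conditional probability that runs of ``m`` samples that
match within tolerance ``r`` (Chebyshev distance, self-matches excluded)
still match when extended to ``m + 1`` samples.  The series is
coarse-grained by averaging non-overlapping blocks of ``tau`` samples
(Eq.-style y_j = mean(x[(j-1)tau+1 .. j tau])) and SE is evaluated at each
scale with ``r`` fixed to a fraction of the original series' SD.  The
complexity index CI is the sum of SE over the evaluated scales.

**Largest Lyapunov exponent (Wolf's algorithm).**  The series is delay
embedded (lag ``tau``, dimension ``m``); a fiducial trajectory is tracked
and its nearest neighbour (outside a temporal Theiler window) is evolved
alongside it.  When their separation exceeds a bound — or a maximum
evolution time elapses — the log stretching rate ln(L'/L)/(K t) is
recorded and a new neighbour is selected.  The exponent is the average of
the recorded rates over the M replacement steps.  Positive values indicate
exponentially diverging trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .errors import (
    DegenerateSignalError,
    NeighbourSearchError,
    SignalLengthError,
)

__all__ = [
    "EntropyConfig",
    "MSEResult",
    "LyapunovConfig",
    "LyapunovResult",
    "sample_entropy",
    "coarse_grain",
    "multiscale_entropy",
    "embed",
    "lyapunov_wolf",
]

logger = logging.getLogger("posturaltone")


# ---------------------------------------------------------------- entropy

@dataclass(frozen=True)
class EntropyConfig:
    """Sample-entropy / MSE parameters.

    ``r`` is the similarity threshold as a fraction of the SD of the
    original (scale-1, truncated) series; ``n`` the analysis length the
    series is truncated to; ``scales`` the coarse-graining factors.
    """

    m: int = 2
    r: float = 0.2
    n: int = 1000
    scales: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("template length m must be >= 1")
        if self.r <= 0:
            raise ValueError("similarity threshold r must be positive")
        if self.n <= self.m + 1:
            raise ValueError("analysis length n must exceed m + 1")
        if any(s < 1 for s in self.scales):
            raise ValueError("coarse-graining scales must be >= 1")


@dataclass(frozen=True)
class MSEResult:
    """Per-scale sample entropy and the complexity index (their sum)."""

    se_per_scale: tuple[float, ...]
    ci: float
    config: EntropyConfig


def sample_entropy(series: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """Sample entropy with absolute tolerance ``r_abs``.

    Template pairs are counted with the Chebyshev norm over the first
    ``N - m`` template positions for both lengths, excluding self-matches.
    A constant series returns 0 (every template matches at both lengths);
    if no (m+1)-length pair matches, the entropy is undefined and NaN is
    returned as the sentinel.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = x.size
    if n <= m + 1:
        raise SignalLengthError(f"need more than m + 1 = {m + 1} samples, got {n}")
    if r_abs is None:
        r_abs = 0.2 * float(np.std(x))
    if r_abs <= 0:
        # constant series: all templates identical; conditional probability 1
        if np.ptp(x) == 0:
            return 0.0
        raise ValueError("r_abs must be positive for a non-constant series")
    templ = _delay_matrix(x, 1, m + 1)[: n - m]  # (n - m, m + 1)
    d_m = pdist(templ[:, :m], metric="chebyshev")
    d_m1 = pdist(templ, metric="chebyshev")
    b = int(np.count_nonzero(d_m <= r_abs))
    a = int(np.count_nonzero(d_m1 <= r_abs))
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Average non-overlapping blocks of ``tau`` samples (remainder dropped)."""
    x = np.asarray(series, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if x.size < tau:
        raise SignalLengthError(f"series of {x.size} samples shorter than tau={tau}")
    n_blocks = x.size // tau
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


def multiscale_entropy(series: np.ndarray, config: EntropyConfig = EntropyConfig()) -> MSEResult:
    """SE across coarse-graining scales with fixed tolerance; CI = sum of SE.

    The series is truncated to ``config.n`` samples from the start of the
    analysis window; the tolerance r_abs = r * SD is fixed from the
    truncated original series and reused at every scale.  An undefined SE
    (no extended matches) is excluded from the CI with a logged warning.
    """
    x = np.asarray(series, dtype=float)
    if x.size < config.n:
        raise SignalLengthError(
            f"series of {x.size} samples shorter than analysis length n={config.n}"
        )
    x = x[: config.n]
    r_abs = config.r * float(np.std(x))
    ses: list[float] = []
    for tau in config.scales:
        cg = coarse_grain(x, tau)
        if cg.size <= config.m + 1:
            raise SignalLengthError(
                f"coarse-grained series at scale {tau} too short ({cg.size} samples)"
            )
        ses.append(sample_entropy(cg, m=config.m, r_abs=r_abs))
    defined = [s for s in ses if np.isfinite(s)]
    if len(defined) < len(ses):
        logger.warning(
            "sample entropy undefined at %d of %d scales; CI sums the defined scales only",
            len(ses) - len(defined),
            len(ses),
        )
    return MSEResult(se_per_scale=tuple(ses), ci=float(np.sum(defined)), config=config)


# ---------------------------------------------------------------- Lyapunov

def _delay_matrix(x: np.ndarray, tau: int, m: int) -> np.ndarray:
    n_pts = x.size - (m - 1) * tau
    idx = np.arange(n_pts)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def embed(series: np.ndarray, tau: int = 1, m: int = 2) -> np.ndarray:
    """Delay embedding: point i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})."""
    x = np.asarray(series, dtype=float)
    if tau < 1 or m < 1:
        raise ValueError("tau and m must be >= 1")
    if x.size <= (m - 1) * tau:
        raise SignalLengthError(
            f"series of {x.size} samples too short for m={m}, tau={tau} embedding"
        )
    return _delay_matrix(x, tau, m)


@dataclass(frozen=True)
class LyapunovConfig:
    """Wolf-algorithm parameters.

    ``t`` is the evolution time lag per step in samples; the neighbour is
    evolved for K in [k_min, k_max] steps of ``t`` samples, with early
    replacement once the separation exceeds ``max_sep_frac`` of the signal
    extent.  ``theiler`` excludes temporal neighbours; ``min_sep_frac``
    floors the admissible initial distance (as a fraction of the series SD)
    so that numerically coincident points are never paired.
    """

    tau: int = 1
    m: int = 2
    t: int = 1
    k_min: int = 1
    k_max: int = 10
    theiler: int = 10
    min_sep_frac: float = 1e-4
    max_sep_frac: float = 0.1

    def __post_init__(self):
        if self.k_min > self.k_max:
            raise ValueError("k_min must not exceed k_max")
        if self.theiler < self.tau * (self.m - 1):
            raise ValueError("theiler window must cover the embedding span tau*(m-1)")


@dataclass(frozen=True)
class LyapunovResult:
    """Largest Lyapunov exponent from Wolf's fiducial-trajectory method."""

    lam: float  # nats per sample
    lam_per_s: float  # nats per second
    n_replacements: int
    config: LyapunovConfig


def _nearest_neighbour(
    points: np.ndarray, i: int, theiler: int, min_sep: float
) -> tuple[int, float]:
    d = np.max(np.abs(points - points[i]), axis=1)
    d[max(0, i - theiler) : i + theiler + 1] = np.inf
    d[d < min_sep] = np.inf
    j = int(np.argmin(d))
    if not np.isfinite(d[j]):
        raise NeighbourSearchError(
            f"no eligible neighbour for fiducial point {i} "
            f"(theiler={theiler}, min_sep={min_sep:.3g}, {points.shape[0]} points)"
        )
    return j, float(d[j])


def lyapunov_wolf(
    series: np.ndarray,
    config: LyapunovConfig = LyapunovConfig(),
    fs: float = 1.0,
) -> LyapunovResult:
    """Largest Lyapunov exponent of a scalar series by Wolf's method.

    lambda = (1/M) sum over replacement steps of ln(L'/L) / (K t), where L
    is the fiducial-neighbour separation at the start of the step, L' the
    separation after K evolution steps of t samples, and M the number of
    replacement steps completed.
    """
    x = np.asarray(series, dtype=float)
    sd = float(np.std(x))
    if sd == 0:
        raise DegenerateSignalError("constant series has no trajectory divergence")
    pts = embed(x, config.tau, config.m)
    n_pts = pts.shape[0]
    min_need = config.theiler + config.t * config.k_max + 2
    if n_pts < min_need:
        raise SignalLengthError(
            f"{n_pts} embedded points insufficient for k_max={config.k_max} evolution"
        )
    min_sep = config.min_sep_frac * sd
    max_sep = config.max_sep_frac * float(np.ptp(x))
    rates: list[float] = []
    i = 0
    j, d0 = _nearest_neighbour(pts, i, config.theiler, min_sep)
    last_start = n_pts - config.t * config.k_min - 1
    while i < last_start:
        k_taken = 0
        d1 = d0
        for k in range(1, config.k_max + 1):
            ii, jj = i + k * config.t, j + k * config.t
            if ii >= n_pts or jj >= n_pts:
                break
            d1 = float(np.max(np.abs(pts[ii] - pts[jj])))
            k_taken = k
            if k >= config.k_min and d1 > max_sep:
                break
        if k_taken == 0:
            break
        if d0 > 0 and d1 > 0:
            rates.append(np.log(d1 / d0) / (k_taken * config.t))
        i = i + k_taken * config.t
        if i >= last_start:
            break
        try:
            j, d0 = _nearest_neighbour(pts, i, config.theiler, min_sep)
        except NeighbourSearchError:
            break
    if not rates:
        raise NeighbourSearchError("no replacement steps completed; series too short or degenerate")
    lam = float(np.mean(rates))
    return LyapunovResult(
        lam=lam, lam_per_s=lam * fs, n_replacements=len(rates), config=config
    )
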