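# Methods

This note documents the models behind `posturaltone`, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical decisions a user relying on the outputs should know.

## Signal conditioning

EMG is band-pass filtered with a 4th-order zero-phase Butterworth at
20–500 Hz and reduced to a 100-sample moving-RMS envelope; COP and force
traces are low-pass filtered with a 4th-order zero-phase Butterworth at
20 Hz. Two conventions need stating:

* **Zero-phase = forward–backward.** Each filter is applied with
  `filtfilt`, so the net group delay is zero and the magnitude response is
  the square of the single-pass design (effectively 8th order). "4th
  order" refers to the per-pass design.
* **The 500 Hz corner at fs = 1000 Hz.** At the standard 1000 Hz sampling
  rate the upper band edge coincides with Nyquist, where a low-pass branch
  is not realisable; the band-pass therefore degenerates to the 20 Hz
  high-pass alone. At higher sampling rates the full band-pass is used.
  Whether the original acquisition applied the band-pass before decimation
  from a higher rate is unknowable from the outside; this implementation
  applies it at the stored rate.

The RMS envelope uses a centred window that shrinks at the record edges
(no zero padding); `time_normalize` uses linear interpolation (shape
preserving, no ringing overshoot).

## Intrinsic stiffness

The passive torque–angle relation over a −20°…+15° dorsiflexion sweep at
5°/s is fitted per repetition with a least-squares quartic after gravity
correction; stiffness is the analytic derivative at the evaluation angle.
Choices:

* **Evaluation angle 0°** — the standing-equivalent ankle position; when
  trimming removes 0° from the fitted domain, the closest in-domain angle
  is used.
* **Gravity correction** is modelled as `reference · cos(θ)` from a resting
  measurement at the neutral angle (the correction method is a modelling
  choice; the reference defaults to 0 for synthetic data, whose torque
  ground truth contains no gravitational term).
* **Edge trim 1°** per side and a **velocity-constancy tolerance of ±10% of
  the nominal 5°/s** over the kept segment exclude the dynamometer's
  acceleration phases.
* **Per-repetition fit, then arithmetic mean** of the first three valid
  repetitions — not a pooled fit — so a single aberrant repetition cannot
  drag the curve.
* Angles are kept in degrees throughout, so stiffness is reported in Nm/°.
* The quartic's r² is reported for the torque fit; the derivative inherits
  no separate goodness-of-fit.

A repetition is valid only if TA, SOL and GM envelopes all stay at or below
5 µV (resting-muscle amplitude); the gate is strict (> 5 µV excludes) and
the offending channel and time are reported. Fewer than three valid
repetitions is an error that lists every exclusion with its rule.

## Functional stiffness

The single-link sagittal inverted pendulum gives θsw = COM/h (small-angle;
the linearisation error is < 0.15% for |θ| < 0.05 rad, far beyond real
sway) and AM = R·COP with R = body weight in newtons. Ka is the OLS slope
of AM on θsw over the **middle 15 s** of a 30 s stance ("stable interval"
operationalised as the exactly centred excerpt), averaged over repetitions.

Ka is reported in **Nm/rad** — the dimensionally consistent unit for a
moment-per-angle slope, even though clinical tables sometimes print N/m
for this quantity.

When COM was not measured, it is estimated as the 0.5 Hz zero-phase
low-pass of the COP (2nd order): in the pendulum model the COM is the
low-frequency image of the COP. On simulated stance this estimate
correlates > 0.95 (mean across seeds) with the true COM. With AM = Kθ + Bθ̇
the OLS slope equals K + B·cov(θ̇,θ)/var(θ); in stationary sway
cov(θ̇,θ) ≈ 0, so the damping-induced bias is negligible — the simulation
recovery experiments measure < 0.1% mean error at the default damping and
< 3% at zero damping.

## Postural events

Baseline statistics (per-direction mean and SD) come from a 15 s
quiet-stance window preceding the task. Rules:

* **T0** (gait initiation): the first local extremum of COP-ML deviating
  more than 3 SD from the baseline mean. Because a 3 SD threshold on a
  long noise stretch is crossed occasionally by chance, the supra-threshold
  episode containing the extremum must persist ≥ 50 ms — the same
  persistence the M0 rule uses — before its peak qualifies.
* **M0**: the earliest sample from which |COP − baseline mean| > 3 SD holds
  for ≥ 50 ms of consecutive samples, in AP or ML (the earlier direction
  wins), searched within [T0 − 450 ms, T0 + 50 ms] when T0 exists and from
  the end of the baseline window otherwise (stand-to-sit).
* **M1**: the first slope-sign inversion of the triggering channel after
  M0. The slope is evaluated on a 20 ms-smoothed trace (truncated, not
  zero-padded, at the edges) so noise micro-inversions do not qualify;
  "curve inversion" is read as the macroscopic reversal.
* The 3 SD rule is applied to the **COP position's deviation** from the
  baseline mean (not to its first difference); the persistence check allows
  no dropout samples.
* Single-force-plate validity is a trial attribute supplied by the data
  source, not inferred from signals.

Detection is invariant to a constant offset of the whole trace, and raising
the baseline SD monotonically delays or suppresses M0.

## Coactivation

CoA = 100·antagonist/(agonist+antagonist) per muscle pair, with the pair
tables described in the README. Composite dorsal activity is the **sum** of
the SOL and GM activities. Two readings of the transition Do/Ve denominator
circulate (one adds SOL to both terms); the agonist + antagonist form is
the default and the other is available behind
`printed_dove_denominator=True`.

Normalisation: transition-task envelopes are divided by the RMS of the 15 s
standing baseline, and the phase excerpt [M0, M1] is linearly resampled to
a 1 s window before its RMS is taken, so indices are unaffected by phase
duration. Standing itself *is* the baseline condition, so standing CoA is
computed on the raw envelopes over the middle 15 s — normalising standing
by its own baseline would fix every standing index at 50% and destroy the
measure. Indices obey coa(A,B) + coa(B,A) = 100 and are invariant to a
common rescaling of all envelopes.

## Linear COP metrics

Over the analysis window ([M0, M1] for transitions, middle 15 s for
standing), on the AP direction: pCOP = window mean − baseline mean (mm);
aCOP = max − min; mdCOP = mean |COP − window mean|; tdCOP = Σ|ΔCOP| (path
length). These are the conventional stabilometric readings of
position/amplitude/mean/total displacement; tdCOP is non-decreasing in
window length and never increases under downsampling.

## Non-linear dynamics

**Sample entropy.** SE(m, r, N) = −ln(A/B) where B and A count template
pairs within tolerance at lengths m and m + 1 (Chebyshev norm, self-matches
excluded, both counts over the first N − m template positions). Defaults
m = 2, r = 0.2·SD, N = 1000. A constant series yields SE = 0 (perfect
predictability); zero extended matches yield NaN — an *undefined* entropy,
deliberately distinct from 0, excluded from the complexity index with a
logged warning rather than fabricating an infinite value.

**Multiscale entropy.** The series is truncated to N samples from the start
of the analysis window (shorter series raise), coarse-grained by
non-overlapping block means at scales τ = 1–3 (remainder dropped), and SE
is computed at each scale with r·SD fixed from the original scale-1 series
— the canonical protocol, which makes the scale profile reflect temporal
structure rather than variance changes. CI is the sum of the defined
per-scale SE values. For white noise SE decreases strictly with scale in
≥ 95% of runs (averaging is a low-pass).

**Largest Lyapunov exponent (Wolf).** The series is delay-embedded
(τ = 1 sample, m = 2). From the first point, the nearest neighbour outside
a Theiler window of 10 samples and beyond a floor of 10⁻⁴·SD is tracked;
both trajectories evolve in 1-sample steps until their separation exceeds
10% of the signal extent or 10 steps elapse, the rate ln(L′/L)/(K·t) is
recorded, and a fresh neighbour of the current fiducial point is selected.
λ is the mean recorded rate over the M replacement steps, reported per
sample and per second. The replacement bound keeps the evolution inside
the linear-growth regime; a fixed long evolution would saturate at the
attractor size on strongly chaotic signals and bias λ low. Calibration:
the fully chaotic logistic map (5000 points) yields λ within 5% of ln 2,
agreeing with the exact-derivative (Benettin-style) oracle; noiseless
periodic signals yield λ ≤ 0.02 nats/sample. All non-linear measures are
deterministic functions of series + configuration.

For COP inputs, "position" (pCOP) and "displacement" (dCOP = first
differences) series are both analysed, as both conventions appear in
stabilometry.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *acquisition conditions* of a typical
postural-tone protocol: 1000 Hz sampling everywhere, 5°/s passive sweeps
from −20° to +15°, 30 s stances, ≥ 15 s pre-task baselines, three
repetitions per condition, and two groups of 12 participants.

* **Dynamometry**: torque = known quartic of angle + Gaussian noise
  (default SD 0.15 Nm ≈ 1% of the torque range); EMG channels are zero-mean
  1 µV noise passed through the standard conditioning chain, with an
  optional contamination burst to exercise the validity gate.
* **Quiet standing**: I·θ̈ = mgh·sinθ − Kθ − Bθ̇ + w, I = m·h², integrated
  with fixed-step RK4 at the recording rate (deterministic, and accurate at
  1000 Hz for sub-Hz sway; an undamped noiseless oscillation conserves
  amplitude to < 10⁻⁴ over 30 s). Noise enters as motor torque (held
  constant within each step), not as measurement noise, keeping
  COP = AM/mg self-consistent. Defaults m = 70 kg, h = 0.9 m,
  K = 1.5·mgh ≈ 927 Nm/rad, B = 50 Nm·s/rad (damping ratio ≈ 0.2),
  torque-noise SD 15 Nm per sample at 1000 Hz — chosen to give a COP sway
  SD of ≈ 3.5 mm, typical of quiet stance. K ≤ mgh is rejected as
  unstable.
* **Transition tasks**: COP = white measurement noise (SD 1 mm) plus a
  raised-cosine excursion (default 20 mm, rise ≈ 0.25–0.3 s — the tempo of
  an anticipatory weight shift). The programmed onset is *defined* as the
  instant the noise-free excursion crosses the detection threshold
  (3 × the SD of the 20 Hz-filtered baseline, known analytically for white
  noise through the filter's |H|⁴ gain): the ramp start is solved so that
  crossing lands exactly at the programmed time, making the onset
  round-trip well-posed. The excursion peaks (inverts) at the programmed
  reversal. Gait initiation adds an ML pulse peaking at the programmed T0
  and calibrated to cross its own threshold at the same onset. EMG is
  generated directly at envelope level (all downstream computation consumes
  envelopes), stepping from baseline to phase amplitude at onset.
* **Cohorts**: between-participant variation is lognormal (CV 0.2 by
  default) on stiffness scale, pendulum parameters, EMG amplitudes and COP
  excursion amplitude; stroke effects are multiplicative factors on the
  underlying ground truth (e.g. `contra_istiff_ratio`). Reproducibility is
  exact: identical spec + seed gives byte-identical serialised trials.

Not emulated: raw EMG interference patterns (only envelopes), reflex or
thixotropic torque components, hysteresis of the return stroke,
multi-segment (hip-strategy) sway, 3-D kinematics, lesion physiology, and
the stepping phase of gait initiation. Passing tests therefore demonstrate
that the *analysis* recovers known ground truth under realistic noise and
sampling conditions — not that any physiological claim about real cohorts
is reproduced.

## Statistics

Medians with 25th/75th percentiles (linear interpolation between order
statistics); two-sided Mann–Whitney U (exact for small tie-free samples,
tie-corrected normal approximation otherwise; reported U is the smaller
one-sided statistic); Spearman rank correlation with average ranks for
ties, classified as very weak (< 0.2), weak (< 0.4), moderate (< 0.6),
strong (< 0.8), very strong (≥ 0.8) on |r|. Shapiro–Wilk is computed and
recorded per metric and group, but the pipeline always proceeds
non-parametrically. **No multiple-testing correction is applied** across
the many comparison families — deliberately, matching common practice in
small clinical cohorts; readers of the comparison tables should treat
isolated p ≈ 0.05 results accordingly. Missing per-participant metrics
(failed trials, undetectable events) propagate as missing with pairwise
deletion, and every exclusion is written to the run log with its rule.

## Problem sizes used by the test suite and acceptance script

Simulation experiments are sized to give stable Monte-Carlo estimates:
200 short series for the entropy oracle; 200 white-noise seeds for the MSE
ordering; 100 dynamometer trials for stiffness recovery; 50 stance seeds
(plus 50 undamped) for Ka recovery; 100 task trials for event timing; 200
null cohorts and 100 effect cohorts (12 + 12 participants each) for type-I
calibration and power. The cohort calibration experiments generate only the
dynamometer component of each cohort — the compared metric is intrinsic
stiffness, and the other recordings would not change the comparison.

## Known limitations

* The COM-from-COP estimate assumes pendulum-like sway; it degrades for
  multi-segment strategies.
* The M0 rule's accuracy depends on the excursion slope at threshold; slow
  drifts are detected late by construction of the rule itself.
* Wolf's λ on short noisy physiological series is a relative, not an
  absolute, stability measure; only its calibration on known dynamics is
  quantitatively validated.
* The standing-CoA convention (raw envelopes, middle 15 s) and the
  transition normalisation (standing-baseline RMS) make standing and
  transition indices not directly comparable in absolute value.
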