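# Methods

## Signal model and pipeline

A walk session holds one tri-axial acceleration series (m/s², 128 Hz) per
foot. The dead-reckoning estimator processes each foot independently:

1. **Gravity removal** — subtract each axis's arithmetic mean over the
   whole recording. This treats the gravity projection per axis as a
   constant, i.e. assumes roughly constant sensor orientation; it is not
   attitude tracking. A useful side effect: any constant accelerometer bias
   is removed exactly, so the estimator is insensitive to static bias by
   construction (the drift experiments below therefore remove gravity with
   the known gravity vector instead, to keep the injected bias alive).
2. **Low-pass filtering** — 4th-order Butterworth, default cut-off 60 Hz,
   applied forward–backward (zero phase). At a 128 Hz sampling rate a
   60 Hz cut-off sits at 0.94 of Nyquist and is nearly a pass-through; the
   default is kept for fidelity to the hardware configuration the package
   targets, and `filter.cutoff_hz` is exposed for more aggressive
   smoothing. A cut-off at or above Nyquist is rejected, never clamped.
   Zero-phase filtering matters because stance-interval timing feeds the
   integration step; the filter family and order are package choices, and
   the analytic Butterworth magnitude response (attenuation ½ at the
   cut-off after two passes) is what the tests check against.
3. **Rest detection** — a foot is resting wherever the Euclidean magnitude
   of the cleaned signal stays strictly below `rest_threshold_ms2`
   (default 1.0 m/s²) for at least `min_rest_duration_s` (default 0.08 s,
   ≈10 samples; suppresses the momentary zero-crossings of the swing
   pulse, which otherwise fragment strides). Intervals are 0-based,
   half-open, maximal, disjoint and sorted. A patient stop is any overlap
   of a left and a right rest strictly longer than `min_stop_overlap_s`
   (default 1 s).
4. **ZVU integration** — cumulative trapezoidal integration per axis at
   the fixed 1/fs step; velocity is exactly zero on every rest/stop sample
   and integration restarts from zero after each interval. Implemented as
   the raw cumulative integral minus its value at the most recent rest
   sample, which is algebraically identical and vectorises.
5. **Stride aggregation** — each gap between consecutive rests is one
   stride; the per-axis time-integral of velocity over the gap gives a 3-D
   displacement vector whose norm is that stride's distance. Chord length
   per stride is used rather than the arc length of the speed curve:
   vertical swing oscillation would inflate arc length, while the chord
   matches "distance walked". Per-foot distance is the sum of stride
   norms; the session total is the arithmetic mean of the two feet
   (`dwa.foot_combine` also offers `left`, `right`, `max`) — each foot
   traverses the full path, and the mean is robust to one-sided detection
   failures.

A foot with no detected rests is not fatal: the estimate is produced with
a drift-prone warning, because that is the realistic failure mode on
heavily irregular gait and aborting would discard the other foot's
information.

The summary estimator is `(cadence/2) × stride_length × duration_min`
under the default one-stride-per-two-steps convention. The wording of
vendor outputs is genuinely ambiguous about whether "cadence" counts steps
or strides, so the convention is a flag (`stride_per_step` doubles the
result) rather than a hidden assumption. When a vendor summary is stored
in the session it wins; otherwise cadence and stride length are derived
from the strides the dead-reckoning pipeline detects.

## Agreement statistics

Differences default to reference − estimate, so a negative mean difference
means the estimator over-reads. SDs use the n−1 denominator. The ICC is
the two-way absolute-agreement single-measure form (ICC(2,1)), computed
from the two-rater mean squares; absolute agreement is the right notion
for method comparison because a systematic offset between methods must
count against them (the tests verify ICC < r under a constant offset, and
equality with the long-hand ANOVA decomposition and with an independent
implementation). Note ICC(2,1) equals Pearson's r for equal-mean,
equal-variance series only up to an O(1/n) term from the column-variance
component; the degenerate all-identical input is defined as ICC 1.
Koo–Li bands are closed on the left: ≥0.90 excellent, ≥0.75 good,
≥0.50 moderate, else poor. Kendall's τ-b, Pearson's r and the t-tests
delegate to scipy; the test suite pins each of them to brute-force
oracles (exhaustive pair enumeration with tie corrections, the
definitional covariance formula, a hand-derived Welch toy).

Relative-error bins default to [0,5), [5,10), [10,20), [20,∞) percent,
half-open, counts conserved by construction. Published summaries sometimes
label the top bin ">20%" while their shares sum to 100% only if it means
"≥10%"; the report prints raw bins so such discrepancies stay visible.

## The simulator

`simulate_session` generates, per foot, alternating stance (gravity plus
Gaussian noise) and swing segments. Each swing carries a single-period
sine pulse on the forward axis,

    a(t) = A·sin(2πt/T_swing),  A = 2π·stride_length/T_swing²,

which has zero net velocity change — the foot genuinely stops between
strides, so the ZVU premise holds by construction — and closed-form
displacement exactly equal to the stride length. Feet are offset by half a
stride period; per-foot stride rate is cadence/2 strides per minute.
Pauses replace scheduled strides with bilateral stance; the ground truth
counts only the strides actually scheduled, so the nominal
`(cadence/2)·duration·stride_length` is recovered up to the one trailing
stride the phase-shifted foot may not fit before the session ends (≤0.5%
on a two-minute walk; ground truth is defined as the mean over feet of
scheduled strides × stride length, which is what the signal contains).

Defaults describe a mildly impaired walk: cadence 110 steps/min, stride
1.30 m (≈143 m in two minutes, a typical clinic distance), stance fraction
0.35, noise SD 0.05 m/s² per axis (stance magnitude then sits far below
the 1 m/s² threshold), zero bias. `inject_bias` adds a constant per-axis
offset for drift experiments.

**Realism limits.** The pulse is one-dimensional, identical across
strides, and contains no turning, no double-support structure, no
stride-to-stride variability, and no orientation change of the sensor.
Passing the simulator-closure tests therefore shows the integration,
detection and bookkeeping are correct under the method's own assumptions;
it does not show the estimator is accurate on pathological gait. One
failure mode does carry over faithfully: when the swing pulse is gentle
enough that its peak approaches the 1 m/s² threshold (long swings with
short strides), mid-swing samples masquerade as rests, strides fragment
and distance is lost. Realistic slow gait pairs low cadence with a larger
stance fraction (shorter swings), which is how the slow profiles in the
validation are parameterised; the regime where that pairing breaks down is
exactly where step detection degrades on real patients too.

## Problem sizes and numerical choices

The validation cohort in `scripts/acceptance.py` uses 40 two-minute
sessions (15,360 samples per foot each) with cadence ~N(108, 14) clipped
to [75, 140] steps/min, stride ~N(1.25, 0.18) m clipped to [0.7, 1.7],
stance fraction interpolated from 0.55 (slow) to 0.32 (fast), noise SD
0.05 m/s², and an every-fifth-session mid-walk pause of 4–12 s; per-session
seeds derive from the command-line seed. Trapezoidal double integration of
one clean swing reproduces the analytic stride length to <0.1% at 128 Hz.
Threshold comparisons are strict (`<` for rest, `>` for the one-second
stop rule) so boundary samples are deterministic. All estimators are
bit-deterministic for fixed input and parameters.

## Known limitations

- Mean-subtraction gravity removal assumes near-constant sensor
  orientation; slow orientation drift aliases into the cleaned signal.
  Attitude-tracking sensor fusion is out of scope.
- Turn corrections at corridor ends are not modelled (neither in the
  estimators nor in the simulator).
- The left/right combination rule (arithmetic mean) and the
  chord-per-stride distance metric are declared package choices; other
  conventions are defensible and selectable where exposed.
- The agreement layer intentionally stops short of multifactorial
  regression modelling; it reports the statistics, not their clinical
  interpretation.
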