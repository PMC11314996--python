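# Methods

## Data model

A recording is a uniformly(-ish) sampled monocular gaze series:
timestamps in ms, positions in screen pixels (origin top-left, y down),
and a validity mask. Missing data are carried as `valid=False`, never as
sentinel coordinates, because (0, 0) is a legal corner position. All
processing preserves the time base — corrections replace values, they
never delete or resample — so downstream block/condition bookkeeping
always sees an unbroken series.

All intervals anywhere in the package (artifacts, blocks, trials, AOI
boxes, screen bounds) are half-open `[start, end)`. A boundary sample
belongs to the later span.

## Geometry and the velocity threshold

One degree of visual angle at screen centre subtends
`d · tan(1°)` metres, hence `d · tan(1°) / (width_m / width_px)` pixels.
The artifact threshold is the physiological saccade-speed ceiling,
0.9 °/ms. Under the default geometry this converts to 39.96 ≈ 40 px/ms.

The default geometry is 1680 × 1050 px at `d` = 1.0 m. The physical
screen width is not a measured quantity of the target setup; 0.6604 m is
**back-derived** so that the 0.9 °/ms ceiling lands on the conventional
40 px/ms figure, and 0.4128 m keeps pixels square. Both are plain config
values and should be overridden for any real display. The conversion is
evaluated at screen centre only (small-eccentricity approximation); a
per-sample eccentricity correction would change the threshold by well
under 1 % across this display and is deliberately omitted, since the
detector uses a single global threshold anyway.

## Detection

Velocity is the **backward** finite difference per axis divided by the
actual Δt (irregular sampling is tolerated). Backward, not central, so
that a corrected value at sample *i* never depends on future corrected
values during displacement reintegration. The first sample and any
sample adjacent to an invalid one have undefined velocity.

Blinks are simply maximal runs of invalid samples.

Sensor artifacts are segmented on the *blink-corrected* trace (the sharp
pre/post-blink excursions would otherwise alias as spikes): every sample
with speed above the threshold is an event; an onset event is paired
with the next event whose velocity vector has **negative dot product**
with the onset's — the 2-D generalisation of "the movement direction is
opposite at the start and end of the error" — within a 500 ms horizon.
Events between onset and return are absorbed into the episode. Episodes
of duration ≤ `max_spike_ms` (default 10 ms; the boundary between "a few
milliseconds" and "tens to hundreds" is qualitative, so this is a
config knob) are spikes, longer ones displacements. An onset with no
qualifying return jump is reported `unterminated` and left uncorrected:
silent correction without a trusted resume point would be invented data.

Genuine saccades are sub-threshold *by construction* (the threshold is
the saccade-speed ceiling), so no fixation/saccade classifier is needed
and none is built.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `speed_threshold` | 40 px/ms | saccade ceiling 0.9 °/ms under default geometry |
| `max_spike_ms` | 10 ms | spike/displacement duration boundary |
| `max_displacement_ms` | 500 ms | search horizon for the return jump |
| `blink_pad_ms` | 200 ms | margin discarded each side of a null run |

## Correction

* **Spike** (default mode `post`): every in-episode sample takes the
  value of the first trusted sample after the episode — the "correct
  data from the final moment". `pre` (hold the last pre-episode value)
  and `bridge` (linear between the two anchors) are provided because for
  a few-ms episode the three are nearly indistinguishable and the right
  choice is a matter of taste.
* **Displacement**: the episode's relative motion is trusted, its
  absolute position is not. With p₀ the last trusted pre-onset position,
  the first in-episode sample becomes `p₀ + v_pre·Δt` (v_pre = the
  velocity immediately before onset, 0 if unavailable) and each later
  sample adds the raw backward difference. The `v_pre·Δt` term replaces
  the corrupted entry jump with one step of extrapolated true motion;
  it makes constant-offset episodes on constant *and* linear traces
  recover exactly, at the cost of assuming short-horizon smoothness for
  one sample. Raw data resume unchanged after the episode, since the
  gaze has physically returned to the correct position.
* **Blink**: the null run padded by 200 ms per side (merging overlapping
  padded windows) is refilled by per-axis linear interpolation between
  the nearest trusted neighbours; a window touching a record boundary is
  held at the nearest trusted value rather than extrapolated. The 200 ms
  pad subsumes the ~100 ms flanking excursions with headroom.

Pipeline order: blinks → velocity → spike/displacement segmentation →
corrections in time order. The pass is idempotent (a second pass reports
all-zero counts) and is the identity on clean input.

## Quantification

At a uniform rate, sample counts are proportional to dwell time, so all
attention measures are sample-count fractions. On-screen rate: valid and
inside `[0,width) × [0,height)`. Task rate: inside any applicable AOI,
side-matched for AJ/NOAJ trials. Null samples count against both rates
in both the raw and the filtered variant — this is what lets filtering
legitimately *raise* rates, since interpolation restores samples to
plausible positions. The denominator is all samples of the condition
(not only on-screen ones), consistent with AJ/NOAJ task rates that are
bounded near 3/5 by stimulus timing.

The AOI geometry of the original stimuli is not available; the defaults
(200×200 px cross box at centre, 400×400 px object boxes at 1/4 and 3/4
screen width) are documented placeholders, config-overridable.

Temporal ("fatigue") analyses use the *trial position*: the within-block
index for the five-trial AJ/NOAJ blocks (averaged over the four block
repeats) and the block occurrence index for the single-trial Center
blocks, giving Center positions 1..4.

## Statistics

Two-tailed throughout; α = 0.05. Wilcoxon signed-rank drops zero
differences (classic convention; the count is reported — Pratt's method
was considered and rejected as the less common textbook default). For
n ≤ 25 non-zero pairs the null distribution of the positive-rank sum is
enumerated exactly by dynamic programming over (possibly tied,
doubled-to-integer) mid-ranks — equivalent to full 2ⁿ sign enumeration —
so a 16-subject cohort is always on the exact path; beyond that, the
normal approximation with tie correction. Friedman uses average ranks
and the tie-robust (Conover) form of the chi-square statistic with
k−1 df, which also supports k = 2. Post hoc: Wilcoxon on every condition
pair with Bonferroni factor m = k(k−1)/2 (the whole family of one
Friedman test). These are implemented in-package because the exact
tie-aware small-n path and k = 2 support are needed; `scipy.stats`
versions serve as independent cross-checks in the test suite.

## Synthetic world

Defaults encode the target acquisition: 1000 Hz, 1680×1050 px at 1 m,
sensor jitter SD 1 px (≪ threshold × Δt), blink null runs of 150 ms
flanked by 300 px vertical excursions over 100 ms (direction random, as
only "up or down" and the ~0.1 s duration are known), spikes of 2 ms /
100 px, displacements of 100 ms / 100 px. Bench protocols: 20 s centre
fixation with ~1 blink/s (20 blinks), and a 20 s inside-out Archimedean
spiral (constant angular velocity, 6 turns, peak speed < 1 px/ms).

Group sessions place each subject's gaze on the trial's AOI centre for a
fraction of each trial and on a fixed off-AOI point for the rest. The
fraction is `adherence[cond] − decay[cond]·(position−1)` plus a
subject-level (SD 0.05) and a trial-level (SD 0.1) Gaussian perturbation,
clipped to [0, 1]; the defaults (Center 0.72, AJ 0.48, NOAJ 0.50) match
the task-adherence regime of a compliant adult cohort where the target
object is active for 3 of each 5 s video. Transitions between dwell
points ramp at 20 px/ms — saccade-like, and safely sub-threshold — so
genuine motion never aliases as an artifact; a side effect is that
"perfect" adherence yields rates a hair below 1.0 (a few in-transit
samples per trial).

What the generator does **not** emulate: oculomotor main-sequence
dynamics, microsaccades/drift within fixations, pupil-size effects,
device-specific excursion shapes around blinks, calibration drift, and
head motion. A green synthetic battery therefore establishes that the
algorithms are implemented correctly and recover their own stated world
— not that the published cohort numbers would be reproduced on real
participants, whose data are not redistributable.

## Numerical and degenerate-case choices

* Velocities and thresholds are strict inequalities (`speed > threshold`).
* Blink interval `end_ms` is the timestamp of the first sample after the
  run (half-open convention; at the record tail, last timestamp + one
  nominal period).
* Unterminated episodes at or near the record end are clipped to the
  record and to the next super-threshold event, keeping detector output
  disjoint and sorted.
* An all-zero-difference Wilcoxon returns p = 1 with a warning; a fully
  tied Friedman matrix returns statistic 0, p = 1.
* Degenerate rate denominators (no samples in a condition) raise rather
  than return NaN.
* Interval matching in the truth scorer is greedy one-to-one on
  same-kind midpoints within 25 ms; empty detection reports precision 1
  with an explicit `precision_undefined` flag.

## Known limitations

* The 1-sample `v_pre` extrapolation at displacement onset assumes the
  eye kept its immediately preceding velocity during the entry jump.
* Linear blink interpolation flattens genuine motion under the padded
  window (up to ~0.55 s for a 150 ms blink); rapid gaze shifts during a
  blink are unrecoverable by design.
* The EyeLink ASC reader covers monocular sample lines only, not EDF
  binaries, binocular records or pupil-size processing.
* Center-of-screen degree↔pixel conversion; no mirror-optics modelling.
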