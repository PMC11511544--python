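# Methods

## Data model

A session is one uniformly sampled recording of a single activity phase
(resting, walking or running).  Each sample holds heart rate (BPM, > 0),
SpO2 (%, 0–100), ambient and body temperature (°C), linear speed (cm/s,
≥ 0) and the device's instantaneous alert flag (0/1); sample times are
strictly increasing.  The packaged reference tables carry no timestamps, so
the sampling period defaults to 1 s — consistent with the per-second
narration of the validation recordings — and is overridable everywhere.
The one-minute cloud-upload interval of the original device is a transport
detail, not the sampling rate, and plays no role here.

Eight 30-sample reference tables ship verbatim at their printed two-decimal
precision: raw resting/walking/running, their width-5 moving-average
counterparts, and Gaussian-filtered resting/walking.  The published
Gaussian *running* table is a cell-for-cell duplicate of the walking one
and is excluded as an erratum; `load_fixture("gauss_running")` raises.
Table comparisons use an absolute tolerance of 0.005 to absorb print
rounding.

The cloud record layout is reproduced as a flat mapping from slash-delimited
node paths (`sensor/acc/{x,y,z}`, `sensor/gyro/{x,y,z}`, `sensor/temp`,
`sensor/BPM`, `sensor/alert`, `timestamp`) to numbers.  `sensor/temp`
carries the body (skin-contact) temperature; SpO2, ambient temperature and
speed travel on extension paths (`sensor/SpO2`, `sensor/ambientTemp`,
`sensor/speed`) so that serialization is a bijection and a sample
round-trips exactly.  No network code exists or is planned.

## Kinematics

The glove's hand motion is modelled as rotation about the elbow: linear
velocity is v = ω × r with r the elbow→sensor vector in metres and ω the
gyroscope reading converted deg/s → rad/s (an explicit, mandatory step).
Speed is ‖v‖ · 100, in cm/s.  The default arm vector is (0.25, 0, 0) m — a
forearm-length scale; radius variation over the stride is neglected, so r
is a per-session constant.  The reference recordings do not state the r
used, and the underlying gyro traces are unprinted, so the published speed
columns cannot be regenerated; kinematics is validated by properties
instead: agreement with an independent determinant-expansion oracle to
1e−12, orthogonality of v to both ω and r (tolerance 1e−9), linearity in
ω, and antisymmetry ω × r = −(r × ω).

## Smoothing

Two filters, applied to each measurement channel independently (never to
the alert flag, which is recomputed downstream):

* **Moving average**, odd window, default 5.  `complete_only` emits one
  value per fully contained window (length n − w + 1); `reflect` pads by
  boundary reflection and preserves length.
* **Gaussian**, default σ = 2, kernel half-width ⌈truncate·σ⌉ with
  truncate = 4, weights ∝ exp(−k²/2σ²) normalized to sum 1.  `reflect`
  delegates to `scipy.ndimage.gaussian_filter1d`; `complete_only` is a
  valid-mode convolution.

The packaged filtered tables were cut from a longer recording: an
offset-search oracle (re-run in the tests, offsets −5..+5) shows that
filtered row i equals the mean of raw rows i+1..i+5, uniquely and for every
channel and phase, to 0.005.  Rows 26–30 of the filtered tables depend on
unprinted samples and are outside the regression.  The Gaussian tables are
*not* regenerable from the raw tables: scanning boundary modes, truncations
and offsets (`scripts/gaussian_calibration.py`) leaves residuals up to
~3 cm/s on the walking speed channel, so the Gaussian fixtures are loadable
data, not a regression surface; the Gaussian implementation is instead
pinned to an explicit-loop convolution oracle at 1e−12.

## Alerts

A sample is flagged when hr > threshold (default 150 BPM); compound logic
additionally requiring speed > 100 cm/s is provided but off by default,
because every flagged row of the running reference table is explained by
heart rate alone.  When an athlete age is supplied the threshold is the
conventional age-predicted maximum heart rate, 220 − age.

The 2 s reset of a triggered alert is modelled two ways: flagged runs whose
separating gap is shorter than the refractory period merge into one
episode (a gap of k unflagged samples lasts k·period), and the abstract
actuator contract (`actuate`: start on rising edge, stop on falling edge)
keeps the motor on across merged runs.  The per-sample flag itself stays
instantaneous, matching the device logs where consecutive above-threshold
samples each carry 1.  With merge gap 0, episodes are exactly the maximal
runs and their sample counts partition the flag count.

Raising the threshold shrinks the flag set pointwise, so the flagged-sample
count is monotone.  The episode count is *not* monotone in general — a
raise can split one run into two runs separated by at least the merge
gap — so monotonicity of episode counts is asserted only on ladders where
no split occurs (e.g. from the operating threshold upward on the running
table).

The filtered reference tables print alert columns whose rows do not align
with their own smoothed heart-rate columns (flags sit on rows whose printed
hr < 150); this package recomputes flags from smoothed values rather than
reproducing those columns.

## Evaluation

Episodes are detected on the raw session and on each smoothed variant
(length-preserving reflect smoothing, same alert config).  The last listed
variant — Gaussian, per this pipeline's ranking of the two filters — is the
reference: a raw episode is confirmed iff it overlaps a reference episode
widened by the matching window (default = the 2 s refractory), each
reference episode confirming at most one candidate, assigned greedily by
candidate start time.  Confirmed + false = raw count always, and the
true-positive rate on zero raised alerts is defined as 100 % (no alarms,
hence no false alarms).  The reference convention is an internal
consistency definition, not clinical ground truth, and the report names it
explicitly.

## Synthetic sessions

The generator emulates the level-and-spread structure of the reference
recordings; it does no physiological ODE modelling.  Per phase (defaults in
parentheses, duration 300 s at 1 Hz):

* **Heart rate**: saturating linear ramp min(base + ramp·t, peak) plus
  Gaussian noise.  Resting 77 ± 2.2; walking 80 ± 12; running ramps from
  95 at 0.5 BPM/s to a 155 BPM plateau ± 8, so the 150 BPM alert path is
  exercised in essentially every run.
* **SpO2**: near-integer plateau (resting 97, walking/running 96) taking
  rare ±1 steps (p = 0.02/sample), clipped to base ± 2 — the tables show
  integer SpO2 hovering within a couple of points.
* **Temperatures**: linear drift plus small jitter.  Per-phase bases follow
  the tables, including the lower body temperature while walking (~34.4 °C)
  than resting (~35.7 °C); the generator reproduces the recorded levels
  without asserting a physiological explanation.
* **Speed**: not drawn directly.  A target speed (resting 0.5 ± 0.3 cm/s,
  walking 28 ± 16 — base + 2 SD near the ~60 cm/s walking ceiling —
  running 150 ± 70 cm/s) is converted to a swing-axis gyro rate, white
  drift noise (0.9–3 deg/s) is added on all three axes, and the trace is
  pushed through the cross-product kinematics.  The resting speed floor
  (~0.7 cm/s) is therefore genuinely the image of gyro noise.
* **Spikes**: Poisson-placed single-sample multiplicative excursions of the
  heart-rate channel (walking/running 1/min at gain 1.5 and 1.4), the
  signature of a sensor shifting on skin during motion.  At rest the sensor
  does not move, so the resting default injects none.  Width-1 spikes are
  maximally attenuated by both filters, which is exactly the false-alarm
  mechanism the evaluation quantifies.

All randomness flows from one caller-supplied seed through a named
`numpy` generator; identical seeds give byte-identical sessions.  Channels
are rounded to the device's two printed decimals.

What passing tests on synthetic data do **not** show: real pulse-oximeter
artifact structure (correlated dropouts, motion-band noise), real HR
kinetics (recovery, drift with fatigue), or any multi-subject variability —
the validation recordings come from a single athlete.

## Problem sizes and numerical choices

The table regressions cover all 375 fully printed filtered cells (25 rows ×
5 channels × 3 phases) at 0.005 absolute.  The filter-ordering study uses
100 seeded 300-sample spike-heavy sessions and compares median episode
counts (raw ≥ moving average ≥ Gaussian, with a strict raw > Gaussian
drop); the published full-session counts (7 raw → 3 moving-average → 1
Gaussian, and the derived true-positive percentages) come from a longer
unprinted recording and are treated as a distributional property, not a
numeric target.  Parameter recovery checks the resting heart-rate mean over
50 seeds × 300 samples against 3 standard errors.  Oracle equivalences
(cross product, Gaussian convolution) are asserted at 1e−12; orthogonality
at 1e−9.  Degenerate inputs (empty sessions, zero-radius arm, even or
oversized windows, non-positive σ, out-of-range ages, negative rates) raise
`ValueError` with the offending field named; CSV rows are rejected with
1-based row numbers.
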