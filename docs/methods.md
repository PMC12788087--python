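# Methods

`cmjkin` implements a semi-automated analysis chain for countermovement
jumps (CMJ) recorded as vertical marker displacement: 2D video-tracking
exports (pixel or metre valued) and 3D motion-capture exports are read,
conditioned, segmented into jump phases by fractional displacement
thresholds, and compared across raters and systems with a standard
method-comparison battery. A synthetic study generator with analytic
ground truth makes every stage testable without access to recorded data.

## Phase segmentation

All detection operates on the baseline-referenced displacement–time
signal `z(t)` of one marker (upward positive; quiet standing defines
`z = 0` via the mean over an initial `baseline_window`, default 0.5 s).

* **Trough** `i_min`: first global minimum of `z` (ties → earliest
  sample). It separates the eccentric (downward) from the concentric
  (upward) phase; `h_Z_min = z[i_min]` is the countermovement depth.
* **Onset**: walking backward from the trough through the contiguous
  run of samples that have descended at least `onset_fraction` (default
  5 %) of the downward range `|z[i_min]|`, the first sample of that run.
  The backward walk makes pre-movement sway that recovers above the
  threshold irrelevant. Because the signal is baseline-centred first,
  "5 % of the trough value" and "5 % of the total downward displacement"
  coincide by construction.
* **Apex** `i_apex`: argmax of `z` after the trough; `h_Z_max` is the
  apex above baseline (default) or above the take-off position
  (`hmax_reference="takeoff"`).
* **Take-off**: first sample after the trough at which the signal has
  risen `takeoff_fraction` (default 5 %) of the trough-to-apex range
  above the trough (the *literal* rule), or is within that fraction of
  the apex (*apex-referenced*). The literal rule is the default; it
  places take-off early in the ascent, which is why both rules are
  exposed — the apex-referenced variant corresponds to reading the rule
  as "5 % short of full upward displacement". Whether "total upward
  displacement" means trough-to-apex or trough-to-baseline is a genuine
  ambiguity; trough-to-apex is implemented.

Derived variables: `dt_ecc` (onset→trough), `dt_PP` (trough→take-off),
`dt_take_off = dt_ecc + dt_PP` (exact identity), `h_Z_min`, `h_Z_max`.

A positive rescaling of `z` leaves all indices unchanged and scales the
`h` variables; adding a constant is absorbed by the baseline estimate.
Both properties are enforced by tests, and the detector is checked
index-for-index against a brute-force threshold scan.

## Signal conditioning

* **Calibration** (2D video in pixels): scale `body_height_m /
  reference_length_px` m/px from a drawn stature reference. A relative
  error δ in the drawn reference multiplies every displacement by
  1/(1−δ) and — because both 5 % rules are *fractional* — leaves every
  duration untouched. The pipeline reproduces this exactly: with
  δ = 0.05 all `h` variables inflate by 1/0.95 while the durations are
  bit-identical. Timing shifts ascribed to calibration error therefore
  require offset/posture effects that a purely multiplicative model
  cannot produce; they are documented, not modelled.
* **Gap filling**: interior occlusion gaps are filled by linear
  (default) or local polynomial interpolation (degree 3, two support
  samples per side — exact for cubics). Boundary gaps or gaps longer
  than `max_gap_s` (default 0.05 s, "a few frames") mark the trajectory
  unrecoverable, mirroring the exclusion of chronically occluded
  markers.
* **Smoothing**: centred moving average with shrinking symmetric edge
  windows (length preserved, constants fixed points). Default window
  ≈17 ms (5 samples at 300 Hz, scaled with rate). The default is
  deliberately short: a boxcar (or any symmetric kernel) shifts a
  minimum with unequal curvature on its two sides toward the flatter
  side by up to ~0.4× the half-window, and CMJ troughs are routinely
  curvature-asymmetric (stiff propulsion after a soft eccentric phase,
  or vice versa). At 50 ms we measured trough shifts up to ~3 samples
  on noise-free signals — a distortion of the motion pattern — whereas
  at 17 ms the worst shift stays near one sample. A property test pins
  the derived bound (≤ 1 + 0.45·half-window samples per event).
* **Differentiation**: central differences (one-sided at the ends),
  exact for quadratics in the interior.

## Synthetic studies

The generator emulates the design of a concurrent-validity experiment:
10 participants × 3 trials, each trial recorded by a 300 Hz reference
("mocap") and two 240 Hz video renditions that share the same true jump
and differ only in rater noise.

One jump is a C1 piecewise model (quiet → half-cosine eccentric descent
to `−depth` → cubic propulsion to take-off height `z_to` with take-off
velocity `v_to` → ballistic flight → landing cubic, cosine settle,
quiet tail). The propulsion cubic is monotone iff
`v_to·T_pp < 3·(z_to + depth)`; the constructor rejects parameters
outside that region (the ascent would dip below the trough) and the
population sampler clips `T_pp` at 85 % of the limit. Marker gains
scale amplitudes (shoulder 1.05, hip 1.00, knee 0.35). A single gain
per marker cannot reproduce both the shoulder's large countermovement
depth and its hip-like apex seen in real data; gains were chosen to
match apex and hip-depth magnitudes, accepting a shallow synthetic
shoulder depth.

Because the model is analytic, the 5 %-rule event times exist in closed
form (onset, on the cosine) or via root solving (take-off), so recovery
tests compare against exact continuous-time truth.

Population defaults (hip-referenced, per-participant between-subject
SDs, within-trial SD = 0.3×): depth 0.28 ± 0.05 m, `v_to`
2.65 ± 0.15 m/s (apex ≈ 0.46 m), `T_ecc` 0.50 ± 0.06 s, `T_pp`
0.31 ± 0.035 s — magnitudes of a recreationally trained male cohort.
Noise defaults: white tracking noise 0.5 mm (mocap) / 2 mm (video),
rater placement drift 2 mm SD with 1 s correlation time, 0.3–0.5
occlusions per trial of 2–10 samples, optional calibration scale error.
The drift correlation time matters: fast drift acts like band-limited
noise against the knee's ~5 mm onset threshold and destroys knee timing
reliability, which contradicts reported experience; slow drift behaves
like a small offset, which the fractional thresholds tolerate. Jitter
and tracking SDs were calibrated so that inter-rater error SDs of the
extracted variables land in the reported SEM range (≈0.002–0.02 s/m).

What the generator does **not** emulate: perspective/parallax error,
marker-template drift correlated between raters, multi-segment posture
effects on calibration, non-Gaussian tracking failures, or any
force/CoM mechanics. Passing recovery and reliability tests therefore
demonstrates correctness of the *algorithms* under the stated noise
model, not accuracy of 2D video jump analysis in the field.

## Agreement statistics

Given an `n_subjects × k_methods` table of one variable (trials
averaged per participant by default; per-trial pooling behind a flag):

* **ICC(3,1)** — two-way mixed, single measure, consistency:
  `(MS_S − MS_E)/(MS_S + (k−1)·MS_E)` from the two-way ANOVA, with the
  F-based 95 % CI (`F_obs = MS_S/MS_E` on (n−1), (n−1)(k−1) df). Tested
  against an explicit sums-of-squares oracle and pingouin's ICC(C,1).
  Zero between-subject variance raises a degenerate-table error. The
  estimator is consistent but not unbiased; at n = 50 its O(1/n) bias
  is ≲ 0.01, which the Monte-Carlo calibration test accounts for.
* **CV%** — mean over subjects of 100·SD_i/|mean_i| (n−1 SD), the usual
  within-subject CV of reliability studies; `sem_ratio`
  (100·SEM/grand mean) is available behind a flag. A zero subject mean
  is reported as undefined rather than propagated.
* **SEM** — `SD_pooled·√(1 − ICC)`.
* **MD** — mean difference, oriented second label minus first
  (video minus reference; rater B minus rater A), logged per table.
* **Pearson r** — `scipy.stats.pearsonr` with Hinkle magnitude labels
  at |r| cut-points 0.30/0.50/0.70/0.90, boundaries to the upper band.
* **Bland–Altman** — bias = mean difference, limits of agreement
  bias ± 1.96·SD(diff); plus the inverse map from printed limits back
  to (bias, SD), used to audit published summaries
  (bias = midpoint, SD = width/3.92).
* **Sample size for a correlation test** — Fisher-z approximation
  `n = ⌈((z_{1−α[/2]} + z_{power})/atanh ρ)² + 3⌉`. One-tailed default
  (ρ = 0.8, α = 0.05, power 0.8 → n = 9; two-tailed → 10).

Centre-of-mass landmarks are not implemented: no CoM definition exists
for a three-marker model without segment masses.

## Numerical and design notes

* Discretisation: a frame-quantized detector localises each threshold
  crossing within one sample period and the trough within one period
  (half under symmetric curvature); a *duration* — the difference of
  two event times — can therefore deviate from continuous-time truth by
  up to ~1.5 periods even for a perfect detector. Recovery tests
  compare durations against grid-aligned truth (the best any sampled
  detector can report), where the bound is exactly one period.
* The zero-noise recovery experiment disables the moving-average filter
  (its only role is noise suppression); filter-induced event bias is
  characterised separately, as above.
* Ties in the global minimum resolve to the earliest sample. Flat,
  monotone, or never-crossing signals raise a no-countermovement error
  rather than returning indices.
* Simulation problem sizes in tests and the acceptance script (10 × 3
  studies, 1000-case oracle and Monte-Carlo batteries, n = 50 tables)
  were chosen to make sampling error small relative to the tested
  effects while keeping a full run in seconds.
* Known limitations: no Butterworth/spline filtering, no 2D→3D
  perspective correction, no force- or velocity-based onset rules, no
  flight-time jump-height formula, no binary motion-capture container
  support.
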