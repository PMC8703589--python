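# Methods

This note documents the models and procedures implemented in `repcoach`,
the design choices made where the design was genuinely open, and what
the synthetic-data results do and do not show about real recordings.

## Data model and conventions

Recordings are fixed-rate (default 50 Hz, 20 ms frames) streams from ten
IMU nodes (left/right thigh, shin, upper arm, forearm; hips; torso),
each providing a 3-axis accelerometer in m/s² with gravity included and
a 3-axis gyroscope in deg/s. Magnetometer and orientation quaternions
are carried in the schema but excluded from all computation (heading
depends on where the user faces). Joint positions are 3-vectors in
meters on a uniform avatar in a fixed, right-handed world frame:
x = right, y = up, z = front; "top"/"bottom" are always aligned with
gravity regardless of posture. Frame indices are 0-based and repetition
boundaries are half-open `[start, end)` ranges.

Gyroscope units deserve a note: the segmentation thresholds
(G_limit ≈ 1–15) are only plausible at the stationary/moving boundary if
rates are in deg/s, so deg/s is fixed throughout.

## Exercise prediction

Every frame is a 60-vector (per node: accel xyz, gyro xyz, in fixed node
order). A support-vector machine with RBF kernel, C = 1 and
gamma = 1/(n_features·var) — standard defaults, isolated behind
`ClassifierConfig` — predicts one of `<exercise>_POSE`,
`<exercise>_REP`, `NEGATIVE_NONE`. Features are z-scored per feature
with statistics fit on the training folds only. Multiclass decisions
are one-vs-one by vote. Per-sample classification (denoise window 1) is
the default; a causal moving-average window can be applied to the sensor
streams first (`--denoise-window`). Evaluation is leave-one-subject-out
cross-validation; accuracy and macro precision/recall/F1 are computed
from the pooled confusion matrix over all held-out frames (classes never
present and never predicted contribute zeros to the macro means). A
`frame_stride` option thins frames for training/evaluation; results in
the test suite use stride 3 (every 60 ms), which leaves per-class counts
in the hundreds-to-thousands.

## Segmentation

The state machine runs on one node's gyroscope stream (right thigh for
squat/lunge, right upper arm for push-up), causally denoised with an
8-sample moving average (160 ms at 50 Hz). Predicates, with strict
inequalities exactly as defined: *stationary* iff |gᵢ| < G_limit for all
axes; *moving* iff Σ|gᵢ| > 3·G_limit; default G_limit = 8 deg/s.

Two deliberate refinements over the bare per-sample predicates:

* **Debounce.** A pose or repetition end is declared only after
  `min_hold_frames` = 5 consecutive stationary frames (100 ms); the raw
  predicate chatters on noisy gyros.
* **Event indexing.** Decisions are made online, but events are indexed
  at the physically meaningful frame: STARTING_POSE/REP_DONE at the
  first frame of the stationarity hold, REP_STARTED at the first
  non-stationary frame once the moving predicate confirms. The decision
  latency is unchanged; only the reported boundary index is refined.
* **Label gating.** Classifier labels, when supplied, gate only the
  STARTING_POSE transition (majority label over the hold window must be
  a `*_POSE` label). Repetition transitions are purely gyro-driven; the
  pose confirmation is the minimal integration point between classifier
  and segmenter.

`segmentation_accuracy` matches detected (start, done) pairs to
ground-truth repetitions greedily and in order; a match requires both
endpoints within a tolerance (150 ms in the test suite). On synthetic
data the recovered boundaries sit ~60–120 ms after the true motion
onset/end — the combined effect of the burst onset and the 160 ms causal
filter — and recovery is 100% with 1–2 s breaks. With no breaks the
inter-repetition stationarity window vanishes, consecutive repetitions
merge, and accuracy collapses; the with-breaks > no-breaks ordering is
the behaviour the method is known for, and only that ordering (not the
exact no-break percentage, which depends on gyro turnaround detail) is
asserted.

## Probabilistic movement models

For each joint, expert repetitions are linearly resampled to n points
(n = rep_duration × rate = 200) and summarized by the elementwise mean
**M** and sample standard deviation **S** (ddof = 1; unspecified
upstream, chosen as the unbiased-variance convention). Zero-variance
columns are kept but flagged with a warning. Expert curation is an
input: `build_model` takes the repetition list as given and applies no
automatic quality filter.

Time alignment is purely elapsed-time-based — repetitions have a fixed
duration, so frame *t* maps to column
`i = round(t / rep_duration × (n−1))` with round-half-up. No dynamic
time warping is attempted (a known limitation: off-tempo executions
misalign).

The detector flags, per axis, `e = d − Sᵢ` when `d = |Mᵢ − p|` exceeds
`k·Sᵢ`, else 0. Two conventions are worth making explicit:

* The else-branch subtracts **one** Sᵢ, not k·Sᵢ, so e jumps by
  (k−1)·Sᵢ at the band edge. The discontinuity is intentional and kept
  as designed (fidelity over smoothness); for k = 1 the map is
  continuous. For k < 1 the raw expression could go negative, so e is
  additionally clamped at 0.
* With k = 2, a position drawn from the expert distribution itself is
  unflagged with probability Φ(2) − Φ(−2) ≈ 95.45% per axis — the
  detector's calibration target, verified by simulation in the
  acceptance script.

Axes are treated independently (no covariance across axes or joints).
Where S = 0 the band has zero width and any deviation is an error; a
configurable sigma floor (`DetectorConfig.sigma_floor`, default 0,
suggested 1 mm) substitutes for zero S when converting to sigma units.

## Haptic feedback

`e_direction` carries the drift side (+e where p ≥ Mᵢ, −e otherwise);
`e_intensity = e_direction / Sᵢ` is dimensionless (sigma units);
`h_power = min(|e_intensity| / f_skill, 1)` per axis. Power is computed
on magnitudes — the sign is routed exclusively into the direction bin —
so power always lies in [0, 1]; applying the rule to the signed value
would produce negative powers, contradicting the [0, 1] contract.
f_skill (default 4σ) trades sensitivity for comfort: larger for
patients, smaller for athletes. Per-command power is the maximum over
axes (conservative, preserves [0, 1] without rescaling; an L2 mode is
available).

Direction binning quantizes each axis to −1/0/+1: an axis is active if
its magnitude is ≥ `dominance_fraction` (default 0.5) of the largest
axis magnitude. Labels compose in the fixed order front/back,
left/right, top/bottom ("front-bottom", "right-bottom", …); the zero
vector maps to "none". Channel lookup places stimulation on the side
the joint drifted toward (outward-drifting elbow → outside-elbow
channels). The shipped 80-channel map — four contact sites per joint,
top/bottom reusing the front+back / left+right pairs — is a documented,
editable fixture; no hardware layout fidelity is claimed.

## Synthetic protocol generator

The generator emulates the data-collection protocol: 2 s lead-in (half
idle/NEGATIVE, half starting pose), repetitions of exactly 4 s (half-
cosine descent over 2 s, ascent over 2 s — zero velocity at endpoints,
matching the stationarity assumption), inter-repetition breaks of
2/1/0 s labeled POSE, 2 s NEGATIVE lead-out. Three templates (squat,
lunge, push-up) define per-joint pose/bottom positions and per-node
pose/bottom/idle gravity vectors.

Gyroscope signals are parametric, not a physics model: per 2 s phase a
burst `A·sin(πv)^¼` (A per node, 36–80 deg/s dominant axis) whose
magnitude structure is what the segmenter and classifier consume —
near zero during holds, a fast onset that clears the moving threshold
within ~2 frames, zero at the turnaround. The ¼ exponent makes the
onset sharp enough that only the exact phase-0 frame of a repetition is
sensor-identical to the pose, which is what "separable" classes mean
here.

Subject variability (seeded per (seed, subject_id)): amplitude scale
±10%, whole-body positional offset ±2 cm, per-node accelerometer bias
(σ = 0.15 m/s²), per-repetition amplitude jitter ±2%, and slow postural
sway during holds (0.25 m/s² accel, 0.8 deg/s gyro, 0.3–0.5 Hz) so that
pose frames are never a degenerate repeated point. `frame_noise_sd`
(default 5 mm) adds white positional noise and proportional sensor noise
(×25 m/s² accel, ×200 deg/s gyro per meter).

What the generator does **not** emulate: biomechanically coupled
accelerations (gravity vectors are interpolated, not differentiated from
pose), soft-tissue artefacts, heteroscedastic or autocorrelated sensor
noise, tempo variation, and fatigue drift. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under the
stated protocol, not field performance on real suit data.

### Error injection

Injected errors displace chosen joints by `severity` × local S along
each type's canonical direction, shaped by a smoothstep plateau (ramps
over the first/last 15% of the repetition, so boundaries and labels are
untouched): type I, spine/clavicle/shoulder +z for squat and lunge, the
arched-back pattern for push-ups; type II, knees toward the midline
(squat/lunge) or elbows outward (push-up); type III, every joint whose
modeled vertical excursion exceeds 5 cm is raised (+y). Knee and ankle
height does not change with squat depth, so type III leaves them clean
by construction — the joint pattern the detector is expected to
recover.

Injection-recovery is evaluated with **probe recordings**: nominal
trajectory plus frame noise, no subject resampling, against a model
trained on a subject-varying expert pool. This isolates the question
"does the detector recover the injected direction and joint set?" from
sampling variation. Under full subject resampling the per-frame
detection probability at severity s is approximately Φ(s − k) (≈84% at
3σ, ≈98% at 4σ, k = 2) — an inherent property of a 2σ band, which is
why the canonical "severe error" magnitude is 4σ (also the `ErrorSpec`
default).

## Reporting

Percentages are rounded to two decimals with round-half-up (decimal,
not binary, so 2.675 → 2.68). The break-condition accuracy table takes
unweighted means across exercises; this convention reproduces, e.g.,
mean(100, 100, 98.18) = 99.39 and mean(96.43, 98.21, 96.30) = 96.98.
All reports carry raw counts so every ratio is recomputable; the
confusion report recomputes its metrics from counts and fails loudly
(IntegrityError) if they disagree with the stored values beyond 1e-12.

## Problem sizes

The shipped tests and acceptance script use desk-scale problems chosen
to exercise every code path with comfortable statistical margins:
5-subject × 3-exercise LOSO datasets (~10⁴ frames), 20 seeded
segmentation datasets of 4 repetitions each, 5-subject expert pools
(20 demonstrations) for movement models, 10-seed injection-recovery
sweeps, and 10⁵ draws for band-coverage calibration.

## Known limitations

* Fixed repetition duration; no tempo normalization or warping.
* Independent per-axis bands; correlated multi-joint errors are flagged
  axis-by-axis, not as patterns.
* The classifier requires a brief stationary starting pose per exercise
  and distinct poses across the exercise pool.
* The on-disk schema is this package's own; no import adapter for any
  particular suit vendor's export format is provided.
* No hardware drivers, pulse synthesis or perception model: the output
  ends at (channel set, power, time) commands.
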