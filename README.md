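# repcoach

IMU-based full-body exercise assessment with haptic-feedback mapping.

`repcoach` is for researchers and engineers building automated movement
coaching from body-worn inertial sensors: a 10-node suit streaming
accelerometer (m/s², gravity included) and gyroscope (deg/s) data at
50 Hz, plus per-frame joint positions of a uniform avatar. The package
covers the whole pipeline:

1. **Exercise prediction** — an SVM classifies every sample as
   `<exercise>_POSE`, `<exercise>_REP` or `NEGATIVE_NONE`, so the
   exercise is identified from its starting pose before the first
   repetition begins. Evaluation is leave-one-subject-out
   cross-validation with macro-averaged precision/recall/F1.
2. **Repetition segmentation** — a thresholded state machine over one
   denoised gyroscope stream: *stationary* when |gᵢ| < G_limit on every
   axis, *moving* when Σ|gᵢ| > 3·G_limit (defaults G_limit = 8 deg/s,
   8-sample moving average = 160 ms at 50 Hz), emitting
   STARTING_POSE → REP_STARTED → REP_DONE events.
3. **Probabilistic movement models** — per joint, a mean trajectory
   **M** ∈ R³ˣⁿ and standard deviation **S** ∈ R³ˣⁿ learned from expert
   repetitions resampled to n points (n = 200 for 4 s reps at 50 Hz).
   At frame index *i* (mapped by elapsed time since REP_STARTED), the
   deviation d = |Mᵢ − p[t]| becomes a per-axis error

       e = 0        if d ≤ k·Sᵢ
       e = d − Sᵢ   otherwise,          (k = 2 ≈ 95% confidence band)

4. **Haptic feedback** — the error is signed by drift side
   (e_direction = ±e depending on p ≷ Mᵢ), scaled to sigma units
   (e_intensity = e_direction / Sᵢ), binned into body-frame directions
   (front/back, left/right, top/bottom) and mapped to stimulation power
   h_power = min(|e_intensity| / f_skill, 1) on the electrotactile
   channels of the side the joint drifted toward. The skill threshold
   f_skill adapts intensity to the user (larger = gentler).

A fully seeded **synthetic protocol generator** emulates the study
conditions (4 s repetitions = 2 s concentric + 2 s eccentric; break
conditions of 2/1/0 s; per-sample labels; ground-truth boundaries) and
injects the three canonical execution errors — torso lean / arched back
(type I), knee/elbow misalignment (type II), insufficient depth
(type III) — so every stage is testable without hardware.

## Worked example

```python
from repcoach import (generate_recording, split_reps, build_model, ErrorSpec,
                      inject_error, events_from_boundaries, assess_rep,
                      emit_commands, error_map, segmentation_accuracy)
from repcoach.segment import segment, SegmenterConfig

# 1. expert demonstrations -> movement model
pool = []
for i in range(1, 6):
    rec = generate_recording("squat", n_reps=4, break_s=2,
                             subject_id=f"EXP{i:02d}", seed=11)
    pool.extend(split_reps(rec))
model = build_model(pool, exercise="squat")
print(f"model: {len(model.joints)} joints, n={model.n} samples/rep")

# 2. segment a new recording from its gyroscope stream
rec = generate_recording("squat", n_reps=4, break_s=2, subject_id="S99", seed=5)
events = segment(rec, SegmenterConfig(), rec.labels)
acc = segmentation_accuracy(events, rec.rep_boundaries, tol_ms=150)
print(f"segmentation: {len(events)} events, boundary recovery {acc:.1f}%")

# 3. inject a 'not deep enough' squat and assess it against the model
probe = generate_recording("squat", n_reps=4, break_s=2, subject_id="PROBE",
                           subject_noise=False, seed=99)
bad = inject_error(probe, ErrorSpec("III", severity=4.0), model)
assessments = assess_rep(bad, events_from_boundaries(bad.rep_boundaries), model)
em = error_map(assessments, model)
top = em.sort_values("n_flagged", ascending=False).head(3)
print(top[["joint", "direction", "flag_rate", "mean_intensity"]].to_string(index=False))

# 4. haptic commands
commands = emit_commands(assessments)
print(f"{len(commands)} haptic commands; first: channels={commands[0].channels} "
      f"power={commands[0].power:.2f} direction={commands[0].direction!r}")
```

Output:

```
model: 17 joints, n=200 samples/rep
segmentation: 9 events, boundary recovery 100.0%
      joint direction  flag_rate  mean_intensity
      hip_r       top    0.87875        3.475937
 clavicle_r       top    0.87750        3.490693
upper_spine       top    0.87750        3.491929
9087 haptic commands; first: channels=[25, 26] power=0.30 direction='top'
```

Reading the numbers: all 4 repetitions were found within 150 ms of the
ground truth (the 9 events are one STARTING_POSE plus 4 start/done
pairs). Under a 4-sigma "not deep enough" injection, the hip, clavicle
and spine joints are flagged in ~88% of their assessed frames, all in
the **top** direction (the body stays too high), at a mean intensity of
~3.5 sigma — while knees and ankles, whose height does not depend on
squat depth, stay clean. Each flagged frame becomes a haptic command on
the channels above the joint, with power 3.5σ/f_skill ≈ 0.87 at the
default f_skill = 4 (0.30 for the first, ramp-in, frame shown).

The same pipeline is scriptable from the shell:

```bash
repcoach simulate --exercise squat --reps 4 --break 2 --subjects 5 --seed 42 --out data/
repcoach train-model --data data/ --exercise squat --out squat.json
repcoach segment --data data/squat_S01.csv --out events.json
repcoach assess --data data/squat_S02.csv --model squat.json --out assessment.jsonl
repcoach feedback --assessment assessment.jsonl --f-skill 4 --out commands.jsonl
```

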