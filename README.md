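# gaitage

Age prediction from trunk-worn IMU gait recordings.

Dynamic balance ability declines with age, and clinicians routinely probe it
with two field tests: the **timed up and go** (TUG — rise from a chair, walk
3 m, turn, walk back, turn, sit) and the **six-minute walk test** (6MWT —
walk a linear course for six minutes). A single inertial measurement unit
strapped to the second lumbar vertebra records tri-axial linear acceleration
(vertical, mediolateral, anterior–posterior; m/s²) and angular velocity
(yaw, pitch, roll; deg/s) at 100 Hz during both tests. `gaitage` turns such
recordings into a 132-dimensional gait profile and regresses chronological
age on it with gradient-boosted trees — age being an indicator that elderly
users understand far more intuitively than a raw balance score.

The pipeline:

1. **Preprocessing** — minimal-order zero-phase Butterworth low-pass
   filtering from a MATLAB-style (passband, steepness, stopband-attenuation)
   triple; resultant acceleration `ACC_RES = √(ACC_VT² + ACC_ML² + ACC_AP²)`;
   full-wave rectification of pitch/yaw for event detection.
2. **TUG segmentation** — chair transfers are pitch excursions above
   25 deg/s, turns are yaw excursions above 32 deg/s; a valid trial yields
   the six sub-tasks *sit-to-stand, forward gait, mid-turn, backward gait,
   end-turn, stand-to-sit*, with the gait phases defined by the gaps between
   events.
3. **TUG features (111)** — six sub-task durations plus RMS/min/max of seven
   signals (three acceleration axes, their resultant, three gyro axes) over
   five sub-task groups (forward/backward gait averaged).
4. **6MWT features (21)** — step detection from vertical-acceleration peaks;
   six spatiotemporal gait parameters (steps, cadence, step time, stature-
   based stride length, distance, speed); step/stride regularity SR and STR
   (first and second peaks of the normalised unbiased autocorrelation
   `A(m) = (1/(N−m)) Σ xᵢ xᵢ₊ₘ`) and the symmetry index
   `SI = (SR − STR)/max(SR, STR)` on three axes; the harmonic ratio of each
   acceleration axis at stride-frequency harmonics (even/odd sums for
   vertical and anterior–posterior, odd/even for mediolateral); and Pincus
   approximate entropy ApEn(m=2, r=0.2·SD).
5. **Model** — subject-level 70/10/20 train/validation/test split, XGBoost
   with Bayesian hyperparameter search against validation MAE, evaluation by
   `MAE = (1/n) Σ|ŷ−y|` (years) and `MAPE = (100/n) Σ|ŷ−y|/y` (%), and
   gain-based feature-importance scores (FIS) normalised to sum to 1.
   Three feature sets are compared: **OT** (TUG only), **OS** (6MWT only)
   and **AG** (all 132).

No public recordings exist for this protocol, so the package ships a
synthetic-cohort generator (`gaitage.synth`) that emulates the study design
— 136 subjects aged 60–90 (36/64/36 per decade, 33 M/103 F), three TUG
trials and one 6MWT each — from a harmonic-sum gait model with age-coupled
speed, cadence, asymmetry, smoothness and turn vigour, plus analytic ground
truth for every event and step.

## Worked example

```python
import gaitage as ga

spec = ga.CohortSpec(n_subjects=36, group_counts=(9, 18, 9), sex_counts=(9, 27),
                     sixmwt_duration_s=60.0)
table = ga.cohort_feature_table(spec, seed=7)
results = ga.compare_feature_sets(table, ga.SplitSpec(seed=7),
                                  ga.SearchSpec(n_trials=10, method="random"),
                                  seed=7)
for name, res in results.items():
    print(f"{name}: MAE {res.mae:.2f} y, MAPE {res.mape:.2f}%")
print("top-5 AG features:")
for feat, score in results["AG"].top_features(5):
    print(f"  {feat}: {score:.3f}")
```

prints

```
OT: MAE 2.29 y, MAPE 3.07%
OS: MAE 1.54 y, MAPE 2.06%
AG: MAE 1.99 y, MAPE 2.66%
top-5 AG features:
  tug.gait.acc_vt.max: 0.498
  tug.sit_to_stand.acc_ml.max: 0.150
  tug.gait.pitch.min: 0.078
  tug.mid_turn.acc_vt.min: 0.065
  tug.gait.acc_ml.rms: 0.037
```

MAE is the mean absolute age error on the held-out test subjects in years;
MAPE is the same error as a percentage of true age. On this small synthetic
cohort every feature set predicts age far better than the no-skill baseline
(the age SD, ≈8 years), because the generator couples gait parameters to age
by construction; the FIS column shows which gait features the booster relied
on. A command-line interface mirrors the library
(`gaitage simulate / segment / extract / train`).

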