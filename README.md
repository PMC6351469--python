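# oculopost

Oculo-postural coupling analysis. The package turns two kinds of raw
recordings into a quantitative statement of how well eye-movement behaviour
predicts standing balance:

- **Postural scoring** (`oculopost.cop`) — irregularly sampled
  center-of-pressure trajectories are resampled to a uniform 25 Hz grid
  (sliding-window average with interpolation fallback), summarized in 1-s
  windows (path length, positional SD, mean speed), classified
  quiet/unquiet by a two-component Gaussian mixture fitted on the pooled
  cohort, and condensed into a 0–100 score
  `100 * ((1 - f_EO) + (1 - f_EC)) / 2` from the unquiet fractions of the
  eyes-open and eyes-closed conditions.
- **Oculomotor features** (`oculopost.gaze`) — an I-VT velocity-threshold
  classifier detects fixations and saccades; 18 biomarkers are computed
  (per-second ranges/SDs, velocities, 95 % confidence-ellipse area, and
  moment statistics of fixation/saccade durations).
- **Coupling model** (`oculopost.coupling`) — a hand-rolled bootstrap
  forest of regression trees provides out-of-bag permutation importance
  `Imp_i = mean(d_i) / sd(d_i)` per feature (five repeated runs; features
  whose lower quartile of Imp exceeds 0.1 are selected) and leave-one-out
  prediction of the postural score with range-normalized RMSE, reported
  with and without the largest residual.
- **Cohort statistics** (`oculopost.stats`) — exact rank-sum group
  comparison and Pearson correlation with an attention subscore.
- **Synthetic cohorts** (`oculopost.synthetic`) — a seeded generator in
  which a latent severity jointly drives gaze statistics (shorter
  fixations, wider scanning) and sway burstiness, planting a known
  gaze↔posture coupling plus a full truth table for testing. Setting
  `effect_scale = 0` yields a null cohort with gaze decoupled from
  severity.

## CLI

All stages are exposed as subcommands of `oculopost`:

```bash
oculopost simulate --out cohort/ --seed 1
oculopost score-posture --cop cohort/cop.csv --out scores.csv --seed 1
oculopost extract-gaze --gaze cohort/gaze.csv --out features.csv
oculopost select  --features features.csv --scores scores.csv \
                  --clinical cohort/truth.csv --out sel/ --seed 1
oculopost predict --features features.csv --scores scores.csv \
                  --clinical cohort/truth.csv --subset sel/selected.csv \
                  --out pred/ --seed 1
oculopost report  --scores scores.csv --clinical cohort/truth.csv --out rep/
```

or end-to-end from one YAML config (every parameter defaults to the
documented values; outputs are stamped with the config hash and rerun
byte-identically):

```bash
oculopost run-all --config config.yaml
```

A minimal config:

```yaml
simulate: {n_patients: 10, n_controls: 9, seed: 1}
out_dir: run
seed: 1
```

Modeling (importance, selection, leave-one-out prediction) is restricted
to the patient subgroup; the group comparison uses all subjects.

## CSV schemas

- gaze: `subject_id, t_s, gaze_x_deg, gaze_y_deg, valid`
- CoP: `subject_id, condition (EO|EC), t_s, cop_x_cm, cop_y_cm`
- clinical/truth: `subject_id, group (patient|control), attention_subscore, ...`

## Conventions worth knowing

- "Variance" features are reported as standard deviations (matching the
  published units); kurtosis is non-excess (normal = 3).
- `RatioRange = RangeX / RangeY`; undefined ratios (no saccades, zero
  vertical range) are NaN and median-imputed, with a log entry, before
  modeling.
- Per-second dynamic features use consecutive non-overlapping 1-s windows
  with the trailing partial window dropped.
- The "25 % quartile" in feature selection is the linear-interpolation
  quantile of the five per-run importance values; selection uses a strict
  `> 0.1` inequality.
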