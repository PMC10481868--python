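# gazeflow

Analysis pipeline for head-mounted eye-tracking studies that compare viewing
modes — e.g. stereoscopic 360° VR video against a flat 2D virtual screen —
during short perception–action tasks. It was built for within-subject designs
in which participants watch brief sport-action clips (here: single boxing
punches, ~3.6 s, 24 trials per condition) while gaze direction (90 Hz unit
vectors) and head orientation (quaternions) are logged, a SIM-TLX workload
questionnaire is completed after each condition, and mean heart rate is kept
as an exercise-intensity control.

It is aimed at sport-science and human-factors researchers who want the whole
chain — raw streams to inferential statistics — as tested, scriptable Python
instead of ad-hoc notebook code.

## What it computes

**Gaze events (adaptive I-VT).** Angular speed between consecutive gaze
directions d_i, d_{i+1} is

    v_i = arccos(d_i · d_{i+1}) / Δt_i   [deg/s]

A per-trial adaptive threshold is set at **5 × median(v)**. Maximal runs of
intervals above the threshold are *saccades* if they last ≤ 50 ms; runs at or
below it are *fixations* if they last > 100 ms; anything else is
unclassified. Tracker dropouts ≤ 75 ms are bridged at constant angular
velocity; longer gaps split the segmentation. Per trial the pipeline reports
the fixation/saccade counts (normalized to a 3600 ms reference duration),
the mean fixation duration, and the search rate (fixation count ÷ total
fixation duration).

**Head excursion.** Orientation quaternions are decomposed intrinsically as
yaw (vertical axis) → pitch (lateral) → roll (forward), unwrapped, and each
axis's excursion is the cumulative absolute angular path, normalized to the
reference duration:

    exc_axis = Σ_i |θ_{i+1} − θ_i| × (T_ref / T_trial)   [deg]

**Workload.** The ten SIM-TLX items (0–20 visual-analogue scales, including
sense of presence) are validated and summarized per condition; no composite
index is formed.

**Inference.** Every metric y is analyzed with a linear mixed model

    y_ij = β0 + β1·condition + β2·sex + β3·condition×sex + b_i + e_ij,
    b_i ~ N(0, τ²) (participant random intercept)

fit by REML, with Wald t tests on between-within denominator degrees of
freedom, 95% CIs, standardized betas (β ÷ SD(y); ≈0.2 small, ≈0.5 medium,
≈0.8 large) and Tukey post-hoc contrasts of estimated marginal means for
significant condition effects (α = 0.05).

**Synthetic studies.** `gazeflow.synthetic` generates complete studies —
raw gaze/head streams with ground-truth event lists and excursions, SIM-TLX
and heart-rate tables — whose condition means default to the reference
study's group values (fixation duration 457.5/365.8 ms, roll 39.9/55.7°,
pitch 41.8/71.2°, presence 7.8/15.1, no yaw effect), so every stage of the
pipeline can be validated against known truth without any data download.

## Worked example

```python
import gazeflow as gf

cfg = gf.GeneratorConfig()                      # default synthetic study
study = gf.generate_study(cfg, seed=1)          # 32 participants x 2 x 24 trials
metrics, events, detected = gf.compute_trial_tables(study)

print(metrics.groupby("condition")[["mean_fix_dur_ms", "roll_exc_deg", "pitch_exc_deg"]]
      .mean().round(1))

fit = gf.fit_lmm(metrics, gf.ModelSpec(response="mean_fix_dur_ms"))
est = fit.estimate("condition[3D360VR]")
print(f"condition effect: beta={est.beta:.1f} ms, "
      f"95% CI [{est.ci_low:.1f}, {est.ci_high:.1f}], p={est.p:.3g}, "
      f"std beta={est.std_beta:.2f} ({est.label})")

rep = gf.recovery_report(study, detected, metrics)
print(f"fixation F1={rep['fixation_f1']:.3f}, "
      f"duration bias={100*rep['fixation_duration_bias']:.1f}%")
```

prints

```
           mean_fix_dur_ms  roll_exc_deg  pitch_exc_deg
condition
2D                   459.8          40.2           42.1
3D360VR              369.6          55.5           72.3
condition effect: beta=-94.1 ms, 95% CI [-103.0, -85.3], p=4.26e-85, std beta=-0.94 (large)
fixation F1=1.000, duration bias=1.3%
```

Reading this: the event detector recovers per-condition mean fixation
durations within a few ms of the generating values (457.5 / 365.8 ms), the
mixed model finds the built-in ~90 ms shortening of fixations in the VR
condition with a large standardized effect, and against ground truth the
detector finds every fixation (F1 = 1.0) with a +1.3% duration bias from
sample-grid quantization at event boundaries.

The same chain is available from a shell:

```bash
gazeflow synth --seed 1 --out study/          # write a synthetic study
gazeflow run --synth --seed 1 --out results/  # full pipeline + summary.json
gazeflow events --gaze study/gaze.csv --manifest study/manifest.csv \
    --out-events events.csv --out-metrics gaze_metrics.csv
```

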