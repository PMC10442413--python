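# crowdeda

Electrodermal-activity (EDA) analysis for single-file crowd-walking
experiments: from raw 32 Hz skin-conductance recordings to study-level
statistics linking walking speed, crowd density and physiological arousal.

## The problem

In crowd experiments, participants walk behind each other at imposed speeds
or circulate on a closed oval whose occupant count sets the density. Wearable
sensors record palmar skin conductance (µS), whose sympathetically driven
changes index arousal. Turning those raw traces into defensible statistics
requires a chain of steps — filtering, artifact screening, tonic/phasic
decomposition, feature extraction, repeated-measures testing — each with
choices that are rarely reproducible from a methods section alone. `crowdeda`
implements that chain as a tested library, plus a seeded synthetic-cohort
generator with ground truth so every stage can be validated without access
to any original recordings.

## The model

Conductance is decomposed as `y = tonic + h*q + residual`, where the tonic
part (skin conductance level, SCL) lives on a coarse spline basis and the
phasic part is a sparse non-negative sudomotor driver `q` convolved with the
biexponential Bateman kernel `h(t) = gain·(e^{-t/τ_d} − e^{-t/τ_r})`
(τ_r = 0.7 s, τ_d = 2.0 s). The split solves the convex program

    min ‖y − h*q − Bc‖² + λ‖q‖₁ + µ‖D₂c‖²   s.t.  q ≥ 0

Per condition segment, four features are computed: mean SCL (µS), the count
of non-specific skin conductance responses (Ns.SCRs: phasic trough-to-peak
amplitudes > 0.01 µS), their mean amplitude, and EDASymp — signal power in
the sympathetic 0.045–0.25 Hz band after downsampling to 2 Hz (Welch PSD,
Blackman window). Conditions are compared with a Greenhouse–Geisser-corrected
repeated-measures ANOVA or the Friedman test (chosen by a Kolmogorov–Smirnov
normality screen), Bonferroni post-hoc paired t-tests, and moderation mixed
models with a random intercept per subject. Full details and every numerical
choice: [docs/methods.md](docs/methods.md).

## Worked example

```python
from crowdeda import PipelineConfig, run_pipeline, simulate_study
from crowdeda.design import design_table

# an oval-density cohort: 6 subjects x 8 occupancy conditions
cohort = simulate_study("study2", n_subjects=6, seed=42, fs=8.0,
                        duration_s=90.0)
config = PipelineConfig(fs=8.0, decompose_fs=2.0, baseline_label=None,
                        edasymp_nperseg=64)
result = run_pipeline(cohort.recordings, cohort.markers, config)

print(result.features[["subject_id", "label", "mean_scl",
                       "nsscr_count"]].head(3))
rep = result.reports["mean_scl"]
print(f"{rep.test}: F = {rep.statistic:.2f}, "
      f"df = ({rep.df1:.2f}, {rep.df2:.2f}), p = {rep.p:.4g}")
print(design_table().to_string(index=False))
```

prints

```
  subject_id label  mean_scl  nsscr_count
0       s001   n=4  2.108941            6
1       s001   n=8  2.205103            3
2       s001  n=16  2.724927            6
rm_anova_gg: F = 20.81, df = (1.37, 6.87), p = 0.001877
 n_persons  gross_space_m  net_space_m     hall_zone
         4           3.74         3.45    social_far
         8           1.87         1.58   social_near
        16           0.94         0.65 personal_near
        20           0.75         0.46 personal_near
        24           0.62         0.33  intimate_far
        32           0.47         0.18  intimate_far
        36           0.42         0.13 intimate_near
        40           0.37         0.08 intimate_near
```

The feature table holds one row per subject × condition (mean SCL rises
with density because the generator plants a monotone arousal gradient);
the omnibus test detects that gradient; the design table gives each
occupancy's per-person space on the 14.97 m oval, gross and net of a
28.8 cm body depth, with its Hall proxemic zone.

Short narrative scripts, one per capability, live in [examples/](examples/).
A thin CLI wraps the same functions:

```bash
crowdeda simulate --study study2 --n-subjects 44 --seed 1 --out data/
crowdeda run --in data/ --out results/
crowdeda design-table
```

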