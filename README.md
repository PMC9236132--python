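# emodyn

EEG analysis of **emotion dynamics under cognitive load**. The package asks a
simple question of a multichannel EEG recording: *does emotional activity slow
down when cognitive load rises?* It answers it by

1. extracting band-power features with the **Hilbert–Huang transform** (EMD +
   Hilbert spectral analysis) and complexity features (approximate, sample,
   permutation and state-space-correlation entropy; wavelet-packet rhythm
   energies and wavelet entropy) from 5-s windows of the emotion-related
   channels (Fp1, F7, T7, Cz, T8, P8, O2);
2. selecting the top-15 subject-independent features with **correlation-based
   feature selection (CFS)** and embedding them with **Isomap** into a
   zero-mean 1-D *emotion trajectory* per participant;
3. quantifying the trajectory's fluctuation with a **zero-crossing-rate
   statistic**: ZCR_EC = Σₙ [Xₙ(k) − Xₙ₋₁(k)]², where Xₙ(k) binarizes the
   order-k binomial high-pass of the trajectory (k = 1 is the plain
   zero-crossing count);
4. indexing cognitive load with the engagement ratio
   **CLI = β̄ / (θ̄ + ᾱ)** over load-sensitive channel subsets; and
5. fitting **ZCR_EC = α·CLI + β** by least squares across participants.
   A negative slope α means emotional activity is slower under higher load.

Because real classroom recordings are not bundled, a first-class
`synthetic_data` module generates two-condition cohorts (a high-load
"grayscale" arm and a low-load "color" arm, 19 participants each by default)
with known ground truth: per-condition rhythm power gains (hence a known CLI
ordering) and a smooth latent emotion state whose zero-crossing rate is set by
Rice's formula (hence a known fluctuation-rate ordering). Every stage of the
pipeline is testable against what the generator built in.

## Worked example

```bash
cat > demo.yaml <<EOF
cohort:
  n_per_condition: 3
  duration: 60.0
  seed: 42
EOF
emodyn run-all --config demo.yaml --out demo_run
```

prints

```
trajectory ZCR_EC ~ CLI: alpha=-11.4409 beta=5.1134 se=10.0338 n=6
raw-signal ZCR ~ CLI: alpha=2464.0479
```

The trajectory slope is **negative**: participants with the larger
beta/(theta+alpha) engagement index (the synthetic high-load arm) have emotion
trajectories that cross zero less often — slower emotional dynamics. The
raw-signal slope is **positive**: higher load comes with relatively more beta
power, i.e. faster raw EEG oscillation. `demo_run/` also contains the
per-subject table (`subjects.csv`), the selected features, per-participant
trajectories, a per-feature one-way ANOVA report (F, p, partial η²), and a
manifest with the config hash — re-running the same config reproduces every
output bit-identically. At this toy size (n = 6) the slope's standard error is
large; the default cohort (n = 38) pins the sign down reliably.

The stages are also importable directly:

```python
from emodyn import (CohortConfig, PipelineConfig, generate_cohort,
                    analyze_cohort)

cfg = PipelineConfig(cohort=CohortConfig(n_per_condition=19, duration=60.0,
                                         seed=7))
recordings, truth = generate_cohort(cfg.cohort)
result = analyze_cohort(recordings, cfg)
print(result.fit_trajectory.alpha)   # < 0: slower emotion change at high load
```

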