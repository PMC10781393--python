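# stridesense

IMU stride analytics for running-fatigue detection, stamina scoring and
training-load control.

Wearable inertial measurement units (IMUs) record triaxial acceleration,
angular velocity and magnetic orientation at high rate (256 Hz in the public
labelled running datasets this package targets). After an exhaustive
incremental shuttle-run protocol, a runner's strides change in
characteristic ways: the median acceleration magnitude drops, its spread
widens, and sporadic outliers appear. `stridesense` turns those signatures
into quantitative monitoring tools for sport scientists and coaches:

1. **Preprocessing and stride segmentation** — zero-phase Butterworth
   low-pass filtering, linear detrending, z-normalization, and peak-driven
   segmentation of the acceleration composite magnitude
   ‖a‖ = √(ax² + ay² + az²) into fixed-length strides.
2. **Feature extraction** — per-stride time-domain statistics (mean, median,
   variance, RMS, min, max, IQR), power-spectral-density descriptors (total
   power, dominant frequency, spectral entropy, band powers), sample entropy
   SampEn(m, r), and the signal magnitude area
   SMA = (1/N)·Σₜ(|ax| + |ay| + |az|).
3. **Fatigue classification** — a scikit-learn-style estimator
   `FatigueClassifier` mapping feature vectors to a fatigue score
   Ŷ ∈ [0, 1], thresholded at τ (default 0.5); a benchmark harness sweeps 14
   classical model families with subject-wise cross-validation, plus an
   optional LSTM sequence model over raw stride tensors.
4. **Stamina scoring** — each stride's dynamic-time-warping (DTW) distance
   *d* to the athlete's own non-fatigued baseline template (pointwise median
   of NF strides) is normalized by a personal scale κ (95th percentile of
   the NF strides' own distances) and mapped to
   **Z = clip(1 − d/κ, 0, 1)**, then banded into low / medium / high
   endurance categories.
5. **Bias control** — the mean signed deviation B of predictions from truth
   is estimated, subtracted, localized to the features most correlated with
   the residual, and iteratively driven below a threshold ε.
6. **Training-load control** — a bounded proportional controller with
   learning rate α adjusts session intensity and duration to hold an
   observed fatigue indicator at a setpoint, exercised in closed loop
   against a simulated first-order athlete plant
   (Fat′ = ρ·Fat + β·i·d + noise).

A seeded synthetic-cohort generator reproduces the fatigue signatures above
with controllable effect sizes (amplitude attenuation δ, variance inflation
γ, outlier rate), so every stage is testable end to end without downloading
data. Readers for the public stride-dataset layout (CSV with a configurable
column dialect) are included for work with real recordings.

## Worked example

```python
import numpy as np
from stridesense import (SyntheticConfig, generate_cohort,
                         benchmark_classifiers, stamina_series)

cfg = SyntheticConfig(n_participants=3, strides_per_condition=15,
                      amplitude_attenuation=0.3, seed=42)
cohort = generate_cohort(cfg)
print(f"cohort: {len(cohort)} strides, "
      f"{cohort.labels.sum()} fatigued / {len(cohort) - cohort.labels.sum()} non-fatigued")

table = benchmark_classifiers(cohort, families=("extra_trees", "logistic",
                                                "dummy_all_positive"))
print(table.round(3).to_string(index=False))

estimates, summary = stamina_series(cohort, "P01")
z_f = np.mean([e.Z for e in estimates if e.label == 1])
z_nf = np.mean([e.Z for e in estimates if e.label == 0])
print(f"P01 stamina: mean Z fatigued {z_f:.3f}, non-fatigued {z_nf:.3f}")
```

prints

```
cohort: 90 strides, 45 fatigued / 45 non-fatigued
        classifier  accuracy  precision  recall    f1
       extra_trees       1.0        1.0     1.0 1.000
          logistic       1.0        1.0     1.0 1.000
dummy_all_positive       0.5        0.5     1.0 0.667
P01 stamina: mean Z fatigued 0.000, non-fatigued 0.128
```

At a 30% fatigue amplitude attenuation the learned classifiers separate the
conditions perfectly on this small synthetic cohort, while the all-positive
baseline shows the characteristic identity precision = accuracy = positive
prevalence with recall 1 — the floor against which benchmark tables should
be read. The stamina score Z of fatigued strides collapses toward 0 (far
from the non-fatigued baseline template), while non-fatigued strides spread
over small positive values because κ is calibrated from their own distance
distribution.

The same pipeline is available from the shell:

```sh
stridesense simulate  --config cfg.yaml --out out/sim
stridesense benchmark out/sim/strides.csv --out out/bench
stridesense stamina   out/sim/strides.csv --out out/stamina
stridesense controlsim --config cfg.yaml --out out/ctl
```

Commands exit 0 on success, 2 on configuration errors, 3 on data/format
errors and 4 on reported non-convergence; artifacts carry no timestamps, so
re-running with the same config and seed reproduces them byte for byte.

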