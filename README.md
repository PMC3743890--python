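# dixonquant

Quantitative muscle-MRI fat-fraction analysis for slowly progressive
neuromuscular disease.

In muscular dystrophies such as limb-girdle muscular dystrophy type 2I
(LGMD2I), muscle is gradually replaced by fat. Radiologists traditionally
grade this on T1-weighted images with a 6-point ordinal scale (0, 1, 2a,
2b, 3, 4 — the Mercuri scale), but ordinal grading is subjective and too
coarse to detect change over a year. The chemical-shift (Dixon) technique
instead measures a continuous **fat fraction** per voxel,

```
FF = 100 · F / (W + F)   [%]
```

where W and F are the water and fat signal amplitudes separated from
multi-echo gradient-echo images after correcting the B0 off-resonance field
ψ. `dixonquant` implements this pipeline end to end, with synthetic ground
truth at every stage so each step is verifiable:

- **`dixonquant.phantom`** — 2D axial leg phantoms (14 named muscle
  compartments of known fat fraction, smooth polynomial B0 field, complex
  Gaussian noise) rendered through the single-peak signal model
  `S(TE) = (W + F·e^{i2πΔf·TE})·e^{i(2πψ·TE + φ0)} + ε`.
- **`dixonquant.recon`** — field-map estimation (like-phase echo pair,
  spatial phase unwrapping, smooth-surface prior, Gauss–Newton refinement)
  and least-squares water–fat separation at arbitrary echo times, plus the
  classical two-point in/opposed-phase path. `DixonModel(image).fit()`
  returns a `DixonResults` with FF, water, fat and field maps.
- **`dixonquant.roi`** — per-muscle ROI quantification with boundary
  erosion against partial-volume effects.
- **`dixonquant.cohort` / `dixonquant.grading`** — paired 32-subject
  baseline/12-month cohorts with per-muscle progression effects, an ordinal
  grader observation model (thresholds at 30% and 60% affected volume, with
  mid-scale observer confusion) and functional tests (six-minute walk with
  learning effect; timed tests that can become infinite).
- **`dixonquant.stats`** — Wilcoxon signed-rank testing (exact enumeration
  for small samples, tie/continuity-corrected normal approximation
  otherwise), Shapiro–Wilk screening, Bland–Altman reliability
  (RC = 1.96·SD of paired differences), grade agreement, Spearman change
  correlations, Holm adjustment, and a Monte-Carlo power comparison of
  continuous vs ordinal vs functional endpoints.
  `LongitudinalModel(table).fit()` returns per-muscle result tables with a
  `summary()`.

## Worked example

```python
import numpy as np
from dixonquant import (DixonModel, ROISet, leg_phantom_spec,
                        measure_all, render_multiecho)

echo_times = [3.45e-3, 4.6e-3, 5.75e-3]          # seconds, 3 T protocol
field = np.array([[10.0, 60.0], [25.0, 0.0]])    # smooth B0 field (Hz)
spec = leg_phantom_spec(field_coeffs=field, noise_sd=2.0, seed=1)
image, truth = render_multiecho(spec, echo_times)

result = DixonModel(image, method="3pt").fit()
print(result.summary())

rois = ROISet.from_label_image(truth.label, truth.names)
for m in measure_all(result.fat_fraction, rois)[:3]:
    print(f"{m.muscle}: {m.ff:.1f}% over {m.n_voxels} voxels")
```

prints

```
Dixon water-fat separation
==========================
method:            3pt
echo times (ms):   3.450, 4.600, 5.750
fat frequency:     434.3 Hz
signal floor:      5.264
valid voxels:      1727 / 9216
FF median (valid): 25.40 %
FF range (valid):  2.95 - 87.09 %
field range:       -45.0 to 63.9 Hz
residual RMS:      1.202
BFLH: 71.5% over 60 voxels
ST: 55.6% over 63 voxels
SM: 49.0% over 63 voxels
```

The biceps femoris long head (BFLH) was simulated at 71.6% fat and is
recovered at 71.5% despite noise (SNR 50) and a B0 field spanning ~110 Hz —
the per-muscle error stays below one FF point, well inside the
inter-observer repeatability of manual ROI analysis.

## Command line

```bash
dixonquant simulate-phantom --seed 1 --noise-sd 2 --out-dir out/phantom
dixonquant reconstruct --sidecar out/phantom/multiecho.json --method 3pt --out-dir out/recon
dixonquant roi-stats --ff out/recon/ff.nii.gz --roi out/phantom/labels --out out/meas.csv
dixonquant simulate-cohort --n 32 --seed 1 --out out/cohort.csv
dixonquant longitudinal-stats --cohort out/cohort.csv --out-dir out/stats
dixonquant power-sim --reps 1000 --seed 7 --out out/power.csv
dixonquant run-all --seed 1 --out-dir out       # full chain
```

Exit codes: 0 success, 2 missing input, 3 schema-version mismatch, 4 stage
failure. Every stage writes a provenance JSON (input checksums, parameters,
seed, software version); re-running with the same config and seed
reproduces numerically identical outputs.

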