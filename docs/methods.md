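# Methods

## Signal model and its assumptions

Each voxel is modelled as a two-component (water/fat) magnetisation with a
single spectral fat peak at 3.4 ppm:

```
S(TE_n) = (W + F · e^{i 2π Δf TE_n}) · e^{i (2π ψ TE_n + φ0)} + ε_n
```

- `W, F ≥ 0` — water and fat amplitudes (arbitrary, equal units);
- `Δf` — fat–water chemical-shift frequency, `42.576 MHz/T · B0 · 3.4 ppm`
  (≈ 434.3 Hz at 3.0 T). The 1.15 ms echo spacing of the default 3 T
  protocol (TE = 3.45/4.6/5.75 ms) corresponds to 1/(2·1.15 ms) = 434.8 Hz,
  i.e. consecutive echoes alternate opposed/in/opposed phase;
- `ψ` — B0 off-resonance (Hz), spatially smooth;
- `φ0` — echo-time-independent initial phase;
- `ε_n` — complex Gaussian noise, iid per channel and echo.

Deliberately **not** modelled: multi-peak fat spectra, T2*/R2* decay,
eddy-current phase, coil sensitivities, k-space effects, T1 weighting.
The fat fraction is therefore a proton-density-style magnitude ratio
`FF = 100·F/(W+F)`; with a single peak and no decay the model inversion is
exact on noiseless data, which is what makes the phantom round-trip a
meaningful oracle.

## Field-map estimation

1. **Like-phase pair.** Among all echo pairs, the one whose fat phase
   advance is closest to a whole number of cycles is selected (echoes 1 and
   3 of the default protocol). For such a pair the water–fat interference
   cancels in `S_j·conj(S_i)` and its phase is `2π ψ ΔT` exactly. If no
   pair is within 0.05 cycles (two-echo in/opposed data), the phase is
   doubled to cancel the sign of `(W−F)`, at the cost of halving the
   unambiguous range.
2. **Unwrapping and anchoring.** The phase-difference image is spatially
   unwrapped (quality-sorted algorithm of scikit-image, masked to voxels
   above the signal floor). The arbitrary global period offset — which
   includes the water/fat swap ambiguity `ψ → ψ + Δf` — is fixed by scoring
   candidate offsets with the model residual on the brightest 5% of voxels
   and breaking ties toward the smallest magnitude-weighted |ψ|. This
   encodes the assumption that the true field lies within half the
   ambiguity period `1/(2 ΔT)`; phantoms violating it are flagged at render
   time.
3. **Smooth-surface prior.** Voxels with FF near 50% have no opposed-phase
   signal, so their phase difference is pure noise. Voxels whose
   phase-difference magnitude falls below 10% of the cohort-weighted mean
   are re-initialised from a weighted degree-3 polynomial surface fitted to
   the reliable voxels — shim fields are smooth at this scale, and the
   phantom's polynomial fields are represented exactly.
4. **Gauss–Newton refinement** (≥ 3 echoes). Per-voxel iterations on the
   full nonlinear model (unknowns: real field increment plus complex water
   and fat amplitudes; 2·n_echoes real equations), initialised from the
   unwrapped estimate and constrained to stay within a quarter period of
   it. Ill-identified voxels (the FF ≈ 50% set above) keep the surface
   value. Four iterations reach machine precision on noiseless data.

## Water–fat separation

Given ψ, each voxel's demodulated signals are solved by linear least
squares against the columns `[1, e^{i2πΔf TE_n}]`; `W` and `F` are the
magnitudes of the complex solutions (φ0 is absorbed, so no phase
calibration is needed). A collinear echo configuration (fat phase advancing
whole cycles between all echoes) raises a diagnostic naming the echo times.
The classical two-point path computes `W = (IP + OP_signed)/2`,
`F = (IP − OP_signed)/2` after removing the field phase estimated from the
doubled inter-echo phase difference, unwrapped and Gaussian-smoothed
(default σ = 2 voxels).

Numerical conventions: voxels with `W+F` below the signal floor (default
5× the background noise SD, estimated from the lowest-magnitude decile per
echo and channel) are marked invalid and excluded from ROI statistics —
never reported as FF = 0, which would bias ROI means downward. Valid FF is
clipped-free by construction (magnitudes are nonnegative). A measured,
seed-fixed regression test bounds the magnitude-rectification bias at the
FF extremes: at SNR 50 the per-compartment bias at true FF 0 or 100 stays
below 2 points (measured ≈ 1.5).

## ROI quantification

Masks live on the acquisition grid (no resampling); polygons rasterise by
centre-of-voxel inclusion. Boundary partial-volume contamination is
handled by explicit morphological erosion (3×3 structuring element,
default margin 1 voxel); erosion that empties a mask raises an error
carrying the muscle name rather than silently dropping the muscle. The
per-muscle summary is the **mean** FF over valid masked voxels — the
conventional MRI summary — with median available since the within-ROI
statistic used in comparable studies is not standardised. Visit pairing
keeps only (subject, muscle) pairs complete at both visits, logging the
exclusions (completers-only analysis).

## Ordinal grading model

Grading operates on the *affected volume fraction* `a ∈ [0,1]`:

- from an image: the fraction of compartment voxels with FF above a
  visibility threshold (default 20%), a proxy for what reads as fatty
  change on T1-weighted images (which are not simulated);
- from a summary FF: `a = FF / 70`, clipped to [0,1] — affected tissue is
  assumed to average ~70% fat, so a muscle at 31% FF is about 45% affected
  by volume.

Thresholds (0.03, 0.10, **0.30**, 0.60, 0.85) separate grades
0/1/2a/2b/3/4; the 0.30 and 0.60 cuts are the published volume bounds of
grades 2a (<30%) and 2b (30–60%), the others are modelling choices for
bands the scale defines only by appearance. Observer noise misreports to an
adjacent grade with per-grade probabilities (0.06, 0.18, 0.26, 0.36, 0.26,
0.10) — heaviest at 2b, chosen so that two independent simulated observers
reproduce the qualitative reliability pattern of the scale: highest
agreement at the extremes, lowest at 2b. With the confusion disabled the
mapping is deterministic and monotone.

## Cohort generator

The generator emulates the measurement structure of a 32-subject paired
natural-history study of 14 leg muscles:

- **Baseline FF** per muscle: Beta distribution on [0, 100] parameterised
  by its exact median (solved numerically at fixed concentration, default
  2.0 → wide, right-skewed at low medians). Default medians are the
  published per-muscle values (BFLH 71.6% … TA 5.5%). The true
  distributional form of patient FF is unknown (only its non-normality is
  established); the bounded right-skewed Beta is a flagged modelling
  choice.
- **Progression**: per-subject normal effect with given median (% points;
  defaults are the published per-muscle 12-month median changes, −1.1 to
  +5.3) and between-subject SD (default 2.0). Truth is clipped to [0, 100].
- **Measurement noise**: additive normal, default SD 3.0 points, clipped to
  [0, 100]. This is deliberately larger than the pure inter-observer
  reading SD (≈ 0.73 points, RC 1.43%): longitudinal re-measurement adds
  repositioning and ROI re-drawing variability.
- **Functional tests**: normal baseline, additive follow-up drift (a
  learning effect for the six-minute walk, default +20 m), test-retest
  noise, and for timed tests a per-subject probability (default 6%) of
  becoming unable to perform — recorded as +∞ and handled by rank, never
  as a float.

All randomness flows from a single integer seed through one
`numpy.random.Generator`; identical spec + seed gives bit-identical
tables. What the generator does **not** emulate: site/scanner effects,
within-muscle spatial progression gradients, correlated progression across
muscles within a subject, drop-out mechanisms, or T1-weighted image
appearance. Passing tests therefore validate the pipeline's statistical
machinery under a known clean generative model, not the clinical
distributions themselves.

## Statistical layer

- **Wilcoxon signed-rank** (authored here; scipy is used only as an
  independent cross-check in tests): zero differences dropped and counted
  (not Pratt's method), midranks for ties. Exact two-sided p —
  `min(1, 2·min(P(W⁺≤w), P(W⁺≥w)))` — by subset-sum recursion for tie-free
  n ≤ 25, by direct 2ⁿ enumeration for tied n ≤ 14; otherwise normal
  approximation with tie correction and continuity correction. The n = 32
  cohort exercises the approximation path; the bound keeps both paths
  testable. Infinite values participate through ranks (∞−∞ counts as a
  zero difference).
- **Shapiro–Wilk** (scipy) as a reporting gate for median summaries only.
- **Bland–Altman**: bias = mean(A−B), RC = 1.96·SD(A−B) with n−1
  denominator, limits = bias ± RC.
- **Spearman change correlation**: exact permutation p for n ≤ 9, else
  asymptotic (the choice of Spearman is a design decision; the comparable
  analyses do not name a method).
- **Multiplicity**: per-muscle p-values are reported uncorrected at
  α = 0.05, matching standard practice in these studies; a Holm-adjusted
  column is additionally emitted and labelled as an extension.
- **Power comparison**: Monte-Carlo rejection rates of the paired Wilcoxon
  at α for (i) observed continuous FF, (ii) ordinal grade ranks, (iii)
  functional tests, under a shared latent cohort. Binomial Monte-Carlo
  standard errors are reported. Because the ordinal endpoint is a
  deterministic coarsening of the same latent change plus independent
  observer noise, its power cannot exceed the continuous endpoint's; the
  type-I rate of the grade endpoint sits *below* nominal α (discrete test
  with heavy ties and zeros — conservatism, not miscalibration).

## Problem sizes

Default grids are 96×96 single-slice phantoms (a single axial level is
analysed, matching how such studies acquire at one anatomical level per
region; 3D stacks are out of scope). Acceptance computations use 1000
replications for type-I calibration and 400 for power (binomial SE ≤
0.025), 220 cases for the exact-test sweep, n = 448 muscle pairs for the
reliability recovery and 30 000 draws for the agreement profile.

## Known limitations

- Single-peak fat model: real fat spectra are multi-peak; absolute FF on
  real scanner data would carry a few-percent model bias.
- No T2*/R2* correction: FF at very low signal or short-T2* tissue would
  be biased on real data.
- The FF→affected-volume mapping for cohort-level grading is a one-
  parameter proxy; real T1w reading depends on spatial pattern, not just
  volume.
- The field-map surface prior assumes a smooth (≈ polynomial) shim field;
  localised susceptibility gradients (metal, air interfaces) would defeat
  it.
- Two-point separation assumes near-exact in/opposed echo timing
  (tolerance 0.1 cycles) and does not correct the residual fat phase.
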