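# Methods

This note documents the models, the synthetic-data calibration, and the
numerical choices behind `dyssync`, in the order the pipeline runs them.

## Kinetic model and MBF estimation

**Model.** Regional ¹³N-NH₃ kinetics follow an irreversible two-tissue
compartment model: exchange K₁ (ml/g/min) and k₂ (1/min) between arterial
blood and a free tissue compartment, and irreversible trapping k₃ (1/min)
into a metabolized compartment.  The tissue curve is the convolution of the
metabolite-corrected arterial input with

    h(t) = K₁ · [k₃ + k₂·e^(−(k₂+k₃)t)] / (k₂+k₃),

with the analytic limit h = K₁ when k₂+k₃ = 0.  A single blood-spill
fraction V_b per region models spillover and partial-volume mixing:
C_meas = (1−V_b)·C_t + V_b·C_wb.  The geometric partial-volume recovery of
dedicated reconstruction-aware methods is approximated by the (1−V_b)
tissue scaling; no recovery coefficients are assumed.  MBF is reported as
K₁ (unity extraction at resting flow); an extraction-correction hook is
available on `fit_region` but off by default, since resting extraction of
ammonia is near unity and any correction model would be an extra assumption.

**Metabolite correction.** ¹³N metabolites contaminate whole blood from
about 2 minutes post-injection.  The input function carries a per-time
metabolite fraction m(t); the true arterial curve is C_wb·(1−m).  The
default m(t) is 0 before 120 s, rises linearly to 0.5 at 600 s, then stays
flat.  The functional form of published correction methods is not
reproduced here; this piecewise-linear model is a declared substitute with
the correct onset behaviour, and is configurable.

**Fitting.** Weighted least squares over (K₁, k₂, k₃, V_b) with bounds
K₁∈[0,5], k₂,k₃∈[0,2], V_b∈[0,0.8], from 5 fixed starting points
(deterministic multi-start; ties break to the lowest weighted SSE, then the
lowest K₁).  Weights are the frame durations by default — the conventional
choice when the weighting law is unspecified — with duration/activity
weighting available.  Only frames ending within the first 10 minutes enter
the fit (19 of the 22 frames of the default schedule: 12×10 s, 4×30 s,
3×120 s, 180 s, 420 s, 600 s); later frames are ignored entirely.

**Numerics.** The convolution runs on a fixed 0.5 s grid.  The exponential
kernel is applied by the exact-decay trapezoid recursion
E_n = a·E_{n−1} + Δt/2·(x_n + a·x_{n−1}), a = e^(−λΔt), implemented as a
linear filter (O(N) per evaluation); the cumulative integral term uses
trapezoid quadrature.  Tests verify agreement with a dense O(N²) trapezoid
convolution.  Frame averages are trapezoid means over the grid points of
each frame; frame boundaries must align with the grid.  All of this is
deterministic, so identical inputs give bit-identical fits.

## FDG regionalization

Wall assignment on the AHA 17-segment bullseye: septal {2,3,8,9,14}
(anteroseptal + inferoseptal), lateral {5,6,11,12,16} (inferolateral +
anterolateral), anterior {1,7,13}, inferior {4,10,15}, apex (17) excluded.
Wall SUVmean is the unweighted mean of the assigned segments (no
segment-area weighting), and FDG SLR = septal mean / lateral mean.  The
mapping is replaceable via `WallRegions` for studies using a custom angular
split.

## Myocardial work

**Pressure.** A normalized piecewise-cosine reference waveform (shipped as
`data/pressure_template.json`) is time-warped so its landmarks coincide
with the patient's valve events (MVC, AVO, AVC, MVO) and amplitude-scaled
so its maximum equals the brachial systolic pressure.  Landmark values:
diastolic plateau 5 mmHg; the isovolumic rise reaches 0.65 of peak at AVO;
the ejection dome peaks at 40% of the AVO–AVC interval; ejection ends at
0.45 of peak at AVC; the isovolumic fall returns to the plateau at MVO.
The published empirical waveform this stands in for is not reproduced in
print; the template is replaceable via `PressureTemplate`.

**Stress and work.** Spherical Laplace stress σ = P/(2·c·h) with mid-wall
curvature c (radius = 1/c) and thickness h (a cylindrical variant,
σ = P/(c·h), is available).  Segmental work per volume is the signed
shoelace area of the (ε, σ) loop with strain in percent on the abscissa,
sign fixed so that shortening under high stress is positive and systolic
stretching gives negative (wasted) work; the area is invariant under cyclic
shifts of the starting sample, and loops must close to 1e-6 relative.  On
the default 501-sample cycle grid the polygon area of a smooth loop is
accurate to ~3·10⁻⁵ relative.

**Aggregation.** 18-segment model, 6 walls × 3 levels.  Regional work per
wall is the mean of its basal/mid/apical segments; the septum is the mean
of the anteroseptal and inferoseptal wall averages (equivalently the mean
of all six septal segments, as both walls carry three levels), unless a
single "septal" wall is supplied, and likewise for the lateral wall.
`wasted_septal` flags negative septal regional work.

## Synthetic cohort generator

The generator defines the study conditions; all defaults are the published
group statistics and are listed in `CohortConfig`.

* **Group sizes** 23 with / 7 without mechanical dyssynchrony (the FDG
  subset protocols use 21/6).
* **Wall values.** MBF and the work of each principal wall, and the lateral
  FDG SUV, are truncated-normal draws (non-positive values redrawn; lower
  bounds 0.1 ml/g/min, 0.1 SUV; ΔESV untruncated).  The truncation shifts
  the distribution mean by <2% for every configured parameter set; tests
  compare empirical means against the exact truncated-normal mean.
* **Septal FDG = SLR × lateral**, with both factors drawn, so the printed
  wall means and the printed SLR means hold jointly.  The anterior and
  inferior walls (no published values) sit at the septal–lateral midpoint
  plus jitter.  Per-segment values spread around the wall value with
  re-centered jitter, so wall means — and hence SLRs — survive the
  17-segment round trip exactly.
* **Septal work in the dyssynchrony group** is a two-component mixture: a
  negative half-normal (scale 500 mmHg·%) with weight 0.40 — the published
  prevalence of wasted septal work — plus a positive truncated normal whose
  (mean, SD) are solved numerically so the mixture matches 370 ± 816
  mmHg·%.  A single normal cannot satisfy the mean, the SD and the 40%
  negative fraction at once (it gives ≈33%).  Calibration failure (targets
  jointly unreachable) raises `CalibrationError`.
* **ΔLV ESV** is generated per group as mean + β·(SLR − SLR-mean) + noise.
  The common slope β is solved in closed form from the target pooled
  Pearson correlation (−0.62) and the configured group moments: the 23:7
  separation between groups already contributes most of the correlation,
  and β supplies the remainder; the within-group residual SD is then chosen
  so the group SDs stay at their printed values (47 ± 14% vs −3 ± 20%).  A
  negative implied residual variance raises `CalibrationError`.
* **TACs** are the exact forward two-tissue model (K₁ = the wall's true
  MBF; defaults k₂ = 0.25/min, k₃ = 0.12/min, spill 0.35 septal / 0.25
  elsewhere — physiologic resting ranges, config-exposed), frame-averaged,
  plus zero-mean Gaussian noise with variance ∝ activity/frame-duration
  (scale 1.0 by default; 0 reproduces the analytic model).  The arterial
  input is a peak-normalized gamma-variate bolus A·(t−t₀)^α·e^(−(t−t₀)/β)
  (α = 2, β = 12 s, t₀ = 10 s, peak 100 kBq/ml), and whole blood is the
  true arterial curve divided by (1−m(t)), so metabolite correction
  recovers the truth exactly.
* **Work traces** realize each segment's prescribed work as a stress–strain
  ellipse of known signed area (strain half-amplitude 10%, stress offset
  ≥100 mmHg), swept once per cycle; thickness is constant (10 mm) and
  curvature is obtained by inverting the Laplace relation against the
  patient's estimated pressure curve.  Downstream stress reconstruction is
  therefore exact, and loop integration recovers the prescription to the
  polygon-area error (≪0.5% on the 501-sample grid).  Works whose ellipse
  would need stress beyond 2000 mmHg are rejected.
* **Readers** observe the true dyssynchrony flag and flip it independently
  with probability 0.035, giving an expected kappa ≈ 0.85 at 77%
  prevalence.  Systolic pressure and baseline ESV are truncated-normal
  (134 ± 21 / 120 ± 28 mmHg; 115 ± 35 ml); valve events default to
  MVC 0.05 s, AVO 0.10 s, AVC 0.42 s, MVO 0.50 s in a 1 s cycle.
* **Determinism.** One `SeedSequence` per cohort spawns an independent
  stream per patient; identical config+seed gives byte-identical files.

**What the generator does not emulate:** image-domain effects (no voxel
phantoms, reconstruction artifacts, motion, or attenuation errors),
inter-wall correlation structure beyond the midpoint construction,
between-modality within-patient correlations (MBF, FDG and work are drawn
independently given the group), and reader errors correlated between
readers.  Passing tests therefore demonstrate correct estimation given the
stated forward models — not robustness to the full physics of clinical
acquisitions.

## Statistics

Shapiro–Wilk (α = 0.05) gates mean ± SD vs median [IQR] summaries; constant
samples report mean ± 0.  Unpaired t tests pool variances (Student) to
match the conventional reading of "unpaired t test"; Welch is available by
flag.  Bonferroni family size defaults to 4 (the regional comparisons per
modality) and is caller-declared.  Cohen's kappa comes from the 2×2
agreement table with the asymptotic (Fleiss) standard error for its 95% CI;
κ is undefined (raises) when both raters are constant and identical.
Identical paired samples return t = 0, p = 1 by convention.  Standard
routines (scipy.stats, statsmodels) implement the tests; hand-formula
oracles in the test suite pin their conventions.

## Pipeline

Stages communicate only through files (cohort CSV/JSON → per-patient fit
JSON + `mbf.csv` → `fdg.csv` → `work.csv` → `metrics.csv` → `report.json`),
so any suffix of the chain can re-run on persisted intermediates.  The
report carries seed, config hash and package version.  Missing-modality
emulation (default: 3 patients without FDG, 1 without NH₃, 2 without
follow-up echo, chosen at random from a dedicated substream) reproduces a
realistic availability pattern; every statistic then carries its own n.
`replicate` repeats the full run across consecutive seeds and reports the
across-replicate mean and SD of every headline metric — cohort-level group
means at n = 23 are noisy, and replicate averaging is what the recovery
protocols in `dyssync.replication` (and `scripts/acceptance.py`) use:
20 replicates throughout, which puts the standard error of the
replicate-averaged group means at roughly 1/20 of the patient-level SD.

## Known limitations

* The compartment fit assumes the same forward model that generated the
  synthetic data; model-mismatch bias (real tracer kinetics, motion,
  residual metabolite error) is out of scope.
* The 4-parameter weighted-SSE surface has a curved valley: K₁ is well
  identified, but k₂/k₃/spill trade off at low SSE, which is why the
  grid-search oracle pins K₁ tightly and the remaining parameters only to
  the coarse-grid scale.
* The pressure template is a schematic stand-in with the correct landmark
  topology, not a digitized physiological waveform; work values scale
  linearly with its amplitude, so group contrasts are insensitive to its
  exact shape, but absolute segmental values depend on it.
* MBF SLR summaries are computed but not calibrated: the generator draws
  septal and lateral MBF independently, so the mean of per-patient flow
  ratios is only qualitatively (≈0.6–0.8) in the published range.
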