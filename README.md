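# dyssync

Regional cardiac PET and myocardial-work quantification for mechanical
dyssynchrony in CRT candidates.

## The problem

In non-ischemic heart-failure patients eligible for cardiac
resynchronization therapy (CRT), discoordinate left-ventricular contraction
("mechanical dyssynchrony", seen on echocardiography as septal flash and/or
apical rocking) redistributes regional workload: the early-activated septum
performs little or even negative (wasted) work, while the late-activated
lateral wall overworks.  Regional glucose metabolism (¹⁸F-FDG uptake) and
myocardial blood flow (MBF, from dynamic ¹³N-NH₃ PET) follow this workload
pattern.  The septal-to-lateral wall ratio (SLR) — mean septal value divided
by mean lateral value — condenses the asymmetry into one number: a low FDG
SLR tracks mechanical dyssynchrony and correlates inversely with volumetric
reverse remodeling after CRT (ΔLV ESV, the relative drop in end-systolic
volume).

This package implements the full quantification chain behind that analysis,
for methodologists who want a tested, reproducible reference implementation:

* **`nh3_kinetics`** — absolute MBF from framed regional time-activity
  curves via an irreversible two-tissue compartment model.  With arterial
  input C_a, free compartment C₁ and trapped compartment C₂:

      dC₁/dt = K₁·C_a − (k₂+k₃)·C₁,   dC₂/dt = k₃·C₁

  so tissue activity is the convolution of C_a with
  h(t) = K₁·[k₃ + k₂·e^(−(k₂+k₃)t)]/(k₂+k₃).  The measured curve mixes
  tissue with blood pool, C_meas = (1−V_b)·C_t + V_b·C_wb, and the four
  parameters (K₁, k₂, k₃, V_b) are estimated by weighted least squares on
  the frames inside the first 10 minutes, after metabolite correction of
  the whole-blood input.  MBF = K₁ (unity extraction at rest).
* **`fdg_regional`** — wall SUVmean and the FDG SLR from standard AHA
  17-segment polar maps (apex excluded; septal = segments 2, 3, 8, 9, 14;
  lateral = 5, 6, 11, 12, 16).
* **`myocardial_work`** — segmental work per volume as the signed area of
  the wall-stress vs. strain loop, W = −∮σ dε, with noninvasive LV pressure
  (a reference waveform warped to the valve events and scaled to systolic
  blood pressure) and spherical Laplace stress σ = P/(2·c·h) from mid-wall
  curvature c and thickness h.  Negative area = wasted work.
* **`cohort_stats`** — group summaries, paired/unpaired t tests with
  Bonferroni correction, Pearson/Spearman correlations, Cohen's kappa for
  reader agreement, and ΔLV ESV.
* **`synthetic_cohort`** — a seeded generator of synthetic cohorts whose
  regional distributions are calibrated to the published group statistics
  (23 patients with dyssynchrony, 7 without), so every stage is testable
  end to end without clinical data.
* **`pipeline` / `dyssync` CLI** — one reproducible run:
  simulate → fit-nh3 → fdg-regional → work → stats.

## Worked example

Generate a synthetic cohort and analyse one dyssynchrony patient:

```python
from dyssync import synthetic_cohort as sc, nh3_kinetics as nk
from dyssync import fdg_regional as fr, myocardial_work as mw

cohort = sc.generate_cohort(sc.CohortConfig(seed=1))
p = cohort.patients[3]                      # a dyssynchrony patient
fn = p.input_function
for wall in ("septal", "lateral"):
    fit = nk.fit_region(p.tacs[wall], fn.times, fn.whole_blood,
                        fn.metabolite_fraction)
    print(f"{wall}: MBF = {fit.mbf:.3f} ml/g/min")
print(fr.analyze_polar_map(p.polar_map))
print(mw.analyze_traces(p.traces).regional)
```

prints (seed 1, patient `P003`):

```
septal: MBF = 0.302 ml/g/min      # true simulated value 0.325
lateral: MBF = 1.157 ml/g/min     # true simulated value 1.157
FDG SUVmean septal = 7.75, lateral = 12.93, SLR = 0.60
work septal = 255 mmHg*%, lateral = 3731 mmHg*%, wasted = False
delta ESV = 51.1%
```

i.e. this patient shows the dyssynchrony signature: septal flow and FDG
uptake well below the lateral wall (FDG SLR 0.60), a near-zero septal
workload against a heavily loaded lateral wall, and strong reverse
remodeling after CRT.

The same chain runs from the shell:

```bash
dyssync run --seed 1 --out run/        # full pipeline, report in run/report.json
dyssync simulate --seed 1 --out run/   # cohort files only
dyssync fit-nh3 --tacs run/cohort/P003_tacs.csv --aif run/cohort/aif.csv --out P003_mbf.json
dyssync fdg-regional --map run/cohort/P003_polarmap.csv
dyssync work --traces run/cohort/P003_traces.csv --events run/cohort/P003_traces.json
dyssync replicate --seed 1 --n-replicates 20 --out reps/
```

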