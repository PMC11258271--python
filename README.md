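# cmrprecision

Precision analysis for cardiac MRI in large-animal infarction studies:
image-quality metrics, cardiac function, infarct-size quantification, and
the observer-agreement statistics that turn precision into sample-size
requirements — all exercised end to end on a digital left-ventricle phantom
with exact analytic ground truth.

The package is aimed at researchers quantifying porcine (or other
large-animal) myocardial infarction models with cine and late-gadolinium-
enhancement (LGE) MRI and ex vivo TTC staining, who need every step of the
post-processing chain to be testable without access to raw scans.

## What it computes

**Image quality** (`cmrprecision.quality`)

- Blood-tissue contrast `BTC = S_b / S_myo`, where the blood-pool mean is
  taken after removing, slice by slice, every blood-pool pixel within one
  standard deviation of the mean myocardial signal (papillary-muscle filter).
- Noise SD of an n-receiver magnitude image from a signal-free 50×50 region:
  `σ = sqrt( Σᵢ pixelᵢ² / (2·L·n) )`, with `L` region pixels and `n`
  receivers (default 16).
- Regional and pixelwise SNR: `SNR_myo = S_myo/σ`, `SNR_pixel = I(p)/σ`.
- Flip angle from ungated B1-map stacks via a maximum-intensity projection
  over the five central slices (robust to per-slice dropout), and the
  receive-pathway normalization `SNR_receive = SNR_myo · sin(FA_max)/sin(FA)`
  (a literal `SNR_myo / sin(FA/FA_max)` mode is available).
- The coil-distance weight `W_d = d·cos(offset)/d_max`.

**Cardiac function** (`cmrprecision.function`) — slice-summation volumes
(`V = Σ area·thickness`), ED/ES selection from the cavity-volume curve,
`EF = 100·(EDV−ESV)/EDV`, myocardial mass at 1.05 g/cm³, and *phase
harmonization*: re-evaluating observer B's volumes at observer A's ED/ES
phases to isolate pure segmentation variability.

**Infarct size** (`cmrprecision.scar`, `cmrprecision.ttc`) — manual labels
(hyper- plus hypointense), FWHM (`I ≥ 0.5·max(bright-scar ROI)`), nSD
(`I > mean + n·SD` of remote myocardium, n ∈ {3,5,7}), each as % of LV
myocardial volume and grams; TTC photograph planimetry with ruler
calibration, top/bottom-view totals, and the line-of-sight and
sawing-discontinuity diagnostics.

**Agreement statistics** (`cmrprecision.repro_stats`) —
`CoV = 100·SD(x₁−x₂)/mean`, within-subject pooled SD `sqrt(Σd²/2n)`,
ICC(A,k) (two-way random effects, absolute agreement, average measures),
Bland-Altman limits, and the paired-design sample size
`n = ceil( f(α,P)·σ²·2/δ² )` with `f = (z₁₋α/₂ + z_P)² ≈ 10.5` at α = 0.05,
P = 0.90.

**Phantom** (`cmrprecision.phantom`) — annular LV with cosine contraction
conserving myocardial cross-section (mass is phase-invariant by
construction), papillary muscles at myocardial intensity inside the blood
pool, an infarct wedge with exact analytic fraction, Rician noise, coil
sensitivity falloff, and TTC photographs with a calibrated ruler.

## Worked example

```python
import numpy as np
from cmrprecision import PhantomSpec
from cmrprecision.phantom import generate_cine_phantom
from cmrprecision.function import compute_function
from cmrprecision.repro_stats import sample_size

spec = PhantomSpec(n_slices=6, rows=128, cols=128, pixel_spacing=(0.8, 0.8),
                   n_phases=10, endo_radius_ed=18.0,
                   endo_radius_es=18.0 * np.sqrt(0.34),  # EF 66% by design
                   wall_thickness_ed=9.0)
_, truth = generate_cine_phantom(spec)
rep = compute_function([m["blood_pool"] for m in truth.label_masks],
                       [m["myocardium"] for m in truth.label_masks],
                       spec.pixel_spacing, spec.slice_thickness_mm)
print(f"true EF {truth.true_ef_pct:.1f}%  recovered {rep.ef_pct:.2f}%")
print(f"n per group at pooled SD 1.9, delta 3: {sample_size(1.9, 3.0).n}")
```

prints

```
true EF 66.0%  recovered 65.74%
n per group at pooled SD 1.9, delta 3: 9
```

The 0.26-point EF gap is pure boundary discretization at 0.8 mm pixels; the
sample size says that with an inter-observer pooled SD of 1.9 EF points, a
3-point EF change is detectable at 90% power and α = 0.05 with 9 subjects
per group (3 at pooled SD 1.0).

## Analysis scripts

The `analysis/` directory holds the numbered study drivers, each a thin
narrative over the library that writes its tables under `results/`:

1. `01_generate_phantom_cohort.py` — longitudinal cohort with ground truth
2. `02_image_quality.py` — BTC/SNR/W_d over a coil-distance series
3. `03_cardiac_function.py` — EF recovery, truth masks vs noisy auto-segmentation
4. `04_infarct_quantification.py` — manual/FWHM/nSD on PSIR and magnitude
5. `05_ttc_planimetry.py` — TTC calibration, views, discontinuity metrics
6. `06_reproducibility.py` — observer agreement, harmonization, sample sizes

Each takes an optional seed argument (`python analysis/06_reproducibility.py 1`).
A `cmrprecision` command-line interface exposes the same stages
(`cmrprecision run --seed 1 --out results/study`, `cmrprecision repro
samplesize --sigma 1.9 --delta 3`, ...).

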