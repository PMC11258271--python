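# Methods

This note documents the models, conventions and numerical choices behind
`cmrprecision`, and what the phantom-based validation does and does not
demonstrate about real data.

## The phantom

The left ventricle is modeled as a stack of annuli — per slice an
endocardial radius `r_endo` and an epicardial radius `r_epi` — optionally
tapered base to apex. This is deliberately not an anatomical mesh: every
downstream quantity must have a closed-form truth, which an annulus stack
provides exactly.

**Contraction.** The endocardial radius follows a cosine law over the
cardiac cycle, `r(p) = r_ES + (r_ED − r_ES)·(1 + cos(2πp/N))/2` for `N`
phases (default 30, the cine sampling of the emulated protocol), so phase 0
is end-diastole and phase N/2 end-systole. The epicardial radius is chosen
each phase as `r_epi = sqrt(r_endo² + A/π)` with `A` the end-diastolic
annulus area: myocardial cross-section is conserved exactly
(incompressibility), which makes mass a phase-invariant test quantity. For
a uniform cylinder `EF = 1 − (r_ES/r_ED)²`, so a 66% ejection fraction —
the healthy baseline of the emulated cohort — corresponds to
`r_ES = r_ED·sqrt(0.34)`.

**Labels and intensities.** Voxelization is by pixel-center distance from
the LV axis. Papillary muscles are discs inside the cavity rendered at
exactly the myocardial mean intensity but belonging to the blood-pool
contour — the worst case for the blood-pool filter and the convention
(papillary included in cavity volume, excluded from mass) used throughout.
Default intensities are arbitrary units: myocardium 100, blood 250,
background 0; LGE uses near-nulled remote myocardium (15), enhancing scar
(150) and an optional dark core (30).

**Infarct wedge.** The wedge is an angular sector of the annulus;
*transmurality is an area fraction*: the wedge's outer radius is
`sqrt(r_endo² + t·(r_epi² − r_endo²))`, so the analytic infarct fraction of
a uniform annulus is exactly `(angular span/360)·t`. A radial-thickness
definition would not have this property. The optional hypointense core is,
recursively, an area fraction of the wedge. A 120° wedge at `t = 0.6` gives
the 20% infarct used in the recovery checks.

**Noise.** Magnitude images get Rician noise: `v → sqrt((v+g₁)² + g₂²)`
with `g₁, g₂ ~ N(0, σ)` — Rayleigh in the background, approximately
Gaussian at high SNR. The underlying protocol does not state its noise
model; Rician is the standard choice for magnitude MRI and a pure-Gaussian
channel is available (`model="gaussian"`), which is also what the signed
PSIR reconstruction uses. All randomness flows from one spec seed through
`numpy.random.default_rng`.

**Coil.** Receive sensitivity is `exp(−d_nearest/λ)` with `d_nearest` the
distance to the closest coil element and decay length λ (default 90–120 mm):
smooth, positive, maximal at the elements, monotone in distance. This is a
phenomenological stand-in for a receive array — sufficient to produce the
negative SNR-distance relation the quality pipeline must detect, not a
field simulation.

**TTC photographs.** The LV is re-sliced at 5 mm (bench cutting thickness,
independent of the 6 mm MRI slices) and both faces of each slice are
rendered: "top" is the base-side face viewed base→apex, "bottom" the
apex-side face viewed apex→base (mirrored). Viable tissue renders red,
infarct white, background dark; a horizontal ruler with 1 mm ticks sits
below the tissue. An `apical_taper` parameter narrows the wedge's angular
span linearly with depth, producing a cone-shaped infarct whose two faces
of one slice differ by a known amount.

## Conventions and numerical choices

- Pixel indices are 0-based `(slice, row, col)`, cine phase is a trailing
  axis; mm positions refer to pixel centers with the origin at the first
  voxel's corner. Masks are per-slice 0/255 PNGs named
  `{label}_s{NN}_p{NN}.png`; stacks are NIfTI or TIFF+JSON-sidecar.
- Polygon fill uses boundary-inclusive pixel-center inclusion (both winding
  orientations handled).
- Blood-pool filtering is per slice; whole-stack `S_myo`/`S_b` are pooled
  over all in-mask pixels, not slice means of means.
- The noise ROI, when not supplied, is the 50×50 corner window with the
  lowest mean intensity. On a noiseless synthetic image the estimate is
  exactly zero and SNR is reported as NaN rather than rejected.
- The receive normalization divides by `sin(FA_norm)` with `FA_norm` a
  dimensionless ratio; the default `sine-ratio` mode reads this as
  `sin(FA_max)/sin(FA)` (signal ∝ sin FA for spoiled gradient echo,
  maximum-flip scan unchanged); the literal radians reading is kept behind
  `mode="literal"` and tagged in the report.
- The angulation correction multiplies the measured distance by
  `cos(offset)` (projection onto the transverse plane).
- FWHM labels `I ≥ 0.5·max(ROI)`; nSD labels `I > mean + n·SD(remote)`
  one-sided by default (hyperenhancement is the target), two-sided by flag;
  remote statistics are pooled per stack by default, per slice by flag.
  Semi-automatic methods do **not** include a hypointense core unless the
  morphological hole fill is enabled — on the core phantom, manual exceeds
  FWHM by design, documenting the known failure mode of intensity
  thresholding rather than silently correcting it.
- CoV uses the sample SD of paired differences over the grand mean of all
  2n values; pooled SD is the duplicate-measurement within-subject form
  `sqrt(Σd²/2n)` with `SD(d)/√2` available (`pooled_convention="sd-diff"`),
  since published one-line definitions rarely pin the convention down.
- ICC(A,k) is computed from two-way ANOVA mean squares,
  `(MSR − MSE)/(MSR + (MSC − MSE)/n)`; it matches pingouin's ICC(A,k) to
  machine precision in the tests.
- Sample size: `n = ceil(f·σ²·2/δ²)` with
  `f = (z₁₋α/₂ + z_P)² = 10.507` at α = 0.05, P = 0.90, computed from
  normal quantiles by default. With the tabulated `f = 10.5` (accepted via
  the `f` argument), `σ = δ` gives the round `n = 21`; the quantile default
  gives 22. Published integer examples (σ 1.9 → n 9; σ 1.0 → n 3) hold
  under either.
- EF is reported to one decimal; all comparisons use unrounded values.
  Slices are assumed contiguous (no gap/overlap).

## Simulated observers and phase harmonization

Observer variability is simulated as two independent components, matching
the two sources harmonization separates:

1. **Contouring:** each slice mask's boundary shifts by an offset drawn from
   `N(0, magnitude)` pixels on the signed distance transform referenced to
   the half-pixel surface. Magnitude 0 reproduces the mask exactly (CoV is
   then identically 0); sub-pixel magnitudes yield occasional one-pixel
   boundary changes. Because phases are perturbed independently, this
   over-disperses EF slightly relative to a human observer whose errors
   correlate across phases.
2. **Phase choice:** observer B evaluates ES a few phases away from A's
   choice. The cosine contraction law is flat at its extrema, so at
   30-phase sampling a 1-phase offset is numerically negligible; the
   acceptance demonstration uses a 3-phase offset, the regime where phase
   disagreement visibly dominates and harmonization recovers agreement
   (mean |ΔEF| drops from ≈5.5 to ≈1.2 points in the shipped cohort).
   Note that CoV, an SD-of-differences statistic, is insensitive to the
   *systematic* part of the phase offset — the mean absolute difference is
   the metric that harmonization provably shrinks.

## Problem sizes

Defaults were chosen so that discretization stays inside the stated
tolerances while everything runs comfortably on one core: function/recovery
phantoms at 128² × 6 slices × 10 phases and 0.8 mm pixels (EF discretization
error ≈ 0.3 points, well under the 1-point band), LGE at 160² and 0.6 mm
(voxel-counted infarct fraction within ~1% relative of analytic truth),
TTC photos at 720 px and 0.1 mm/px, agreement cohorts of 4–6 subjects at
30 phases. The full test suite runs in about a minute; the acceptance
script in seconds.

## What the phantom does and does not show

Passing on the phantom demonstrates that the *formulas and decision rules*
are implemented correctly against analytic truth: volume summation, the
noise estimator's scaling, threshold rules matching exhaustive per-voxel
scans, agreement statistics matching hand ANOVA, calibration and geometry
in the TTC chain. It does not demonstrate robustness to the things the
phantom lacks: trabeculation and valve-plane ambiguity, motion and banding
artifacts, B0/B1 inhomogeneity beyond a smooth sensitivity field, partial
voluming of oblique walls, contrast kinetics, or tissue shrinkage between
in vivo imaging and bench TTC (no shrinkage model is provided). Real-data
use should treat the auto color/threshold segmentations as conveniences for
simulation, not replacements for expert contouring.

## Known limitations

- The annular geometry cannot probe basal-slice inclusion rules; on real
  stacks the valve-plane convention can shift volumes by a slice.
- g-factor and noise-correlation effects of parallel imaging are out of
  scope; the noise estimator assumes the stated root-sum-of-squares model.
- The sawing-discontinuity metric's subtraction order (top of slice i+1
  minus bottom of slice i, over total infarct) is a convention; it is
  recorded in the output metadata and trivially negatable.
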