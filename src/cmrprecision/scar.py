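"""Infarct-size quantification from late-gadolinium-enhancement stacks.

Three routes to scar volume: manual labels (hyper- plus hypointense areas),
the full-width-at-half-maximum (FWHM) rule thresholding at half the peak
intensity of a reference ROI in the brightest scar, and the nSD rule
thresholding at n standard deviations above a remote (healthy) myocardium
ROI. Output is infarct fraction (% of LV myocardial volume) and infarct mass
in grams at a fixed tissue density; since density is constant, the volume
fraction and the mass fraction coincide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

MM3_PER_ML = 1000.0
DEFAULT_TISSUE_DENSITY = 1.05  # g/cm³


@dataclass
class ScarReport:
    method: str  # manual | FWHM | SD3 | SD5 | SD7
    source: str  # magnitude | PSIR
    infarct_fraction_pct: float
    infarct_mass_g: float
    per_slice_area_mm2: np.ndarray = field(default_factory=lambda: np.array([]))
    threshold: float = math.nan
    infarct_mask: np.ndarray | None = None


def _volumes(infarct_mask: np.ndarray, myo_mask: np.ndarray,
             pixel_spacing, slice_thickness_mm, density) -> tuple[float, float, np.ndarray]:
    px_area = pixel_spacing[0] * pixel_spacing[1]
    inf_vol_mm3 = infarct_mask.sum() * px_area * slice_thickness_mm
    myo_vol_mm3 = myo_mask.sum() * px_area * slice_thickness_mm
    if myo_vol_mm3 == 0:
        raise ValueError("myocardium mask is empty; infarct fraction undefined")
    fraction = 100.0 * inf_vol_mm3 / myo_vol_mm3
    mass = inf_vol_mm3 / MM3_PER_ML * density
    per_slice = infarct_mask.sum(axis=(1, 2)) * px_area
    return float(fraction), float(mass), per_slice


def manual_scar_size(myo_masks: np.ndarray, infarct_hyper: np.ndarray,
                     infarct_hypo: np.ndarray | None,
                     pixel_spacing: tuple[float, float], slice_thickness_mm: float,
                     density: float = DEFAULT_TISSUE_DENSITY,
                     source: str = "PSIR") -> ScarReport:
    """Infarct size from manual labels: hyperenhancement plus hypointense core."""
    myo = np.asarray(myo_masks, bool)
    infarct = np.asarray(infarct_hyper, bool)
    if infarct_hypo is not None:
        infarct = infarct | np.asarray(infarct_hypo, bool)
    outside = infarct & ~myo
    if outside.any():
        idx = np.argwhere(outside)[:5]
        raise ValueError(
            f"infarct labels extend outside myocardium at (slice,row,col) {idx.tolist()}"
            + (" ..." if outside.sum() > 5 else "")
        )
    frac, mass, per_slice = _volumes(infarct, myo, pixel_spacing, slice_thickness_mm, density)
    return ScarReport("manual", source, frac, mass, per_slice, infarct_mask=infarct)


def fwhm_scar(image: np.ndarray, myo_masks: np.ndarray, fwhm_roi: np.ndarray,
              pixel_spacing: tuple[float, float], slice_thickness_mm: float,
              density: float = DEFAULT_TISSUE_DENSITY, source: str = "PSIR",
              fill_hypo_core: bool = False) -> ScarReport:
    """FWHM scar: threshold at half the peak intensity of the bright-scar ROI.

    All myocardial voxels with I >= 0.5·max(ROI) are labeled infarct. A
    hypointense core inside the enhancing rim falls below the threshold and
    is *not* labeled unless ``fill_hypo_core`` enables the morphological
    hole fill (per-slice fill of regions enclosed by labeled voxels).
    """
    image = np.asarray(image, dtype=float)
    myo = np.asarray(myo_masks, bool)
    roi = np.asarray(fwhm_roi, bool)
    if not roi.any():
        raise ValueError("FWHM reference ROI is empty")
    if (roi & ~myo).any():
        raise ValueError("FWHM reference ROI must lie inside the myocardium")
    threshold = 0.5 * float(image[roi].max())
    infarct = myo & (image >= threshold)
    if fill_hypo_core:
        infarct = _fill_enclosed(infarct, myo)
    frac, mass, per_slice = _volumes(infarct, myo, pixel_spacing, slice_thickness_mm, density)
    return ScarReport("FWHM", source, frac, mass, per_slice, threshold, infarct)


def nsd_scar(image: np.ndarray, myo_masks: np.ndarray, remote_roi: np.ndarray,
             n_sd: float, pixel_spacing: tuple[float, float], slice_thickness_mm: float,
             density: float = DEFAULT_TISSUE_DENSITY, source: str = "PSIR",
             two_sided: bool = False, per_slice_stats: bool = False,
             fill_hypo_core: bool = False) -> ScarReport:
    """nSD scar: threshold at mean(remote) + n·SD(remote).

    One-sided by default — hyperenhancement is the target — with a two-sided
    variant (|I − mean| > n·SD) by flag. Remote statistics are pooled over
    the whole stack by default; ``per_slice_stats`` recomputes them slice by
    slice.
    """
    image = np.asarray(image, dtype=float)
    myo = np.asarray(myo_masks, bool)
    remote = np.asarray(remote_roi, bool)
    if not remote.any():
        raise ValueError("remote ROI is empty")
    if (remote & ~myo).any():
        raise ValueError("remote ROI must lie inside the myocardium")

    def _label(img, myo_m, remote_vals):
        mean, sd = remote_vals.mean(), remote_vals.std(ddof=1)
        if sd == 0 and img[myo_m].std() > 0:
            warnings.warn("remote ROI has zero SD while the image is not constant; "
                          "threshold degenerates to the remote mean")
        thr = mean + n_sd * sd
        if two_sided:
            return (myo_m & (np.abs(img - mean) > n_sd * sd)), thr
        return (myo_m & (img > thr)), thr

    if per_slice_stats:
        infarct = np.zeros_like(myo)
        thresholds = []
        for s in range(image.shape[0]):
            if remote[s].any() and myo[s].any():
                infarct[s], thr = _label(image[s], myo[s], image[s][remote[s]])
                thresholds.append(thr)
        threshold = float(np.mean(thresholds)) if thresholds else math.nan
    else:
        infarct, threshold = _label(image, myo, image[remote])
    if fill_hypo_core:
        infarct = _fill_enclosed(infarct, myo)
    frac, mass, per_slice = _volumes(infarct, myo, pixel_spacing, slice_thickness_mm, density)
    return ScarReport(f"SD{n_sd:g}", source, frac, mass, per_slice, float(threshold), infarct)


def _fill_enclosed(infarct: np.ndarray, myo: np.ndarray) -> np.ndarray:
    """Fill holes in the infarct label that are enclosed by labeled voxels."""
    out = infarct.copy()
    for s in range(infarct.shape[0]):
        out[s] = ndimage.binary_fill_holes(infarct[s]) & myo[s]
    return out


def compare_methods(manual_values, method_values: dict[str, list[float]]) -> dict[str, dict[str, float]]:
    """Agreement of each semi-automatic method with manual reference values.

    For each method: Pearson r against the manual series and the mean paired
    difference (method − manual). Requires >= 3 pairs.
    """
    manual = np.asarray(manual_values, dtype=float)
    if manual.size < 3:
        raise ValueError(f"need >= 3 paired values, got {manual.size}")
    out = {}
    for name, vals in method_values.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size != manual.size:
            raise ValueError(f"method {name!r} has {vals.size} values, manual has {manual.size}")
        if np.std(vals) == 0 and np.std(manual) == 0:
            r = 1.0 if np.allclose(vals, manual) else math.nan
        elif np.std(vals) == 0 or np.std(manual) == 0:
            r = math.nan
        else:
            r = float(stats.pearsonr(manual, vals).statistic)
        out[name] = {
            "pearson_r": r,
            "mean_difference": float(np.mean(vals - manual)),
            "n": int(manual.size),
        }
    return out
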