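"""Image-quality metrics for short-axis cine MRI at ultra-high field.

Implements blood-tissue contrast (BTC) with the papillary-muscle filter,
the multi-receiver noise estimate from a signal-free region, regional and
pixelwise SNR, flip-angle estimation from B1 maps via maximum-intensity
projection, the receive-pathway SNR normalization, and the coil-to-LV
distance weight.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .image_io import ImageStack

DEFAULT_N_RECEIVERS = 16
NOISE_ROI_SIZE = 50  # pixels, square


@dataclass
class QualityReport:
    """Per-scan image-quality summary (one cardiac phase)."""

    s_myo: float = math.nan  # mean myocardial intensity, a.u.
    s_blood: float = math.nan  # mean filtered blood-pool intensity, a.u.
    btc: float = math.nan  # S_b / S_myo
    sigma_noise: float = math.nan
    noise_pixels: int = 0  # L
    n_receivers: int = DEFAULT_N_RECEIVERS
    snr_myo: float = math.nan
    fa_deg: float = math.nan
    fa_norm: float = math.nan
    snr_receive: float = math.nan
    snr_receive_mode: str = "sine-ratio"
    d_coil_lv_mm: float = math.nan
    angulation_offset_deg: float = 0.0
    d_corrected_mm: float = math.nan
    w_d: float = math.nan
    per_slice_btc: list = field(default_factory=list)


# -- blood-tissue contrast -----------------------------------------------------


def filter_blood_pool(image: np.ndarray, blood_mask: np.ndarray,
                      myo_mask: np.ndarray) -> np.ndarray:
    """Remove papillary-like pixels from one slice's blood-pool mask.

    Drops every blood-pool pixel whose intensity lies within one standard
    deviation of the mean myocardial signal of the same slice, i.e. keeps
    pixel p iff ``|I(p) − mean_myo| > SD_myo``. Papillary muscle sits at
    myocardium-like intensity inside the cavity contour and is exactly what
    this removes.
    """
    image = np.asarray(image, dtype=float)
    blood_mask = np.asarray(blood_mask, dtype=bool)
    myo_mask = np.asarray(myo_mask, dtype=bool)
    if not myo_mask.any():
        raise ValueError("myocardium mask is empty; cannot compute its statistics")
    if np.any(blood_mask & myo_mask):
        raise ValueError("blood-pool and myocardium masks must be disjoint")
    mean_myo = image[myo_mask].mean()
    sd_myo = image[myo_mask].std(ddof=1) if myo_mask.sum() > 1 else 0.0
    keep = blood_mask & (np.abs(image - mean_myo) > sd_myo)
    return keep


def compute_btc(stack: ImageStack | np.ndarray, myo_masks: np.ndarray,
                blood_masks: np.ndarray, apply_filter: bool = True) -> tuple[float, list[float]]:
    """Blood-tissue contrast BTC = S_b / S_myo.

    The blood pool is filtered slice by slice (see :func:`filter_blood_pool`)
    before averaging. Returns the whole-stack BTC — means pooled over all
    in-mask pixels of all slices — and the per-slice values (NaN where the
    filter empties a slice's blood pool).
    """
    vox = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack, dtype=float)
    if vox.ndim == 2:
        vox = vox[None]
        myo_masks = np.asarray(myo_masks, bool)[None]
        blood_masks = np.asarray(blood_masks, bool)[None]
    myo_masks = np.asarray(myo_masks, bool)
    blood_masks = np.asarray(blood_masks, bool)

    per_slice = []
    kept = np.zeros_like(blood_masks)
    for s in range(vox.shape[0]):
        if not myo_masks[s].any():
            per_slice.append(math.nan)
            continue
        keep = (filter_blood_pool(vox[s], blood_masks[s], myo_masks[s])
                if apply_filter else blood_masks[s])
        kept[s] = keep
        if not keep.any():
            warnings.warn(f"slice {s}: blood pool empty after filtering; BTC undefined")
            per_slice.append(math.nan)
            continue
        per_slice.append(float(vox[s][keep].mean() / vox[s][myo_masks[s]].mean()))

    s_myo_all = vox[myo_masks]
    if s_myo_all.size == 0 or s_myo_all.mean() == 0:
        raise ValueError("mean myocardial signal is zero or undefined; BTC undefined")
    if not kept.any():
        raise ValueError("blood pool empty after filtering on every slice; BTC undefined")
    btc = float(vox[kept].mean() / s_myo_all.mean())
    return btc, per_slice


# -- noise and SNR -------------------------------------------------------------


def auto_noise_roi(image: np.ndarray, size: int = NOISE_ROI_SIZE) -> tuple[slice, slice]:
    """Pick the corner ``size``×``size`` window with minimum mean intensity.

    Used when no signal-free region is supplied; the darkest corner of a
    magnitude image is the best automatic guess at air.
    """
    image = np.asarray(image)
    rows, cols = image.shape[-2:]
    if size > rows or size > cols:
        raise ValueError(f"noise ROI {size}px does not fit image {image.shape}")
    corners = [
        (slice(0, size), slice(0, size)),
        (slice(0, size), slice(cols - size, cols)),
        (slice(rows - size, rows), slice(0, size)),
        (slice(rows - size, rows), slice(cols - size, cols)),
    ]
    means = [image[..., r, c].mean() for r, c in corners]
    return corners[int(np.argmin(means))]


def estimate_noise_sd(image: np.ndarray, noise_roi: tuple[slice, slice] | np.ndarray | None = None,
                      n_receivers: int = DEFAULT_N_RECEIVERS,
                      tissue_mask: np.ndarray | None = None) -> float:
    """Noise SD from a signal-free region of a multi-receiver magnitude image.

    sigma = sqrt( sum(pixel²) / (2·L·n) ) with L the number of region pixels
    and n the receiver count. The factor accounts for the Rayleigh statistics
    of combined background noise; with n = 1 it reduces to the classic
    half-RMS background estimator.
    """
    image = np.asarray(image, dtype=float)
    if noise_roi is None:
        noise_roi = auto_noise_roi(image)
    if isinstance(noise_roi, tuple):
        region = image[noise_roi]
        if tissue_mask is not None and np.asarray(tissue_mask, bool)[noise_roi].any():
            warnings.warn("noise ROI overlaps a tissue mask; estimate may be biased high")
    else:
        sel = np.asarray(noise_roi, dtype=bool)
        region = image[sel]
        if tissue_mask is not None and (sel & np.asarray(tissue_mask, bool)).any():
            warnings.warn("noise ROI overlaps a tissue mask; estimate may be biased high")
    L = region.size
    if L == 0:
        raise ValueError("noise region is empty")
    if n_receivers <= 0:
        raise ValueError(f"n_receivers must be positive, got {n_receivers}")
    return float(np.sqrt(np.sum(region.astype(float) ** 2) / (2.0 * L * n_receivers)))


def compute_snr(image: np.ndarray | ImageStack, myo_mask: np.ndarray,
                sigma_noise: float) -> tuple[float, np.ndarray]:
    """Regional and pixelwise myocardial SNR.

    Returns ``(SNR_myo, SNR_pixel_map)`` where SNR_myo = mean(myocardium)/σ
    and the map holds I(p)/σ inside the myocardium mask and NaN elsewhere.
    """
    if sigma_noise <= 0:
        raise ValueError(f"sigma_noise must be positive, got {sigma_noise}")
    vox = image.voxels if isinstance(image, ImageStack) else np.asarray(image, dtype=float)
    myo_mask = np.asarray(myo_mask, bool)
    if myo_mask.shape != vox.shape:
        raise ValueError(f"mask shape {myo_mask.shape} != image shape {vox.shape}")
    if not myo_mask.any():
        raise ValueError("myocardium mask is empty")
    snr_myo = float(vox[myo_mask].mean() / sigma_noise)
    snr_map = np.full(vox.shape, np.nan)
    snr_map[myo_mask] = vox[myo_mask] / sigma_noise
    return snr_myo, snr_map


# -- flip angle / receive normalization ----------------------------------------


def estimate_fa_from_b1(b1_stack: ImageStack | np.ndarray, roi_center: tuple[int, int],
                        roi_radius_px: float, n_central_slices: int = 5,
                        invalid_value: float = 0.0) -> float:
    """Flip angle from a B1-map stack via maximum-intensity projection.

    Ungated B1 maps suffer slice-varying signal dropouts; since the true B1
    field is smooth, a voxelwise maximum over the ``n_central_slices`` central
    slices recovers the field wherever any slice is valid. The estimate is
    the mean over a circular ROI (anterior RV-LV insertion) of that MIP.
    Voxels equal to ``invalid_value`` are treated as dropout.
    """
    vox = b1_stack.voxels if isinstance(b1_stack, ImageStack) else np.asarray(b1_stack, dtype=float)
    if vox.ndim != 3:
        raise ValueError(f"B1 stack must be 3D, got {vox.ndim}D")
    n_slices = vox.shape[0]
    if n_slices < n_central_slices:
        raise ValueError(f"need >= {n_central_slices} slices, got {n_slices}")
    start = (n_slices - n_central_slices) // 2
    central = vox[start : start + n_central_slices].astype(float)
    central = np.where(central == invalid_value, -np.inf, central)
    mip = central.max(axis=0)
    mip[~np.isfinite(mip)] = np.nan

    rr, cc = np.mgrid[0 : mip.shape[0], 0 : mip.shape[1]]
    roi = (rr - roi_center[0]) ** 2 + (cc - roi_center[1]) ** 2 <= roi_radius_px**2
    if not roi.any():
        raise ValueError("flip-angle ROI is empty or outside the image")
    vals = mip[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("flip-angle ROI contains no valid B1 voxels after MIP")
    return float(vals.mean())


def normalize_snr_receive(snr_myo: float, fa_deg: float, fa_max_deg: float,
                          mode: str = "sine-ratio") -> float:
    """Receive-pathway SNR by normalizing out the transmit flip angle.

    ``sine-ratio`` (default): SNR_receive = SNR_myo · sin(FA_max)/sin(FA),
    i.e. signal ∝ sin(FA) for a spoiled gradient echo, referenced so the
    maximum-flip-angle scan is unchanged. ``literal``: divides by
    sin(FA/FA_max) with the dimensionless ratio read as radians.
    """
    if fa_deg <= 0:
        raise ValueError(f"flip angle must be positive, got {fa_deg}")
    if fa_deg > fa_max_deg:
        raise ValueError(f"flip angle {fa_deg} exceeds cohort maximum {fa_max_deg}")
    if mode == "sine-ratio":
        return float(snr_myo * math.sin(math.radians(fa_max_deg)) / math.sin(math.radians(fa_deg)))
    if mode == "literal":
        return float(snr_myo / math.sin(fa_deg / fa_max_deg))
    raise ValueError(f"mode must be 'sine-ratio' or 'literal', got {mode!r}")


# -- distance weight -----------------------------------------------------------


def compute_distance_weight(d_measured_mm: float, angulation_offset_deg: float,
                            d_max_mm: float) -> tuple[float, float]:
    """Coil-to-LV distance weight.

    The measured short-axis distance is projected onto the true transverse
    plane (multiplied by cos of the angulation offset) and normalized to the
    cohort maximum: W_d = d·cos(offset)/d_max. W_d near 1 marks the scans
    where coil-tissue distance costs the most SNR.
    """
    if d_measured_mm <= 0:
        raise ValueError(f"distance must be positive, got {d_measured_mm}")
    if not 0 <= angulation_offset_deg < 90:
        raise ValueError(f"angulation offset must be in [0, 90), got {angulation_offset_deg}")
    if d_max_mm <= 0:
        raise ValueError(f"d_max must be positive, got {d_max_mm}")
    d_corr = d_measured_mm * math.cos(math.radians(angulation_offset_deg))
    return float(d_corr), float(d_corr / d_max_mm)


# -- whole-scan convenience ----------------------------------------------------


def quality_report(image: np.ndarray, myo_masks: np.ndarray, blood_masks: np.ndarray,
                   noise_roi: tuple[slice, slice] | None = None,
                   n_receivers: int = DEFAULT_N_RECEIVERS) -> QualityReport:
    """BTC + noise + SNR for one phase of one scan (3D image + masks)."""
    image = np.asarray(image, dtype=float)
    btc, per_slice = compute_btc(image, myo_masks, blood_masks)
    sigma = float(np.mean([
        estimate_noise_sd(image[s], noise_roi, n_receivers) for s in range(image.shape[0])
    ]))
    if sigma > 0:
        snr_myo, _ = compute_snr(image, np.asarray(myo_masks, bool), sigma)
    else:  # noiseless image: noise SD is exactly zero, SNR undefined
        warnings.warn("noise region is identically zero; SNR undefined (NaN)")
        snr_myo = math.nan
    myo = np.asarray(myo_masks, bool)
    kept = np.zeros_like(np.asarray(blood_masks, bool))
    for s in range(image.shape[0]):
        if myo[s].any():
            kept[s] = filter_blood_pool(image[s], np.asarray(blood_masks, bool)[s], myo[s])
    return QualityReport(
        s_myo=float(image[myo].mean()),
        s_blood=float(image[kept].mean()) if kept.any() else math.nan,
        btc=btc,
        sigma_noise=sigma,
        noise_pixels=NOISE_ROI_SIZE**2,
        n_receivers=n_receivers,
        snr_myo=snr_myo,
        per_slice_btc=per_slice,
    )
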