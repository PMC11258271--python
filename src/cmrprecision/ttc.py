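"""Infarct planimetry from TTC-stained slice photographs.

TTC histochemistry stains viable myocardium red while infarct remains white;
each 5 mm LV slice is photographed from both faces ("top" = base-side face,
"bottom" = apex-side face) with a ruler in frame for pixel calibration.
This module calibrates from the ruler, segments viable vs infarct tissue
(auto mode in HSV space; manual masks pass through), totals infarct fraction
and mass per view and as the mean of views, and computes the two normalized
difference diagnostics: the line-of-sight effect (top vs bottom face of the
same slice) and the sawing-discontinuity effect (the two faces created by
one cut).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import label as cc_label

TTC_SLICE_THICKNESS_MM = 5.0
DEFAULT_TISSUE_DENSITY = 1.05  # g/cm³


@dataclass
class TtcSliceResult:
    view: str  # top | bottom
    slice_index: int
    mm_per_px: float
    lv_area_mm2: float
    infarct_area_mm2: float
    slice_thickness_mm: float = TTC_SLICE_THICKNESS_MM

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError(f"mm_per_px must be positive, got {self.mm_per_px}")
        if self.infarct_area_mm2 > self.lv_area_mm2 + 1e-9:
            raise ValueError(
                f"infarct area {self.infarct_area_mm2} exceeds LV area {self.lv_area_mm2}"
            )


# -- ruler calibration ---------------------------------------------------------


def calibrate_ruler(photo: np.ndarray, tick_spacing_mm: float = 1.0,
                    manual_mm_per_px: float | None = None) -> float:
    """mm/pixel from the median spacing of ruler ticks.

    Looks for a bright horizontal ruler band carrying dark tick marks,
    collects tick centroid columns, and converts the median inter-tick pixel
    distance to mm/px. With fewer than 3 detected ticks the photo is rejected
    unless a manual calibration value is supplied.
    """
    photo = np.asarray(photo)
    if photo.ndim == 3:
        gray = photo[..., :3].astype(float).mean(axis=-1)
    else:
        gray = photo.astype(float)

    # the ruler band: rows that are predominantly bright
    bright = gray > 0.85 * gray.max()
    band_rows = np.where(bright.mean(axis=1) > 0.5)[0]
    tick_cols: list[float] = []
    if band_rows.size:
        band = gray[band_rows.min() : band_rows.max() + 1]
        # only search between the band's bright ends, not the background margins
        col_bright = (band > 0.85 * gray.max()).mean(axis=0) > 0.3
        cols_on = np.where(col_bright)[0]
        dark = band < 0.3 * gray.max()
        if cols_on.size:
            dark[:, : cols_on.min()] = False
            dark[:, cols_on.max() + 1 :] = False
        labels = cc_label(dark, connectivity=2)
        for lab in range(1, labels.max() + 1):
            cols = np.where(labels == lab)[1]
            if cols.size:
                tick_cols.append(float(cols.mean()))
    tick_cols.sort()
    if len(tick_cols) < 3:
        if manual_mm_per_px is not None:
            return float(manual_mm_per_px)
        raise ValueError(
            f"only {len(tick_cols)} ruler ticks detected (need >= 3); "
            "supply manual_mm_per_px"
        )
    spacing_px = float(np.median(np.diff(tick_cols)))
    return tick_spacing_mm / spacing_px


# -- segmentation --------------------------------------------------------------


def segment_ttc(photo: np.ndarray, mode: str = "auto",
                lv_mask: np.ndarray | None = None, infarct_mask: np.ndarray | None = None,
                value_floor: float = 0.25, infarct_saturation_max: float = 0.25,
                exclude_ruler: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """(LV mask, infarct mask) for one TTC photo.

    Auto mode works in HSV: tissue is anything bright enough above the dark
    background, infarct is the low-saturation high-value (white) part of it,
    viable tissue the saturated red remainder. The ruler band (bright *and*
    unsaturated rows spanning the frame) is excluded from tissue. Manual mode
    passes supplied masks through unchanged. Auto mode exists so synthetic
    tests run unattended; the bench analysis it mirrors was manual planimetry.
    """
    if mode == "manual":
        if lv_mask is None or infarct_mask is None:
            raise ValueError("manual mode requires lv_mask and infarct_mask")
        lv = np.asarray(lv_mask, bool)
        if not lv.any():
            raise ValueError("LV mask is empty")
        return lv, np.asarray(infarct_mask, bool) & lv
    if mode != "auto":
        raise ValueError(f"mode must be 'auto' or 'manual', got {mode!r}")

    photo = np.asarray(photo)
    if photo.ndim != 3 or photo.shape[-1] < 3:
        raise ValueError("auto mode requires an RGB photo")
    hsv = rgb2hsv(photo[..., :3])
    value, sat = hsv[..., 2], hsv[..., 1]
    tissue = value > value_floor
    if exclude_ruler:
        ruler_rows = ((value > 0.8) & (sat < 0.2)).mean(axis=1) > 0.5
        tissue[ruler_rows, :] = False
    if not tissue.any():
        raise ValueError("no LV tissue found above the background threshold")
    infarct = tissue & (sat < infarct_saturation_max) & (value > 0.7)
    return tissue, infarct


# -- totals and diagnostics ----------------------------------------------------


def ttc_infarct_size(results: list[TtcSliceResult],
                     density: float = DEFAULT_TISSUE_DENSITY) -> dict:
    """Study totals per view and the mean of views.

    Fraction per view = Σ infarct area / Σ LV area · 100; mass per view
    = Σ infarct area · thickness · density. The mean of views averages the
    two per-view totals; if one view is missing, available totals are
    reported and the mean is flagged absent (NaN).
    """
    if not results:
        raise ValueError("no slice results supplied")
    out: dict = {}
    for view in ("top", "bottom"):
        sub = [r for r in results if r.view == view]
        if not sub:
            out[view] = None
            continue
        lv = sum(r.lv_area_mm2 for r in sub)
        inf = sum(r.infarct_area_mm2 for r in sub)
        mass = sum(r.infarct_area_mm2 * r.slice_thickness_mm for r in sub) / 1000.0 * density
        out[view] = {
            "infarct_fraction_pct": 100.0 * inf / lv if lv > 0 else math.nan,
            "infarct_mass_g": mass,
            "n_slices": len(sub),
        }
    if out["top"] and out["bottom"]:
        out["mean_of_views"] = {
            k: 0.5 * (out["top"][k] + out["bottom"][k])
            for k in ("infarct_fraction_pct", "infarct_mass_g")
        }
    else:
        out["mean_of_views"] = None
    return out


def discontinuity_and_view_metrics(results: list[TtcSliceResult]) -> dict[str, np.ndarray]:
    """Normalized face-difference diagnostics, slices ordered base→apex.

    ``line_of_sight[i]`` = (top_i − bottom_i) / total infarct area: how much
    the photographed face choice changes slice i's infarct estimate.
    ``discontinuity[i]`` = (top_{i+1} − bottom_i) / total infarct area: the
    mismatch across physical cut i — the two faces a saw cut creates are the
    bottom face of slice i and the top face of slice i+1, which would be
    identical for a perfectly smooth infarct and lossless cut. Signs follow
    the stated subtraction order. A single slice has no cuts; the
    discontinuity array is then empty.
    """
    tops = {r.slice_index: r for r in results if r.view == "top"}
    bottoms = {r.slice_index: r for r in results if r.view == "bottom"}
    indices = sorted(tops.keys() & bottoms.keys())
    if not indices:
        raise ValueError("need both views of at least one slice")
    total = sum(r.infarct_area_mm2 for r in results)
    if total == 0:
        raise ValueError("total infarct area is zero; normalized metrics undefined")
    los = np.array([
        (tops[i].infarct_area_mm2 - bottoms[i].infarct_area_mm2) / total for i in indices
    ])
    disc = np.array([
        (tops[j].infarct_area_mm2 - bottoms[i].infarct_area_mm2) / total
        for i, j in zip(indices[:-1], indices[1:])
    ])
    return {"line_of_sight": los, "discontinuity": disc,
            "slice_indices": np.array(indices)}


def quantify_photo(photo: np.ndarray, view: str, slice_index: int,
                   tick_spacing_mm: float = 1.0, mode: str = "auto",
                   lv_mask: np.ndarray | None = None,
                   infarct_mask: np.ndarray | None = None,
                   manual_mm_per_px: float | None = None) -> TtcSliceResult:
    """Calibrate, segment and measure one photo end to end."""
    mm_per_px = calibrate_ruler(photo, tick_spacing_mm, manual_mm_per_px)
    lv, infarct = segment_ttc(photo, mode=mode, lv_mask=lv_mask, infarct_mask=infarct_mask)
    px_area = mm_per_px**2
    return TtcSliceResult(
        view=view, slice_index=slice_index, mm_per_px=mm_per_px,
        lv_area_mm2=float(lv.sum() * px_area),
        infarct_area_mm2=float(infarct.sum() * px_area),
    )
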