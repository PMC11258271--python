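"""Cardiac function from per-phase short-axis segmentations.

Volumes by slice summation (Simpson's rule with contiguous slices), ED/ES
phase selection from the cavity volume curve, ejection fraction, myocardial
mass at a fixed tissue density, and the phase-harmonization procedure that
recomputes one observer's volumes at the other observer's chosen phases to
isolate pure segmentation variability.

Papillary muscle is included in the blood-pool volume (and therefore excluded
from mass) by convention; the phantom renders it at myocardial intensity but
inside the cavity contour, matching that convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

MM3_PER_ML = 1000.0
DEFAULT_TISSUE_DENSITY = 1.05  # g/cm³


@dataclass
class FunctionReport:
    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_pct: float
    ed_mass_g: float
    ed_phase: int
    es_phase: int
    per_slice_area_mm2: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def ef_rounded(self) -> float:
        """EF for reporting, one decimal; comparisons use ``ef_pct``."""
        return round(self.ef_pct, 1)


def slice_summation_volume(masks: np.ndarray, pixel_spacing: tuple[float, float],
                           slice_thickness_mm: float) -> float:
    """Volume in ml of per-slice binary masks: Σ slices (area · thickness).

    Area per slice is the pixel count times the pixel area; slices are
    assumed contiguous (no gap, no overlap).
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 3 or masks.shape[0] == 0:
        raise ValueError(f"need a (slice,row,col) mask volume with >=1 slice, got {masks.shape}")
    px_area = pixel_spacing[0] * pixel_spacing[1]
    areas = masks.sum(axis=(1, 2)) * px_area
    return float(areas.sum() * slice_thickness_mm / MM3_PER_ML)


def select_phases(volumes_ml) -> tuple[int, int]:
    """ED = phase of maximum cavity volume, ES = phase of minimum.

    Ties resolve to the earliest phase. A constant volume curve has no
    meaningful extrema; it warns and returns ``(0, 0)``.
    """
    volumes = np.asarray(volumes_ml, dtype=float)
    if volumes.size < 2:
        raise ValueError(f"need >= 2 phases, got {volumes.size}")
    if np.all(volumes == volumes[0]):
        warnings.warn("cavity volume is constant across phases; ED/ES undefined, returning (0, 0)")
        return 0, 0
    return int(np.argmax(volumes)), int(np.argmin(volumes))


def compute_function(endo_masks_by_phase: np.ndarray | list[np.ndarray],
                     myo_masks_by_phase: np.ndarray | list[np.ndarray] | None,
                     pixel_spacing: tuple[float, float], slice_thickness_mm: float,
                     density_g_per_cm3: float = DEFAULT_TISSUE_DENSITY,
                     phases: tuple[int, int] | None = None) -> FunctionReport:
    """EDV/ESV/SV/EF and end-diastolic mass from per-phase segmentations.

    ``endo_masks_by_phase``: sequence over phases of (slice,row,col) cavity
    masks (papillary included). ``myo_masks_by_phase``: matching myocardial
    annulus masks, or None to skip mass. ``phases`` pins (ed, es) externally
    — the hook used by phase harmonization; otherwise they are selected from
    the volume curve.
    """
    volumes = np.array([
        slice_summation_volume(m, pixel_spacing, slice_thickness_mm)
        for m in endo_masks_by_phase
    ])
    if phases is None:
        ed, es = select_phases(volumes)
    else:
        ed, es = phases
        if not (0 <= ed < len(volumes) and 0 <= es < len(volumes)):
            raise ValueError(
                f"harmonization phases (ed={ed}, es={es}) outside available range "
                f"0..{len(volumes) - 1}"
            )
    edv, esv = float(volumes[ed]), float(volumes[es])
    if edv == 0:
        raise ValueError("EDV is zero; ejection fraction undefined")
    sv = edv - esv
    ef = 100.0 * sv / edv

    ed_mass = math.nan
    per_slice: dict[str, np.ndarray] = {}
    if myo_masks_by_phase is not None:
        myo_ed = np.asarray(myo_masks_by_phase[ed], dtype=bool)
        myo_vol_ml = slice_summation_volume(myo_ed, pixel_spacing, slice_thickness_mm)
        ed_mass = myo_vol_ml * density_g_per_cm3  # 1 ml = 1 cm³
        px_area = pixel_spacing[0] * pixel_spacing[1]
        per_slice["myocardium_ed"] = myo_ed.sum(axis=(1, 2)) * px_area
    endo_ed = np.asarray(endo_masks_by_phase[ed], dtype=bool)
    per_slice["endo_ed"] = endo_ed.sum(axis=(1, 2)) * pixel_spacing[0] * pixel_spacing[1]

    return FunctionReport(
        edv_ml=edv, esv_ml=esv, sv_ml=sv, ef_pct=ef, ed_mass_g=ed_mass,
        ed_phase=ed, es_phase=es, per_slice_area_mm2=per_slice,
    )


def harmonize_phases(report_a: FunctionReport,
                     endo_masks_b, myo_masks_b,
                     pixel_spacing: tuple[float, float], slice_thickness_mm: float,
                     density_g_per_cm3: float = DEFAULT_TISSUE_DENSITY) -> FunctionReport:
    """Re-evaluate observer B's function at observer A's ED/ES phases.

    Inter-observer EF differences mix two sources: where each observer drew
    contours and *which cardiac phases* each called ED/ES. Recomputing B's
    volumes at A's phase choices removes the second source, leaving the pure
    segmentation component. Requires B to have masks at A's phases.
    """
    n_phases = len(endo_masks_b)
    missing = [p for p in (report_a.ed_phase, report_a.es_phase) if not 0 <= p < n_phases]
    if missing:
        raise ValueError(
            f"observer B lacks segmentations at observer A's phase(s) {missing}; "
            f"B covers phases 0..{n_phases - 1}"
        )
    return compute_function(
        endo_masks_b, myo_masks_b, pixel_spacing, slice_thickness_mm,
        density_g_per_cm3, phases=(report_a.ed_phase, report_a.es_phase),
    )
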