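"""Digital cardiac phantom with exact analytic ground truth.

The phantom is deliberately simple geometry — a stack of left-ventricular
annuli (optionally tapered base to apex) with a contracting cavity, papillary
muscles inside the blood pool, and an anteroseptal infarct wedge — because
every downstream quantity (volumes, ejection fraction, mass, blood-tissue
contrast, SNR, infarct fraction) must be computable in closed form. It is not
an anatomical model: no trabeculation, no valve plane, no k-space simulation.

Contraction conserves myocardial cross-sectional area per slice
(incompressibility), so end-diastolic and end-systolic mass are equal by
construction and mass is a phase-invariant test quantity.

Noise is Rician by default, the standard model for magnitude MR images
(Rayleigh in signal-free background); a pure-Gaussian channel is available
via ``add_rician_noise(..., model="gaussian")`` for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .image_io import ImageStack, LabelMaskSet

MM3_PER_ML = 1000.0
DEFAULT_TISSUE_DENSITY = 1.05  # g/cm³, myocardium


@dataclass
class InfarctWedge:
    """Angular infarct sector within the myocardial annulus.

    Angles are degrees measured counter-clockwise from the +col axis.
    ``transmurality`` is the *area* fraction of the annulus covered radially,
    measured from the endocardium outward: the wedge's outer radius is
    ``sqrt(r_endo² + t·(r_epi² − r_endo²))``, so on a uniform annulus the
    true infarct fraction is exactly ``(angular span/360)·t``.
    ``hypo_core_fraction`` carves the innermost part of the wedge (again by
    area fraction of the wedge) into a hypointense core, emulating
    microvascular obstruction.
    """

    angle_start_deg: float = -45.0
    angle_end_deg: float = 45.0
    transmurality: float = 1.0
    slice_range: tuple[int, int] | None = None  # [start, stop) slices; None = all
    hypo_core_fraction: float = 0.0

    @property
    def angular_fraction(self) -> float:
        span = (self.angle_end_deg - self.angle_start_deg) % 360.0
        if span == 0 and self.angle_end_deg != self.angle_start_deg:
            span = 360.0
        return span / 360.0


@dataclass
class CoilModel:
    """Surface-coil array: element positions (mm) and exponential decay.

    Sensitivity at a point is ``exp(-d_nearest / decay_mm)`` with
    ``d_nearest`` the distance to the closest element, so it is smooth,
    positive, maximal at each element, and monotonically decreasing with
    distance from the array. ``decay_mm = inf`` gives uniform sensitivity.
    """

    element_positions_mm: list[tuple[float, float, float]] = field(default_factory=list)
    decay_mm: float = 120.0


@dataclass
class PhantomSpec:
    """Full parametric ground truth for the generator.

    Radii and thicknesses are in mm. ``endo_radius_ed``/``endo_radius_es``
    may be scalars (uniform cylinder) or per-slice sequences (base→apex
    taper). Intensities are in arbitrary units and name the noiseless value
    inside each tissue label.
    """

    n_slices: int = 10
    rows: int = 128
    cols: int = 128
    pixel_spacing: tuple[float, float] = (0.8, 0.8)
    slice_thickness_mm: float = 6.0
    n_phases: int = 30
    endo_radius_ed: float | list[float] = 18.0
    endo_radius_es: float | list[float] = 11.0
    wall_thickness_ed: float = 9.0
    papillary: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    infarct_wedge: InfarctWedge | None = None
    intensities: dict[str, float] = field(
        default_factory=lambda: {
            "myocardium": 100.0,
            "blood": 250.0,
            "infarct_hyper": 150.0,
            "infarct_hypo_core": 30.0,
            "background": 0.0,
        }
    )
    noise_sigma: float = 0.0
    coil_model: CoilModel | None = None
    seed: int = 0
    tissue_density: float = DEFAULT_TISSUE_DENSITY
    center_offset_mm: tuple[float, float] = (0.0, 0.0)

    # -- derived geometry ------------------------------------------------------

    def _per_slice(self, value) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            return np.full(self.n_slices, arr[0])
        if arr.size != self.n_slices:
            raise ValueError(f"per-slice value has length {arr.size}, expected {self.n_slices}")
        return arr

    @property
    def endo_ed(self) -> np.ndarray:
        return self._per_slice(self.endo_radius_ed)

    @property
    def endo_es(self) -> np.ndarray:
        return self._per_slice(self.endo_radius_es)

    @property
    def annulus_area_mm2(self) -> np.ndarray:
        """Myocardial cross-section per slice, conserved over the cycle."""
        r = self.endo_ed
        return math.pi * ((r + self.wall_thickness_ed) ** 2 - r**2)

    def epi_radius(self, endo_radius: np.ndarray) -> np.ndarray:
        """Epicardial radius preserving the per-slice annulus area."""
        return np.sqrt(endo_radius**2 + self.annulus_area_mm2 / math.pi)

    def endo_radius_at_phase(self, p: int) -> np.ndarray:
        """Cosine contraction law: phase 0 is ED, phase n/2 is ES."""
        frac = 0.5 * (1.0 + math.cos(2.0 * math.pi * p / self.n_phases))
        return self.endo_es + (self.endo_ed - self.endo_es) * frac

    @property
    def ed_phase(self) -> int:
        return 0

    @property
    def es_phase(self) -> int:
        return self.n_phases // 2

    def validate(self) -> None:
        ed, es = self.endo_ed, self.endo_es
        if np.any(es > ed):
            raise ValueError(
                f"contraction requires endo_radius_es <= endo_radius_ed on every slice; "
                f"got ES {es.tolist()} vs ED {ed.tolist()}"
            )
        if self.wall_thickness_ed <= 0:
            raise ValueError(f"wall thickness must be positive, got {self.wall_thickness_ed}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError(f"intensities must be nonnegative: {self.intensities}")
        if self.infarct_wedge is not None:
            t = self.infarct_wedge.transmurality
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"transmurality must be in [0, 1], got {t}")
        fov = (self.rows * self.pixel_spacing[0], self.cols * self.pixel_spacing[1])
        max_epi = float(self.epi_radius(es).max())  # epi is largest at ES
        if 2 * max_epi > min(fov):
            raise ValueError(
                f"epicardium (radius {max_epi:.1f} mm) does not fit the "
                f"{fov[0]:.0f}×{fov[1]:.0f} mm field of view"
            )

    # -- analytic truths -------------------------------------------------------

    def cavity_volume_ml(self, endo_radius: np.ndarray) -> float:
        """Blood-pool volume by slice summation of analytic disc areas."""
        areas = math.pi * np.asarray(endo_radius) ** 2
        return float(areas.sum() * self.slice_thickness_mm / MM3_PER_ML)

    @property
    def true_edv_ml(self) -> float:
        return self.cavity_volume_ml(self.endo_ed)

    @property
    def true_esv_ml(self) -> float:
        return self.cavity_volume_ml(self.endo_es)

    @property
    def true_ef_pct(self) -> float:
        return 100.0 * (self.true_edv_ml - self.true_esv_ml) / self.true_edv_ml

    @property
    def true_mass_g(self) -> float:
        vol_ml = float(self.annulus_area_mm2.sum() * self.slice_thickness_mm / MM3_PER_ML)
        return vol_ml * self.tissue_density  # 1 ml = 1 cm³

    @property
    def true_infarct_fraction_pct(self) -> float:
        """Hyper+hypo wedge volume as % of myocardial volume (exact)."""
        if self.infarct_wedge is None:
            return 0.0
        w = self.infarct_wedge
        lo, hi = w.slice_range if w.slice_range is not None else (0, self.n_slices)
        area = self.annulus_area_mm2
        wedge = area[lo:hi].sum() * w.angular_fraction * w.transmurality
        return float(100.0 * wedge / area.sum())

    @property
    def true_infarct_mass_g(self) -> float:
        return self.true_infarct_fraction_pct / 100.0 * self.true_mass_g


@dataclass
class GroundTruth:
    """Analytic truth plus noiseless rasters and per-phase label masks."""

    true_edv_ml: float
    true_esv_ml: float
    true_sv_ml: float
    true_ef_pct: float
    true_mass_g: float
    true_infarct_fraction_pct: float
    true_infarct_mass_g: float
    noiseless_stack: ImageStack
    label_masks: list[LabelMaskSet]  # one per phase (single entry for LGE)
    ed_phase: int = 0
    es_phase: int = 0


# -- rasterization helpers -----------------------------------------------------


def _pixel_grid_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates (mm) relative to the LV axis."""
    cy = spec.rows / 2.0 * spec.pixel_spacing[0] + spec.center_offset_mm[0]
    cx = spec.cols / 2.0 * spec.pixel_spacing[1] + spec.center_offset_mm[1]
    y = (np.arange(spec.rows) + 0.5) * spec.pixel_spacing[0] - cy
    x = (np.arange(spec.cols) + 0.5) * spec.pixel_spacing[1] - cx
    return np.meshgrid(y, x, indexing="ij")


def _slice_masks(spec: PhantomSpec, endo_r: float, epi_r: float,
                 slice_index: int) -> dict[str, np.ndarray]:
    yy, xx = _pixel_grid_mm(spec)
    rr = np.hypot(yy, xx)
    cavity = rr <= endo_r
    annulus = (rr > endo_r) & (rr <= epi_r)
    masks = {"myocardium": annulus, "blood_pool": cavity}

    pap = np.zeros_like(cavity)
    for (py, px), pr in spec.papillary:
        pap |= np.hypot(yy - py, xx - px) <= pr
    masks["papillary"] = pap & cavity

    if spec.infarct_wedge is not None:
        w = spec.infarct_wedge
        lo, hi = w.slice_range if w.slice_range is not None else (0, spec.n_slices)
        if lo <= slice_index < hi and w.transmurality > 0 and w.angular_fraction > 0:
            theta = np.degrees(np.arctan2(yy, xx))
            span = (w.angle_end_deg - w.angle_start_deg) % 360.0 or 360.0
            in_sector = ((theta - w.angle_start_deg) % 360.0) <= span
            r_out = math.sqrt(endo_r**2 + w.transmurality * (epi_r**2 - endo_r**2))
            wedge = annulus & in_sector & (rr <= r_out)
            if w.hypo_core_fraction > 0:
                r_core = math.sqrt(endo_r**2 + w.hypo_core_fraction * (r_out**2 - endo_r**2))
                core = wedge & (rr <= r_core)
            else:
                core = np.zeros_like(wedge)
            masks["infarct_hyper"] = wedge & ~core
            masks["infarct_hypo"] = core
    masks.setdefault("infarct_hyper", np.zeros_like(annulus))
    masks.setdefault("infarct_hypo", np.zeros_like(annulus))
    return masks


def _require_feasible(spec: PhantomSpec) -> None:
    spec.validate()


# -- generators ----------------------------------------------------------------


def generate_cine_phantom(spec: PhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Phase-resolved short-axis cine stack with per-phase truth masks.

    Noiseless intensities equal ``spec.intensities`` inside each label;
    papillary muscles are rendered at the myocardial intensity (worst case
    for the blood-pool filter) but belong to the blood-pool contour, matching
    the convention that the cavity segmentation includes papillary muscle.
    Rician noise and coil sensitivity are applied on top when requested.
    """
    _require_feasible(spec)
    inten = spec.intensities
    vox = np.full(
        (spec.n_slices, spec.rows, spec.cols, spec.n_phases),
        inten["background"],
        dtype=float,
    )
    per_phase_masks: list[LabelMaskSet] = []
    for p in range(spec.n_phases):
        endo = spec.endo_radius_at_phase(p)
        epi = spec.epi_radius(endo)
        masks = {
            label: np.zeros((spec.n_slices, spec.rows, spec.cols), dtype=bool)
            for label in ("myocardium", "blood_pool", "papillary")
        }
        for s in range(spec.n_slices):
            sm = _slice_masks(spec, float(endo[s]), float(epi[s]), s)
            frame = vox[s, :, :, p]
            frame[sm["blood_pool"]] = inten["blood"]
            frame[sm["myocardium"]] = inten["myocardium"]
            frame[sm["papillary"]] = inten["myocardium"]
            for label in masks:
                masks[label][s] = sm[label]
        per_phase_masks.append(LabelMaskSet(masks=masks, phase_index=p))

    stack = ImageStack(
        voxels=vox,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness_mm=spec.slice_thickness_mm,
        modality="cine",
    )
    noiseless = ImageStack(
        voxels=vox.copy(),
        pixel_spacing=spec.pixel_spacing,
        slice_thickness_mm=spec.slice_thickness_mm,
        modality="cine",
    )
    if spec.coil_model is not None:
        stack = apply_coil_sensitivity(stack, spec.coil_model)
    if spec.noise_sigma > 0:
        stack = add_rician_noise(stack, spec.noise_sigma, seed=spec.seed)

    truth = GroundTruth(
        true_edv_ml=spec.true_edv_ml,
        true_esv_ml=spec.true_esv_ml,
        true_sv_ml=spec.true_edv_ml - spec.true_esv_ml,
        true_ef_pct=spec.true_ef_pct,
        true_mass_g=spec.true_mass_g,
        true_infarct_fraction_pct=spec.true_infarct_fraction_pct,
        true_infarct_mass_g=spec.true_infarct_mass_g,
        noiseless_stack=noiseless,
        label_masks=per_phase_masks,
        ed_phase=spec.ed_phase,
        es_phase=spec.es_phase,
    )
    return stack, truth


def generate_lge_phantom(spec: PhantomSpec, source: str = "magnitude") -> tuple[ImageStack, GroundTruth]:
    """Late-enhancement stack at end-diastole with an enhancing wedge.

    Remote (viable) myocardium is near-nulled; the wedge enhances at
    ``infarct_hyper`` with an optional hypointense core. ``source`` selects
    the reconstruction: ``"psir"`` preserves signed intensities (nulled
    myocardium may sit slightly below zero), ``"magnitude"`` takes absolute
    values — which is what compresses the scar-to-remote contrast and makes
    magnitude-derived infarct sizes run low.
    """
    if spec.infarct_wedge is None:
        raise ValueError("generate_lge_phantom requires spec.infarct_wedge")
    if source not in ("magnitude", "psir"):
        raise ValueError(f"source must be 'magnitude' or 'psir', got {source!r}")
    _require_feasible(spec)
    inten = spec.intensities
    nulled_myo = inten.get("myocardium_nulled", 15.0)
    vox = np.full((spec.n_slices, spec.rows, spec.cols), inten["background"], dtype=float)
    endo, epi = spec.endo_ed, spec.epi_radius(spec.endo_ed)
    masks = {
        label: np.zeros((spec.n_slices, spec.rows, spec.cols), dtype=bool)
        for label in ("myocardium", "blood_pool", "infarct_hyper", "infarct_hypo", "papillary")
    }
    for s in range(spec.n_slices):
        sm = _slice_masks(spec, float(endo[s]), float(epi[s]), s)
        frame = vox[s]
        frame[sm["blood_pool"]] = inten["blood"]
        frame[sm["myocardium"]] = nulled_myo
        frame[sm["papillary"]] = nulled_myo
        frame[sm["infarct_hyper"]] = inten["infarct_hyper"]
        frame[sm["infarct_hypo"]] = inten["infarct_hypo_core"]
        for label in masks:
            masks[label][s] = sm[label]
    stack = ImageStack(
        voxels=vox,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness_mm=spec.slice_thickness_mm,
        modality="lge-psir" if source == "psir" else "lge-magnitude",
    )
    noiseless = ImageStack(
        voxels=vox.copy(),
        pixel_spacing=spec.pixel_spacing,
        slice_thickness_mm=spec.slice_thickness_mm,
        modality=stack.modality,
    )
    if spec.coil_model is not None:
        stack = apply_coil_sensitivity(stack, spec.coil_model)
    if spec.noise_sigma > 0:
        stack = add_rician_noise(stack, spec.noise_sigma, seed=spec.seed,
                                 model="gaussian" if source == "psir" else "rician")
    if source == "magnitude":
        stack.voxels = np.abs(stack.voxels)

    truth = GroundTruth(
        true_edv_ml=spec.true_edv_ml,
        true_esv_ml=spec.true_esv_ml,
        true_sv_ml=spec.true_edv_ml - spec.true_esv_ml,
        true_ef_pct=spec.true_ef_pct,
        true_mass_g=spec.true_mass_g,
        true_infarct_fraction_pct=spec.true_infarct_fraction_pct,
        true_infarct_mass_g=spec.true_infarct_mass_g,
        noiseless_stack=noiseless,
        label_masks=[LabelMaskSet(masks=masks, phase_index=0)],
    )
    return stack, truth


def add_rician_noise(stack: ImageStack, sigma: float, seed: int = 0,
                     model: str = "rician") -> ImageStack:
    """Corrupt a stack with magnitude-image noise of channel SD ``sigma``.

    Rician model: each voxel v becomes ``sqrt((v + g1)² + g2²)`` with g1, g2
    independent N(0, sigma) — Rayleigh in background, approximately Gaussian
    at high SNR. ``model="gaussian"`` adds plain additive noise (appropriate
    for signed phase-sensitive reconstructions).
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if model not in ("rician", "gaussian"):
        raise ValueError(f"model must be 'rician' or 'gaussian', got {model!r}")
    if sigma == 0:
        return ImageStack(stack.voxels.copy(), stack.pixel_spacing,
                          stack.slice_thickness_mm, stack.modality, stack.origin_mm)
    rng = np.random.default_rng(seed)
    v = stack.voxels.astype(float)
    if model == "rician":
        g1 = rng.normal(0.0, sigma, v.shape)
        g2 = rng.normal(0.0, sigma, v.shape)
        noisy = np.hypot(v + g1, g2)
    else:
        noisy = v + rng.normal(0.0, sigma, v.shape)
    return ImageStack(noisy, stack.pixel_spacing, stack.slice_thickness_mm,
                      stack.modality, stack.origin_mm)


def coil_sensitivity_field(stack: ImageStack, coil: CoilModel) -> np.ndarray:
    """Smooth positive sensitivity ``exp(-d_nearest/decay)`` on the stack grid."""
    if not coil.element_positions_mm:
        return np.ones(stack.voxels.shape[:3])
    sr, sc = stack.pixel_spacing
    z = (np.arange(stack.n_slices) + 0.5) * stack.slice_thickness_mm
    y = (np.arange(stack.voxels.shape[1]) + 0.5) * sr
    x = (np.arange(stack.voxels.shape[2]) + 0.5) * sc
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    d_min = np.full(zz.shape, np.inf)
    for (ey, ex, ez) in coil.element_positions_mm:
        d = np.sqrt((yy - ey) ** 2 + (xx - ex) ** 2 + (zz - ez) ** 2)
        np.minimum(d_min, d, out=d_min)
    if not np.isfinite(coil.decay_mm):
        return np.ones_like(d_min)
    return np.exp(-d_min / coil.decay_mm)


def apply_coil_sensitivity(stack: ImageStack, coil: CoilModel) -> ImageStack:
    """Multiply voxel intensities by the receive-sensitivity field."""
    field3d = coil_sensitivity_field(stack, coil)
    vox = stack.voxels.astype(float)
    if vox.ndim == 4:
        vox = vox * field3d[..., None]
    else:
        vox = vox * field3d
    return ImageStack(vox, stack.pixel_spacing, stack.slice_thickness_mm,
                      stack.modality, stack.origin_mm)


# -- TTC photographs -----------------------------------------------------------

TTC_SLICE_THICKNESS_MM = 5.0
TTC_COLORS = {
    "background": (25, 25, 30),
    "viable": (190, 40, 45),  # TTC-stained red
    "infarct": (240, 238, 232),  # unstained white
    "ruler": (250, 250, 250),
    "tick": (10, 10, 10),
}


@dataclass
class TtcPhoto:
    """One photographed face of one TTC-stained LV slice."""

    image: np.ndarray  # (rows, cols, 3) uint8
    view: str  # "top" (base-side face) or "bottom" (apex-side face)
    slice_index: int
    mm_per_px: float
    true_lv_area_mm2: float
    true_infarct_area_mm2: float
    ruler_tick_spacing_mm: float = 1.0


def _ttc_face_radii(spec: PhantomSpec, z_mm: float) -> tuple[float, float]:
    """Endo/epi radius at depth ``z_mm`` with linear base→apex taper."""
    height = spec.n_slices * spec.slice_thickness_mm
    endo = spec.endo_ed
    frac = np.clip(z_mm / height, 0.0, 1.0)
    # interpolate per-slice radii linearly along z, using slice centers
    centers = (np.arange(spec.n_slices) + 0.5) * spec.slice_thickness_mm
    r_endo = float(np.interp(z_mm, centers, endo))
    r_epi = float(np.interp(z_mm, centers, spec.epi_radius(endo)))
    del frac, height
    return r_endo, r_epi


def generate_ttc_photos(spec: PhantomSpec, mm_per_px: float = 0.1,
                        image_px: int = 720, ruler_tick_spacing_mm: float = 1.0,
                        apical_taper: float = 0.0) -> list[TtcPhoto]:
    """Photographs of both faces of each 5 mm TTC-stained LV slice.

    The LV is re-sliced at 5 mm (the bench-cutting thickness, independent of
    the MRI slice thickness). Viable myocardium renders red, infarct white,
    background dark; a horizontal ruler with ticks every
    ``ruler_tick_spacing_mm`` is drawn along the bottom of every photo. The
    ``top`` view is the base-side face seen base→apex, the ``bottom`` view the
    apex-side face seen apex→base, so the two faces of one physical cut are
    (bottom of slice i, top of slice i+1).

    ``apical_taper`` (0–1) shrinks the wedge's angular span linearly toward
    the apex, producing a cone-shaped infarct whose top/bottom face areas of
    one slice differ by an analytic amount.
    """
    _require_feasible(spec)
    if spec.infarct_wedge is None and apical_taper > 0:
        raise ValueError("apical_taper needs an infarct wedge")
    height = spec.n_slices * spec.slice_thickness_mm
    n_ttc = int(round(height / TTC_SLICE_THICKNESS_MM))
    photos: list[TtcPhoto] = []
    w = spec.infarct_wedge
    for i in range(n_ttc):
        for view, z in (("top", i * TTC_SLICE_THICKNESS_MM),
                        ("bottom", (i + 1) * TTC_SLICE_THICKNESS_MM)):
            z_eval = min(z, height - 1e-9)
            r_endo, r_epi = _ttc_face_radii(spec, z_eval)
            if w is not None:
                depth_frac = z_eval / height
                span = w.angular_fraction * 360.0 * (1.0 - apical_taper * depth_frac)
                r_out = math.sqrt(r_endo**2 + w.transmurality * (r_epi**2 - r_endo**2))
                infarct_area = (span / 360.0) * math.pi * (r_out**2 - r_endo**2)
            else:
                span, r_out, infarct_area = 0.0, r_endo, 0.0
            lv_area = math.pi * (r_epi**2 - r_endo**2)

            img = _render_ttc_face(spec, r_endo, r_epi, r_out, span, mm_per_px,
                                   image_px, ruler_tick_spacing_mm, view)
            photos.append(TtcPhoto(
                image=img, view=view, slice_index=i, mm_per_px=mm_per_px,
                true_lv_area_mm2=lv_area, true_infarct_area_mm2=infarct_area,
                ruler_tick_spacing_mm=ruler_tick_spacing_mm,
            ))
    return photos


def _render_ttc_face(spec: PhantomSpec, r_endo: float, r_epi: float, r_out: float,
                     span_deg: float, mm_per_px: float, image_px: int,
                     tick_mm: float, view: str) -> np.ndarray:
    img = np.empty((image_px, image_px, 3), dtype=np.uint8)
    img[:] = TTC_COLORS["background"]
    cy = cx = image_px / 2.0
    if cy + r_epi / mm_per_px >= image_px - 44:  # tissue must clear the ruler band
        raise ValueError(
            f"LV (epi radius {r_epi:.1f} mm) collides with the ruler band at "
            f"{image_px}px/{mm_per_px} mm-per-px; enlarge image_px"
        )
    yy, xx = np.mgrid[0:image_px, 0:image_px]
    ym = (yy + 0.5 - cy) * mm_per_px
    xm = (xx + 0.5 - cx) * mm_per_px
    if view == "bottom":  # apex→base line of sight mirrors left-right
        xm = -xm
    rr = np.hypot(ym, xm)
    annulus = (rr > r_endo) & (rr <= r_epi)
    img[annulus] = TTC_COLORS["viable"]
    if span_deg > 0 and spec.infarct_wedge is not None:
        w = spec.infarct_wedge
        mid = (w.angle_start_deg + (w.angle_end_deg - w.angle_start_deg) % 360.0 / 2.0)
        theta = np.degrees(np.arctan2(ym, xm))
        half = span_deg / 2.0
        dtheta = (theta - mid + 180.0) % 360.0 - 180.0
        wedge = annulus & (np.abs(dtheta) <= half) & (rr <= r_out)
        img[wedge] = TTC_COLORS["infarct"]
    # ruler: bright band near the bottom with dark ticks every tick_mm
    band_top = image_px - 40
    img[band_top : band_top + 24, 20 : image_px - 20] = TTC_COLORS["ruler"]
    tick_px = tick_mm / mm_per_px
    col = 24.0
    while col < image_px - 24:
        c = int(round(col))
        img[band_top : band_top + 16, c : c + 2] = TTC_COLORS["tick"]
        col += tick_px
    return img
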