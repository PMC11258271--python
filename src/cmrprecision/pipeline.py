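"""Study orchestration: phantom cohorts, simulated observers, report bundles.

`make_demo_dataset` builds a small longitudinal phantom cohort that emulates
the study design — baseline plus three post-infarction timepoints with a
growing heart, increasing coil-to-LV distance (hence falling SNR), and an
infarct wedge from the first post-MI timepoint on. Two simulated "observers"
re-segment every scan: observer masks are boundary perturbations of the
truth (signed-distance shifts of sub-pixel to one-pixel magnitude) plus
optional jitter in which cardiac phases they call ED/ES — the two
variability sources that phase harmonization separates.

`run_study` runs every stage over such a cohort and writes the four report
tables (quality, function, scar-method agreement, observer agreement) plus a
JSON summary and a log; outputs are deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from . import repro_stats
from .function import FunctionReport, compute_function, harmonize_phases
from .image_io import ImageStack, write_mask_set, write_stack
from .phantom import (CoilModel, GroundTruth, InfarctWedge, PhantomSpec,
                      generate_cine_phantom, generate_lge_phantom)
from .quality import compute_distance_weight, quality_report
from .scar import fwhm_scar, manual_scar_size, nsd_scar, compare_methods

log = logging.getLogger("cmrprecision")


# -- cohort definition ---------------------------------------------------------

# Per-timepoint condition template mirroring the study course: EF collapses
# acutely then partially recovers; the heart and the coil distance grow.
TIMEPOINT_TEMPLATE = {
    "MRI1": {"ef_target": 66.0, "endo_ed": 16.0, "coil_distance_mm": 58.0, "infarct": False},
    "MRI2": {"ef_target": 45.0, "endo_ed": 19.0, "coil_distance_mm": 63.0, "infarct": True},
    "MRI3": {"ef_target": 49.0, "endo_ed": 20.0, "coil_distance_mm": 65.0, "infarct": True},
    "MRI4": {"ef_target": 50.0, "endo_ed": 24.0, "coil_distance_mm": 76.0, "infarct": True},
}

DEFAULT_CONFIG = {
    "subjects": ["A", "B", "C"],
    "timepoints": ["MRI1", "MRI2", "MRI3", "MRI4"],
    "rows": 160,
    "cols": 160,
    "n_slices": 6,
    "pixel_spacing_mm": 1.0,
    "n_phases": 10,
    "noise_sigma": 2.0,
    "observer_perturbation_px": 0.5,
    "observer_phase_jitter": 1,
    "infarct_fraction_target_pct": 20.0,
    "seed": 0,
}


@dataclass
class StudyLayout:
    """In-memory (optionally on-disk) longitudinal phantom cohort."""

    subjects: list[str]
    timepoints: list[str]
    scans: dict[tuple[str, str], dict] = field(default_factory=dict)
    root: Path | None = None

    def scan(self, subject: str, timepoint: str) -> dict:
        return self.scans[(subject, timepoint)]


def spec_for_scan(subject_index: int, timepoint: str, config: dict, seed: int) -> PhantomSpec:
    """Phantom spec for one subject/timepoint from the cohort template."""
    tpl = TIMEPOINT_TEMPLATE[timepoint]
    # small deterministic per-subject size variation
    size_scale = 1.0 + 0.06 * (subject_index - 1)
    endo_ed = tpl["endo_ed"] * size_scale
    # EF = 1 - (r_es/r_ed)^2 for a uniform cylinder
    endo_es = endo_ed * float(np.sqrt(1.0 - tpl["ef_target"] / 100.0))
    wedge = None
    if tpl["infarct"]:
        target = config["infarct_fraction_target_pct"]
        wedge = InfarctWedge(angle_start_deg=-60.0, angle_end_deg=60.0,
                             transmurality=target / 100.0 * 360.0 / 120.0)
    d = tpl["coil_distance_mm"]
    fov_r = config["rows"] * config["pixel_spacing_mm"]
    coil = CoilModel(
        element_positions_mm=[(fov_r / 2.0 - d, fov_r / 2.0, z)
                              for z in np.linspace(0, config["n_slices"] * 6.0, 4)],
        decay_mm=90.0,
    )
    return PhantomSpec(
        n_slices=config["n_slices"], rows=config["rows"], cols=config["cols"],
        pixel_spacing=(config["pixel_spacing_mm"],) * 2,
        n_phases=config["n_phases"],
        endo_radius_ed=endo_ed, endo_radius_es=endo_es, wall_thickness_ed=9.0,
        papillary=[((endo_ed * 0.45, endo_ed * 0.2), 2.5),
                   ((-endo_ed * 0.4, endo_ed * 0.3), 2.0)],
        infarct_wedge=wedge,
        noise_sigma=config["noise_sigma"],
        coil_model=coil,
        seed=seed,
    )


# -- simulated observers -------------------------------------------------------


def perturb_mask(mask: np.ndarray, magnitude_px: float, rng: np.random.Generator) -> np.ndarray:
    """Shift a mask boundary by a random signed distance per slice.

    The boundary of each slice's mask moves inward/outward by an offset drawn
    from N(0, magnitude_px), implemented on the signed Euclidean distance
    transform referenced to the half-pixel surface (innermost pixels sit at
    +0.5, nearest outside pixels at −0.5). Magnitude 0 returns the mask
    unchanged; sub-pixel magnitudes produce the occasional one-pixel boundary
    change, mimicking contouring variability.
    """
    mask = np.asarray(mask, bool)
    if magnitude_px == 0:
        return mask.copy()
    out = np.zeros_like(mask)
    for s in range(mask.shape[0]):
        if not mask[s].any():
            continue
        sd = ndimage.distance_transform_edt(mask[s]) - ndimage.distance_transform_edt(~mask[s])
        sd -= 0.5 * np.sign(sd)  # boundary surface lies between pixel centers
        out[s] = sd > rng.normal(0.0, magnitude_px)
    return out


def simulate_observer(truth: GroundTruth, magnitude_px: float, phase_jitter: int,
                      rng: np.random.Generator, pixel_spacing, slice_thickness_mm) -> FunctionReport:
    """One observer's function report from perturbed contours and phase choice."""
    endo = [perturb_mask(m["blood_pool"], magnitude_px, rng) for m in truth.label_masks]
    myo = [perturb_mask(m["myocardium"], magnitude_px, rng) for m in truth.label_masks]
    report = compute_function(endo, myo, pixel_spacing, slice_thickness_mm)
    if phase_jitter:
        n = len(endo)
        es = int(np.clip(report.es_phase + rng.integers(-phase_jitter, phase_jitter + 1), 0, n - 1))
        ed = int(np.clip(report.ed_phase + rng.integers(-phase_jitter, phase_jitter + 1), 0, n - 1))
        report = compute_function(endo, myo, pixel_spacing, slice_thickness_mm, phases=(ed, es))
    report.per_slice_area_mm2["_masks"] = (endo, myo)  # kept for harmonization
    return report


# -- auto segmentation (noisy phantoms) ----------------------------------------


def segment_cine_auto(stack: ImageStack) -> list[np.ndarray]:
    """Threshold-based cavity segmentation of a (possibly noisy) cine stack.

    Per phase: a three-class Otsu split (background / myocardium / blood)
    labels the bright cavity, each slice keeps its largest connected
    component, and per-slice hole filling folds papillary muscle back into
    the cavity (papillary is conventionally part of the blood-pool contour).
    Returns per-phase endocardial masks.
    """
    if stack.voxels.ndim != 4:
        raise ValueError("expected a phase-resolved cine stack")
    masks = []
    for p in range(stack.n_phases):
        vol = stack.voxels[..., p]
        thr = threshold_multiotsu(vol, classes=3)[-1]
        cavity = vol > thr
        out = np.zeros_like(cavity)
        for s in range(cavity.shape[0]):
            lab, n = ndimage.label(cavity[s])
            if n == 0:
                continue
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
            keep = lab == (1 + int(np.argmax(sizes)))
            out[s] = ndimage.binary_fill_holes(keep)
        masks.append(out)
    return masks


# -- study runner --------------------------------------------------------------


def make_demo_dataset(seed: int = 0, out_dir: str | Path | None = None,
                      config: dict | None = None) -> StudyLayout:
    """Generate the longitudinal phantom cohort (optionally written to disk).

    Each scan entry carries the cine stack, ground truth, an LGE stack for
    post-MI timepoints, and two simulated observer function reports. With
    ``out_dir`` set, stacks go to NIfTI and truth masks to per-slice PNGs
    under ``<out>/<subject>/<timepoint>/``.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {}), "seed": seed}
    rng = np.random.default_rng(seed)
    layout = StudyLayout(subjects=list(cfg["subjects"]), timepoints=list(cfg["timepoints"]),
                         root=Path(out_dir) if out_dir else None)
    spacing = (cfg["pixel_spacing_mm"],) * 2
    for si, subject in enumerate(layout.subjects):
        for timepoint in layout.timepoints:
            scan_seed = int(rng.integers(0, 2**31 - 1))
            spec = spec_for_scan(si, timepoint, cfg, scan_seed)
            cine, truth = generate_cine_phantom(spec)
            obs_rngs = [np.random.default_rng(scan_seed + 1), np.random.default_rng(scan_seed + 2)]
            observers = [
                simulate_observer(truth, cfg["observer_perturbation_px"],
                                  cfg["observer_phase_jitter"] if i == 1 else 0,
                                  obs_rngs[i], spacing, spec.slice_thickness_mm)
                for i in range(2)
            ]
            entry = {"spec": spec, "cine": cine, "truth": truth, "observers": observers,
                     "coil_distance_mm": TIMEPOINT_TEMPLATE[timepoint]["coil_distance_mm"]}
            if spec.infarct_wedge is not None:
                lge_spec = PhantomSpec(**{**spec.__dict__, "noise_sigma": cfg["noise_sigma"]})
                entry["lge"], entry["lge_truth"] = generate_lge_phantom(lge_spec, source="psir")
            layout.scans[(subject, timepoint)] = entry
            if layout.root is not None:
                scan_dir = layout.root / subject / timepoint
                write_stack(cine, scan_dir / "cine.nii.gz")
                for p, masks in enumerate(truth.label_masks):
                    write_mask_set(masks, scan_dir / "masks", phase_index=p)
                if "lge" in entry:
                    write_stack(entry["lge"], scan_dir / "lge.nii.gz")
                    write_mask_set(entry["lge_truth"].label_masks[0], scan_dir / "lge_masks")
    return layout


def _scar_rois(truth: GroundTruth, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Reference ROIs for semi-automatic scar methods, from the truth masks.

    The FWHM ROI samples the brightest scar (a few voxels inside the hyper
    label); the remote ROI samples healthy myocardium away from the wedge.
    """
    masks = truth.label_masks[0]
    hyper = masks["infarct_hyper"]
    myo = masks["myocardium"]
    remote_candidates = np.argwhere(myo & ~hyper & ~masks["infarct_hypo"])
    hyper_candidates = np.argwhere(hyper)
    fwhm_roi = np.zeros_like(hyper)
    remote_roi = np.zeros_like(hyper)
    for roi, cand, k in ((fwhm_roi, hyper_candidates, 30), (remote_roi, remote_candidates, 60)):
        sel = cand[rng.choice(len(cand), size=min(k, len(cand)), replace=False)]
        roi[tuple(sel.T)] = True
    return fwhm_roi, remote_roi


def run_study(config: dict | str | Path | None = None, seed: int = 0,
              out_dir: str | Path = "results/study") -> dict:
    """Run every analysis stage over a demo cohort and write the report bundle.

    Emits ``quality.csv`` (per-scan BTC/σ/SNR/W_d), ``function.csv`` (EF,
    volumes, mass per scan and observer), ``scar_methods.csv`` (infarct size
    per method with agreement vs manual), ``agreement.csv`` (per-metric
    observer statistics), ``summary.json`` and ``study.log``. Stages missing
    their inputs (e.g. no infarct at baseline) are skipped with a logged
    reason. Returns the summary dict.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "study.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_study_inner(cfg, seed, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_study_inner(cfg: dict, seed: int, out: Path) -> dict:
    layout = make_demo_dataset(seed=seed, config=cfg)
    spacing = (cfg["pixel_spacing_mm"],) * 2
    d_max = max(e["coil_distance_mm"] for e in layout.scans.values())
    rng = np.random.default_rng(seed + 1)

    quality_rows, function_rows, scar_rows = [], [], []
    manual_series, method_series = [], {m: [] for m in ("FWHM", "SD3", "SD5", "SD7")}
    ef_pairs = {"A_obs": [], "B_obs": [], "B_harmonized": [], "truth": []}

    for (subject, timepoint), entry in layout.scans.items():
        spec, truth = entry["spec"], entry["truth"]
        ed = truth.ed_phase
        masks_ed = truth.label_masks[ed]
        qr = quality_report(entry["cine"].voxels[..., ed],
                            masks_ed["myocardium"], masks_ed["blood_pool"])
        d_corr, w_d = compute_distance_weight(entry["coil_distance_mm"], 0.0, d_max)
        quality_rows.append({
            "subject": subject, "timepoint": timepoint, "dBTC": qr.btc,
            "sigma_noise": qr.sigma_noise, "dSNR": qr.snr_myo,
            "distance_C_LV_mm": entry["coil_distance_mm"], "W_d": w_d,
        })
        log.info("quality %s %s: BTC=%.2f SNR=%.1f W_d=%.2f", subject, timepoint, qr.btc,
                 qr.snr_myo, w_d)

        obs_a, obs_b = entry["observers"]
        endo_b, myo_b = obs_b.per_slice_area_mm2["_masks"]
        harmonized_b = harmonize_phases(obs_a, endo_b, myo_b, spacing, spec.slice_thickness_mm)
        ef_pairs["A_obs"].append(obs_a.ef_pct)
        ef_pairs["B_obs"].append(obs_b.ef_pct)
        ef_pairs["B_harmonized"].append(harmonized_b.ef_pct)
        ef_pairs["truth"].append(truth.true_ef_pct)
        for name, rep in (("obs1", obs_a), ("obs2", obs_b), ("obs2_harmonized", harmonized_b)):
            function_rows.append({
                "subject": subject, "timepoint": timepoint, "observer": name,
                "EF_pct": rep.ef_pct, "EDV_ml": rep.edv_ml, "ESV_ml": rep.esv_ml,
                "SV_ml": rep.sv_ml, "ED_mass_g": rep.ed_mass_g,
                "ed_phase": rep.ed_phase, "es_phase": rep.es_phase,
                "true_EF_pct": truth.true_ef_pct,
            })

        if "lge" not in entry:
            log.info("scar %s %s: skipped (no infarct at this timepoint)", subject, timepoint)
            continue
        lge, lge_truth = entry["lge"], entry["lge_truth"]
        lmask = lge_truth.label_masks[0]
        fwhm_roi, remote_roi = _scar_rois(lge_truth, rng)
        reports = {
            "manual": manual_scar_size(lmask["myocardium"], lmask["infarct_hyper"],
                                       lmask["infarct_hypo"], spacing, spec.slice_thickness_mm),
            "FWHM": fwhm_scar(lge.voxels, lmask["myocardium"], fwhm_roi, spacing,
                              spec.slice_thickness_mm),
        }
        for n_sd in (3, 5, 7):
            reports[f"SD{n_sd}"] = nsd_scar(lge.voxels, lmask["myocardium"], remote_roi,
                                            n_sd, spacing, spec.slice_thickness_mm)
        manual_series.append(reports["manual"].infarct_fraction_pct)
        for m in method_series:
            method_series[m].append(reports[m].infarct_fraction_pct)
        for method, rep in reports.items():
            scar_rows.append({
                "subject": subject, "timepoint": timepoint, "method": method,
                "infarct_fraction_pct": rep.infarct_fraction_pct,
                "infarct_mass_g": rep.infarct_mass_g,
                "true_fraction_pct": lge_truth.true_infarct_fraction_pct,
            })

    # agreement statistics on EF
    agreement_rows = []
    for label, b_key in (("inter_observer", "B_obs"), ("inter_observer_harmonized", "B_harmonized")):
        rep = repro_stats.agreement_report(ef_pairs["A_obs"], ef_pairs[b_key])
        agreement_rows.append({"comparison": label, "metric": "EF_pct",
                               **{k: getattr(rep, k) for k in
                                  ("n_pairs", "cov_pct", "pooled_sd", "pearson_r", "icc",
                                   "bias", "loa_lower", "loa_upper")}})
    if len(manual_series) >= 3:
        method_agreement = compare_methods(manual_series, method_series)
    else:
        method_agreement = {}
        log.info("scar method agreement skipped: %d paired values (< 3)", len(manual_series))

    q_df = pd.DataFrame(quality_rows).sort_values(["subject", "timepoint"])
    f_df = pd.DataFrame(function_rows).sort_values(["subject", "timepoint", "observer"])
    s_df = pd.DataFrame(scar_rows)
    a_df = pd.DataFrame(agreement_rows)
    q_df.to_csv(out / "quality.csv", index=False, float_format="%.6g")
    f_df.to_csv(out / "function.csv", index=False, float_format="%.6g")
    s_df.to_csv(out / "scar_methods.csv", index=False, float_format="%.6g")
    a_df.to_csv(out / "agreement.csv", index=False, float_format="%.6g")

    harm = repro_stats.agreement_report(ef_pairs["A_obs"], ef_pairs["B_harmonized"])
    unharm = repro_stats.agreement_report(ef_pairs["A_obs"], ef_pairs["B_obs"])
    baseline_ef = f_df[(f_df.timepoint == "MRI1") & (f_df.observer == "obs1")].EF_pct.mean()
    post = f_df[(f_df.timepoint != "MRI1") & (f_df.observer == "obs1")]
    summary = {
        "n_scans": len(layout.scans),
        "mean_EF_baseline_pct": float(baseline_ef),
        "mean_EF_post_MI_pct": float(post.EF_pct.mean()) if len(post) else None,
        "EF_cov_interobserver_pct": unharm.cov_pct,
        "EF_cov_interobserver_harmonized_pct": harm.cov_pct,
        "EF_pooled_sd_harmonized": harm.pooled_sd,
        "scar_method_agreement": method_agreement,
        "seed": seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log.info("study complete: %d scans -> %s", len(layout.scans), out)
    return summary
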