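#!/usr/bin/env python
"""Ejection-fraction recovery: truth masks vs image-derived segmentation.

One phantom designed for EF 66% (the healthy baseline value) is analyzed
three ways: analytic truth, slice summation over the truth masks, and
threshold auto-segmentation of the Rician-noisy images at myocardial
SNR ~ 50. Writes results/function_recovery.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cmrprecision.function import compute_function
from cmrprecision.phantom import PhantomSpec, generate_cine_phantom
from cmrprecision.pipeline import segment_cine_auto

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    spec = PhantomSpec(n_slices=6, rows=128, cols=128, pixel_spacing=(0.8, 0.8),
                       n_phases=10, endo_radius_ed=18.0,
                       endo_radius_es=18.0 * float(np.sqrt(0.34)),
                       wall_thickness_ed=9.0, papillary=[((6.0, 3.0), 2.5)],
                       seed=seed)
    _, truth = generate_cine_phantom(spec)
    mask_rep = compute_function([m["blood_pool"] for m in truth.label_masks],
                                [m["myocardium"] for m in truth.label_masks],
                                spec.pixel_spacing, spec.slice_thickness_mm)

    noisy_spec = PhantomSpec(**{**spec.__dict__, "noise_sigma": 2.0})
    stack, _ = generate_cine_phantom(noisy_spec)
    auto_rep = compute_function(segment_cine_auto(stack), None,
                                spec.pixel_spacing, spec.slice_thickness_mm)

    df = pd.DataFrame([
        {"route": "analytic truth", "EF_pct": truth.true_ef_pct,
         "EDV_ml": truth.true_edv_ml, "ESV_ml": truth.true_esv_ml,
         "mass_g": truth.true_mass_g},
        {"route": "truth masks (noiseless)", "EF_pct": mask_rep.ef_pct,
         "EDV_ml": mask_rep.edv_ml, "ESV_ml": mask_rep.esv_ml,
         "mass_g": mask_rep.ed_mass_g},
        {"route": "auto segmentation (SNR~50)", "EF_pct": auto_rep.ef_pct,
         "EDV_ml": auto_rep.edv_ml, "ESV_ml": auto_rep.esv_ml,
         "mass_g": float("nan")},
    ])
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "function_recovery.csv", index=False, float_format="%.4f")
    print(df.to_string(index=False))
    err_mask = abs(mask_rep.ef_pct - truth.true_ef_pct)
    err_auto = abs(auto_rep.ef_pct - truth.true_ef_pct)
    print(f"\nEF error: {err_mask:.2f} points from truth masks (discretization), "
          f"{err_auto:.2f} points from noisy auto-segmentation.")
    print(f"Wrote {RESULTS / 'function_recovery.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
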