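#!/usr/bin/env python
"""Infarct sizing on the LGE phantom: manual vs FWHM vs 3/5/7 SD.

A sharp-wedge phantom with exactly 20% infarct (120° sector, transmural
area fraction 0.6) plus a hypo-core variant are quantified with every
method, on PSIR and magnitude reconstructions. Writes
results/scar_method_comparison.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cmrprecision.phantom import InfarctWedge, PhantomSpec, generate_lge_phantom
from cmrprecision.scar import fwhm_scar, manual_scar_size, nsd_scar

RESULTS = Path(__file__).resolve().parents[1] / "results"


def quantify(spec, source, seed):
    stack, truth = generate_lge_phantom(spec, source=source)
    masks = truth.label_masks[0]
    rng = np.random.default_rng(seed)
    roi = np.zeros_like(masks["infarct_hyper"])
    idx = np.argwhere(masks["infarct_hyper"])
    roi[tuple(idx[rng.choice(len(idx), 40, replace=False)].T)] = True
    remote = masks["myocardium"] & ~masks["infarct_hyper"] & ~masks["infarct_hypo"]
    args = (spec.pixel_spacing, spec.slice_thickness_mm)
    reports = {"manual": manual_scar_size(masks["myocardium"], masks["infarct_hyper"],
                                          masks["infarct_hypo"], *args),
               "FWHM": fwhm_scar(stack.voxels, masks["myocardium"], roi, *args)}
    for n in (3, 5, 7):
        reports[f"SD{n}"] = nsd_scar(stack.voxels, masks["myocardium"], remote, n, *args)
    return truth, reports


def main(seed: int = 1) -> None:
    rows = []
    for label, core in (("sharp wedge", 0.0), ("with hypo core", 0.4)):
        spec = PhantomSpec(n_slices=5, rows=160, cols=160, pixel_spacing=(0.6, 0.6),
                           endo_radius_ed=18.0, endo_radius_es=11.0,
                           wall_thickness_ed=9.0,
                           infarct_wedge=InfarctWedge(-60.0, 60.0, 0.6,
                                                      hypo_core_fraction=core),
                           noise_sigma=1.5, seed=seed)
        for source in ("psir", "magnitude"):
            truth, reports = quantify(spec, source, seed + 5)
            for method, rep in reports.items():
                rows.append({"phantom": label, "source": source, "method": method,
                             "infarct_fraction_pct": rep.infarct_fraction_pct,
                             "infarct_mass_g": rep.infarct_mass_g,
                             "true_fraction_pct": truth.true_infarct_fraction_pct})
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "scar_method_comparison.csv", index=False, float_format="%.4f")
    print(df.to_string(index=False))
    sharp = df[(df.phantom == "sharp wedge") & (df.source == "psir")]
    fwhm_err = abs(sharp[sharp.method == "FWHM"].infarct_fraction_pct.iloc[0] - 20.0)
    core = df[(df.phantom == "with hypo core") & (df.source == "psir")]
    print(f"\nSharp wedge (PSIR): FWHM within {fwhm_err:.2f} points of the 20% truth.")
    print("Hypo-core phantom: manual "
          f"{core[core.method == 'manual'].infarct_fraction_pct.iloc[0]:.1f}% vs FWHM "
          f"{core[core.method == 'FWHM'].infarct_fraction_pct.iloc[0]:.1f}% — "
          "thresholding misses the dark core unless the morphological fill is enabled.")
    print(f"Wrote {RESULTS / 'scar_method_comparison.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
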