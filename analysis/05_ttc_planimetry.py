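#!/usr/bin/env python
"""TTC photo planimetry: ruler calibration, per-view totals, face diagnostics.

Renders both faces of every 5 mm slice of a wedge phantom (with an apically
narrowing infarct), calibrates each photo from its ruler, auto-segments red
(viable) vs white (infarct), and computes per-view totals plus the
line-of-sight and sawing-discontinuity metrics. Writes
results/ttc_planimetry.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from cmrprecision.phantom import InfarctWedge, PhantomSpec, generate_ttc_photos
from cmrprecision.ttc import (discontinuity_and_view_metrics, quantify_photo,
                              ttc_infarct_size)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    spec = PhantomSpec(n_slices=5, endo_radius_ed=15.0, endo_radius_es=11.0,
                       wall_thickness_ed=8.0,
                       infarct_wedge=InfarctWedge(-45.0, 45.0, 1.0), seed=seed)
    photos = generate_ttc_photos(spec, apical_taper=0.5)
    results = [quantify_photo(p.image, p.view, p.slice_index) for p in photos]
    df = pd.DataFrame([{
        "view": r.view, "slice": r.slice_index, "mm_per_px": r.mm_per_px,
        "lv_area_mm2": r.lv_area_mm2, "infarct_area_mm2": r.infarct_area_mm2,
        "true_infarct_area_mm2": p.true_infarct_area_mm2,
    } for r, p in zip(results, photos)])
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "ttc_planimetry.csv", index=False, float_format="%.4f")

    totals = ttc_infarct_size(results)
    metrics = discontinuity_and_view_metrics(results)
    print(df.to_string(index=False))
    print(f"\nInfarct fraction: top {totals['top']['infarct_fraction_pct']:.2f}% / "
          f"bottom {totals['bottom']['infarct_fraction_pct']:.2f}% / "
          f"mean of views {totals['mean_of_views']['infarct_fraction_pct']:.2f}% "
          f"(cone narrows apically, so top > bottom).")
    print(f"Line-of-sight effect per slice (max |.|): "
          f"{abs(metrics['line_of_sight']).max():.4f} of total infarct;")
    print(f"sawing discontinuity per cut (max |.|): "
          f"{abs(metrics['discontinuity']).max():.4f} — ~0 because the phantom's "
          f"cuts are lossless and the infarct is smooth.")
    print(f"Wrote {RESULTS / 'ttc_planimetry.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
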