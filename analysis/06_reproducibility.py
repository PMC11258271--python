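#!/usr/bin/env python
"""Observer agreement, phase harmonization, and what precision buys in sample size.

Simulates two observers (contour perturbation; observer B also calls
end-systole three phases early) on a six-subject phantom cohort, computes
CoV / pooled SD / ICC / Bland-Altman before and after phase harmonization,
and feeds the pooled SDs into the sample-size formula. Writes
results/reproducibility.csv and results/sample_size.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cmrprecision.function import compute_function, harmonize_phases
from cmrprecision.phantom import PhantomSpec, generate_cine_phantom
from cmrprecision.pipeline import perturb_mask
from cmrprecision.repro_stats import agreement_report, power_factor, sample_size

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    efs_a, efs_b, efs_harm = [], [], []
    for i in range(6):
        endo_ed = 13.0 + 0.7 * i
        spec = PhantomSpec(n_slices=4, rows=96, cols=96, pixel_spacing=(0.8, 0.8),
                           n_phases=30, endo_radius_ed=endo_ed,
                           endo_radius_es=endo_ed * float(np.sqrt(0.34)),
                           wall_thickness_ed=7.0, seed=seed * 50 + i)
        _, truth = generate_cine_phantom(spec)
        endo_a = [m["blood_pool"] for m in truth.label_masks]
        myo_a = [m["myocardium"] for m in truth.label_masks]
        rng = np.random.default_rng(seed * 60 + i)
        endo_b = [perturb_mask(m, 0.4, rng) for m in endo_a]
        myo_b = [perturb_mask(m, 0.4, rng) for m in myo_a]
        a = compute_function(endo_a, myo_a, spec.pixel_spacing, 6.0)
        b = compute_function(endo_b, myo_b, spec.pixel_spacing, 6.0,
                             phases=(a.ed_phase, a.es_phase - 3))
        harm = harmonize_phases(a, endo_b, myo_b, spec.pixel_spacing, 6.0)
        efs_a.append(a.ef_pct)
        efs_b.append(b.ef_pct)
        efs_harm.append(harm.ef_pct)

    rows = []
    for label, b_vals in (("pre-harmonization", efs_b), ("post-harmonization", efs_harm)):
        rep = agreement_report(efs_a, b_vals)
        rows.append({"comparison": label, **{k: getattr(rep, k) for k in (
            "n_pairs", "cov_pct", "pooled_sd", "pearson_r", "icc",
            "bias", "loa_lower", "loa_upper")},
            "mean_absdiff": float(np.mean(np.abs(np.array(efs_a) - np.array(b_vals))))})
    agree_df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    agree_df.to_csv(RESULTS / "reproducibility.csv", index=False, float_format="%.4f")
    print(agree_df.to_string(index=False))

    ss_rows = []
    for sigma in (agree_df.pooled_sd.iloc[1], 1.9, 1.0):
        spec_ss = sample_size(max(sigma, 1e-6), 3.0)
        ss_rows.append({"pooled_sd": sigma, "delta_EF_pct": 3.0,
                        "f": spec_ss.f, "n_per_group": spec_ss.n})
    ss_df = pd.DataFrame(ss_rows)
    ss_df.to_csv(RESULTS / "sample_size.csv", index=False, float_format="%.4f")
    print()
    print(ss_df.to_string(index=False))
    print(f"\nPhase harmonization cut the mean |EF difference| from "
          f"{agree_df.mean_absdiff.iloc[0]:.2f} to {agree_df.mean_absdiff.iloc[1]:.2f} "
          f"points. f(0.05, 0.90) = {power_factor():.2f}; pooled SDs of 1.9 and 1.0 "
          f"EF points need {ss_df.n_per_group.iloc[1]} and {ss_df.n_per_group.iloc[2]} "
          f"subjects per group to detect a 3-point EF change.")
    print(f"Wrote {RESULTS / 'reproducibility.csv'} and {RESULTS / 'sample_size.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
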