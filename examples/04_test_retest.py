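"""Segmentation test-retest: how stable are BP_ND and ROI volume?

Each synthetic subject is one PET scan quantified under two independently
perturbed segmentations (emulating automated segmentation of two repeated
MRI acquisitions). Regional volumes swing by several percent between the
two runs, while the binding potentials barely move — the contrast that
justifies automated-ROI quantification.
"""

import numpy as np

from pibquant.phantom import build_testretest_cohort
from pibquant.pipeline import testretest_cohort, testretest_to_frame

subjects, truths = build_testretest_cohort(n_subjects=4, seed=7)
results, long = testretest_cohort(subjects)

vols = long.groupby("region")["volume"].mean()
print(f"{'region':28s} {'voxels':>7s} {'dBP%':>7s} {'dVOL%':>7s} {'ICC_BP':>7s}")
for r in sorted(results, key=lambda r: -r.delta_vol_pct):
    if vols[r.region] < 500 or r.delta_vol_pct == 0:
        continue
    icc = f"{r.icc_bp:.4f}" if r.icc_bp is not None else "  n/a"
    print(f"{r.region:28s} {vols[r.region]:7.0f} {r.delta_bp_pct:7.3f} "
          f"{r.delta_vol_pct:7.2f} {icc:>7s}")

cortical = [r for r in results if vols[r.region] >= 500 and r.delta_vol_pct > 0]
print(f"\nmean dVOL% = {np.mean([r.delta_vol_pct for r in cortical]):.2f}   "
      f"max dBP% = {max(r.delta_bp_pct for r in cortical):.3f}")
print("BP_ND is an order of magnitude more stable than the ROI volumes that feed it.")
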