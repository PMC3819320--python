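"""Two-component (brain vs CSF) partial-volume correction.

A region near CSF loses apparent activity because the scanner's point
spread function mixes in cold CSF signal. The correction computes, per
region, the mean of the PSF-smoothed brain mask (the "CSF dilution
factor") and divides the regional TAC by it before kinetic fitting.

The first part verifies the factor against the analytic Gaussian-blurred
half-space; the second runs PVC inside the full pipeline on a blurred
phantom and shows the corrected MCBP moving back toward truth.
"""

import numpy as np
from scipy.special import erf

import pibquant as pq
from pibquant.io import LabelVolume
from pibquant.pipeline import RunConfig
from pibquant.pvc import FWHM_TO_SIGMA, dilution_factors
from pibquant.regions import RegionSet, RegionSpec

# --- analytic check: slab 3 mm below a brain/CSF boundary, 6 mm PSF ---
grid = np.zeros((40, 40, 60), np.int32)
grid[14:26, 14:26, 28] = 1
vol = LabelVolume(labels=grid, lut={1: "slab"})
mask = np.zeros((40, 40, 60))
mask[:, :, :30] = 1.0
rs = RegionSet(specs=[RegionSpec("slab", frozenset({1}))])
factor = dilution_factors(mask, vol, rs, psf_fwhm_mm=6.0, voxel_size_mm=(2, 2, 2))["slab"]
sigma = 6.0 * FWHM_TO_SIGMA
analytic = 0.5 * (1 + erf((29.5 - 28) * 2.0 / (sigma * np.sqrt(2))))
print(f"slab dilution factor: measured {factor:.4f}, analytic erf {analytic:.4f}")

# --- pipeline: blurred phantom quantified with and without PVC ---
img, labels, truth = pq.build_phantom(pq.PhantomConfig(psf_fwhm_mm=6.0))
raw, _, _ = pq.quantify(img, labels, RunConfig(pvc=False))
pvc, _, _ = pq.quantify(img, labels, RunConfig(pvc=True, psf_fwhm_mm=6.0))
print(f"\nground-truth MCBP      : {truth.mcbp_true:.4f}")
print(f"MCBP without PVC       : {raw.mcbp:.4f}   (blur dilutes cortical signal)")
print(f"MCBP with PVC          : {pvc.mcbp:.4f}")
print(f"example factors        : " + ", ".join(
    f"{k}={v:.3f}" for k, v in list(pvc.dilution_factors.items())[:4]))
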