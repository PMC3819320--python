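"""Two-component (brain vs CSF/background) partial-volume correction.

Limited PET resolution dilutes the signal of regions adjacent to CSF. The
two-component correction builds a binary brain-tissue mask from the
segmentation, smooths it with the scanner's point-spread function
(modelled as an isotropic Gaussian), and averages the smoothed mask over
each ROI. That average — the CSF dilution factor, in (0, 1] — is the
fraction of the region's signal originating in brain tissue; dividing the
raw regional TAC by it recovers the undiluted activity before kinetic
fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import LabelVolume
from .regions import RegionSet
from .tac import TimeActivityCurve

__all__ = [
    "PVCFactors",
    "brain_mask",
    "dilution_factors",
    "correct_tac",
    "DEFAULT_PSF_FWHM_MM",
    "FACTOR_FLOOR",
    "NON_BRAIN_NAMES",
]

DEFAULT_PSF_FWHM_MM = 6.0  # typical post-reconstruction resolution of an HR+ scan
FACTOR_FLOOR = 0.05  # guard against division blow-up in pathological masks
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# LUT names counted as non-brain when building the tissue mask. Matched
# against canonical (hemisphere-stripped) names, case-insensitively.
NON_BRAIN_NAMES = frozenset(
    s.lower()
    for s in (
        "CSF",
        "Lateral-Ventricle",
        "Inf-Lat-Vent",
        "3rd-Ventricle",
        "4th-Ventricle",
        "5th-Ventricle",
        "vessel",
        "choroid-plexus",
        "Unknown",
        "Background",
    )
)


@dataclass(frozen=True)
class PVCFactors:
    """Per-region CSF dilution factors for a given PSF width."""

    factors: dict[str, float]
    psf_fwhm_mm: float

    def __post_init__(self):
        bad = {k: v for k, v in self.factors.items() if not (0.0 < v <= 1.0 + 1e-12)}
        if bad:
            raise ValueError(f"dilution factors must lie in (0, 1]: {bad}")

    def __getitem__(self, region: str) -> float:
        return self.factors[region]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": list(self.factors), "dilution_factor": list(self.factors.values()),
             "psf_fwhm_mm": self.psf_fwhm_mm}
        )


def _is_brain(name: str, exclude: frozenset[str]) -> bool:
    canon = name.lower()
    for prefix in ("left-", "right-"):
        if canon.startswith(prefix):
            canon = canon[len(prefix):]
            break
    return canon not in exclude


def brain_mask(labels: LabelVolume, exclude_names=NON_BRAIN_NAMES) -> np.ndarray:
    """Binary mask of brain tissue: every named gray/white structure.

    CSF, ventricles, vessels, choroid plexus and background (label 0)
    are excluded; the exclusion list is configurable.
    """
    exclude = frozenset(s.lower() for s in exclude_names)
    brain_ids = [i for i, name in labels.lut.items() if _is_brain(name, exclude)]
    mask = np.isin(labels.labels, brain_ids)
    mask &= labels.labels != 0
    return mask


def dilution_factors(
    mask: np.ndarray,
    labels: LabelVolume,
    regionset: RegionSet,
    psf_fwhm_mm: float = DEFAULT_PSF_FWHM_MM,
    voxel_size_mm=(1.0, 1.0, 1.0),
) -> PVCFactors:
    """CSF dilution factor per ROI: ROI-mean of the PSF-smoothed brain mask.

    FWHM = 0 degenerates to the fraction of region voxels inside the mask.
    Factors are clamped to [FACTOR_FLOOR, 1] with a warning on clamping.
    """
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be non-negative")
    mask = np.asarray(mask, dtype=float)
    if mask.shape != labels.labels.shape:
        raise ValueError("mask and label volume must share a grid")
    if psf_fwhm_mm > 0:
        sigma_vox = [psf_fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size_mm]
        smoothed = gaussian_filter(mask, sigma=sigma_vox, mode="constant", cval=0.0)
    else:
        smoothed = mask

    factors: dict[str, float] = {}
    names = list(regionset.names) + list(regionset.composites)
    for name in names:
        spec = regionset.composite_spec(name) if name in regionset.composites else regionset[name]
        roi = labels.mask(spec.member_ids)
        if not roi.any():
            raise ValueError(f"empty region {name!r} in dilution-factor computation")
        f = float(smoothed[roi].mean())
        f = min(f, 1.0)
        if f < FACTOR_FLOOR:
            warnings.warn(
                f"dilution factor {f:.3g} for {name!r} below floor {FACTOR_FLOOR}; clamping",
                stacklevel=2,
            )
            f = FACTOR_FLOOR
        factors[name] = f
    return PVCFactors(factors=factors, psf_fwhm_mm=float(psf_fwhm_mm))


def correct_tac(tac: TimeActivityCurve, factor: float) -> TimeActivityCurve:
    """Divide a regional TAC frame-wise by its dilution factor."""
    if not factor > 0:
        raise ValueError(f"dilution factor must be positive, got {factor}")
    if factor > 1.0 + 1e-12:
        raise ValueError(f"dilution factor must be <= 1, got {factor}")
    return TimeActivityCurve(
        region=tac.region,
        values=tac.values / factor,
        mid_times=tac.mid_times,
        n_voxels=tac.n_voxels,
    )
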