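"""Digital dynamic-PiB phantom with known kinetic ground truth.

The phantom emulates a 60-minute dynamic PiB acquisition on a small grid:
an ellipsoidal brain with a cortical shell split into named FreeSurfer
parcels (left/right), white matter, caudate/putamen, lateral ventricles,
a sulcal CSF rim, a cerebellar reference region and a brainstem. The
cerebellar (reference) curve is generated by a one-tissue compartment
model driven by a gamma-variate arterial input; every other tissue region
follows the simplified reference tissue model (SRTM) with region-specific
R1, k2 and a known BP_ND, so the whole quantification pipeline can be
validated against generator truth. CSF activity is a small fixed fraction
of the reference curve (no specific binding, low delivery).

Voxel activities are frame averages of the fine-grid model curves.
Optional isotropic Gaussian PSF blur emulates scanner resolution, and
optional Gaussian noise with variance proportional to activity over frame
duration emulates count statistics.

``perturb_segmentation`` emulates the run-to-run variability of an
MRI-based segmentation: a fraction of each region's boundary voxels is
reassigned to adjacent labels, with a per-region random growth/shrink
bias. The pial (CSF) boundary is comparatively stable in practice, so
CSF, ventricles and background are frozen by default and exchange happens
between tissue labels only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import DynamicImage, FrameSchedule, LabelVolume, default_frame_schedule
from .kinetics import SRTMParams, _exp_conv_linear, cumtrapz_from_origin
from .pvc import FWHM_TO_SIGMA
from .regions import COMPOSITE_MEMBERS, MCBP_COMPOSITES

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "build_phantom",
    "build_geometry",
    "perturb_segmentation",
    "reference_curve",
    "frame_average",
    "DEFAULT_KINETICS",
]

SECONDS_PER_MINUTE = 60.0

# FreeSurfer wmparc-style label IDs used by the phantom geometry.
_CTX_INDEX = {
    "cuneus": 5,
    "lateralorbitofrontal": 12,
    "lingual": 13,
    "medialorbitofrontal": 14,
    "middletemporal": 15,
    "precuneus": 25,
    "rostralmiddlefrontal": 27,
    "superiorfrontal": 28,
    "superiortemporal": 30,
}
_SUBCORTICAL = {
    "Left-Cerebral-White-Matter": 2,
    "Right-Cerebral-White-Matter": 41,
    "Left-Lateral-Ventricle": 4,
    "Right-Lateral-Ventricle": 43,
    "Left-Cerebellum-Cortex": 8,
    "Right-Cerebellum-Cortex": 47,
    "Left-Caudate": 11,
    "Right-Caudate": 50,
    "Left-Putamen": 12,
    "Right-Putamen": 51,
    "Brain-Stem": 16,
    "CSF": 24,
}

# Cortical shell partition: (z-band, azimuth sector) -> parcel name.
_BAND_SECTORS = (
    ("superiortemporal", "middletemporal", "lingual"),
    ("lateralorbitofrontal", "medialorbitofrontal", "cuneus"),
    ("rostralmiddlefrontal", "superiorfrontal", "precuneus"),
)

# Region kinetics of the default phantom subject (an amyloid-positive
# pattern: high precuneus/prefrontal binding, low occipital binding).
# R1 near 1 for gray matter, lower for white matter; k2 near the
# protocol's 0.16/min reference washout.
DEFAULT_KINETICS: dict[str, SRTMParams] = {
    "ctx-rostralmiddlefrontal": SRTMParams(1.05, 0.17, 0.60),
    "ctx-superiorfrontal": SRTMParams(1.00, 0.16, 0.55),
    "ctx-lateralorbitofrontal": SRTMParams(0.95, 0.15, 0.50),
    "ctx-medialorbitofrontal": SRTMParams(1.00, 0.16, 0.45),
    "ctx-superiortemporal": SRTMParams(1.00, 0.16, 0.40),
    "ctx-middletemporal": SRTMParams(1.05, 0.17, 0.45),
    "ctx-lingual": SRTMParams(1.00, 0.16, 0.25),
    "ctx-cuneus": SRTMParams(0.95, 0.16, 0.20),
    "ctx-precuneus": SRTMParams(1.05, 0.16, 0.80),
    "Cerebral-White-Matter": SRTMParams(0.80, 0.14, 0.35),
    "Caudate": SRTMParams(0.95, 0.16, 0.50),
    "Putamen": SRTMParams(1.00, 0.17, 0.60),
    "Brain-Stem": SRTMParams(0.90, 0.15, 0.30),
    "Cerebellum-Cortex": SRTMParams(1.00, 0.16, 0.0),
}

REFERENCE_REGION = "Cerebellum-Cortex"

# Labels frozen during segmentation perturbation (stable pial boundary).
DEFAULT_FROZEN_NAMES = ("CSF", "Lateral-Ventricle", "Cerebellum-Cortex")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, kinetics and noise of one synthetic subject."""

    shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.5)
    schedule: FrameSchedule = field(default_factory=default_frame_schedule)
    kinetics: dict[str, SRTMParams] = field(default_factory=lambda: dict(DEFAULT_KINETICS))
    binding_scale: float = 1.0  # multiplies every bp_nd_true (0 -> null phantom)
    bp_smoothing_fwhm_mm: float = 12.0  # spatial smoothness of the binding field
    csf_fraction: float = 0.15  # CSF activity as a fraction of the reference curve
    psf_fwhm_mm: float = 0.0  # Gaussian PSF blur; 0 = no blur
    noise_sd: float = 0.0  # noise scale; variance ~ activity / frame duration
    fine_dt_s: float = 0.6  # fine simulation grid step
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be non-negative")
        if self.binding_scale < 0:
            raise ValueError("binding_scale must be non-negative")
        if not (0.0 <= self.csf_fraction < 1.0):
            raise ValueError("csf_fraction must be in [0, 1)")


@dataclass
class PhantomTruth:
    """Generator ground truth accompanying one phantom dataset."""

    kinetics: dict[str, SRTMParams]
    volumes: dict[str, int]
    mcbp_true: float
    psf_fwhm_mm: float
    noise_sd: float
    seed: int

    def to_json(self, path=None) -> str:
        payload = {
            "mcbp_true": self.mcbp_true,
            "psf_fwhm_mm": self.psf_fwhm_mm,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "volumes": self.volumes,
            "kinetics": {
                name: {"r1": p.r1, "k2_per_min": p.k2, "bp_nd_true": p.bp_nd_true}
                for name, p in self.kinetics.items()
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def plasma_input(t_min: np.ndarray, peak_time_min: float = 1.5, alpha: float = 2.0,
                 scale: float = 100.0) -> np.ndarray:
    """Gamma-variate arterial input peaking at ``peak_time_min``."""
    t = np.asarray(t_min, dtype=float)
    beta = peak_time_min / alpha
    with np.errstate(invalid="ignore"):
        c = scale * (t / peak_time_min) ** alpha * np.exp(alpha * (1.0 - t / peak_time_min))
    return np.nan_to_num(c, nan=0.0)


def reference_curve(
    duration_min: float = 3605.0 / SECONDS_PER_MINUTE,
    fine_dt_s: float = 0.6,
    k1: float = 0.12,
    k2_ref: float = 0.16,
) -> tuple[np.ndarray, np.ndarray]:
    """Fine-grid cerebellar (reference) curve: 1-tissue model on a gamma input.

    Returns (t_min, C_R). k2_ref defaults to the protocol's 0.16/min so the
    fixed washout assumed by the Logan fit is exact for the phantom.
    """
    dt_min = fine_dt_s / SECONDS_PER_MINUTE
    n = int(np.ceil(duration_min / dt_min)) + 1
    t = np.arange(n) * dt_min
    cp = plasma_input(t)
    cr = k1 * _exp_conv_linear(t, cp, k2_ref)
    return t, cr


def frame_average(t_min: np.ndarray, curve: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each acquisition frame."""
    tt = np.asarray(t_min, dtype=float)
    integral = cumtrapz_from_origin(tt, np.asarray(curve, dtype=float))
    starts = schedule.starts / SECONDS_PER_MINUTE
    ends = (schedule.starts + schedule.durations) / SECONDS_PER_MINUTE
    if ends[-1] > tt[-1] + 1e-9:
        raise ValueError("fine grid does not cover the full frame schedule")
    i_start = np.interp(starts, tt, integral)
    i_end = np.interp(ends, tt, integral)
    return (i_end - i_start) / (ends - starts)


def _ellipsoid(grid, center, semi):
    x, y, z = grid
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    )


def build_geometry(shape=(64, 64, 48)) -> LabelVolume:
    """Labeled phantom anatomy on the given grid.

    An ellipsoidal cerebrum (cortical shell over white matter, with
    ventricles, caudate and putamen), a sulcal CSF rim, a cerebellar
    ellipsoid below, and a brainstem column. All structures are split
    left/right where FreeSurfer names are hemispheric.
    """
    nx, ny, nz = shape
    grid = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy = nx / 2.0, ny / 2.0
    labels = np.zeros(shape, dtype=np.int32)

    brain_center = (cx, cy, 0.62 * nz)
    brain_semi = (0.40 * nx, 0.44 * ny, 0.30 * nz)
    rho2 = _ellipsoid(grid, brain_center, brain_semi)
    left = grid[0] < cx

    # sulcal CSF rim just outside the pial surface
    labels[(rho2 > 1.0) & (rho2 <= 1.12**2)] = _SUBCORTICAL["CSF"]

    # white matter interior
    wm = rho2 <= 0.9**2
    labels[wm & left] = _SUBCORTICAL["Left-Cerebral-White-Matter"]
    labels[wm & ~left] = _SUBCORTICAL["Right-Cerebral-White-Matter"]

    # cortical shell partitioned into (z-band, azimuth-sector) parcels
    shell = (rho2 > 0.9**2) & (rho2 <= 1.0)
    zn = (grid[2] - (brain_center[2] - brain_semi[2])) / (2.0 * brain_semi[2])
    band = np.clip(np.digitize(zn, [0.38, 0.66]), 0, 2)
    theta = np.arctan2(grid[1] - cy, grid[0] - cx)
    sector = np.clip((3 * (theta + np.pi) / (2 * np.pi + 1e-9)).astype(int), 0, 2)
    for b in range(3):
        for s in range(3):
            name = _BAND_SECTORS[b][s]
            idx = _CTX_INDEX[name]
            sel = shell & (band == b) & (sector == s)
            labels[sel & left] = 1000 + idx
            labels[sel & ~left] = 2000 + idx

    # central structures overwrite white matter
    vent = _ellipsoid(grid, (cx, cy, brain_center[2]), (5, 7, 4)) <= 1.0
    labels[vent & left] = _SUBCORTICAL["Left-Lateral-Ventricle"]
    labels[vent & ~left] = _SUBCORTICAL["Right-Lateral-Ventricle"]
    for side, xoff in (("Left", -0.14 * nx), ("Right", 0.14 * nx)):
        cau = _ellipsoid(grid, (cx + xoff, cy + 4, brain_center[2] + 2), (3, 3, 2.5)) <= 1.0
        put = _ellipsoid(grid, (cx + 1.6 * xoff, cy - 2, brain_center[2]), (3, 3.5, 2.5)) <= 1.0
        labels[cau] = _SUBCORTICAL[f"{side}-Caudate"]
        labels[put] = _SUBCORTICAL[f"{side}-Putamen"]

    # cerebellum below the cerebrum; brainstem column in front of it
    cereb = _ellipsoid(grid, (cx, cy + 0.16 * ny, 0.19 * nz), (0.20 * nx, 0.16 * ny, 0.125 * nz))
    sel = cereb <= 1.0
    labels[sel & left] = _SUBCORTICAL["Left-Cerebellum-Cortex"]
    labels[sel & ~left] = _SUBCORTICAL["Right-Cerebellum-Cortex"]
    bs = (
        ((grid[0] - cx) ** 2 + (grid[1] - (cy - 0.125 * ny)) ** 2 <= (0.075 * nx) ** 2)
        & (grid[2] >= 0.04 * nz)
        & (grid[2] < 0.31 * nz)
    )
    labels[bs] = _SUBCORTICAL["Brain-Stem"]

    lut = dict(_SUBCORTICAL_LUT)
    return LabelVolume(labels=labels, lut=lut)


_SUBCORTICAL_LUT = {v: k for k, v in _SUBCORTICAL.items()}
for _name, _idx in _CTX_INDEX.items():
    _SUBCORTICAL_LUT[1000 + _idx] = f"ctx-lh-{_name}"
    _SUBCORTICAL_LUT[2000 + _idx] = f"ctx-rh-{_name}"


def _canonical(name: str) -> str:
    for prefix in ("ctx-lh-", "ctx-rh-"):
        if name.startswith(prefix):
            return "ctx-" + name[len(prefix):]
    for prefix in ("Left-", "Right-"):
        if name.startswith(prefix):
            return name[len(prefix):]
    return name


def _truth_mcbp(effective: dict[str, SRTMParams], volumes: dict[str, int]) -> float:
    comp_bp = []
    for comp in MCBP_COMPOSITES:
        members = COMPOSITE_MEMBERS[comp]
        w = np.array([volumes[m] for m in members], dtype=float)
        bp = np.array([effective[m].bp_nd_true for m in members])
        comp_bp.append(float((w * bp).sum() / w.sum()))
    return float(np.mean(comp_bp))


_BP_QUANTUM = 0.01  # binding-field quantization step for TAC synthesis


def build_phantom(config: PhantomConfig | None = None) -> tuple[DynamicImage, LabelVolume, PhantomTruth]:
    """Generate one synthetic dynamic PiB subject with ground truth.

    The binding field is the per-parcel BP_ND values smoothed over the
    cerebral tissue mask (amyloid deposition varies smoothly in space, so
    kinetics are continuous across parcel borders even where parcel means
    differ) and quantized in steps of 0.01 for TAC synthesis. R1 and k2
    stay at their parcel values. The cerebellar reference and CSF spaces
    are excluded from the field: the reference stays exactly BP_ND = 0.

    Ground-truth regional BP_ND is the mean of the quantized field over
    the region's voxels. Deterministic for a fixed config (all randomness
    flows from ``config.seed``).
    """
    from .kinetics import srtm_tac

    config = config or PhantomConfig()
    vol = build_geometry(config.shape)
    counts = vol.counts()

    duration_min = config.schedule.total_duration / SECONDS_PER_MINUTE
    t, cr = reference_curve(duration_min=duration_min, fine_dt_s=config.fine_dt_s)
    crf = frame_average(t, cr, config.schedule)
    n_frames = config.schedule.n_frames

    # per-voxel parcel parameters for tissue regions governed by SRTM
    special = {"CSF", "Lateral-Ventricle", REFERENCE_REGION}
    max_id = int(vol.labels.max())
    r1_of = np.zeros(max_id + 1)
    k2_of = np.zeros(max_id + 1)
    bp_of = np.zeros(max_id + 1)
    tissue_ids = []
    for label_id, name in vol.lut.items():
        canon = _canonical(name)
        if canon in special:
            continue
        if canon not in config.kinetics:
            raise ValueError(f"no kinetic model for phantom region {canon!r}")
        p = config.kinetics[canon]
        r1_of[label_id], k2_of[label_id] = p.r1, p.k2
        bp_of[label_id] = p.bp_nd_true * config.binding_scale
        tissue_ids.append(label_id)

    tissue = np.isin(vol.labels, tissue_ids)
    bp_field = bp_of[vol.labels] * tissue
    if config.bp_smoothing_fwhm_mm > 0 and tissue.any():
        sigma_vox = [config.bp_smoothing_fwhm_mm * FWHM_TO_SIGMA / v
                     for v in config.voxel_size_mm]
        num = gaussian_filter(bp_field, sigma=sigma_vox, mode="constant", cval=0.0)
        den = gaussian_filter(tissue.astype(float), sigma=sigma_vox,
                              mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            bp_field = np.where(tissue, num / np.maximum(den, 1e-12), 0.0)
    levels = np.rint(bp_field / _BP_QUANTUM).astype(np.int32)

    # synthesize one TAC per (parcel, quantized-bp) combination
    voxels = np.zeros(config.shape + (n_frames,), dtype=np.float64)
    csf_tac = config.csf_fraction * crf
    for label_id, name in vol.lut.items():
        if label_id not in counts:
            continue
        canon = _canonical(name)
        region_mask = vol.labels == label_id
        if canon == REFERENCE_REGION:
            voxels[region_mask] = crf
        elif canon in ("CSF", "Lateral-Ventricle"):
            voxels[region_mask] = csf_tac
        else:
            r1, k2 = r1_of[label_id], k2_of[label_id]
            for lvl in np.unique(levels[region_mask]):
                bp = float(lvl) * _BP_QUANTUM
                curve = srtm_tac(t, cr, SRTMParams(r1, k2, bp))
                voxels[region_mask & (levels == lvl)] = frame_average(
                    t, curve, config.schedule
                )

    # ground truth: field means per canonical (bilateral) region
    volumes: dict[str, int] = {}
    bp_sums: dict[str, float] = {}
    params_of: dict[str, SRTMParams] = {}
    for label_id, name in vol.lut.items():
        if label_id not in counts:
            continue
        canon = _canonical(name)
        region_mask = vol.labels == label_id
        volumes[canon] = volumes.get(canon, 0) + counts[label_id]
        if canon in special:
            bp_sums[canon] = bp_sums.get(canon, 0.0)
        else:
            bp_sums[canon] = bp_sums.get(canon, 0.0) + float(
                (levels[region_mask] * _BP_QUANTUM).sum()
            )
            params_of[canon] = config.kinetics[canon]
    effective: dict[str, SRTMParams] = {}
    for canon, v in volumes.items():
        if canon in ("CSF", "Lateral-Ventricle"):
            continue
        base = params_of.get(canon, config.kinetics.get(canon, SRTMParams(1.0, 0.16, 0.0)))
        effective[canon] = replace(base, bp_nd_true=bp_sums[canon] / v)
    small = {r: v for r, v in volumes.items() if v < 27}
    if small:
        raise ValueError(f"phantom regions too small (<27 voxels): {small}")

    if config.psf_fwhm_mm > 0:
        sigma_vox = [config.psf_fwhm_mm * FWHM_TO_SIGMA / v for v in config.voxel_size_mm]
        for f in range(n_frames):
            voxels[..., f] = gaussian_filter(voxels[..., f], sigma=sigma_vox,
                                             mode="constant", cval=0.0)

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        dur_min = config.schedule.durations / SECONDS_PER_MINUTE
        sd = config.noise_sd * np.sqrt(np.clip(voxels, 0.0, None) / dur_min)
        voxels = voxels + rng.normal(0.0, 1.0, voxels.shape) * sd

    img = DynamicImage(voxels=voxels.astype(np.float32), voxel_size=config.voxel_size_mm,
                       frames=config.schedule)
    truth = PhantomTruth(
        kinetics=effective,
        volumes=volumes,
        mcbp_true=_truth_mcbp(effective, volumes),
        psf_fwhm_mm=config.psf_fwhm_mm,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    return img, vol, truth


def build_testretest_cohort(
    n_subjects: int = 10,
    seed: int = 0,
    magnitude: float = 0.05,
    outline_shift_sd: float = 0.1,
    binding_scale_range: tuple[float, float] = (0.2, 1.3),
    base_config: PhantomConfig | None = None,
) -> tuple[list[tuple[DynamicImage, LabelVolume, LabelVolume]], list[PhantomTruth]]:
    """Cohort for the segmentation test-retest experiment.

    Each subject is one phantom scan (binding scaled by a subject-specific
    factor spanning amyloid-negative to strongly positive) quantified under
    two independently perturbed segmentations of the same anatomy —
    emulating one PET scan processed with automated segmentations from two
    repeated MRI acquisitions. The perturbation magnitude and outline-shift
    spread are calibrated so regional volumes differ by a nominal ~5%
    between the two segmentations.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base = base_config or PhantomConfig()
    rng = np.random.default_rng(seed)
    subjects = []
    truths = []
    for i in range(n_subjects):
        scale = float(rng.uniform(*binding_scale_range))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        config = replace(base, binding_scale=scale, seed=sub_seed)
        img, vol, truth = build_phantom(config)
        seg1 = perturb_segmentation(vol, magnitude, seed=sub_seed + 1,
                                    outline_shift_sd=outline_shift_sd)
        seg2 = perturb_segmentation(vol, magnitude, seed=sub_seed + 2,
                                    outline_shift_sd=outline_shift_sd)
        subjects.append((img, seg1, seg2))
        truths.append(truth)
    return subjects, truths


_NEIGHBOR_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _neighbor_stack(labels: np.ndarray) -> np.ndarray:
    """(6, x, y, z) array of 6-neighborhood labels; out-of-grid = -1."""
    padded = np.full(tuple(s + 2 for s in labels.shape), -1, dtype=labels.dtype)
    padded[1:-1, 1:-1, 1:-1] = labels
    stack = np.empty((6,) + labels.shape, dtype=labels.dtype)
    for i, (dx, dy, dz) in enumerate(_NEIGHBOR_OFFSETS):
        stack[i] = padded[1 + dx: labels.shape[0] + 1 + dx,
                          1 + dy: labels.shape[1] + 1 + dy,
                          1 + dz: labels.shape[2] + 1 + dz]
    return stack


def _move_voxels(labels, idx, rng, n_move, targets, counts, label_id):
    """Reassign n_move randomly chosen voxels from idx to per-voxel target labels."""
    n_keep_floor = counts[label_id] - 1
    if n_move > n_keep_floor:
        warnings.warn(
            f"perturbation would empty region id {label_id}; capping to keep 1 voxel",
            stacklevel=3,
        )
        n_move = n_keep_floor
    if n_move <= 0:
        return
    sel = rng.choice(idx.shape[0], size=n_move, replace=False)
    chosen = idx[sel]
    labels[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = targets[sel]
    counts[label_id] -= n_move


def perturb_segmentation(
    vol: LabelVolume,
    magnitude: float,
    seed: int,
    outline_shift_sd: float | None = None,
    frozen_names=DEFAULT_FROZEN_NAMES,
) -> LabelVolume:
    """Reassign a fraction of each region's boundary voxels to adjacent labels.

    Emulates the run-to-run variability of an automated MRI segmentation
    with two mechanisms:

    1. *Boundary jitter*: for each (non-frozen) region, ``magnitude``
       of its boundary voxels is reassigned to the label of a uniformly
       chosen differing tissue neighbor — symmetric exchange at every
       interface, emulating voxel-level label noise at parcel borders.
    2. *Outline dilation/erosion*: per region, a signed Gaussian draw
       (sd = ``outline_shift_sd``, default ``magnitude``) grows the region
       into, or erodes it toward, its entire one-voxel surround —
       emulating the coherent surface-placement differences that drive the
       few-percent volume changes between repeated segmentations. Because
       the whole outline moves, gained or lost voxels sample every
       adjacent compartment the way the region's own boundary does.

    Interior voxels are never touched and every region keeps at least one
    voxel. Regions matching ``frozen_names`` (CSF spaces and the
    cerebellar reference by default) are not themselves perturbed, though
    tissue regions may exchange voxels with them. Deterministic under
    ``seed``.
    """
    if not (0.0 <= magnitude < 0.5):
        raise ValueError("magnitude must be in [0, 0.5)")
    labels = vol.labels.copy()
    if magnitude == 0.0:
        return LabelVolume(labels=labels, lut=dict(vol.lut))
    if outline_shift_sd is None:
        outline_shift_sd = magnitude

    rng = np.random.default_rng(seed)
    frozen_ids = {
        i for i, name in vol.lut.items()
        if any(fr.lower() in name.lower() for fr in frozen_names)
    }
    frozen_ids.add(0)

    neighbors = _neighbor_stack(vol.labels)
    in_grid = neighbors >= 0
    differs = (neighbors != vol.labels[None]) & in_grid
    # jitter exchanges only between tissue labels (not into CSF/background)
    jitter_ok = differs & np.isin(neighbors, list(frozen_ids), invert=True)

    counts = vol.counts()
    region_ids = [i for i in vol.present_ids() if i not in frozen_ids]

    # phase 1: symmetric boundary jitter between tissue labels
    for label_id in region_ids:
        region_mask = vol.labels == label_id
        boundary = region_mask & jitter_ok.any(axis=0)
        idx = np.argwhere(boundary)
        if idx.size == 0:
            continue
        nb_labels = neighbors[:, idx[:, 0], idx[:, 1], idx[:, 2]]
        nb_ok = jitter_ok[:, idx[:, 0], idx[:, 1], idx[:, 2]]
        weights = nb_ok.astype(float)
        weights /= weights.sum(axis=0, keepdims=True)
        pick = (rng.random(idx.shape[0]) < np.cumsum(weights, axis=0)).argmax(axis=0)
        targets = nb_labels[pick, np.arange(idx.shape[0])]
        n_move = int(round(magnitude * idx.shape[0]))
        _move_voxels(labels, idx, rng, n_move, targets, counts, label_id)

    # phase 2: whole-outline dilation (+) or erosion (-) per region, against
    # tissue neighbors only (the pial/CSF boundary is comparatively stable)
    frozen_mask = np.isin(vol.labels, list(frozen_ids))
    for label_id in region_ids:
        b = rng.normal(0.0, outline_shift_sd)
        frac = min(abs(b), 0.95)
        region_mask = vol.labels == label_id
        if b >= 0:
            # grow: tissue voxels outside the region but 6-adjacent to it flip in
            ring = (neighbors == label_id).any(axis=0) & ~region_mask & ~frozen_mask
            idx = np.argwhere(ring)
            if idx.size == 0:
                continue
            n_move = int(round(frac * idx.shape[0]))
            if n_move == 0:
                continue
            sel = rng.choice(idx.shape[0], size=n_move, replace=False)
            chosen = idx[sel]
            donors = labels[chosen[:, 0], chosen[:, 1], chosen[:, 2]]
            keep = np.ones(n_move, dtype=bool)
            for donor in np.unique(donors):
                d = int(donor)
                if d == 0:
                    continue
                take = np.flatnonzero(donors == d)
                avail = counts.get(d, 0) - 1
                if take.size > avail:
                    warnings.warn(
                        f"outline growth would empty region id {d}; capping",
                        stacklevel=2,
                    )
                    keep[take[avail:]] = False
                    take = take[:avail]
                counts[d] = counts.get(d, 1) - take.size
            chosen = chosen[keep]
            labels[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = label_id
            counts[label_id] = counts.get(label_id, 0) + int(keep.sum())
        else:
            # erode: region boundary voxels flip to a differing tissue neighbor
            boundary = region_mask & jitter_ok.any(axis=0)
            idx = np.argwhere(boundary)
            if idx.size == 0:
                continue
            nb_labels = neighbors[:, idx[:, 0], idx[:, 1], idx[:, 2]]
            nb_ok = jitter_ok[:, idx[:, 0], idx[:, 1], idx[:, 2]]
            weights = nb_ok.astype(float)
            weights /= weights.sum(axis=0, keepdims=True)
            pick = (rng.random(idx.shape[0]) < np.cumsum(weights, axis=0)).argmax(axis=0)
            targets = nb_labels[pick, np.arange(idx.shape[0])]
            _move_voxels(labels, idx, rng, int(round(frac * idx.shape[0])),
                         targets, counts, label_id)

    return LabelVolume(labels=labels, lut=dict(vol.lut))
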