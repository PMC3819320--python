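"""End-to-end quantification workflows.

``quantify`` runs the full single-subject protocol: bilateral + composite
ROI construction from the LUT, regional TAC extraction, optional
two-component partial-volume correction, reference-Logan BP_ND per
region, MCBP and PiB status. ``testretest_cohort`` repeats quantification
under two segmentations of the same PET data and summarizes per-region
BP_ND / volume variability (delta percent and ICC).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io import DynamicImage, LabelVolume
from .kinetics import DEFAULT_K2_REF, DEFAULT_T_STAR, KineticResult, logan_ref
from .pvc import DEFAULT_PSF_FWHM_MM, brain_mask, correct_tac, dilution_factors
from .regions import MCBP_COMPOSITES, RegionSet, merge_bilateral, table1_composites
from .stats import (
    DEFAULT_CUTOFF,
    SubjectReport,
    TestRetestResult,
    classify_pib,
    delta_pct,
    icc_vc,
    mcbp,
)
from .tac import extract_all

__all__ = ["RunConfig", "quantify", "quantify_tacs", "testretest_cohort"]

REFERENCE_REGION = "Cerebellum-Cortex"


@dataclass(frozen=True)
class RunConfig:
    """Quantification settings; the defaults are the protocol's constants."""

    t_star: float = DEFAULT_T_STAR  # seconds
    k2_ref: float = DEFAULT_K2_REF  # 1/min
    pvc: bool = False
    psf_fwhm_mm: float = DEFAULT_PSF_FWHM_MM
    correct_reference: bool = True  # apply PVC to the cerebellar reference TAC too
    composite_mode: str = "pool"  # "pool" voxels before fitting | "average" member BPs
    mcbp_members: tuple[str, ...] = MCBP_COMPOSITES
    cutoff: float = DEFAULT_CUTOFF
    reference_region: str = REFERENCE_REGION
    seed: int = 0

    def __post_init__(self):
        if self.composite_mode not in ("pool", "average"):
            raise ValueError("composite_mode must be 'pool' or 'average'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mcbp_members"] = list(self.mcbp_members)
        return d


def build_regionset(labels: LabelVolume) -> RegionSet:
    return table1_composites(merge_bilateral(labels.lut))


def quantify_tacs(
    tacs: dict,
    regionset: RegionSet,
    config: RunConfig,
    factors=None,
) -> tuple[dict[str, KineticResult], dict[str, float]]:
    """Logan BP_ND per region/composite from already-extracted TACs."""
    work = dict(tacs)
    if config.pvc:
        if factors is None:
            raise ValueError("PVC requested but no dilution factors supplied")
        for name in list(work):
            if name == config.reference_region and not config.correct_reference:
                continue
            work[name] = correct_tac(work[name], factors[name])
    ref = work[config.reference_region]

    results: dict[str, KineticResult] = {}
    for name, tac in work.items():
        results[name] = logan_ref(tac, ref, k2_ref=config.k2_ref, t_star=config.t_star)

    regional_bp = {name: r.bp_nd for name, r in results.items()}
    if config.composite_mode == "average":
        for comp, members in regionset.composites.items():
            w = np.array([tacs[m].n_voxels for m in members], dtype=float)
            bp = np.array([regional_bp[m] for m in members])
            regional_bp[comp] = float((w * bp).sum() / w.sum())
    return results, regional_bp


def quantify(
    img: DynamicImage,
    labels: LabelVolume,
    config: RunConfig | None = None,
    subject: str = "subject",
    regionset: RegionSet | None = None,
):
    """Full single-subject quantification.

    Returns (SubjectReport, {region: KineticResult}, {region: TAC}).
    """
    config = config or RunConfig()
    regionset = regionset or build_regionset(labels)
    if config.reference_region not in regionset:
        raise ValueError(f"reference region {config.reference_region!r} not in segmentation")

    tacs = extract_all(img, labels, regionset)

    factors = None
    if config.pvc:
        mask = brain_mask(labels)
        factors = dilution_factors(
            mask, labels, regionset,
            psf_fwhm_mm=config.psf_fwhm_mm, voxel_size_mm=img.voxel_size,
        )

    results, regional_bp = quantify_tacs(tacs, regionset, config, factors)
    mcbp_value = mcbp(regional_bp, members=config.mcbp_members)
    report = SubjectReport(
        subject=subject,
        regional_bp=regional_bp,
        mcbp=mcbp_value,
        pib_status=classify_pib(mcbp_value, cutoff=config.cutoff),
        pvc_applied=config.pvc,
        dilution_factors=dict(factors.factors) if factors is not None else None,
        config=config.to_dict(),
    )
    return report, results, tacs


def _region_volumes(labels: LabelVolume, regionset: RegionSet) -> dict[str, int]:
    counts = labels.counts()
    vols = {}
    for spec in regionset.specs:
        vols[spec.name] = sum(counts.get(i, 0) for i in spec.member_ids)
    for comp, members in regionset.composites.items():
        vols[comp] = sum(vols[m] for m in members)
    return vols


def testretest_cohort(
    subjects: list[tuple[DynamicImage, LabelVolume, LabelVolume]],
    config: RunConfig | None = None,
) -> tuple[list[TestRetestResult], pd.DataFrame]:
    """Per-region test-retest variability across a cohort.

    Each subject contributes one PET scan quantified under two
    segmentations (emulating repeated MRI + automated segmentation).
    Returns the per-region summary plus the long-format per-subject table
    (subject, replicate, region, bp_nd, volume). Regions present in only
    one segmentation of a subject are excluded from that subject with a
    note in the long table. With a single subject the delta metrics are
    still computed but ICC is undefined (None).
    """
    config = config or RunConfig()
    rows = []
    for i, (img, seg1, seg2) in enumerate(subjects):
        for rep, seg in ((1, seg1), (2, seg2)):
            regionset = build_regionset(seg)
            report, _, _ = quantify(img, seg, config, subject=f"S{i:03d}", regionset=regionset)
            vols = _region_volumes(seg, regionset)
            for region, bp in report.regional_bp.items():
                rows.append(
                    {
                        "subject": f"S{i:03d}",
                        "replicate": rep,
                        "region": region,
                        "bp_nd": bp,
                        "volume": vols.get(region, 0),
                    }
                )
    long = pd.DataFrame(rows)

    results: list[TestRetestResult] = []
    for region, grp in long.groupby("region", sort=True):
        wide = grp.pivot_table(index="subject", columns="replicate", values=["bp_nd", "volume"])
        complete = wide.dropna()
        n = len(complete)
        if n == 0:
            continue
        bp_pairs = complete["bp_nd"].to_numpy()
        vol_pairs = complete["volume"].to_numpy()
        d_bp = delta_pct(bp_pairs)
        d_vol = delta_pct(vol_pairs)
        icc_bp = icc_vol = None
        if n >= 2:
            tbl_bp = complete["bp_nd"].stack().rename("value").reset_index()
            tbl_vol = complete["volume"].stack().rename("value").reset_index()
            if np.ptp(bp_pairs) > 0:
                icc_bp = icc_vc(tbl_bp, rater_col="replicate").icc
            if np.ptp(vol_pairs) > 0:
                icc_vol = icc_vc(tbl_vol, rater_col="replicate").icc
        results.append(
            TestRetestResult(
                region=region,
                delta_bp_pct=d_bp,
                delta_vol_pct=d_vol,
                icc_bp=icc_bp,
                icc_vol=icc_vol,
                n_subjects=n,
            )
        )
    return results, long


def testretest_to_frame(results: list[TestRetestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": r.region,
                "delta_bp_pct": r.delta_bp_pct,
                "delta_vol_pct": r.delta_vol_pct,
                "icc_bp": r.icc_bp,
                "icc_vol": r.icc_vol,
                "n_subjects": r.n_subjects,
            }
            for r in results
        ]
    )
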