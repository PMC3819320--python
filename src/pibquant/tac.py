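"""Regional time-activity curve (TAC) extraction.

A TAC is the per-frame unweighted mean activity over the voxels of one
ROI. Frames are treated as frame-average samples at the frame mid-time;
no intra-frame duration weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DynamicImage, LabelVolume, check_same_grid
from .regions import RegionSet, RegionSpec

__all__ = ["TimeActivityCurve", "extract_tac", "extract_all", "tacs_to_frame", "tacs_from_frame"]


@dataclass(frozen=True)
class TimeActivityCurve:
    """Mean regional activity per frame, sampled at frame mid-times (s)."""

    region: str
    values: np.ndarray
    mid_times: np.ndarray
    n_voxels: int

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        mid_times = np.asarray(self.mid_times, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mid_times", mid_times)
        if values.shape != mid_times.shape or values.ndim != 1:
            raise ValueError("values and mid_times must be 1-D arrays of equal length")
        if np.any(np.diff(mid_times) <= 0):
            raise ValueError("mid_times must be strictly increasing")
        if self.n_voxels < 1:
            raise ValueError(f"region {self.region!r} has no voxels")

    def __len__(self) -> int:
        return self.values.size


def extract_tac(img: DynamicImage, labels: LabelVolume, spec: RegionSpec) -> TimeActivityCurve:
    """Per-frame unweighted mean over the ROI's member voxels."""
    check_same_grid(img, labels)
    mask = labels.mask(spec.member_ids)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"empty region: {spec.name!r} has no voxels in the label volume")
    values = np.asarray(img.voxels[mask], dtype=float).mean(axis=0)
    return TimeActivityCurve(
        region=spec.name, values=values, mid_times=img.frames.mid_times, n_voxels=n
    )


def extract_all(
    img: DynamicImage, labels: LabelVolume, regionset: RegionSet
) -> dict[str, TimeActivityCurve]:
    """One TAC per ROI and per composite.

    Composite TACs pool member voxels (equivalently, the voxel-count
    weighted mean of the member TACs). Per-region failures (empty ROIs)
    are collected and reported together.
    """
    check_same_grid(img, labels)
    out: dict[str, TimeActivityCurve] = {}
    errors: list[str] = []
    for spec in regionset.specs:
        try:
            out[spec.name] = extract_tac(img, labels, spec)
        except ValueError as exc:
            errors.append(str(exc))
    for comp in regionset.composites:
        members = regionset.composites[comp]
        if not all(m in out for m in members):
            errors.append(f"composite {comp!r} has missing/empty members")
            continue
        n_total = sum(out[m].n_voxels for m in members)
        pooled = sum(out[m].values * out[m].n_voxels for m in members) / n_total
        out[comp] = TimeActivityCurve(
            region=comp, values=pooled, mid_times=img.frames.mid_times, n_voxels=n_total
        )
    if errors:
        raise ValueError("TAC extraction failed for some regions: " + "; ".join(errors))
    return out


def tacs_to_frame(tacs: dict[str, TimeActivityCurve]) -> pd.DataFrame:
    """Tidy long-format table: region, frame, mid_time_sec, value, n_voxels."""
    rows = []
    for name, tac in tacs.items():
        for i, (t, v) in enumerate(zip(tac.mid_times, tac.values)):
            rows.append(
                {"region": name, "frame": i, "mid_time_sec": t, "value": v, "n_voxels": tac.n_voxels}
            )
    return pd.DataFrame(rows)


def tacs_from_frame(df: pd.DataFrame) -> dict[str, TimeActivityCurve]:
    out = {}
    for name, grp in df.groupby("region", sort=False):
        grp = grp.sort_values("frame")
        out[name] = TimeActivityCurve(
            region=name,
            values=grp["value"].to_numpy(float),
            mid_times=grp["mid_time_sec"].to_numpy(float),
            n_voxels=int(grp["n_voxels"].iloc[0]),
        )
    return out
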