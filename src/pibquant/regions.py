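"""Mapping label IDs to analysis ROIs.

FreeSurfer wmparc-style LUTs name hemispheric structures either
``Left-X``/``Right-X`` (subcortical) or ``ctx-lh-X``/``ctx-rh-X``
(cortical parcels). For quantitative analysis, corresponding left and
right regions are pooled into a single bilateral ROI; composite ROIs
(PREF_FS, GR_FS, TEMP_FS, OCC_FS, PREC_FS) then pool the bilateral
cortical parcels that maximally overlap the classic manually-traced
amyloid ROIs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionSpec",
    "RegionSet",
    "merge_bilateral",
    "table1_composites",
    "COMPOSITE_MEMBERS",
    "MCBP_COMPOSITES",
    "dice",
]

# Composite cortical ROIs and their bilateral members (canonical names).
COMPOSITE_MEMBERS: dict[str, tuple[str, ...]] = {
    "PREF_FS": ("ctx-rostralmiddlefrontal", "ctx-superiorfrontal"),
    "GR_FS": ("ctx-lateralorbitofrontal", "ctx-medialorbitofrontal"),
    "TEMP_FS": ("ctx-superiortemporal", "ctx-middletemporal"),
    "OCC_FS": ("ctx-lingual", "ctx-cuneus"),
    "PREC_FS": ("ctx-precuneus",),
}

# The four composites whose mean BP_ND defines MCBP.
MCBP_COMPOSITES = ("PREF_FS", "PREC_FS", "GR_FS", "TEMP_FS")


@dataclass(frozen=True)
class RegionSpec:
    """One analysis ROI: a name and the set of label IDs pooled into it."""

    name: str
    member_ids: frozenset[int]

    def __post_init__(self):
        object.__setattr__(self, "member_ids", frozenset(int(i) for i in self.member_ids))
        if not self.member_ids:
            raise ValueError(f"region {self.name!r} has no member label IDs")


@dataclass
class RegionSet:
    """Bilateral ROIs plus named composites (composite -> member ROI names)."""

    specs: list[RegionSpec] = field(default_factory=list)
    composites: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        names = [s.name for s in self.specs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate ROI names in RegionSet")
        by_name = set(names)
        for comp, members in self.composites.items():
            missing = [m for m in members if m not in by_name]
            if missing:
                raise ValueError(f"composite {comp!r} references unknown ROIs: {missing}")

    def __getitem__(self, name: str) -> RegionSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def composite_spec(self, name: str) -> RegionSpec:
        """A composite as a single pooled-ID RegionSpec."""
        ids: set[int] = set()
        for member in self.composites[name]:
            ids |= self[member].member_ids
        return RegionSpec(name=name, member_ids=frozenset(ids))

    def to_json(self, path=None) -> str:
        payload = {
            "specs": {s.name: sorted(s.member_ids) for s in self.specs},
            "composites": {k: list(v) for k, v in self.composites.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RegionSet":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        specs = [RegionSpec(n, frozenset(ids)) for n, ids in payload["specs"].items()]
        return cls(specs=specs, composites=payload.get("composites", {}))


def _canonical_name(name: str) -> tuple[str, bool]:
    """Strip hemisphere prefixes to a canonical bilateral name.

    Returns (canonical, was_hemispheric). ``ctx-lh-X``/``ctx-rh-X`` map to
    ``ctx-X``; ``Left-X``/``Right-X`` map to ``X``; anything else passes
    through unchanged.
    """
    for prefix in ("ctx-lh-", "ctx-rh-"):
        if name.startswith(prefix):
            return "ctx-" + name[len(prefix):], True
    for prefix in ("Left-", "Right-"):
        if name.startswith(prefix):
            return name[len(prefix):], True
    for prefix in ("wm-lh-", "wm-rh-"):
        if name.startswith(prefix):
            return "wm-" + name[len(prefix):], True
    return name, False


def merge_bilateral(lut: dict[int, str]) -> RegionSet:
    """Pool left/right label IDs into one bilateral ROI per anatomical region.

    Unilateral structures (e.g. Brain-Stem, CSF) pass through as
    single-ID ROIs. A hemispheric name without a contralateral partner
    still becomes an ROI, with a warning.
    """
    groups: dict[str, set[int]] = {}
    hemis: dict[str, set[str]] = {}
    for label_id, name in lut.items():
        canon, was_hemi = _canonical_name(name)
        groups.setdefault(canon, set()).add(int(label_id))
        if was_hemi:
            side = "lh" if ("lh-" in name or name.startswith("Left-")) else "rh"
            hemis.setdefault(canon, set()).add(side)
    for canon, sides in hemis.items():
        if len(sides) == 1:
            warnings.warn(
                f"hemispheric region {canon!r} has only one hemisphere in the LUT; "
                "passing through unpaired",
                stacklevel=2,
            )
    specs = [RegionSpec(name, frozenset(ids)) for name, ids in sorted(groups.items())]
    return RegionSet(specs=specs)


def table1_composites(regionset: RegionSet) -> RegionSet:
    """Attach the standard composite ROIs to a bilateral RegionSet.

    PREF_FS, GR_FS, TEMP_FS, OCC_FS and PREC_FS pool the FreeSurfer
    cortical parcels that maximally overlap the corresponding manual
    amyloid ROIs. Raises KeyError if a required member ROI is absent.
    """
    composites = dict(regionset.composites)
    for comp, members in COMPOSITE_MEMBERS.items():
        missing = [m for m in members if m not in regionset]
        if missing:
            raise KeyError(f"composite {comp} requires missing ROIs: {missing}")
        composites[comp] = list(members)
    return RegionSet(specs=list(regionset.specs), composites=composites)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap coefficient 2|A∩B| / (|A|+|B|) of two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"masks must share a grid: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("Dice coefficient undefined for two empty masks")
    return 2.0 * int(np.logical_and(a, b).sum()) / (na + nb)
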