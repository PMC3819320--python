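"""Input/output for dynamic PET volumes, label volumes and frame timing.

All images are NIfTI-1 (via nibabel). Label lookup tables use the
FreeSurfer color-LUT text dialect (whitespace-separated ``ID name ...``
records, ``#`` comments). Frame timing is a two-column CSV with header
``start_sec,duration_sec``.

Dynamic PET and label volumes are assumed already co-registered and
resampled to a common grid; this module validates shape equality and
refuses mismatches rather than resampling. Activities are assumed
decay-corrected (standard reconstruction output).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "LabelVolume",
    "default_frame_schedule",
    "read_dynamic_pet",
    "write_dynamic_pet",
    "read_label_volume",
    "write_label_volume",
    "read_frame_timing",
    "write_frame_timing",
    "read_lut",
    "write_lut",
]

TIMING_COLUMNS = ("start_sec", "duration_sec")


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame acquisition timing of a dynamic scan, in seconds.

    ``mid_times`` (start + duration/2) are the time points at which
    frame-average activities are treated as samples of the underlying
    time-activity curve.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or starts.shape != durations.shape:
            raise ValueError("starts and durations must be 1-D arrays of equal length")
        if starts.size == 0:
            raise ValueError("empty frame schedule")
        if np.any(durations <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        ends = starts + durations
        if np.any(starts[1:] < ends[:-1] - 1e-9):
            raise ValueError("frames overlap")

    @property
    def mid_times(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    @property
    def n_frames(self) -> int:
        return int(self.starts.size)

    @property
    def total_duration(self) -> float:
        """End of the last frame, in seconds."""
        return float(self.starts[-1] + self.durations[-1])

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class DynamicImage:
    """A 4D dynamic PET volume with its frame schedule.

    ``voxels`` has shape (x, y, z, frame); activities are in arbitrary
    consistent units (e.g. kBq/mL). ``voxel_size`` is mm per axis.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    frames: FrameSchedule

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"dynamic image must be 4-D, got {self.voxels.ndim}-D")
        if self.voxels.shape[3] != self.frames.n_frames:
            raise ValueError(
                f"frame count mismatch: image has {self.voxels.shape[3]} frames, "
                f"schedule has {self.frames.n_frames}"
            )
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be 3 positive lengths (mm)")
        self.voxel_size = vs

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]


@dataclass
class LabelVolume:
    """3D integer segmentation grid plus a label-ID -> region-name table."""

    labels: np.ndarray
    lut: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got {labels.ndim}-D")
        if not np.issubdtype(labels.dtype, np.integer):
            flo = np.asarray(labels, dtype=float)
            as_int = np.rint(flo).astype(np.int32)
            if not np.allclose(flo, as_int, atol=1e-6):
                raise ValueError("label volume contains non-integer voxel values")
            labels = as_int
        if labels.min() < 0:
            raise ValueError("label IDs must be non-negative")
        self.labels = labels
        self.lut = {int(k): str(v) for k, v in self.lut.items()}
        present = self.present_ids()
        missing = sorted(set(present) - set(self.lut))
        if missing:
            raise ValueError(f"label IDs present in grid but absent from LUT: {missing}")

    def present_ids(self) -> list[int]:
        """Nonzero label IDs that actually occur in the grid."""
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    def mask(self, label_ids) -> np.ndarray:
        return np.isin(self.labels, np.asarray(list(label_ids), dtype=self.labels.dtype))

    def counts(self) -> dict[int, int]:
        ids, n = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, n) if i != 0}


def default_frame_schedule() -> FrameSchedule:
    """The 60-minute dynamic PiB schedule: 25 x 5 s, 9 x 20 s, 10 x 60 s, 9 x 300 s.

    53 contiguous frames totalling 3605 s.
    """
    durations = np.concatenate([
        np.full(25, 5.0),
        np.full(9, 20.0),
        np.full(10, 60.0),
        np.full(9, 300.0),
    ])
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts=starts, durations=durations)


def read_frame_timing(path) -> FrameSchedule:
    df = pd.read_csv(path)
    for col in TIMING_COLUMNS:
        if col not in df.columns:
            raise ValueError(
                f"timing CSV {path} must have columns {TIMING_COLUMNS}, got {list(df.columns)}"
            )
    return FrameSchedule(
        starts=df["start_sec"].to_numpy(float),
        durations=df["duration_sec"].to_numpy(float),
    )


def write_frame_timing(schedule: FrameSchedule, path) -> None:
    pd.DataFrame(
        {"start_sec": schedule.starts, "duration_sec": schedule.durations}
    ).to_csv(path, index=False)


def read_dynamic_pet(path, timing_path) -> DynamicImage:
    """Load a 4D NIfTI and its frame-timing CSV into a DynamicImage.

    Raises ValueError on a non-4D image or when the CSV row count does not
    equal the number of frames in the image.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D dynamic PET image, got {data.ndim}-D")
    schedule = read_frame_timing(timing_path)
    if data.shape[3] != schedule.n_frames:
        raise ValueError(
            f"frame count mismatch: {path} has {data.shape[3]} frames but "
            f"{timing_path} lists {schedule.n_frames}"
        )
    zooms = img.header.get_zooms()[:3]
    return DynamicImage(voxels=data, voxel_size=tuple(float(z) for z in zooms), frames=schedule)


def write_dynamic_pet(img: DynamicImage, path, timing_path=None) -> None:
    affine = np.diag(list(img.voxel_size) + [1.0])
    nii = nib.Nifti1Image(np.asarray(img.voxels, dtype=np.float32), affine)
    nii.header.set_zooms(tuple(img.voxel_size) + (1.0,))
    nib.save(nii, str(path))
    if timing_path is not None:
        write_frame_timing(img.frames, timing_path)


def read_lut(path) -> dict[int, str]:
    """Parse a FreeSurfer-color-LUT-style text file into {ID: name}.

    Records are whitespace-separated, the first two fields are the integer
    ID and the region name; ``#`` starts a comment; extra fields (RGBA
    columns) are ignored.
    """
    lut: dict[int, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed LUT line: {raw!r}")
        lut[int(parts[0])] = parts[1]
    return lut


def write_lut(lut: dict[int, str], path) -> None:
    lines = ["# ID  name"]
    for label_id in sorted(lut):
        lines.append(f"{label_id:6d}  {lut[label_id]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_label_volume(path, lut_path) -> LabelVolume:
    """Load a 3D integer label NIfTI and its LUT into a LabelVolume.

    Every nonzero ID present in the grid must be named in the LUT.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D label image, got {data.ndim}-D")
    return LabelVolume(labels=data, lut=read_lut(lut_path))


def write_label_volume(vol: LabelVolume, path, lut_path=None, voxel_size=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nii = nib.Nifti1Image(np.asarray(vol.labels, dtype=np.int32), affine)
    nib.save(nii, str(path))
    if lut_path is not None:
        write_lut(vol.lut, lut_path)


def check_same_grid(img: DynamicImage, labels: LabelVolume) -> None:
    if img.shape3d != labels.labels.shape:
        raise ValueError(
            f"shape mismatch: PET grid {img.shape3d} vs label grid {labels.labels.shape}; "
            "inputs must be co-registered and resampled to a common grid"
        )
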