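"""Segmentation-mask and measurement-table I/O.

Masks are NIfTI-1 volumes; the in-memory :class:`VoxelMask` is always in a
canonical right-handed frame with 0-based (x, y, z) indices, world position
of a voxel at its *centre*, and world units of millimetres.  Files whose
affine is oblique (not an axis permutation with flips) are rejected rather
than resampled: the pipeline is orientation-covariant, so one canonical frame
is enough and silent resampling would blur the binary mask.

Measurement tables are RFC-4180 CSV in long format with columns
``hip_id, plane, rater, alpha_deg`` — one row per measured alpha angle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    DimensionError,
    EmptyMaskError,
    MaskFormatError,
    TableFormatError,
    ValidationError,
)

log = logging.getLogger(__name__)

TABLE_COLUMNS = ["hip_id", "plane", "rater", "alpha_deg"]


@dataclass
class VoxelMask:
    """Binary occupancy grid with world geometry.

    index -> world: ``world = origin_mm + index * spacing_mm`` (per axis).
    """

    occupancy: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy).astype(bool)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.occupancy.ndim != 3:
            raise DimensionError("mask must be 3D")
        if self.spacing_mm.shape != (3,) or np.any(self.spacing_mm <= 0):
            raise ValidationError("spacing must be 3 positive lengths")
        if self.origin_mm.shape != (3,):
            raise ValidationError("origin must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing_mm)
        a[:3, 3] = self.origin_mm
        return a

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.asarray(idx, dtype=float) * self.spacing_mm

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin_mm) / self.spacing_mm

    def foreground_world(self) -> np.ndarray:
        """World coordinates (mm) of all foreground voxel centres."""
        idx = np.argwhere(self.occupancy)
        return self.index_to_world(idx)

    def require_nonempty(self) -> "VoxelMask":
        if not self.occupancy.any():
            raise EmptyMaskError("mask has no foreground voxels")
        return self


def read_mask(path) -> VoxelMask:
    """Load a NIfTI mask, canonicalize the frame and binarize (nonzero)."""
    path = Path(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise MaskFormatError(f"{path.name}: expected 3D data, got shape {img.shape}")
    # reject oblique affines: each world axis must be carried by exactly one
    # voxel axis (tolerance 1e-3 relative)
    rot = np.asarray(img.affine[:3, :3], dtype=float)
    for row in rot:
        mags = np.sort(np.abs(row))[::-1]
        if mags[1] > 1e-3 * max(mags[0], 1e-12):
            raise MaskFormatError(
                f"{path.name}: oblique affine not supported; resample upstream")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    labels = np.unique(data[data != 0])
    if labels.size > 1:
        log.warning("%s: %d nonzero labels collapsed to foreground", path.name,
                    labels.size)
    affine = img.affine
    mask = VoxelMask(occupancy=data != 0,
                     spacing_mm=np.abs(np.diag(affine)[:3]),
                     origin_mm=affine[:3, 3])
    return mask.require_nonempty()


def write_mask(mask: VoxelMask, path, overwrite: bool = True) -> None:
    """Write the mask as uint8 NIfTI (.nii or .nii.gz)."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists and overwrite=False")
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), mask.affine)
    img.header.set_zooms(tuple(mask.spacing_mm))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

@dataclass
class MeasurementTable:
    """Long-format alpha-angle records: one row per (hip, plane, rater)."""

    frame: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.frame)
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise TableFormatError(f"missing columns {missing}")
        df = df[TABLE_COLUMNS].copy()
        df["alpha_deg"] = pd.to_numeric(df["alpha_deg"], errors="coerce")
        bad = df.index[~((df["alpha_deg"] > 0) & (df["alpha_deg"] < 180))].tolist()
        if bad:
            raise TableFormatError(
                f"alpha_deg out of (0, 180) or non-numeric in rows {bad}")
        dup = df.duplicated(subset=["hip_id", "plane", "rater"])
        if dup.any():
            raise TableFormatError(
                f"duplicate (hip_id, plane, rater) in rows {df.index[dup].tolist()}")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def raters(self) -> list[str]:
        return sorted(self.frame["rater"].unique())

    def pivot(self, raters: tuple[str, str]) -> pd.DataFrame:
        """Units (hip x plane) as rows, the two raters as columns."""
        sub = self.frame[self.frame["rater"].isin(raters)]
        wide = sub.pivot_table(index=["hip_id", "plane"], columns="rater",
                               values="alpha_deg", aggfunc="first")
        missing = [r for r in raters if r not in wide.columns]
        if missing:
            raise TableFormatError(f"rater(s) {missing} not present in table")
        return wide[list(raters)]


def read_table(path) -> MeasurementTable:
    df = pd.read_csv(path, dtype={"hip_id": str, "plane": str, "rater": str})
    return MeasurementTable(df)


def write_table(table: MeasurementTable, path) -> None:
    table.frame.to_csv(path, index=False)
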