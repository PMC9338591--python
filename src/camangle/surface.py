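"""Femur surface extraction, initial landmarks and head/neck partition.

The femoral head hosts the largest sphere inscribable in the proximal femur,
so the global maximum of the Euclidean distance transform of the foreground
gives a robust initial head centre and radius.  The neck direction is then
initialized from the foreground voxels in a spherical shell around the head
(the bone mass leaving the head is the neck), and both estimates are later
refined by RANSAC sphere fitting and minimal-circumference axis search in
:mod:`camangle.geometry` — the initializer only has to land inside that
refinement's basin of attraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from .config import SurfaceConfig
from .errors import DegenerateSurfaceError, LandmarkError, PartitionError
from .volume_io import VoxelMask

LABEL_OTHER, LABEL_HEAD, LABEL_NECK = 0, 1, 2


@dataclass
class TriangleMesh:
    """Triangle surface in world millimetres."""

    vertices: np.ndarray  # (n, 3) float
    triangles: np.ndarray  # (m, 3) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise DegenerateSurfaceError("triangle index out of range")

    @property
    def edges(self) -> np.ndarray:
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def area(self) -> float:
        a, b, c = (self.vertices[self.triangles[:, i]] for i in range(3))
        return float(np.linalg.norm(np.cross(b - a, c - a), axis=1).sum() / 2.0)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.triangles,
                               process=False)

    def export(self, path) -> None:
        """Write PLY/OBJ (format chosen from the file suffix) for inspection."""
        self.as_trimesh().export(path)


@dataclass
class InitialLandmarks:
    head_center_mm: np.ndarray
    head_radius_mm: float
    neck_axis: np.ndarray  # unit, head -> neck

    def __post_init__(self):
        self.head_center_mm = np.asarray(self.head_center_mm, dtype=float)
        self.neck_axis = np.asarray(self.neck_axis, dtype=float)
        n = np.linalg.norm(self.neck_axis)
        if not n > 0 or self.head_radius_mm <= 0:
            raise LandmarkError("degenerate landmarks")
        self.neck_axis = self.neck_axis / n


def extract_surface(mask: VoxelMask, config: SurfaceConfig | None = None) -> TriangleMesh:
    """Iso-surface the mask at occupancy 0.5 and keep the largest component.

    The binary grid is pre-smoothed with a sub-voxel Gaussian so the 0.5
    level set interpolates the true boundary instead of following voxel
    staircases; vertices come out in world millimetres.
    """
    config = config or SurfaceConfig()
    mask.require_nonempty()
    vol = mask.occupancy.astype(np.float32)
    if config.smooth_sigma_vox > 0:
        vol = ndimage.gaussian_filter(vol, sigma=config.smooth_sigma_vox)
        # smoothing must not erase the object or the 0.5 crossing
        if vol.max() <= 0.5:
            vol = mask.occupancy.astype(np.float32)
    verts, faces, _, _ = marching_cubes(vol, level=0.5,
                                        spacing=tuple(mask.spacing_mm))
    verts = verts + mask.origin_mm
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        tm = max(parts, key=lambda p: len(p.vertices))
    tm.update_faces(tm.area_faces > 1e-9)
    tm.remove_unreferenced_vertices()
    if len(tm.vertices) <= config.min_vertices:
        raise DegenerateSurfaceError(
            f"surface has {len(tm.vertices)} vertices (<= {config.min_vertices})")
    return TriangleMesh(vertices=np.asarray(tm.vertices),
                        triangles=np.asarray(tm.faces))


def initial_landmarks(mask: VoxelMask,
                      config: SurfaceConfig | None = None) -> InitialLandmarks:
    """Approximate head centre, head radius and neck direction from the mask.

    * head centre = world position of the global maximum of the Euclidean
      distance transform (ties broken toward the lowest (x, y, z) index);
    * head radius = distance-transform value there;
    * neck axis = the ray from the head centre to the centre of mass of the
      foreground voxels in the shell at ``shell_band`` times the head radius
      from the centre — the bone mass leaving the head is the neck (plus some
      shaft, whose pull is well inside the downstream refinement's basin).
      The shell's principal (PCA) direction is deliberately not used: for a
      proximal femur the annular shell's largest variance runs across the
      bent neck-shaft mass, not along the neck.
    """
    config = config or SurfaceConfig()
    mask.require_nonempty()
    dt = ndimage.distance_transform_edt(mask.occupancy, sampling=mask.spacing_mm)
    idx = np.unravel_index(int(np.argmax(dt)), dt.shape)  # first in C order
    head_center = mask.index_to_world(np.asarray(idx))
    head_radius = float(dt[idx])

    fg = mask.foreground_world()
    dist = np.linalg.norm(fg - head_center, axis=1)
    b0, b1 = config.shell_band
    shell = fg[(dist >= b0 * head_radius) & (dist <= b1 * head_radius)]
    if len(shell) < 10:
        raise LandmarkError("no bone mass in the neck shell; is this a femur?")
    centroid = shell.mean(axis=0)
    axis = (centroid - head_center) / np.linalg.norm(centroid - head_center)
    return InitialLandmarks(head_center_mm=head_center,
                            head_radius_mm=head_radius,
                            neck_axis=axis)


def partition_head_neck(mesh: TriangleMesh, lm: InitialLandmarks,
                        config: SurfaceConfig | None = None) -> np.ndarray:
    """Label every vertex head / neck / other relative to the landmarks.

    head: within ``head_margin`` times the head radius of the head centre;
    neck: remaining vertices whose projection onto the neck axis lies in
    ``neck_band`` times the head radius and whose distance to the axis is at
    most ``neck_radial_margin`` times the head radius.
    """
    config = config or SurfaceConfig()
    v = mesh.vertices - lm.head_center_mm
    r = np.linalg.norm(v, axis=1)
    labels = np.full(len(v), LABEL_OTHER, dtype=np.int8)
    labels[r <= config.head_margin * lm.head_radius_mm] = LABEL_HEAD

    t = v @ lm.neck_axis
    radial = np.linalg.norm(v - t[:, None] * lm.neck_axis, axis=1)
    b0, b1 = config.neck_band
    neck = ((labels == LABEL_OTHER)
            & (t >= b0 * lm.head_radius_mm) & (t <= b1 * lm.head_radius_mm)
            & (radial <= config.neck_radial_margin * lm.head_radius_mm))
    labels[neck] = LABEL_NECK
    if not (labels == LABEL_HEAD).any() or not neck.any():
        raise PartitionError("empty head or neck region; check landmarks")
    return labels
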