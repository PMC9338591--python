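"""Refined head sphere, neck axis and the radial slice group.

The head centre/radius are refined by RANSAC sphere fitting on the
head-labeled vertices (robust to the cam deformity and to junction vertices
contaminating the head region).  The neck axis is refined by locating the
planar cross-section of the neck surface with the smallest circumference —
the anatomical "narrowest point" of the neck — and taking the direction from
the sphere centre through that section's centroid, iterated to a fixed point.
The radial slice group is the family of half-planes bounded by the refined
axis, evenly spaced in azimuth, on which alpha is measured slice by slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GeometryConfig
from .errors import NeckAxisError, SliceAnchorError, SphereFitError, ValidationError
from .surface import LABEL_NECK, TriangleMesh


@dataclass
class SphereFit:
    center_mm: np.ndarray
    radius_mm: float
    inlier_fraction: float
    rms_residual_mm: float

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        if self.radius_mm <= 0:
            raise SphereFitError("non-positive fitted radius")


@dataclass
class NeckAxis:
    anchor_mm: np.ndarray  # head centre
    direction: np.ndarray  # unit, head -> neck
    neck_plane_center_mm: np.ndarray
    neck_min_circumference_mm: float
    iterations: int = 0
    converged: bool = True

    def __post_init__(self):
        self.anchor_mm = np.asarray(self.anchor_mm, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not n > 0 or self.neck_min_circumference_mm <= 0:
            raise NeckAxisError("degenerate neck axis")
        self.direction = self.direction / n


@dataclass
class RadialSliceGroup:
    """Half-planes bounded by the neck axis at evenly spaced azimuths.

    phi = 0 is anchored to the anterior reference direction projected
    orthogonal to the axis; phi grows toward e2 = axis x e1 (so 0 anterior,
    90 superior, 180 posterior, 270 inferior when viewed along the axis from
    head to neck with the standard reference frame).
    """

    axis: NeckAxis
    center_mm: np.ndarray
    azimuths_deg: np.ndarray
    e1: np.ndarray = field(repr=False, default=None)
    e2: np.ndarray = field(repr=False, default=None)

    @property
    def n_slices(self) -> int:
        return len(self.azimuths_deg)

    def direction(self, phi_deg: float, theta_deg: float) -> np.ndarray:
        """Unit ray direction at spherical coordinates about the axis."""
        th, ph = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
        return (np.cos(th) * self.axis.direction
                + np.sin(th) * (np.cos(ph) * self.e1 + np.sin(ph) * self.e2))


# ---------------------------------------------------------------------------
# RANSAC sphere
# ---------------------------------------------------------------------------

def _kasa_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere (exact for noiseless points)."""
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise SphereFitError("algebraic sphere fit degenerate")
    return center, float(np.sqrt(r2))


def ransac_sphere(points: np.ndarray, seed: int = 0,
                  config: GeometryConfig | None = None) -> SphereFit:
    """Robust sphere fit: best of N minimal 4-point hypotheses + LS polish.

    Each hypothesis is the exact circumsphere of 4 sampled points (coplanar
    quadruples rejected); inliers are points within max(0.75 mm, 2% of the
    hypothesis radius) of the hypothesis surface.  The winning consensus set
    is polished by algebraic least squares, inliers are re-selected once
    against the polished sphere, and the final fit is re-estimated on them.
    Deterministic for a fixed seed.
    """
    config = config or GeometryConfig()
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 50:
        raise SphereFitError(f"need >= 50 points, got {n}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(config.ransac_iters, 4))
    ok = np.array([len(set(row)) == 4 for row in idx])
    idx = idx[ok]
    quads = points[idx]  # (m, 4, 3)
    p0 = quads[:, 0]
    A = 2.0 * (quads[:, 1:] - p0[:, None, :])  # (m, 3, 3)
    b = (quads[:, 1:] ** 2).sum(-1) - (p0 ** 2).sum(-1)[:, None]
    det = np.linalg.det(A)
    scale = np.abs(A).max(axis=(1, 2)) ** 3 + 1e-30
    solvable = np.abs(det) > 1e-9 * scale
    centers = np.full((len(A), 3), np.nan)
    centers[solvable] = np.linalg.solve(A[solvable], b[solvable, :, None])[:, :, 0]
    radii = np.linalg.norm(p0 - centers, axis=1)
    thresh = np.maximum(config.ransac_thresh_mm, 0.02 * radii)

    best_count, best_i = -1, -1
    chunk = max(1, int(4e6 // max(n, 1)))
    for s in range(0, len(centers), chunk):
        c, r = centers[s:s + chunk], radii[s:s + chunk]
        good = np.isfinite(r) & (r > 0)
        d = np.linalg.norm(points[None, :, :] - c[:, None, :], axis=2)
        res = np.abs(d - r[:, None])
        counts = np.where(good, (res <= thresh[s:s + chunk, None]).sum(axis=1), -1)
        i = int(np.argmax(counts))
        if counts[i] > best_count:
            best_count, best_i = int(counts[i]), s + i

    if best_count < 4:
        raise SphereFitError("no sphere hypothesis gathered a consensus")
    c0, r0 = centers[best_i], radii[best_i]
    inl = np.abs(np.linalg.norm(points - c0, axis=1) - r0) <= thresh[best_i]
    for _ in range(2):  # polish and re-select once
        c0, r0 = _kasa_sphere(points[inl])
        tol = max(config.ransac_thresh_mm, 0.02 * r0)
        inl = np.abs(np.linalg.norm(points - c0, axis=1) - r0) <= tol
    frac = float(inl.mean())
    if frac < config.min_inlier_frac:
        raise SphereFitError(f"inlier fraction {frac:.2f} below "
                             f"{config.min_inlier_frac}")
    rms = float(np.sqrt(np.mean(
        (np.linalg.norm(points[inl] - c0, axis=1) - r0) ** 2)))
    return SphereFit(center_mm=c0, radius_mm=r0, inlier_fraction=frac,
                     rms_residual_mm=rms)


# ---------------------------------------------------------------------------
# minimal-circumference neck axis
# ---------------------------------------------------------------------------

def _section_perimeters(verts: np.ndarray, faces: np.ndarray, axis: np.ndarray,
                        anchor: np.ndarray, stations: np.ndarray):
    """Perimeter and centroid of the mesh-plane intersection at each station.

    Planes are normal to ``axis`` through ``anchor + t * axis``.  A station is
    only trusted when its section is a set of *closed* loops (every
    intersection point shared by exactly two face segments) that wraps around
    the axis (largest angular gap below 60 degrees): open arcs — partial rims
    where the plane runs off the edge of the neck-labeled band — would
    otherwise masquerade as small-circumference sections.
    """
    tv = (verts - anchor) @ axis
    # in-plane frame for angular-coverage checks
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(tmp @ axis) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    u = tmp - (tmp @ axis) * axis
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)

    out = []
    ft = tv[faces]  # (m, 3)
    for t in stations:
        s = ft - t
        crossing = (s.min(axis=1) < 0) & (s.max(axis=1) > 0)
        if not crossing.any():
            out.append((t, np.nan, None))
            continue
        pts_a, pts_b = [], []
        tri = faces[crossing]
        sv = s[crossing]
        for e0, e1 in ((0, 1), (1, 2), (2, 0)):
            a, b = sv[:, e0], sv[:, e1]
            hit = (a * b) < 0
            if not hit.any():
                continue
            frac = a[hit] / (a[hit] - b[hit])
            p = (verts[tri[hit, e0]]
                 + frac[:, None] * (verts[tri[hit, e1]] - verts[tri[hit, e0]]))
            pts_a.append(np.repeat(np.nonzero(hit)[0], 1))
            pts_b.append(p)
        if not pts_b:
            out.append((t, np.nan, None))
            continue
        face_ids = np.concatenate(pts_a)
        pts = np.concatenate(pts_b)
        # pair the two crossing points of each face into a segment
        order = np.argsort(face_ids, kind="stable")
        face_ids, pts = face_ids[order], pts[order]
        same = face_ids[:-1] == face_ids[1:]
        a_pts = pts[:-1][same]
        b_pts = pts[1:][same]
        seg_len = np.linalg.norm(b_pts - a_pts, axis=1)
        total = float(seg_len.sum())
        if total <= 0:
            out.append((t, np.nan, None))
            continue
        mid = (a_pts + b_pts) / 2.0
        centroid = (mid * seg_len[:, None]).sum(axis=0) / total
        # one closed loop: every crossing point appears on exactly two faces
        # and the segments form a single connected cycle
        n_segments = int(same.sum())
        endpoints = np.vstack([a_pts, b_pts])
        _, point_ids = np.unique(np.round(endpoints, 4), axis=0,
                                 return_inverse=True)
        n_unique = int(point_ids.max()) + 1
        if n_unique != n_segments:
            out.append((t, np.nan, None))
            continue
        parent = np.arange(n_unique)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for pa, pb in zip(point_ids[:n_segments], point_ids[n_segments:]):
            parent[find(pa)] = find(pb)
        if len({find(i) for i in range(n_unique)}) != 1:
            out.append((t, np.nan, None))
            continue
        # angular coverage around the axis
        rel = pts - (anchor + t * axis)
        ang = np.sort(np.arctan2(rel @ w, rel @ u))
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
        if gaps.max() > np.deg2rad(60.0):
            out.append((t, np.nan, None))
            continue
        out.append((t, total, centroid))
    return out


def _neck_waist_index(perims: np.ndarray, uptick: float = 0.05) -> int:
    """Station of the first sustained circumference minimum from the head side.

    Walking distally from the head, the neck circumference shrinks to the
    anatomical waist and then grows toward the trochanter/shaft; the walk
    stops once the perimeter has risen ``uptick`` (5%) above the running
    minimum, so oblique cuts through the shaft further out can never win even
    if they happen to be shorter (ties resolve toward the head).
    """
    valid = np.nonzero(np.isfinite(perims))[0]
    best = valid[0]
    for i in valid[1:]:
        if perims[i] < perims[best]:
            best = i
        elif perims[i] > perims[best] * (1.0 + uptick):
            break
    return int(best)


def min_circumference_neck(mesh: TriangleMesh, labels: np.ndarray,
                           sphere: SphereFit, axis0: np.ndarray,
                           config: GeometryConfig | None = None) -> NeckAxis:
    """Refine the neck axis from the narrowest neck cross-section.

    Planar cross-sections of the neck-labeled surface are taken normal to the
    current axis at stations every ``station_step_mm`` along it; the station
    with the smallest section perimeter defines the neck plane, and the
    refined axis runs from the sphere centre through that section's centroid.
    The procedure is iterated (re-slicing normal to the refined axis) until
    the direction moves less than ``axis_tol_deg`` or ``axis_max_iter`` is
    reached, in which case the last iterate is returned flagged unconverged.
    """
    config = config or GeometryConfig()
    neck_faces = mesh.triangles[(labels[mesh.triangles] == LABEL_NECK).all(axis=1)]
    if len(neck_faces) == 0:
        raise NeckAxisError("no neck-labeled triangles")
    axis = np.asarray(axis0, dtype=float)
    axis = axis / np.linalg.norm(axis)
    anchor = sphere.center_mm

    best = None
    iterations = 0
    converged = False
    for iterations in range(1, config.axis_max_iter + 1):
        tv = (mesh.vertices[np.unique(neck_faces)] - anchor) @ axis
        t0, t1 = float(tv.min()), float(tv.max())
        stations = np.arange(t0 + config.station_step_mm / 2.0, t1,
                             config.station_step_mm)
        if len(stations) == 0:
            raise NeckAxisError("neck band too thin for any slicing station")
        sections = _section_perimeters(mesh.vertices, neck_faces, axis, anchor,
                                       stations)
        perims = np.array([p for _, p, _ in sections])
        if np.all(np.isnan(perims)):
            raise NeckAxisError("no slicing station intersects the neck surface")
        k = _neck_waist_index(perims)
        _, perim, centroid = sections[k]
        new_axis = centroid - anchor
        new_axis = new_axis / np.linalg.norm(new_axis)
        delta = np.degrees(np.arccos(np.clip(axis @ new_axis, -1.0, 1.0)))
        axis = new_axis
        best = (perim, centroid)
        if delta < config.axis_tol_deg:
            converged = True
            break
    perim, centroid = best
    return NeckAxis(anchor_mm=anchor, direction=axis,
                    neck_plane_center_mm=np.asarray(centroid),
                    neck_min_circumference_mm=float(perim),
                    iterations=iterations, converged=converged)


# ---------------------------------------------------------------------------
# radial slice group
# ---------------------------------------------------------------------------

def build_slice_group(sphere: SphereFit, axis: NeckAxis, n_slices: int | None = None,
                      config: GeometryConfig | None = None) -> RadialSliceGroup:
    """Evenly spaced radial half-planes around the refined neck axis.

    ``slice_mode='full'`` spaces ``n_slices`` azimuths over [0, 360) so head
    asphericity anywhere on the circumference is sampled; ``'arc180'`` is the
    legacy clinical arc: ``n_slices`` planes over [0, 180] inclusive
    (7 slices -> the classical 30-degree scheme).
    """
    config = config or GeometryConfig()
    n = int(n_slices if n_slices is not None else config.n_slices)
    if n < 7:
        raise ValidationError("need at least 7 slices")
    d = axis.direction
    ref = np.asarray(config.reference_direction, dtype=float)
    e1 = ref - (ref @ d) * d
    norm = np.linalg.norm(e1)
    if norm < 1e-9:
        raise SliceAnchorError("reference direction parallel to the neck axis")
    e1 /= norm
    e2 = np.cross(d, e1)
    if config.slice_mode == "arc180":
        az = np.linspace(0.0, 180.0, n)
    else:
        az = np.arange(n) * (360.0 / n)
    return RadialSliceGroup(axis=axis, center_mm=sphere.center_mm,
                            azimuths_deg=az, e1=e1, e2=e2)
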