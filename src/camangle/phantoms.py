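"""Voxelized proximal-femur phantoms with analytic alpha-angle ground truth.

The phantom is the union of four solids expressed in world millimetres:

* a quasi-spherical femoral **head** of radius ``R`` centred at ``c``;
* an optional **cam** deformity — supra-spherical bone on the head–neck
  junction, ``r_surface = R * (1 + h * w(theta, phi))`` inside an angular
  window, where ``theta`` is the polar angle measured from the neck-axis
  direction and ``phi`` the azimuth around it;
* a cylindrical **neck** of radius ``r_neck < R`` along the neck axis;
* a conical **trochanteric flare** widening the neck radius to the shaft
  radius along the neck axis (the calcar region);
* a **shaft** cylinder continuing from the flare end at the neck–shaft angle.

The bump profile ``w`` is a flat-topped tapered-cosine (Tukey) window in both
angular coordinates: identically 1 on an interior plateau, raised-cosine
flanks, and exactly 0 on the window boundary.  With that choice the analytic
first-exceedance angle — the largest polar angle at which the surface leaves
the head sphere, i.e. the ground-truth alpha angle — equals ``cam_theta_max``
for every azimuth strictly inside the cam window, while the surface stays
C1-smooth.

Because every solid is analytic, the module can also emit exact surface-radius
fields and radial-slice contours, which downstream tests use as independent
oracles for the voxel pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import DimensionError, ValidationError
from .volume_io import VoxelMask

__all__ = [
    "FemurPhantomSpec",
    "GroundTruthAlpha",
    "generate_phantom",
    "analytic_alpha",
    "analytic_surface_radius",
    "analytic_contour",
    "analytic_roundness",
]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("zero-length direction vector")
    return v / n


def tukey_window(x: np.ndarray, lo: float, hi: float, taper: float) -> np.ndarray:
    """Flat-topped raised-cosine window on [lo, hi].

    0 outside and on the boundary, 1 on [lo + taper, hi - taper], cosine
    flanks of width ``taper``.  If 2 * taper >= hi - lo the window degenerates
    to a full raised cosine (Hann) over the interval.
    """
    x = np.asarray(x, dtype=float)
    width = hi - lo
    t = min(taper, width / 2.0)
    w = np.zeros_like(x)
    inside = (x > lo) & (x < hi)
    if t <= 0:
        w[inside] = 1.0
        return w
    xi = x - lo
    rise = inside & (xi < t)
    fall = inside & (xi > width - t)
    flat = inside & ~rise & ~fall
    w[flat] = 1.0
    w[rise] = 0.5 * (1.0 - np.cos(np.pi * xi[rise] / t))
    w[fall] = 0.5 * (1.0 - np.cos(np.pi * (width - xi[fall]) / t))
    return w


@dataclass(frozen=True)
class FemurPhantomSpec:
    """Parametric description of a proximal-femur phantom.

    Angles are in degrees; lengths in millimetres.  ``neck_axis_direction``
    points from the head centre into the neck.  The cam window is given in
    spherical coordinates about the neck axis: polar angle ``theta`` from the
    axis direction (the head apex sits at theta = 180) and azimuth ``phi``
    about it, with phi = 0 anchored to ``reference_direction`` (anterior).
    """

    head_radius_mm: float = 24.0
    neck_radius_mm: float = 16.0
    neck_length_mm: float = 30.0
    neck_flare_length_mm: float = 10.0
    shaft_radius_mm: float = 14.0
    shaft_length_mm: float = 40.0
    neck_shaft_angle_deg: float = 130.0
    neck_axis_direction: tuple[float, float, float] = (0.6, 0.0, 0.8)
    head_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    reference_direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    cam_present: bool = False
    cam_theta_min_deg: float = 45.0
    cam_theta_max_deg: float = 70.0
    cam_phi_min_deg: float = 0.0
    cam_phi_max_deg: float = 60.0
    cam_height_frac: float = 0.15
    cam_taper_theta_deg: float = 3.0
    cam_taper_phi_deg: float = 6.0
    surface_noise_mm: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.head_radius_mm, self.neck_radius_mm, self.neck_length_mm,
               self.shaft_radius_mm, self.shaft_length_mm) <= 0:
            raise ValidationError("all phantom lengths must be positive")
        if self.neck_radius_mm >= self.head_radius_mm:
            raise ValidationError("neck radius must be smaller than head radius")
        d = np.asarray(self.neck_axis_direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValidationError("neck_axis_direction must have unit norm (1e-9)")
        if self.cam_height_frac < 0:
            raise ValidationError("cam_height_frac must be >= 0")
        if self.cam_present:
            if not 0 < self.cam_theta_min_deg < self.cam_theta_max_deg <= 170:
                raise ValidationError("need 0 < cam_theta_min < cam_theta_max <= 170")
            if not self.cam_phi_min_deg < self.cam_phi_max_deg:
                raise ValidationError("need cam_phi_min < cam_phi_max")

    # -- derived frames -------------------------------------------------
    @property
    def axis(self) -> np.ndarray:
        return np.asarray(self.neck_axis_direction, dtype=float)

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.head_center_mm, dtype=float)

    def azimuth_frame(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit vectors (e1, e2) spanning the plane orthogonal to the axis.

        phi = 0 along e1 (the anterior reference projected off-axis);
        phi grows toward e2 = axis x e1.
        """
        d = self.axis
        r = np.asarray(self.reference_direction, dtype=float)
        e1 = r - (r @ d) * d
        n = np.linalg.norm(e1)
        if n < 1e-9:
            raise ValidationError("reference direction parallel to the neck axis")
        e1 /= n
        return e1, np.cross(d, e1)

    def flare_target_radius(self) -> float:
        """Radius at the distal end of the trochanteric flare.

        The bone widens distal to the neck waist (greater/lesser trochanter),
        so the flare always ends wider than the neck regardless of the shaft
        radius — otherwise a narrow shaft would fake a second, distal waist.
        """
        return max(self.shaft_radius_mm, self.neck_radius_mm + 4.0)

    def shaft_direction(self) -> np.ndarray:
        """Shaft axis (proximal -> distal), tilted off the neck axis.

        The neck–shaft angle is the anatomical angle between the two axes, so
        the shaft direction makes (180 - angle) degrees with the neck
        direction, bent within the plane spanned by the neck axis and e1.
        """
        d = self.axis
        e1, _ = self.azimuth_frame()
        bend = np.deg2rad(180.0 - self.neck_shaft_angle_deg)
        return np.cos(bend) * d + np.sin(bend) * e1

    def bump(self, theta_deg: np.ndarray, phi_deg: np.ndarray) -> np.ndarray:
        """Bump profile w(theta, phi) in [0, 1]; 0 when no cam is present."""
        theta_deg = np.asarray(theta_deg, dtype=float)
        phi_deg = np.asarray(phi_deg, dtype=float)
        if not self.cam_present or self.cam_height_frac == 0:
            return np.zeros(np.broadcast(theta_deg, phi_deg).shape)
        wt = tukey_window(theta_deg, self.cam_theta_min_deg,
                          self.cam_theta_max_deg, self.cam_taper_theta_deg)
        span = (self.cam_phi_max_deg - self.cam_phi_min_deg) / 2.0
        mid = (self.cam_phi_max_deg + self.cam_phi_min_deg) / 2.0
        dphi = (phi_deg - mid + 180.0) % 360.0 - 180.0  # wrap to (-180, 180]
        wp = tukey_window(dphi, -span, span, self.cam_taper_phi_deg)
        return wt * wp

    # -- (de)serialization ----------------------------------------------
    def to_json(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "FemurPhantomSpec":
        d = json.loads(Path(path).read_text())
        for k in ("neck_axis_direction", "head_center_mm", "reference_direction"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruthAlpha:
    """Dense analytic alpha profile, 1 degree azimuth steps over [0, 360)."""

    phi_deg: np.ndarray
    alpha_deg: np.ndarray
    baseline_alpha_deg: float

    def at(self, phi: float) -> float:
        """Truth alpha at an arbitrary azimuth (nearest tabulated value)."""
        i = int(np.argmin(np.abs((self.phi_deg - phi + 180.0) % 360.0 - 180.0)))
        return float(self.alpha_deg[i])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"phi_deg": self.phi_deg, "alpha_deg": self.alpha_deg}).to_csv(
            path, index=False)


# ---------------------------------------------------------------------------
# analytic surface model
# ---------------------------------------------------------------------------

def analytic_surface_radius(spec: FemurPhantomSpec,
                            theta_deg: np.ndarray,
                            phi_deg: np.ndarray) -> np.ndarray:
    """Exact distance from the head centre to the phantom surface.

    Evaluated along the ray at spherical coordinates (theta from the neck
    axis, phi about it).  Covers head, cam and neck (wall and end cap); the
    shaft is deliberately excluded — it never forms the first bone-exit
    surface in the angular range where alpha is defined.
    """
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    theta_deg = np.asarray(theta_deg, dtype=float)
    phi_deg = np.asarray(phi_deg, dtype=float)
    R, rn, L = spec.head_radius_mm, spec.neck_radius_mm, spec.neck_length_mm

    r = np.full(np.broadcast(theta, phi_deg).shape, R, dtype=float)
    # cam shell
    w = spec.bump(theta_deg, phi_deg)
    r = np.maximum(r, R * (1.0 + spec.cam_height_frac * w))
    # neck wall: exit at rn / sin(theta), valid while still on the cylinder
    with np.errstate(divide="ignore", invalid="ignore"):
        sin_t = np.sin(theta)
        cos_t = np.cos(theta)
        wall = np.where(sin_t > 1e-12, rn / sin_t, np.inf)
        wall_ok = (cos_t > 0) & (wall * cos_t <= L)
        r = np.maximum(r, np.where(wall_ok, wall, -np.inf))
        # neck end cap: exit at L / cos(theta) if the ray leaves axially
        cap = np.where(cos_t > 1e-12, L / cos_t, np.inf)
        cap_ok = (cos_t > 1e-12) & (cap * sin_t <= rn)
        r = np.maximum(r, np.where(cap_ok, cap, -np.inf))
    return r


def analytic_alpha(spec: FemurPhantomSpec, tol_mm: float = 0.0) -> GroundTruthAlpha:
    """Closed-form alpha profile of the phantom.

    Alpha at azimuth phi is the largest polar angle at which the surface
    radius exceeds the head radius by more than ``tol_mm`` when sweeping from
    the head apex (theta = 180) toward the neck axis; without a detectable cam
    this is the spherical-junction baseline arcsin(r_neck / R).

    With ``tol_mm = 0`` the profile is the exact geometric truth: the bump is
    positive everywhere strictly inside its window, so alpha equals
    ``cam_theta_max_deg`` for every azimuth strictly inside the cam span.
    """
    R = spec.head_radius_mm
    baseline = float(np.degrees(np.arcsin(spec.neck_radius_mm / R)))
    phi = np.arange(0.0, 360.0, 1.0)
    alpha = np.full(phi.shape, baseline)
    if spec.cam_present and spec.cam_height_frac > 0:
        # dense theta scan of the analytic bump; 0.01 deg resolution near the
        # cam upper edge keeps the tabulated truth sharp.
        theta = np.arange(spec.cam_theta_min_deg, spec.cam_theta_max_deg + 1e-9, 0.01)
        w = spec.bump(theta[None, :], phi[:, None])
        exceeds = R * spec.cam_height_frac * w > tol_mm
        has = exceeds.any(axis=1)
        last = np.where(has, exceeds.shape[1] - 1 - np.argmax(exceeds[:, ::-1], axis=1), 0)
        cam_alpha = theta[last]
        alpha = np.where(has, np.maximum(cam_alpha, baseline), alpha)
    return GroundTruthAlpha(phi_deg=phi, alpha_deg=alpha, baseline_alpha_deg=baseline)


def analytic_contour(spec: FemurPhantomSpec, phi_deg: float,
                     step_deg: float = 0.1) -> np.ndarray:
    """Exact 2D contour of the radial plane at azimuth ``phi_deg``.

    Returns an ordered (N, 2) polyline in plane coordinates (x along the neck
    axis, y along the in-plane radial direction e(phi)); y > 0 is the
    ``phi_deg`` half-plane, y < 0 the antipodal half-plane at phi + 180.
    """
    theta = np.arange(step_deg, 180.0, step_deg)
    r_pos = analytic_surface_radius(spec, theta, np.full_like(theta, phi_deg % 360.0))
    r_neg = analytic_surface_radius(spec, theta,
                                    np.full_like(theta, (phi_deg + 180.0) % 360.0))
    ct, st = np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))
    upper = np.column_stack([r_pos * ct, r_pos * st])
    lower = np.column_stack([r_neg * ct, -r_neg * st])
    # one open loop: neck side (+) -> apex -> neck side (-)
    return np.vstack([upper, lower[::-1]])


def analytic_roundness(spec: FemurPhantomSpec, azimuths_deg: np.ndarray,
                       theta_deg: np.ndarray) -> np.ndarray:
    """Exact roundness field rho(phi, theta) = surface radius / head radius."""
    az = np.asarray(azimuths_deg, dtype=float)[:, None]
    th = np.asarray(theta_deg, dtype=float)[None, :]
    return analytic_surface_radius(spec, th, az) / spec.head_radius_mm


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def generate_phantom(spec: FemurPhantomSpec,
                     spacing_mm=1.0,
                     padding_mm: float = 8.0) -> VoxelMask:
    """Voxelize the phantom solid on an axis-aligned grid.

    A voxel is foreground when its centre lies inside the solid (centre-in-
    solid test).  The grid is sized to enclose the phantom plus ``padding_mm``
    on every side; the returned mask carries the spacing and world origin.
    """
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,)).copy()
    if np.any(spacing <= 0.2) or np.any(spacing > 2.0):
        raise ValidationError("voxel spacing components must be in (0.2, 2.0] mm")

    c, d = spec.center, spec.axis
    R = spec.head_radius_mm
    if spec.cam_present:
        R *= 1.0 + spec.cam_height_frac
    flare_end = spec.neck_length_mm + spec.neck_flare_length_mm
    q0 = c + flare_end * d
    s_dir = spec.shaft_direction()
    q1 = q0 + spec.shaft_length_mm * s_dir
    # bounding box over all primitives
    wide = max(spec.shaft_radius_mm, spec.flare_target_radius())
    lo = np.minimum.reduce([c - R,
                            np.minimum(c, q0) - wide,
                            np.minimum(q0, q1) - wide])
    hi = np.maximum.reduce([c + R,
                            np.maximum(c, q0) + wide,
                            np.maximum(q0, q1) + wide])
    origin = lo - padding_mm
    shape = np.ceil((hi + padding_mm - origin) / spacing).astype(int) + 1
    if np.any(shape < 8):
        raise DimensionError("phantom grid degenerate; increase padding or extent")
    if np.prod(shape) > 6e7:
        raise DimensionError("phantom grid too large; coarsen spacing")

    ax = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    X = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    v = X - c
    rr = np.linalg.norm(v, axis=1)

    noise = 0.0
    if spec.surface_noise_mm > 0:
        rng = np.random.default_rng(spec.rng_seed)
        noise = rng.normal(0.0, spec.surface_noise_mm, rr.shape)

    occ = rr <= spec.head_radius_mm + noise
    # cam shell
    if spec.cam_present and spec.cam_height_frac > 0:
        with np.errstate(invalid="ignore"):
            ct = np.clip(np.where(rr > 0, (v @ d) / np.maximum(rr, 1e-12), 1.0), -1, 1)
        theta = np.degrees(np.arccos(ct))
        e1, e2 = spec.azimuth_frame()
        phi = np.degrees(np.arctan2(v @ e2, v @ e1)) % 360.0
        w = spec.bump(theta, phi)
        occ |= rr <= spec.head_radius_mm * (1.0 + spec.cam_height_frac * w) + noise
    # neck cylinder, then trochanteric flare (cone from r_neck to r_shaft)
    t = v @ d
    radial = np.sqrt(np.maximum(rr ** 2 - t ** 2, 0.0))
    occ |= (t >= 0) & (t <= spec.neck_length_mm) & (radial <= spec.neck_radius_mm + noise)
    frac = np.clip((t - spec.neck_length_mm) / spec.neck_flare_length_mm, 0.0, 1.0)
    flare_r = spec.neck_radius_mm + frac * (spec.flare_target_radius() - spec.neck_radius_mm)
    occ |= ((t > spec.neck_length_mm) & (t <= flare_end) & (radial <= flare_r))
    # shaft cylinder
    w2 = X - q0
    ts = w2 @ s_dir
    rad_s = np.linalg.norm(w2 - ts[:, None] * s_dir, axis=1)
    occ |= (ts >= 0) & (ts <= spec.shaft_length_mm) & (rad_s <= spec.shaft_radius_mm)

    return VoxelMask(occupancy=occ.reshape(shape), spacing_mm=spacing,
                     origin_mm=origin)


def default_phantom_spec(**overrides) -> FemurPhantomSpec:
    """Adult-scale default phantom (R = 24 mm, r_neck = 16 mm)."""
    return replace(FemurPhantomSpec(), **overrides) if overrides else FemurPhantomSpec()
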