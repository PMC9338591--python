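"""Run configuration for the measurement pipeline.

All thresholds the pipeline depends on live here with their defaults, so a
result file can echo the exact configuration that produced it and a run can
be reproduced from that echo alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .errors import ValidationError


@dataclass
class SurfaceConfig:
    """Mask-to-mesh and head/neck partition parameters.

    head_margin, neck_band and neck_radial_margin are expressed as multiples
    of the initial head radius; smooth_sigma_vox is the Gaussian pre-smoothing
    applied to the binary mask (in voxels) before iso-surfacing, which places
    the 0.5 level set much closer to the true bone boundary than iso-surfacing
    the raw binary grid.
    """

    head_margin: float = 1.10
    neck_band: tuple[float, float] = (0.8, 2.2)
    neck_radial_margin: float = 1.2
    shell_band: tuple[float, float] = (1.1, 2.0)
    smooth_sigma_vox: float = 0.7
    min_vertices: int = 100


@dataclass
class GeometryConfig:
    """Sphere fit, neck-axis refinement and radial slice group parameters."""

    ransac_iters: int = 2000
    ransac_thresh_mm: float = 0.75  # floor; effective threshold max(floor, 0.02 r)
    min_inlier_frac: float = 0.5
    station_step_mm: float = 1.0
    axis_tol_deg: float = 0.5
    axis_max_iter: int = 10
    n_slices: int = 120
    slice_mode: str = "full"  # "full": [0, 360); "arc180": legacy 7-plane arc
    reference_direction: tuple[float, float, float] = (0.0, 1.0, 0.0)  # anterior


@dataclass
class AlphaConfig:
    """Roundness map and optimal-cut parameters.

    tau_floor_mm is the absolute asphericity tolerance floor: a surface point
    only counts as aspherical when it protrudes more than
    max(tau_floor_mm, half voxel diagonal) beyond the fitted head sphere.
    """

    theta_step_deg: float = 0.5
    theta_max_deg: float = 175.0
    tau_floor_mm: float = 0.6
    w_head: float = 10.0
    w_neck: float = 1.0
    lambda_smooth: float = 2.0
    max_missing_frac: float = 0.3


@dataclass
class RunConfig:
    surface: SurfaceConfig = field(default_factory=SurfaceConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    alpha: AlphaConfig = field(default_factory=AlphaConfig)
    seed: int = 0

    def validate(self) -> "RunConfig":
        g, a, s = self.geometry, self.alpha, self.surface
        if g.ransac_iters < 1 or g.ransac_thresh_mm <= 0:
            raise ValidationError("RANSAC iterations and threshold must be positive")
        if not 0 < g.min_inlier_frac <= 1:
            raise ValidationError("min_inlier_frac must be in (0, 1]")
        if g.slice_mode not in ("full", "arc180"):
            raise ValidationError(f"unknown slice_mode {g.slice_mode!r}")
        if g.n_slices < 7 or g.n_slices > 360:
            raise ValidationError("n_slices must be in [7, 360]")
        if not 0 < a.theta_step_deg <= 2.0:
            raise ValidationError("theta_step_deg must be in (0, 2]")
        if a.w_head <= 0 or a.w_neck < 0 or a.lambda_smooth < 0:
            raise ValidationError("cut weights must be non-negative (w_head > 0)")
        if s.neck_band[0] >= s.neck_band[1] or s.shell_band[0] >= s.shell_band[1]:
            raise ValidationError("band limits must be increasing")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, sub):
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - fields
            if unknown:
                raise ValidationError(f"unknown config keys {sorted(unknown)}")
            sub = {k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()}
            return klass(**sub)

        cfg = cls(
            surface=build(SurfaceConfig, d.get("surface", {})),
            geometry=build(GeometryConfig, d.get("geometry", {})),
            alpha=build(AlphaConfig, d.get("alpha", {})),
            seed=int(d.get("seed", 0)),
        )
        return cfg.validate()

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
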