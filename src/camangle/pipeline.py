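"""End-to-end automated alpha-angle measurement.

Chains the pipeline stages: mask -> surface mesh -> initial landmarks ->
head/neck partition -> RANSAC head sphere -> minimal-circumference neck axis
-> radial slice group -> roundness map -> optimal-cut alpha profile -> seven
named clinical planes.  The result object carries every fitted quantity plus
run metadata (stage durations, convergence flags, config echo, seed, tool
version) so a run is fully reproducible from its own output.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .alpha import (
    AlphaProfile,
    RoundnessMap,
    alpha_by_optimal_cut,
    build_roundness_map,
    select_named_planes,
)
from .config import RunConfig
from .geometry import (
    NeckAxis,
    RadialSliceGroup,
    SphereFit,
    build_slice_group,
    min_circumference_neck,
    ransac_sphere,
)
from .surface import (
    LABEL_HEAD,
    InitialLandmarks,
    TriangleMesh,
    extract_surface,
    initial_landmarks,
    partition_head_neck,
)
from .volume_io import VoxelMask


@dataclass
class MeasureResult:
    sphere: SphereFit
    axis: NeckAxis
    slice_group: RadialSliceGroup
    roundness: RoundnessMap
    profile: AlphaProfile
    named_planes: pd.DataFrame
    landmarks: InitialLandmarks
    mesh: TriangleMesh
    config: RunConfig
    seed: int
    tau: float
    metadata: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "schema_version": 1,
            "tool": "camangle",
            "version": __version__,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "sphere": {
                "center_mm": self.sphere.center_mm.tolist(),
                "radius_mm": self.sphere.radius_mm,
                "inlier_fraction": self.sphere.inlier_fraction,
                "rms_residual_mm": self.sphere.rms_residual_mm,
            },
            "neck_axis": {
                "anchor_mm": self.axis.anchor_mm.tolist(),
                "direction": self.axis.direction.tolist(),
                "neck_plane_center_mm": self.axis.neck_plane_center_mm.tolist(),
                "neck_min_circumference_mm": self.axis.neck_min_circumference_mm,
                "iterations": self.axis.iterations,
                "converged": self.axis.converged,
            },
            "asphericity_tolerance_frac": self.tau,
            "alpha_profile": {
                "azimuth_deg": self.profile.azimuth_deg.tolist(),
                "alpha_deg": self.profile.alpha_deg.tolist(),
                "flags": self.profile.flags.tolist(),
            },
            "named_planes": self.named_planes.drop(columns=["hip_id", "rater"])
                                             .to_dict(orient="records"),
            "metadata": self.metadata,
        }

    def profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "azimuth_deg": self.profile.azimuth_deg,
            "alpha_deg": self.profile.alpha_deg,
            "flag": self.profile.flags,
        })


def measure_alpha(mask: VoxelMask, config: RunConfig | None = None,
                  seed: int | None = None, hip_id: str = "hip") -> MeasureResult:
    """Run the full automated measurement on one segmentation mask."""
    config = (config or RunConfig()).validate()
    seed = config.seed if seed is None else int(seed)
    meta: dict = {"stages": {}}

    def stage(name, fn):
        t0 = time.perf_counter()
        out = fn()
        meta["stages"][name] = round(time.perf_counter() - t0, 3)
        return out

    mask.require_nonempty()
    mesh = stage("surface", lambda: extract_surface(mask, config.surface))
    lm = stage("landmarks", lambda: initial_landmarks(mask, config.surface))
    labels = stage("partition", lambda: partition_head_neck(mesh, lm, config.surface))
    head_pts = mesh.vertices[labels == LABEL_HEAD]
    sphere = stage("ransac_sphere",
                   lambda: ransac_sphere(head_pts, seed=seed, config=config.geometry))
    axis = stage("neck_axis",
                 lambda: min_circumference_neck(mesh, labels, sphere, lm.neck_axis,
                                                config.geometry))
    group = build_slice_group(sphere, axis, config=config.geometry)
    rmap = stage("roundness_map",
                 lambda: build_roundness_map(mesh, sphere, group, config.alpha))
    half_diag = 0.5 * float(np.linalg.norm(mask.spacing_mm))
    tau = max(config.alpha.tau_floor_mm, half_diag) / sphere.radius_mm
    profile = stage("optimal_cut",
                    lambda: alpha_by_optimal_cut(rmap, tau=tau, config=config.alpha))
    named = select_named_planes(profile, hip_id=hip_id)
    meta["axis_iterations"] = axis.iterations
    meta["axis_converged"] = axis.converged
    meta["sphere_inlier_fraction"] = sphere.inlier_fraction
    meta["n_vertices"] = int(len(mesh.vertices))
    return MeasureResult(sphere=sphere, axis=axis, slice_group=group,
                         roundness=rmap, profile=profile, named_planes=named,
                         landmarks=lm, mesh=mesh, config=config, seed=seed,
                         tau=tau, metadata=meta)
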