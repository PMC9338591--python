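"""Roundness map, optimal-cut DP, Noetzli 2D construction, named planes."""

from itertools import product

import numpy as np
import pytest

from camangle.alpha import (
    FLAG_EXTRAPOLATED,
    NAMED_PLANES,
    AlphaProfile,
    RoundnessMap,
    _cut_data_term,
    alpha_by_optimal_cut,
    build_roundness_map,
    notzli_alpha_2d,
    optimal_cut_indices,
    select_named_planes,
)
from camangle.geometry import NeckAxis, SphereFit, build_slice_group
from camangle.phantoms import FemurPhantomSpec, analytic_contour, analytic_roundness
from camangle.surface import extract_surface
from camangle.volume_io import VoxelMask


def make_map(rho: np.ndarray, theta_step=1.0) -> RoundnessMap:
    n_phi, n_theta = rho.shape
    return RoundnessMap(rho=rho, sampled=np.isfinite(rho),
                        phi_deg=np.arange(n_phi) * 360.0 / n_phi,
                        theta_deg=np.arange(1, n_theta + 1) * theta_step)


def analytic_map(spec, n_phi=72, theta_step=0.5, theta_max=175.0):
    az = np.arange(n_phi) * 360.0 / n_phi
    th = np.arange(theta_step, theta_max + 1e-9, theta_step)
    return make_map(analytic_roundness(spec, az, th), theta_step)


@pytest.fixture(scope="module")
def sphere_map():
    x = np.arange(-26.0, 27.0)
    G = np.stack(np.meshgrid(x, x, x, indexing="ij"), axis=-1)
    occ = np.linalg.norm(G, axis=-1) <= 20.0
    mask = VoxelMask(occupancy=occ, spacing_mm=np.ones(3),
                     origin_mm=np.full(3, -26.0))
    mesh = extract_surface(mask)
    sph = SphereFit(center_mm=np.zeros(3), radius_mm=20.0,
                    inlier_fraction=1.0, rms_residual_mm=0.0)
    ax = NeckAxis(anchor_mm=np.zeros(3), direction=np.array([0.6, 0.0, 0.8]),
                  neck_plane_center_mm=np.array([18.0, 0.0, 24.0]),
                  neck_min_circumference_mm=100.0)
    grp = build_slice_group(sph, ax, n_slices=36)
    return mesh, sph, ax, grp, build_roundness_map(mesh, sph, grp)


class TestRoundnessMap:
    def test_sphere_roundness_is_unity(self, sphere_map):
        *_, rmap = sphere_map
        band = rmap.theta_deg > 30.0
        assert np.nanmean(np.abs(rmap.rho[:, band] - 1.0)) < 0.02

    def test_rotation_covariance(self, sphere_map):
        mesh, sph, ax, grp, rmap = sphere_map
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        from camangle.config import GeometryConfig
        from camangle.surface import TriangleMesh

        mesh_r = TriangleMesh(vertices=mesh.vertices @ R.T,
                              triangles=mesh.triangles)
        ax_r = NeckAxis(anchor_mm=R @ ax.anchor_mm, direction=R @ ax.direction,
                        neck_plane_center_mm=R @ ax.neck_plane_center_mm,
                        neck_min_circumference_mm=ax.neck_min_circumference_mm)
        cfg = GeometryConfig(reference_direction=tuple(R @ np.array([0.0, 1.0, 0.0])))
        grp_r = build_slice_group(sph, ax_r, n_slices=36, config=cfg)
        rmap_r = build_roundness_map(mesh_r, sph, grp_r)
        assert np.allclose(rmap_r.rho, rmap.rho, atol=1e-9, equal_nan=True)

    def test_neck_cone_closed_form(self, baseline_runs):
        spec, _, res = baseline_runs[0.7]
        rmap = res.roundness
        baseline = np.degrees(np.arcsin(0.7))
        j = int(np.argmin(np.abs(rmap.theta_deg - 0.8 * baseline)))
        want = (spec.neck_radius_mm
                / np.sin(np.deg2rad(rmap.theta_deg[j]))) / res.sphere.radius_mm
        col = rmap.rho[:, j]
        assert np.nanmedian(col) == pytest.approx(want, rel=0.02)
        assert want > 1.0


class TestOptimalCut:
    def test_zero_smoothness_equals_per_column_minimum(self):
        rng = np.random.default_rng(12345)
        for _ in range(50):
            rho = rng.uniform(0.8, 1.3, (int(rng.integers(8, 30)),
                                         int(rng.integers(10, 60))))
            D = _cut_data_term(make_map(rho), 0.05, 10.0, 1.0)
            assert np.array_equal(optimal_cut_indices(D, 0.0),
                                  D.argmin(axis=1))

    def test_large_smoothness_forces_best_constant_cut(self):
        rng = np.random.default_rng(7)
        rho = rng.uniform(0.8, 1.3, (24, 40))
        D = _cut_data_term(make_map(rho), 0.05, 10.0, 1.0)
        cut = optimal_cut_indices(D, 1e8)
        assert len(set(cut.tolist())) == 1
        assert cut[0] == int(D.sum(axis=0).argmin())

    def test_circular_dp_matches_brute_force(self):
        rng = np.random.default_rng(99)
        lam = 0.7
        for _ in range(5):
            D = rng.uniform(0.0, 5.0, (5, 6))
            best = min(
                sum(D[i, c[i]] for i in range(5))
                + lam * sum(abs(c[(i + 1) % 5] - c[i]) for i in range(5))
                for c in product(range(6), repeat=5))
            cut = optimal_cut_indices(D, lam)
            cost = (sum(D[i, cut[i]] for i in range(5))
                    + lam * sum(abs(int(cut[(i + 1) % 5]) - int(cut[i]))
                                for i in range(5)))
            assert cost == pytest.approx(best, abs=1e-9)

    def test_exact_map_cut_at_baseline(self):
        spec = FemurPhantomSpec()
        rmap = analytic_map(spec)
        prof = alpha_by_optimal_cut(rmap, tau=1e-3, lambda_smooth=0.0,
                                    refine=False)
        baseline = np.degrees(np.arcsin(2.0 / 3.0))
        assert np.all(np.abs(prof.alpha_deg - baseline) <= 0.5 + 1e-9)

    def test_cam_map_recovers_plateau_and_baseline(self):
        spec = FemurPhantomSpec(cam_present=True, cam_theta_min_deg=50,
                                cam_theta_max_deg=70, cam_phi_min_deg=0,
                                cam_phi_max_deg=60, cam_height_frac=0.15)
        prof = alpha_by_optimal_cut(analytic_map(spec), tau=0.025)
        az = prof.azimuth_deg
        plateau = (az >= 6) & (az <= 54)
        assert np.all(np.abs(prof.alpha_deg[plateau] - 70.0) <= 1.0)
        anti = prof.alpha_deg[np.argmin(np.abs(az - 180.0))]
        assert anti == pytest.approx(np.degrees(np.arcsin(2 / 3)), abs=1.0)

    def test_monotone_in_cam_severity(self):
        prev = None
        for tmax in (55.0, 62.0, 70.0, 78.0, 85.0):
            spec = FemurPhantomSpec(cam_present=True,
                                    cam_theta_min_deg=tmax - 20,
                                    cam_theta_max_deg=tmax)
            prof = alpha_by_optimal_cut(analytic_map(spec), tau=0.025)
            inside = prof.alpha_deg[(prof.azimuth_deg >= 10)
                                    & (prof.azimuth_deg <= 50)]
            if prev is not None:
                assert np.all(inside >= prev - 0.5)
            prev = inside

    def test_empty_column_flagged_and_interpolated(self):
        rng = np.random.default_rng(5)
        rho = rng.uniform(0.99, 1.01, (12, 30))
        rho[:, :8] = 1.2  # a neck-like exceedance band
        rho[4, :] = np.nan
        prof = alpha_by_optimal_cut(make_map(rho), tau=0.05)
        assert prof.flags[4] == FLAG_EXTRAPOLATED
        assert np.isfinite(prof.alpha_deg[4])

    def test_periodicity_on_symmetric_phantom(self, baseline_runs):
        _, _, res = baseline_runs[0.6]
        spread = res.profile.alpha_deg.max() - res.profile.alpha_deg.min()
        assert spread <= 3.0  # rotationally symmetric within map resolution


class TestNotzli2D:
    def test_sphere_cylinder_baseline(self):
        nz = notzli_alpha_2d(analytic_contour(FemurPhantomSpec(), 0.0),
                             np.zeros(2))
        assert nz.ok
        assert nz.alpha_deg == pytest.approx(41.81, abs=0.2)
        assert nz.r == pytest.approx(24.0, abs=0.1)

    def test_cam_contour_alpha_at_bump_edge(self):
        spec = FemurPhantomSpec(cam_present=True, cam_theta_min_deg=50,
                                cam_theta_max_deg=70)
        nz = notzli_alpha_2d(analytic_contour(spec, 30.0), np.zeros(2))
        assert nz.ok
        assert nz.alpha_deg == pytest.approx(70.0, abs=0.5)
        assert np.linalg.norm(nz.A - nz.hc) > nz.r

    def test_pure_circle_has_no_exceedance(self):
        th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        circle = 24.0 * np.column_stack([np.cos(th), np.sin(th)])
        nz = notzli_alpha_2d(circle, np.zeros(2),
                             neck_point=np.array([24.0, 0.0]))
        assert not nz.ok and nz.alpha_deg is None

    def test_antipodal_side_of_cam_slice_reads_baseline(self):
        spec = FemurPhantomSpec(cam_present=True, cam_theta_min_deg=50,
                                cam_theta_max_deg=70)
        nz = notzli_alpha_2d(analytic_contour(spec, 30.0), np.zeros(2), side=-1)
        assert nz.ok
        assert nz.alpha_deg == pytest.approx(41.81, abs=0.5)

    def test_too_few_points_rejected(self):
        from camangle.errors import ValidationError

        with pytest.raises(ValidationError):
            notzli_alpha_2d(np.zeros((10, 2)), np.zeros(2))


class TestNamedPlanes:
    def make_profile(self, az, alpha):
        return AlphaProfile(azimuth_deg=np.asarray(az, float),
                            alpha_deg=np.asarray(alpha, float),
                            flags=np.full(len(az), "ok", dtype=object))

    def test_grid_alignment_at_120_slices(self):
        az = np.arange(120) * 3.0
        prof = self.make_profile(az, az * 0 + 55.0 + az / 100)
        rows = select_named_planes(prof).set_index("plane")
        assert rows.loc["superior", "matched_azimuth_deg"] == 90.0
        assert not rows["warning"].any()

    def test_seven_plane_arc_identity(self):
        az = [0, 30, 60, 90, 120, 150, 180]
        prof = self.make_profile(az, [50, 51, 52, 53, 54, 55, 56])
        rows = select_named_planes(prof)
        assert np.array_equal(rows["matched_azimuth_deg"].to_numpy(),
                              np.asarray(az, float))
        assert np.array_equal(rows["alpha_deg"].to_numpy(),
                              np.asarray([50, 51, 52, 53, 54, 55, 56], float))

    def test_constant_profile_gives_equal_values(self):
        prof = self.make_profile(np.arange(36) * 10.0, np.full(36, 47.0))
        rows = select_named_planes(prof)
        assert np.all(rows["alpha_deg"] == 47.0)
        assert set(rows["plane"]) == set(NAMED_PLANES)
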