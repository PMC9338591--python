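"""Alpha-angle computation.

Two independent routes to the same clinical quantity:

* **Automated 3D route** — a roundness map rho(phi, theta) is sampled by
  casting rays from the fitted head centre (theta is the polar angle from the
  neck-axis direction, phi the slice azimuth); rho is the surface radius
  divided by the fitted head radius.  The per-azimuth alpha profile is the
  polar angle of an optimal horizontal cut through that map: the cut that
  minimizes an asymmetric misclassification cost (asphericity left on the
  head side of the cut is penalized heavily, sphericity left on the neck side
  lightly) plus an L1 smoothness penalty on the cut's azimuthal variation,
  solved exactly by dynamic programming over the circular azimuth domain.

* **Manual 2D route (Noetzli construction)** — on a single radial-plane
  contour: a best-fit circle to the head arc gives the head centre ``hc`` and
  radius ``r``; the neck centre ``nc`` is the midpoint of the narrowest
  cross-section of the neck; point ``A`` is the first contour point, walking
  from the head apex toward the neck, whose distance from ``hc`` exceeds the
  circle radius (by more than a small tolerance); alpha is the angle A-hc-nc.

The single most consequential convention, shared by both routes: **the
traversal for point A runs from the head apex toward the neck**, so alpha is
the largest polar angle at which the bone still departs from sphericity —
the head-side edge of the cam.  With theta measured from the head-to-neck
axis direction, the cut angle *is* the alpha angle, with no offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AlphaConfig
from .errors import RoundnessMapError, ValidationError
from .geometry import RadialSliceGroup, SphereFit
from .surface import TriangleMesh

NAMED_PLANES = {
    "anterior": 0.0,
    "anterior-superior": 30.0,
    "superior-anterior": 60.0,
    "superior": 90.0,
    "superior-posterior": 120.0,
    "posterior-superior": 150.0,
    "posterior": 180.0,
}

FLAG_OK, FLAG_EXTRAPOLATED, FLAG_FAILED = "ok", "extrapolated", "failed"


@dataclass
class RoundnessMap:
    """rho(phi, theta) = surface radius / head radius on a spherical grid."""

    rho: np.ndarray        # (n_phi, n_theta), nan where unsampled
    sampled: np.ndarray    # bool, same shape
    phi_deg: np.ndarray    # (n_phi,)
    theta_deg: np.ndarray  # (n_theta,)

    def __post_init__(self):
        if self.rho.shape != (len(self.phi_deg), len(self.theta_deg)):
            raise ValidationError("roundness map shape mismatch")


@dataclass
class AlphaProfile:
    azimuth_deg: np.ndarray
    alpha_deg: np.ndarray
    flags: np.ndarray  # str per azimuth

    def as_series(self) -> pd.Series:
        return pd.Series(self.alpha_deg, index=self.azimuth_deg, name="alpha_deg")

    def max_of_antipodal_pairs(self) -> pd.Series:
        """Full-plane view: max of the two half-plane alphas per plane."""
        out = {}
        for i, a in enumerate(self.azimuth_deg):
            j = int(np.argmin(np.abs((self.azimuth_deg - a - 180.0) % 360.0)))
            key = min(a % 180.0, self.azimuth_deg[j] % 180.0)
            out[key] = max(self.alpha_deg[i], self.alpha_deg[j])
        return pd.Series(out, name="alpha_deg").sort_index()


@dataclass
class NotzliConstruction:
    hc: np.ndarray
    r: float
    nc: np.ndarray | None
    A: np.ndarray | None
    alpha_deg: float | None
    ok: bool


# ---------------------------------------------------------------------------
# roundness map by ray casting
# ---------------------------------------------------------------------------

def build_roundness_map(mesh: TriangleMesh, sphere: SphereFit,
                        slice_group: RadialSliceGroup,
                        config: AlphaConfig | None = None) -> RoundnessMap:
    """Cast a ray per (phi, theta) bin from the head centre; rho = hit / R.

    Rays share one origin, so a spherical broad phase (bucketing triangles by
    the azimuth interval they subtend) keeps the exact Moeller-Trumbore
    narrow phase tractable.  Rays with no intersection are marked missing;
    if more than ``max_missing_frac`` of the clinically relevant band
    (theta in [20, 120]) is missing the geometry is presumed wrong.
    """
    config = config or AlphaConfig()
    theta = np.arange(config.theta_step_deg, config.theta_max_deg + 1e-9,
                      config.theta_step_deg)
    phi = slice_group.azimuths_deg
    origin = sphere.center_mm
    d, e1, e2 = slice_group.axis.direction, slice_group.e1, slice_group.e2

    verts, faces = mesh.vertices, mesh.triangles
    rel = verts - origin
    rn = np.linalg.norm(rel, axis=1)
    vtheta = np.degrees(np.arccos(np.clip(rel @ d / np.maximum(rn, 1e-12), -1, 1)))
    vphi = np.degrees(np.arctan2(rel @ e2, rel @ e1)) % 360.0

    fphi = vphi[faces]  # (m, 3)
    ftheta = vtheta[faces]
    span = fphi.max(axis=1) - fphi.min(axis=1)
    wrap = (span > 180.0) | (ftheta.min(axis=1) < 3.0) | (ftheta.max(axis=1) > 177.0)
    lo = np.where(wrap, -np.inf, fphi.min(axis=1) - 1.0)
    hi = np.where(wrap, np.inf, fphi.max(axis=1) + 1.0)

    v0 = verts[faces[:, 0]]
    edge1 = verts[faces[:, 1]] - v0
    edge2 = verts[faces[:, 2]] - v0

    n_phi, n_theta = len(phi), len(theta)
    rho = np.full((n_phi, n_theta), np.nan)
    th_r = np.deg2rad(theta)
    cos_t, sin_t = np.cos(th_r), np.sin(th_r)
    eps = 1e-10
    for i, p in enumerate(phi):
        cand = (lo <= p) & (p <= hi)
        if not cand.any():
            continue
        ph = np.deg2rad(p)
        dirs = (cos_t[:, None] * d
                + sin_t[:, None] * (np.cos(ph) * e1 + np.sin(ph) * e2))  # (nt, 3)
        E1, E2, V0 = edge1[cand], edge2[cand], v0[cand]
        pvec = np.cross(dirs[:, None, :], E2[None, :, :])        # (nt, k, 3)
        det = np.einsum("kj,ikj->ik", E1, pvec)
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = origin - V0                                        # (k, 3)
        u = np.einsum("kj,ikj->ik", tvec, pvec) * inv
        qvec = np.cross(tvec, E1)                                 # (k, 3)
        v = np.einsum("ij,kj->ik", dirs, qvec) * inv
        t = np.einsum("kj,kj->k", E2, qvec)[None, :] * inv
        hit = (ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
               & (t > 1e-6))
        t = np.where(hit, t, np.inf)
        tmin = t.min(axis=1)
        got = np.isfinite(tmin)
        rho[i, got] = tmin[got] / sphere.radius_mm

    sampled = np.isfinite(rho)
    band = (theta >= 20.0) & (theta <= 120.0)
    missing_frac = 1.0 - sampled[:, band].mean()
    if missing_frac > config.max_missing_frac:
        raise RoundnessMapError(
            f"{missing_frac:.0%} of the head band is unsampled; "
            "sphere/axis geometry likely wrong")
    return RoundnessMap(rho=rho, sampled=sampled, phi_deg=np.asarray(phi),
                        theta_deg=theta)


# ---------------------------------------------------------------------------
# optimal horizontal cut (dynamic programming)
# ---------------------------------------------------------------------------

def _cut_data_term(rmap: RoundnessMap, tau: float, w_head: float,
                   w_neck: float) -> np.ndarray:
    """Misclassification cost D(phi, theta_cut), counting sampled cells only.

    Head side of the cut = theta' > theta_cut; each aspherical cell there
    (rho > 1 + tau) costs ``w_head``.  Neck side = theta' <= theta_cut; each
    spherical cell there costs ``w_neck``.
    """
    aspheric = rmap.sampled & (rmap.rho > 1.0 + tau)
    spheric = rmap.sampled & ~aspheric
    head_above = (aspheric[:, ::-1].cumsum(axis=1)[:, ::-1] - aspheric)
    neck_below = spheric.cumsum(axis=1)
    return w_head * head_above + w_neck * neck_below


def _l1_min_convolution(v: np.ndarray, lam: float) -> np.ndarray:
    """min_j v[..., j] + lam * |i - j| along the last axis (two-pass DT)."""
    out = v.copy()
    if lam <= 0:
        m = out.min(axis=-1, keepdims=True)
        return np.broadcast_to(m, out.shape).copy()
    for j in range(1, out.shape[-1]):
        np.minimum(out[..., j], out[..., j - 1] + lam, out=out[..., j])
    for j in range(out.shape[-1] - 2, -1, -1):
        np.minimum(out[..., j], out[..., j + 1] + lam, out=out[..., j])
    return out


def _dp_single_start(D: np.ndarray, lam: float, start: int) -> np.ndarray:
    """Exact cut with theta(0) fixed, L1-penalized transitions; backtracked."""
    n_phi, n_theta = D.shape
    j = np.arange(n_theta)
    pen = lam * np.abs(j[:, None] - j[None, :])  # pen[i, j] = lam|i-j|
    V = np.full(n_theta, np.inf)
    V[start] = D[0, start]
    ptr = np.zeros((n_phi, n_theta), dtype=np.int32)
    for p in range(1, n_phi):
        tot = V[None, :] + pen  # (i, j): arrive at i from j
        ptr[p] = np.argmin(tot, axis=1)
        V = tot[j, ptr[p]] + D[p]
    closing = V + lam * np.abs(j - start)
    cut = np.empty(n_phi, dtype=np.int32)
    cut[-1] = int(np.argmin(closing))
    for p in range(n_phi - 1, 0, -1):
        cut[p - 1] = ptr[p, cut[p]]
    return cut


def optimal_cut_indices(D: np.ndarray, lam: float) -> np.ndarray:
    """Globally optimal circular cut through the cost map D (phi x theta).

    Minimizes sum_phi D(phi, cut(phi)) + lam * sum_phi |cut(phi+1) - cut(phi)|
    with circular closure, exactly: a vectorized value pass over every
    possible starting state finds the optimal start, then a single
    pointer-tracking pass recovers that cut.
    """
    n_phi, n_theta = D.shape
    if lam <= 0:
        return D.argmin(axis=1).astype(np.int32)
    V = np.full((n_theta, n_theta), np.inf)  # (start, state)
    s = np.arange(n_theta)
    V[s, s] = D[0, s]
    for p in range(1, n_phi):
        V = _l1_min_convolution(V, lam) + D[p][None, :]
    closing = V + lam * np.abs(s[None, :] - s[:, None])
    best_start = int(np.argmin(closing.min(axis=1)))
    return _dp_single_start(D, lam, best_start)


def _refine_to_unit_crossing(rmap: RoundnessMap, cut: np.ndarray, tau: float,
                             n_fit: int = 4, max_shift_deg: float = 3.0,
                             ) -> np.ndarray:
    """Sub-threshold refinement of the cut to the rho = 1 crossing.

    The cut localizes alpha at the angle where roundness drops below the
    asphericity tolerance 1 + tau; the alpha angle proper is where the bone
    surface first leaves the *fitted head radius* (rho = 1).  Interpolating
    directly on the spherical side is ill-conditioned (rho hovers around 1
    there), so the steep aspherical branch just below each column's cut — the
    last ``n_fit`` samples with rho > 1 + tau — is continued linearly to
    rho = 1.  The refinement only ever moves the cut toward the head, by at
    most ``max_shift_deg``; columns without a usable branch keep the raw cut
    angle.  This removes the systematic tolerance-proportional underestimate
    without loosening the tolerance that guards against voxelization noise.
    """
    alpha = rmap.theta_deg[cut].astype(float)
    step = float(rmap.theta_deg[1] - rmap.theta_deg[0]) if len(rmap.theta_deg) > 1 else 1.0
    reach = max(int(round(2 * max_shift_deg / step)), n_fit)
    for i, j in enumerate(cut):
        lo = max(j - reach, 0)
        idx = np.nonzero(rmap.sampled[i, lo:j + 1]
                         & (rmap.rho[i, lo:j + 1] > 1.0 + tau))[0] + lo
        if idx.size < 2:
            continue
        idx = idx[-n_fit:]
        th = rmap.theta_deg[idx]
        rho = rmap.rho[i, idx]
        slope, intercept = np.polyfit(th, rho, 1)
        if slope >= -1e-5:
            continue
        theta_star = (1.0 - intercept) / slope
        alpha[i] = float(np.clip(theta_star, alpha[i], alpha[i] + max_shift_deg))
    return alpha


def alpha_by_optimal_cut(rmap: RoundnessMap, tau: float | None = None,
                         lambda_smooth: float | None = None,
                         w_head: float | None = None,
                         w_neck: float | None = None,
                         config: AlphaConfig | None = None,
                         circular: bool | None = None,
                         refine: bool = True) -> AlphaProfile:
    """Per-azimuth alpha from the smoothness-regularized optimal cut.

    ``tau`` is the fractional asphericity tolerance ((1 + tau) R is the
    exceedance radius).  With ``refine`` the cut is then interpolated to the
    rho = 1 crossing (see :func:`_refine_to_unit_crossing`).  Azimuth columns
    with no samples at all are flagged ``extrapolated`` and their cut is
    interpolated from the neighbouring columns.  The azimuth domain is
    treated as circular unless the map covers only an arc.
    """
    config = config or AlphaConfig()
    tau = config.tau_floor_mm / 24.0 if tau is None else tau  # fraction of R
    lam = config.lambda_smooth if lambda_smooth is None else lambda_smooth
    wh = config.w_head if w_head is None else w_head
    wn = config.w_neck if w_neck is None else w_neck
    D = _cut_data_term(rmap, tau, wh, wn)
    if circular is None:
        span = rmap.phi_deg.max() - rmap.phi_deg.min()
        circular = span > 180.0 + 1e-9
    if circular:
        cut = optimal_cut_indices(D, lam)
    elif lam <= 0:
        cut = D.argmin(axis=1).astype(np.int32)
    else:
        # open-chain variant: start unconstrained
        n_phi, n_theta = D.shape
        V = D[0].copy()
        ptrs = np.zeros((n_phi, n_theta), dtype=np.int32)
        j = np.arange(n_theta)
        pen = lam * np.abs(j[:, None] - j[None, :])
        for p in range(1, n_phi):
            tot = V[None, :] + pen
            ptrs[p] = np.argmin(tot, axis=1)
            V = tot[j, ptrs[p]] + D[p]
        cut = np.empty(n_phi, dtype=np.int32)
        cut[-1] = int(np.argmin(V))
        for p in range(n_phi - 1, 0, -1):
            cut[p - 1] = ptrs[p, cut[p]]

    alpha = (_refine_to_unit_crossing(rmap, cut, tau) if refine
             else rmap.theta_deg[cut].astype(float))
    flags = np.full(len(alpha), FLAG_OK, dtype=object)
    empty = ~rmap.sampled.any(axis=1)
    if empty.any():
        flags[empty] = FLAG_EXTRAPOLATED
        good = np.nonzero(~empty)[0]
        if good.size == 0:
            flags[:] = FLAG_FAILED
        else:
            phi = rmap.phi_deg
            alpha[empty] = np.interp(phi[empty], phi[good], alpha[good],
                                     period=360.0 if circular else None)
    return AlphaProfile(azimuth_deg=np.asarray(rmap.phi_deg, dtype=float),
                        alpha_deg=alpha, flags=flags)


# ---------------------------------------------------------------------------
# Noetzli 2D construction
# ---------------------------------------------------------------------------

def _fit_circle_2d(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) circle fit; exact for noiseless circular points."""
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = sol[:2]
    r2 = sol[2] + c @ c
    if r2 <= 0:
        raise ValidationError("degenerate circle fit")
    return c, float(np.sqrt(r2))


def notzli_alpha_2d(contour: np.ndarray, head_side_hint: np.ndarray,
                    tol_mm: float = 0.6, side: int = +1,
                    neck_point: np.ndarray | None = None,
                    neck_direction_hint: np.ndarray = (1.0, 0.0),
                    nc_station_band: tuple[float, float] = (0.6, 1.25),
                    ) -> NotzliConstruction:
    """Manual-style alpha construction on one radial-plane contour.

    ``contour`` is an ordered (N, 2) polyline of the full radial plane (both
    half-planes); ``head_side_hint`` is a rough in-plane head-centre guess
    used only to flag the head arc before the robust circle fit.  ``side``
    selects which half-plane (by the sign of the angle about the neck ray)
    the exceedance search runs on.  ``neck_direction_hint`` seeds the
    narrowest-point search — radial-plane images are conventionally framed
    with the neck roughly along +x, and the measured ``nc`` then refines the
    direction.  ``nc_station_band`` restricts that search to this multiple of
    the head radius from ``hc`` — the anatomical neck — so distal
    (trochanteric/shaft) cross-sections cannot masquerade as the neck waist.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2 or len(contour) < 50:
        raise ValidationError("need an ordered 2D contour with >= 50 points")
    hint = np.asarray(head_side_hint, dtype=float)

    # --- head circle: flag the head arc, robust refit -----------------
    d0 = np.linalg.norm(contour - hint, axis=1)
    # the head arc sits at a sharply peaked distance from the hint, while
    # neck/shaft points spread widely: the histogram mode is a robust radius
    # guess even when most of the contour is not head (full-femur outlines)
    bins = np.arange(0.0, d0.max() + 1.0, 1.0)
    counts, edges = np.histogram(d0, bins=bins)
    m = float(edges[np.argmax(counts)] + 0.5)
    head_sel = (d0 >= 0.85 * m) & (d0 <= 1.15 * m)
    hc, r = _fit_circle_2d(contour[head_sel])
    for _ in range(3):  # robust refit: drop aspherical arcs, converges fast
        res = np.abs(np.linalg.norm(contour[head_sel] - hc, axis=1) - r)
        thr = 2.0 * max(float(np.median(res)), 0.05)
        keep = res <= thr
        if keep.sum() < 10:
            break
        hc, r = _fit_circle_2d(contour[head_sel][keep])

    # --- neck centre at the narrowest point ---------------------------
    if neck_point is not None:
        nc = np.asarray(neck_point, dtype=float)
    else:
        rel = contour - hc
        dist = np.linalg.norm(rel, axis=1)
        non_head = dist > 1.05 * r
        if not non_head.any():
            return NotzliConstruction(hc=hc, r=r, nc=None, A=None,
                                      alpha_deg=None, ok=False)
        u0 = np.asarray(neck_direction_hint, dtype=float)
        u = u0 / np.linalg.norm(u0)
        # the narrowest-point search and the neck direction depend on each
        # other; iterate the pair to a fixed point (two rounds suffice), but
        # never let the measured direction run far from the frame hint — a
        # cam bump must tilt neither the waist search nor the angle origin.
        nc = None
        for _ in range(3):
            uperp = np.array([-u[1], u[0]])
            xi = rel @ u
            eta = rel @ uperp
            t_lo, t_hi = nc_station_band[0] * r, nc_station_band[1] * r
            stations = np.arange(t_lo, t_hi, max(r / 200.0, 0.05))
            best = None  # (width, t, mid_eta)
            a_xi, b_xi = xi[:-1], xi[1:]
            a_eta, b_eta = eta[:-1], eta[1:]
            for t in stations:
                crosses = (a_xi - t) * (b_xi - t) < 0
                if crosses.sum() < 2:
                    continue
                frac = (t - a_xi[crosses]) / (b_xi[crosses] - a_xi[crosses])
                etas = a_eta[crosses] + frac * (b_eta[crosses] - a_eta[crosses])
                width = float(etas.max() - etas.min())
                if width <= 0:
                    continue
                if best is None or width < best[0] - 1e-9:
                    best = (width, t, float((etas.max() + etas.min()) / 2.0))
            if best is None:
                return NotzliConstruction(hc=hc, r=r, nc=None, A=None,
                                          alpha_deg=None, ok=False)
            _, t_star, mid = best
            nc = hc + t_star * u + mid * uperp
            u_new = (nc - hc) / np.linalg.norm(nc - hc)
            if float(u_new @ (u0 / np.linalg.norm(u0))) < np.cos(np.deg2rad(30.0)):
                break  # implausible drift away from the frame direction
            done = float(u_new @ u) > np.cos(np.deg2rad(0.2))
            u = u_new
            if done:
                break

    # --- point A: first exceedance from the apex toward the neck ------
    axis_dir = nc - hc
    norm = np.linalg.norm(axis_dir)
    if norm == 0:
        return NotzliConstruction(hc=hc, r=r, nc=nc, A=None, alpha_deg=None,
                                  ok=False)
    axis_dir = axis_dir / norm
    rel = contour - hc
    dist = np.linalg.norm(rel, axis=1)
    cross = rel[:, 0] * axis_dir[1] - rel[:, 1] * axis_dir[0]
    psi = np.degrees(np.arctan2(-np.sign(side) * cross, rel @ axis_dir))
    on_side = psi > 0
    if not on_side.any():
        return NotzliConstruction(hc=hc, r=r, nc=nc, A=None, alpha_deg=None,
                                  ok=False)
    # walk *along the contour* from the head apex toward the neck on the
    # chosen side — the order a reader's eye follows.  An angle-sorted sweep
    # would be fooled by distal bone (shaft end) that subtends a larger
    # angle than the head-neck junction.
    n = len(contour)
    closed = np.linalg.norm(contour[0] - contour[-1]) < 1e-6
    a = int(np.nonzero(on_side)[0][np.argmax(psi[on_side])])
    walk_idx = None
    for step in (+1, -1):
        seq = []
        i = a
        for _ in range(n):
            i2 = i + step
            if closed:
                i2 %= n
            elif not 0 <= i2 < n:
                break
            if not on_side[i2]:
                break
            seq.append(i2)
            i = i2
        if seq and (walk_idx is None or psi[seq[min(2, len(seq) - 1)]]
                    < psi[walk_idx[min(2, len(walk_idx) - 1)]]):
            walk_idx = seq
    if not walk_idx:
        return NotzliConstruction(hc=hc, r=r, nc=nc, A=None, alpha_deg=None,
                                  ok=False)
    walk = np.asarray([a] + walk_idx)
    psi_s = psi[walk]
    dist_s = dist[walk]
    pts_s = contour[walk]
    exceeds = dist_s > r + tol_mm
    if not exceeds.any():
        return NotzliConstruction(hc=hc, r=r, nc=nc, A=None, alpha_deg=None,
                                  ok=False)
    k = int(np.argmax(exceeds))  # first exceeding point in the traversal
    A = pts_s[k]
    alpha = float(psi_s[k])
    # refine to the d = r crossing: the tolerance only localizes the
    # departure, alpha proper is where the bone leaves the circle radius.
    # The exceeding branch (steep, well-conditioned) is continued linearly
    # back to d = r; the shift is toward the apex and bounded by 3 degrees.
    branch = np.nonzero(exceeds & (psi_s >= psi_s[k] - 3.0)
                        & (dist_s <= r + 3.0 * tol_mm))[0]
    if branch.size >= 6:
        # dense branch: quadratic continuation absorbs the 1/sin curvature
        coeffs = np.polyfit(psi_s[branch], dist_s[branch] - r, 2)
        roots = np.roots(coeffs)
        roots = roots[np.isreal(roots)].real
        roots = roots[(roots >= alpha - 0.5) & (roots <= alpha + 3.5)]
        if roots.size:
            alpha = float(np.clip(roots.max(), alpha, alpha + 3.0))
    elif branch.size >= 2:
        slope, intercept = np.polyfit(psi_s[branch], dist_s[branch], 1)
        if slope < -1e-9:
            psi_star = (r - intercept) / slope
            alpha = float(np.clip(psi_star, alpha, alpha + 3.0))
    return NotzliConstruction(hc=hc, r=r, nc=nc, A=A, alpha_deg=alpha, ok=True)


def plane_contour(mesh: TriangleMesh, center: np.ndarray, axis: np.ndarray,
                  reference: np.ndarray, phi_deg: float) -> np.ndarray:
    """Ordered 2D contour of the mesh cut by the full radial plane at phi.

    Plane basis: x along ``axis``, y along the in-plane radial direction
    e(phi); y > 0 is the phi half-plane.  Returns the longest chained
    polyline of the mesh-plane intersection.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ref = np.asarray(reference, dtype=float)
    e1 = ref - (ref @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    ph = np.deg2rad(phi_deg)
    ey = np.cos(ph) * e1 + np.sin(ph) * e2
    normal = np.cross(axis, ey)

    s = (mesh.vertices - center) @ normal
    # vertices exactly in-plane (common on symmetry planes) break the strict
    # sign test; nudge them to one side for a consistent section topology
    eps0 = 1e-7
    s = np.where(np.abs(s) < eps0, eps0, s)
    fs = s[mesh.triangles]
    crossing = (fs.min(axis=1) < 0) & (fs.max(axis=1) > 0)
    tri = mesh.triangles[crossing]
    sv = fs[crossing]
    segs = []
    for f in range(len(tri)):
        pts = []
        for ea, eb in ((0, 1), (1, 2), (2, 0)):
            a, b = sv[f, ea], sv[f, eb]
            if a * b < 0:
                frac = a / (a - b)
                p = (mesh.vertices[tri[f, ea]]
                     + frac * (mesh.vertices[tri[f, eb]] - mesh.vertices[tri[f, ea]]))
                pts.append(p)
        if len(pts) == 2:
            segs.append(pts)
    if not segs:
        raise ValidationError("plane does not intersect the mesh")
    segs3 = np.asarray(segs)  # (k, 2, 3)
    rel = segs3 - center
    seg2 = np.stack([rel @ axis, rel @ ey], axis=-1)  # (k, 2, 2)

    # chain segments into polylines on a quantized endpoint graph: endpoints
    # within tolerance collapse to one node, every interior node then has
    # degree 2 and the section decomposes into cycles/paths deterministically
    ends = seg2.reshape(-1, 2)
    quant = np.round(ends / 1e-5).astype(np.int64)
    nodes, node_of = np.unique(quant, axis=0, return_inverse=True)
    n_nodes = len(nodes)
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n_nodes)]
    for s in range(len(seg2)):
        a, b = int(node_of[2 * s]), int(node_of[2 * s + 1])
        if a != b:
            adj[a].append((b, s))
            adj[b].append((a, s))
    seg_used = np.zeros(len(seg2), dtype=bool)

    def walk(start: int) -> list[int]:
        path = [start]
        cur = start
        while True:
            nxt = next(((n, s) for n, s in adj[cur] if not seg_used[s]), None)
            if nxt is None:
                break
            node, s = nxt
            seg_used[s] = True
            path.append(node)
            cur = node
            if cur == start:
                break
        return path

    chains = []
    # open paths first (from odd-degree nodes), then remaining cycles
    for start in range(n_nodes):
        if len(adj[start]) % 2 == 1:
            p = walk(start)
            if len(p) > 1:
                chains.append(p)
    for s in range(len(seg2)):
        if not seg_used[s]:
            p = walk(int(node_of[2 * s]))
            if len(p) > 1:
                chains.append(p)
    if not chains:
        raise ValidationError("plane section degenerated to isolated points")

    def chain_length(p):
        c = nodes[p] * 1e-5
        return float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())

    best = max(chains, key=chain_length)
    return nodes[best].astype(float) * 1e-5


# ---------------------------------------------------------------------------
# named clinical planes
# ---------------------------------------------------------------------------

def select_named_planes(profile: AlphaProfile, hip_id: str = "hip",
                        rater: str = "software",
                        scheme: dict[str, float] | None = None) -> pd.DataFrame:
    """Map the alpha profile onto the seven named clinical radial planes.

    Each named plane reads the profile at the nearest computed azimuth; the
    chosen azimuth is recorded, and a mismatch beyond one azimuth step is
    flagged in the ``warning`` column.
    """
    scheme = scheme or NAMED_PLANES
    az = profile.azimuth_deg
    step = float(np.min(np.diff(np.sort(az)))) if len(az) > 1 else 360.0
    rows = []
    for name, target in scheme.items():
        diff = np.abs((az - target + 180.0) % 360.0 - 180.0)
        i = int(np.argmin(diff))
        rows.append({
            "hip_id": hip_id,
            "plane": name,
            "rater": rater,
            "alpha_deg": float(profile.alpha_deg[i]),
            "matched_azimuth_deg": float(az[i]),
            "warning": bool(diff[i] > step + 1e-9),
        })
    return pd.DataFrame(rows)
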