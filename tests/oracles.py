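"""Independent oracles and shared synthetic fixtures for the test suite.

Everything here deliberately avoids the package's own solution paths: the
pairwise-superimposition oracle runs a numerical optimizer over rotation
parameterizations, the TPS oracle assembles and pseudo-inverts the full
bordered kernel matrix, the sliding oracle is a coordinate-descent grid
search over per-point 1D slides, and the mesh-projection oracle scans every
triangle.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import Delaunay
from scipy.spatial.transform import Rotation

from crownmorph import LandmarkConfiguration, SurfaceGeometry, Tooth
from crownmorph.geometry import closest_point_on_triangles
from crownmorph.tps import bending_energy_matrix, bending_energy_of


# -- pairwise Procrustes oracle --------------------------------------------

def pairwise_distance_by_optimizer(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum distance between unit-size centered configurations over all
    rotations, found numerically over rotation-vector parameterizations."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    ac = ac / np.linalg.norm(ac)
    bc = bc / np.linalg.norm(bc)

    def objective(rv):
        r = Rotation.from_rotvec(rv).as_matrix()
        return np.sum((ac - bc @ r) ** 2)

    best = np.inf
    rng = np.random.default_rng(12345)
    starts = [np.zeros(3)] + [rng.uniform(-np.pi, np.pi, 3) for _ in range(15)]
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return float(np.sqrt(best))


# -- TPS oracle -------------------------------------------------------------

def tps_oracle(source: np.ndarray, target: np.ndarray):
    """Solve the bordered TPS system with a generic pseudo-inverse and
    evaluate the bending energy through the energy-matrix quadratic form."""
    n = source.shape[0]
    k = np.linalg.norm(source[:, None] - source[None], axis=-1)
    p = np.hstack([np.ones((n, 1)), source])
    gamma = np.zeros((n + 4, n + 4))
    gamma[:n, :n] = k
    gamma[:n, n:] = p
    gamma[n:, :n] = p.T
    inv = np.linalg.pinv(gamma)
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = target
    sol = inv @ rhs
    weights, affine = sol[:n], sol[n:]
    lk = -(inv[:n, :n] + inv[:n, :n].T) / 2
    energy = float(np.einsum("nd,nm,md->", target, lk, target))

    def warp(q):
        q = np.atleast_2d(q)
        u = np.linalg.norm(q[:, None] - source[None], axis=-1)
        return affine[0] + q @ affine[1:] + u @ weights

    return weights, affine, energy, warp


# -- mesh projection oracle --------------------------------------------------

def project_all_faces(geometry: SurfaceGeometry, points: np.ndarray) -> np.ndarray:
    """Nearest point on the mesh by exhaustively scanning every triangle."""
    tri = geometry.vertices[geometry.faces]
    pts = np.atleast_2d(points)
    out = np.empty_like(pts)
    for i, p in enumerate(pts):
        cand = closest_point_on_triangles(p[None, None, :], tri[None])[0]
        d2 = np.sum((cand - p) ** 2, axis=-1)
        out[i] = cand[np.argmin(d2)]
    return out


# -- sliding oracle ----------------------------------------------------------

def grid_search_slide_energy(
    specimen: LandmarkConfiguration,
    reference: LandmarkConfiguration,
    geometry: SurfaceGeometry,
    scales=(0.8, 0.4, 0.2, 0.1, 0.05, 0.02, 0.01),
    passes_per_scale: int = 2,
    max_rounds: int = 8,
    round_rtol: float = 0.003,
) -> float:
    """Multi-scale coordinate-descent grid search over per-point 1D slides.

    Each semilandmark in turn tries a grid of signed offsets along its local
    tangent direction(s); every candidate is re-projected onto the geometry
    and accepted if it lowers the bending energy against the reference.  The
    offset grid shrinks scale by scale, and the whole schedule repeats until
    a round no longer improves the energy appreciably.
    """
    lmat = bending_energy_matrix(reference.points)
    pts = specimen.points.copy()
    curve_names = list(geometry.curves)
    energy = bending_energy_of(lmat, pts)
    for _ in range(max_rounds):
        round_start = energy
        energy, pts = _grid_round(
            specimen, geometry, lmat, pts, energy, scales, passes_per_scale, curve_names
        )
        if energy >= round_start * (1 - round_rtol):
            break
    return energy


def _grid_round(specimen, geometry, lmat, pts, energy, scales, passes_per_scale, curve_names):
    for scale in scales:
        offsets = scale * np.linspace(-1.0, 1.0, 9)
        for _ in range(passes_per_scale):
            for i in np.where(specimen.semilandmark_mask)[0]:
                if specimen.roles[i] == "curve":
                    poly = geometry.polyline(curve_names[specimen.curve_id[i]])
                    _, s, _ = poly.project(pts[i])
                    dirs = [poly.tangent_at(s)[0]]
                else:
                    _, face, _ = geometry.project_to_surface(pts[i])
                    t1, t2 = geometry.tangent_plane(np.atleast_1d(face))
                    dirs = [t1[0], t2[0]]
                for d in dirs:
                    for o in offsets:
                        cand_pt = pts[i] + o * d
                        if specimen.roles[i] == "curve":
                            cand_pt = poly.project(cand_pt)[0][0]
                        else:
                            cand_pt = geometry.project_to_surface(cand_pt)[0][0]
                        trial = pts.copy()
                        trial[i] = cand_pt
                        e = bending_energy_of(lmat, trial)
                        if e < energy:
                            energy = e
                            pts = trial
    return energy, pts


# -- paraboloid sliding fixture ----------------------------------------------

def _parab_z(x, y):
    return -0.05 * (np.asarray(x) ** 2 + np.asarray(y) ** 2) + 0.6 * np.exp(
        -((np.asarray(x) - 1.0) ** 2 + (np.asarray(y) + 0.5) ** 2) / 5.0
    )


def _parab_lift(xy):
    xy = np.atleast_2d(xy)
    return np.column_stack([xy[:, 0], xy[:, 1], _parab_z(xy[:, 0], xy[:, 1])])


def make_paraboloid_fixture():
    """A smooth synthetic crown-like surface with 4 fixed + 5 curve + 8
    surface landmarks; the specimen's semilandmarks are tangentially
    displaced so sliding has work to do."""
    g = np.arange(-5.0, 5.01, 0.35)
    xx, yy = np.meshgrid(g, g)
    xy = np.column_stack([xx.ravel(), yy.ravel()])
    tri = Delaunay(xy)
    faces = tri.simplices
    v = xy[faces]
    area2 = (v[:, 1, 0] - v[:, 0, 0]) * (v[:, 2, 1] - v[:, 0, 1]) - (
        v[:, 2, 0] - v[:, 0, 0]
    ) * (v[:, 1, 1] - v[:, 0, 1])
    faces = np.where(area2[:, None] < 0, faces[:, [0, 2, 1]], faces)

    t = np.linspace(0, 1, 220)
    curve = _parab_lift(np.column_stack([-4 + 8 * t, 0.8 * np.sin(np.pi * t)]))
    geometry = SurfaceGeometry(
        vertices=_parab_lift(xy), faces=faces, curves={"ridge": curve}
    )

    from crownmorph.geometry import Polyline

    poly = Polyline(curve)
    fixed_xy = np.array([[-3.8, -3.8], [3.8, -3.8], [3.8, 3.8], [-3.8, 3.8]])
    ref_fixed = _parab_lift(fixed_xy)
    s_ref = np.arange(1, 6) / 6 * poly.total_length
    ref_curve = poly.point_at(s_ref)
    ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    surf_xy = np.column_stack([2.5 * np.cos(ang), 2.5 * np.sin(ang)])
    ref_surface = geometry.project_to_surface(_parab_lift(surf_xy))[0]

    roles = np.array(["fixed"] * 4 + ["curve"] * 5 + ["surface"] * 8, dtype="U7")
    cid = np.array([-1] * 4 + [0] * 5 + [-1] * 8)
    reference = LandmarkConfiguration(
        "parab_ref", Tooth.FP, np.vstack([ref_fixed, ref_curve, ref_surface]), roles, cid
    )

    spec_fixed = _parab_lift(fixed_xy + np.array([0.3, -0.25]))
    spec_curve = poly.point_at(s_ref + np.array([0.7, -0.5, 0.6, -0.4, 0.5]))
    rot = np.deg2rad(14.0)
    rmat = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
    spec_surface = geometry.project_to_surface(_parab_lift(surf_xy @ rmat.T))[0]
    specimen = LandmarkConfiguration(
        "parab_spec", Tooth.FP, np.vstack([spec_fixed, spec_curve, spec_surface]), roles, cid
    )
    return reference, specimen, geometry
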