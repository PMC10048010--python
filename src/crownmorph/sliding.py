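"""Sliding-semilandmark relaxation against a reference configuration.

Semilandmark positions along a curve or across a surface are arbitrary; to
make them comparable across specimens they are slid to minimize the TPS
bending energy between the specimen and a reference configuration, then
re-projected back onto the specimen's actual geometry.  Each cycle:

1. tangent directions — one unit tangent per curve semilandmark (central
   differences on its polyline), two orthonormal tangent-plane vectors per
   surface semilandmark (from the area-weighted vertex normal of the nearest
   mesh face);
2. the bending-energy-minimizing displacement restricted to those tangents
   (closed form; fixed landmarks are immobile);
3. re-projection of every slid semilandmark to the nearest point on its
   curve / the crown mesh (curve ends clamp with a warning).

Bending energy is invariant under affine transforms of the target, so the
specimen needs no pre-alignment to the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import CurveClampWarning, InvalidInputError, ShapeMismatchError
from .geometry import SurfaceGeometry
from .tps import bending_energy_matrix, bending_energy_of
from .types import ROLE_CURVE, LandmarkConfiguration


@dataclass
class SlideDiagnostics:
    """Per-cycle bending energies recorded during sliding.

    ``energy_after_slide`` is the tangent-step (pre-projection) energy per
    cycle; ``energy_after_projection`` follows the re-projection step.
    """

    energy_initial: float
    energy_after_slide: list
    energy_after_projection: list


def _tangent_directions(
    config: LandmarkConfiguration, geometry: SurfaceGeometry
):
    """Index/direction pairs for every semilandmark's allowed motions."""
    idx_list = []
    dirs_list = []

    curve_ids = sorted(set(config.curve_id[config.curve_mask]))
    curve_names = list(geometry.curves)
    for cid in curve_ids:
        sel = np.where((config.roles == ROLE_CURVE) & (config.curve_id == cid))[0]
        try:
            name = curve_names[cid]
        except IndexError:
            raise InvalidInputError(
                f"specimen {config.specimen_id!r}: no geometry curve for curve id {cid}"
            ) from None
        poly = geometry.polyline(name)
        _, s, _ = poly.project(config.points[sel])
        tangents = poly.tangent_at(s)
        idx_list.append(sel)
        dirs_list.append(tangents)

    surf = np.where(config.surface_mask)[0]
    if surf.size:
        if len(geometry.faces) == 0:
            raise InvalidInputError(
                f"specimen {config.specimen_id!r}: surface semilandmarks but no mesh"
            )
        _, faces, _ = geometry.project_to_surface(config.points[surf])
        t1, t2 = geometry.tangent_plane(faces)
        idx_list.extend([surf, surf])
        dirs_list.extend([t1, t2])

    if idx_list:
        return np.concatenate(idx_list), np.concatenate(dirs_list)
    return np.empty(0, dtype=int), np.empty((0, 3))


def _minimizing_step(
    points: np.ndarray, l_matrix: np.ndarray, idx: np.ndarray, dirs: np.ndarray
) -> np.ndarray:
    """Closed-form tangent displacement minimizing the bending energy.

    With E(Y) = sum_d Y_d' L Y_d and displacement dY = sum_c t_c * d_c e_{i_c},
    the optimum solves (d_c . d_c') L[i_c, i_c'] t = -(L Y)_{i_c} . d_c.
    """
    if idx.size == 0:
        return points
    a = (dirs @ dirs.T) * l_matrix[np.ix_(idx, idx)]
    ly = l_matrix @ points
    b = np.einsum("ck,ck->c", ly[idx], dirs)
    # a is a projected energy Hessian (PSD, possibly rank-deficient along the
    # affine null space); a tiny jitter keeps the solve fast and stable
    jitter = 1e-10 * max(np.trace(a) / len(a), 1e-30)
    try:
        t = np.linalg.solve(a + jitter * np.eye(len(a)), -b)
    except np.linalg.LinAlgError:
        t, *_ = np.linalg.lstsq(a, -b, rcond=None)
    out = points.copy()
    np.add.at(out, idx, dirs * t[:, None])
    return out


def _reproject(
    config: LandmarkConfiguration, points: np.ndarray, geometry: SurfaceGeometry
) -> np.ndarray:
    out = points.copy()
    curve_names = list(geometry.curves)
    for cid in sorted(set(config.curve_id[config.curve_mask])):
        sel = np.where((config.roles == ROLE_CURVE) & (config.curve_id == cid))[0]
        poly = geometry.polyline(curve_names[cid])
        proj, _, clamped = poly.project(out[sel])
        out[sel] = proj
        if np.any(clamped):
            warnings.warn(
                f"specimen {config.specimen_id!r}: {int(clamped.sum())} semilandmark(s) "
                f"clamped at an endpoint of curve {curve_names[cid]!r}",
                CurveClampWarning,
                stacklevel=3,
            )
    surf = np.where(config.surface_mask)[0]
    if surf.size:
        proj, _, _ = geometry.project_to_surface(out[surf])
        out[surf] = proj
    return out


def slide_semilandmarks(
    specimen: LandmarkConfiguration,
    reference: LandmarkConfiguration,
    geometry: SurfaceGeometry,
    n_cycles: int = 6,
    l_matrix: np.ndarray | None = None,
    return_diagnostics: bool = False,
):
    """Relax the specimen's semilandmarks against the reference.

    Parameters
    ----------
    specimen, reference : LandmarkConfiguration
        Must conform to the same template (same point count and roles).
    geometry : SurfaceGeometry
        The specimen's crown mesh and curve polylines.
    n_cycles : int
        Slide + re-project cycles; 0 returns the input unchanged.
    l_matrix : optional
        Precomputed bending-energy matrix of the reference (shared across a
        sample for speed).
    """
    if specimen.n_points != reference.n_points:
        raise ShapeMismatchError(
            f"specimen has {specimen.n_points} points, reference {reference.n_points}"
        )
    if not np.array_equal(specimen.roles, reference.roles):
        raise ShapeMismatchError("specimen and reference role layouts differ")
    if n_cycles < 0:
        raise InvalidInputError("n_cycles must be >= 0")

    if l_matrix is None:
        l_matrix = bending_energy_matrix(reference.points)

    points = specimen.points.copy()
    diag = SlideDiagnostics(
        energy_initial=bending_energy_of(l_matrix, points),
        energy_after_slide=[],
        energy_after_projection=[],
    )
    for _ in range(n_cycles):
        idx, dirs = _tangent_directions(specimen.with_points(points), geometry)
        points = _minimizing_step(points, l_matrix, idx, dirs)
        diag.energy_after_slide.append(bending_energy_of(l_matrix, points))
        points = _reproject(specimen, points, geometry)
        diag.energy_after_projection.append(bending_energy_of(l_matrix, points))

    result = specimen.with_points(points)
    if return_diagnostics:
        return result, diag
    return result
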