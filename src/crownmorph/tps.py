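"""Thin-plate-spline interpolation and bending energy in 3D.

The interpolating map decomposes into an affine part and a nonaffine part;
the bending energy is the quadratic form of the nonaffine coefficients
against the kernel matrix and vanishes exactly for affine source->target
maps.  The 3D radial kernel is U(r) = r (the convention of 3D semilandmark
practice); because r is conditionally negative definite, the energy carries
a minus sign so it is nonnegative on the side-condition subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DegenerateConfigurationError, InvalidInputError
from .procrustes import _as_points


def _kernel_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """U(||x_i - y_j||) with U(r) = r."""
    return np.linalg.norm(x[:, None, :] - y[None, :, :], axis=-1)


def _check_source(source: np.ndarray) -> None:
    n = source.shape[0]
    if n < 5:
        raise InvalidInputError(f"TPS needs >= 5 source points, got {n}")
    d = _kernel_matrix(source, source)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1e-9:
        raise DegenerateConfigurationError("duplicated source landmarks")


@dataclass
class TpsModel:
    """A fitted 3D thin-plate-spline interpolant.

    ``affine`` is a (4, 3) matrix (first row: offset; rows 1-3: linear map);
    ``weights`` holds one nonaffine 3-vector per source point, satisfying the
    side conditions (zero sum, orthogonal to the source coordinates).
    """

    source: np.ndarray
    affine: np.ndarray
    weights: np.ndarray
    bending_energy: float

    def warp(self, query_points: np.ndarray) -> np.ndarray:
        return tps_warp(self, query_points)


def tps_fit(source, target, ridge: float = 0.0) -> TpsModel:
    """Fit the interpolating TPS mapping ``source`` points onto ``target``.

    Solves the standard bordered linear system; the fitted map reproduces
    ``target`` at the source points exactly.  ``ridge`` (default 0) adds a
    small diagonal to the kernel block for near-singular configurations, at
    the cost of exact interpolation.
    """
    src = _as_points(source)
    tgt = _as_points(target)
    if src.shape != tgt.shape:
        raise InvalidInputError(
            f"source/target point counts differ: {src.shape[0]} vs {tgt.shape[0]}"
        )
    _check_source(src)
    n = src.shape[0]
    k = _kernel_matrix(src, src)
    if ridge:
        k = k + ridge * np.eye(n)
    p = np.hstack([np.ones((n, 1)), src])
    gamma = np.zeros((n + 4, n + 4))
    gamma[:n, :n] = k
    gamma[:n, n:] = p
    gamma[n:, :n] = p.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = tgt
    try:
        sol = scipy.linalg.solve(gamma, rhs)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise DegenerateConfigurationError(f"singular TPS system: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise DegenerateConfigurationError("singular TPS system")
    weights = sol[:n]
    affine = sol[n:]
    # U(r) = r is conditionally negative definite, hence the sign flip
    energy = float(max(-np.sum(weights * (k @ weights)), 0.0))
    return TpsModel(source=src.copy(), affine=affine, weights=weights, bending_energy=energy)


def tps_warp(model: TpsModel, query_points) -> np.ndarray:
    """Evaluate the fitted affine + kernel expansion at the query points."""
    q = np.atleast_2d(np.asarray(query_points, dtype=float))
    if q.shape[-1] != 3:
        raise InvalidInputError("query points must be 3D")
    u = _kernel_matrix(q, model.source)
    return model.affine[0] + q @ model.affine[1:] + u @ model.weights


def bending_energy_matrix(source, ridge: float = 0.0) -> np.ndarray:
    """The n x n bending-energy matrix L of a source configuration.

    For any target Y (n x 3), the TPS bending energy of the source->Y map is
    ``sum_d Y[:, d].T @ L @ Y[:, d]``.  L is positive semidefinite with the
    affine functions of the source in its null space.
    """
    src = _as_points(source)
    _check_source(src)
    n = src.shape[0]
    k = _kernel_matrix(src, src)
    if ridge:
        k = k + ridge * np.eye(n)
    p = np.hstack([np.ones((n, 1)), src])
    gamma = np.zeros((n + 4, n + 4))
    gamma[:n, :n] = k
    gamma[:n, n:] = p
    gamma[n:, :n] = p.T
    inv = np.linalg.inv(gamma)
    lk = -inv[:n, :n]  # sign flip matches the U(r) = r convention
    return (lk + lk.T) / 2.0


def bending_energy_of(l_matrix: np.ndarray, target) -> float:
    """Bending energy of mapping the matrix's source onto ``target``."""
    y = _as_points(target)
    return float(max(np.einsum("nd,nm,md->", y, l_matrix, y), 0.0))
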