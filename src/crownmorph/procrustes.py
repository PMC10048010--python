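"""Centroid size, pairwise and generalized Procrustes superimposition.

Shape is what remains of a landmark configuration after translation, scale
and rotation are removed.  Size is carried separately by centroid size (the
root summed squared distance of the points from their centroid).  Pairwise
superimposition uses the closed-form cross-covariance (Kabsch) solution with
a determinant correction so anatomical configurations are never mirrored;
generalized Procrustes analysis (GPA) iterates rotate-to-mean / re-mean until
the mean shape stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateConfigurationError, InvalidInputError, ShapeMismatchError
from .types import LandmarkConfiguration, Tooth


def _as_points(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.points
    pts = np.asarray(config, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidInputError(f"expected (n, 3) points, got shape {pts.shape}")
    return pts


def centroid_size(config) -> float:
    """Centroid size in mm: sqrt(sum of squared distances from the centroid).

    Invariant under translation/rotation, 1-homogeneous under scaling.
    """
    pts = _as_points(config)
    if pts.shape[0] < 1:
        raise InvalidInputError("need at least one point")
    if not np.all(np.isfinite(pts)):
        raise InvalidInputError("non-finite coordinates")
    centered = pts - pts.mean(axis=0)
    return float(np.linalg.norm(centered))


def optimal_rotation(a_centered: np.ndarray, b_centered: np.ndarray) -> np.ndarray:
    """Rotation R (points as rows, applied as ``b @ R``) maximizing the
    alignment of ``b_centered`` to ``a_centered``; reflections forbidden."""
    h = b_centered.T @ a_centered
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, 1.0, d])
    return u @ correction @ vt


@dataclass
class PairAlignment:
    """Similarity transform of B onto A plus the resulting shape distance.

    ``B_aligned = scale * (B - B_centroid) @ rotation + A_centroid``;
    ``distance`` is the partial Procrustes distance between the unit-size,
    centered, optimally rotated configurations.
    """

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    distance: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.scale * (pts - pts.mean(axis=0)) @ self.rotation + self.translation


def procrustes_align_pair(a, b) -> PairAlignment:
    """Optimally superimpose configuration B onto configuration A.

    Returns the closed-form translation/scale/rotation minimizing the summed
    squared distance of B to A, and the shape distance between the two
    unit-centroid-size centered configurations after optimal rotation.
    """
    pa, pb = _as_points(a), _as_points(b)
    if pa.shape != pb.shape:
        raise ShapeMismatchError(
            f"point counts differ: {pa.shape[0]} vs {pb.shape[0]}"
        )
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    ac, bc = pa - ca, pb - cb
    sa, sb = np.linalg.norm(ac), np.linalg.norm(bc)
    if sa <= 0 or sb <= 0:
        raise DegenerateConfigurationError("zero centroid size")
    rot = optimal_rotation(ac, bc)
    # least-squares scale for mapping B onto A
    scale = float(np.trace(rot.T @ bc.T @ ac) / sb**2)
    distance = float(np.linalg.norm(ac / sa - (bc / sb) @ rot))
    return PairAlignment(rotation=rot, scale=scale, translation=ca, distance=distance)


def procrustes_distance(a, b) -> float:
    """Partial Procrustes distance between two configurations."""
    return procrustes_align_pair(a, b).distance


@dataclass
class AlignedSample:
    """Procrustes-aligned shape coordinates for one tooth's sample.

    ``aligned`` holds unit-centroid-size shape coordinates (N, n, 3);
    ``mean_shape`` is their arithmetic mean rescaled to unit centroid size;
    ``centroid_sizes`` are the original sizes in mm.
    """

    tooth: Tooth
    specimen_ids: list
    aligned: np.ndarray
    mean_shape: np.ndarray
    centroid_sizes: np.ndarray
    iterations_used: int
    converged: bool
    residual_history: np.ndarray

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_points(self) -> int:
        return self.aligned.shape[1]

    def flattened(self) -> np.ndarray:
        """(N, 3n) matrix of shape coordinates, x/y/z interleaved per point."""
        return self.aligned.reshape(self.n_specimens, -1)


def generalized_procrustes(
    configs: Sequence[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedSample:
    """Generalized Procrustes analysis of >= 2 configurations of one tooth.

    Each configuration is centered, scaled to unit centroid size and
    iteratively rotated to the current mean shape; the mean is recomputed
    (and rescaled to unit size) until it moves by less than ``tol``.
    Non-convergence within ``max_iter`` sets ``converged=False`` rather than
    raising.
    """
    if len(configs) < 2:
        raise InvalidInputError("GPA needs at least two configurations")
    if tol <= 0:
        raise InvalidInputError("tol must be positive")
    teeth = {c.tooth for c in configs if isinstance(c, LandmarkConfiguration)}
    if len(teeth) > 1:
        raise ShapeMismatchError(f"mixed tooth types in GPA: {sorted(t.value for t in teeth)}")
    tooth = teeth.pop() if teeth else Tooth.FP
    ids = [
        c.specimen_id if isinstance(c, LandmarkConfiguration) else str(i)
        for i, c in enumerate(configs)
    ]
    pts = [_as_points(c) for c in configs]
    n = pts[0].shape[0]
    if any(p.shape[0] != n for p in pts):
        raise ShapeMismatchError("configurations have differing point counts")

    sizes = np.empty(len(pts))
    shapes = np.empty((len(pts), n, 3))
    for i, p in enumerate(pts):
        centered = p - p.mean(axis=0)
        s = np.linalg.norm(centered)
        if s <= 0:
            raise DegenerateConfigurationError(f"zero centroid size for {ids[i]!r}")
        sizes[i] = s
        shapes[i] = centered / s

    mean = shapes[0].copy()
    mean /= np.linalg.norm(mean)
    converged = False
    iterations = 0
    residuals = []
    for iterations in range(1, max_iter + 1):
        for i in range(len(shapes)):
            shapes[i] = shapes[i] @ optimal_rotation(mean, shapes[i])
        new_mean = shapes.mean(axis=0)
        new_mean /= np.linalg.norm(new_mean)
        residuals.append(float(np.sum((shapes - new_mean) ** 2)))
        change = np.linalg.norm(new_mean - mean)
        mean = new_mean
        if change < tol:
            converged = True
            break

    return AlignedSample(
        tooth=tooth,
        specimen_ids=ids,
        aligned=shapes,
        mean_shape=mean,
        centroid_sizes=sizes,
        iterations_used=iterations,
        converged=converged,
        residual_history=np.asarray(residuals),
    )
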