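"""Core landmark containers.

A specimen is represented by an ordered set of 3D points (millimetres), each
tagged with a role: ``fixed`` anatomical landmarks (cusp tips, fossae),
``curve`` semilandmarks that live on ridge/sulcus polylines, and ``surface``
semilandmarks spread over the occlusal crown surface.  The point order is
canonical: all fixed points first, then curve points grouped per curve, then
surface points — the same order the tooth templates prescribe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .errors import InvalidInputError

ROLE_FIXED = "fixed"
ROLE_CURVE = "curve"
ROLE_SURFACE = "surface"
ROLES = (ROLE_FIXED, ROLE_CURVE, ROLE_SURFACE)


class Tooth(str, Enum):
    """Maxillary left tooth types analysed by the pipeline."""

    FP = "FP"  # first premolar
    SP = "SP"  # second premolar
    M = "M"    # first molar

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 3D landmark/semilandmark configuration.

    Parameters
    ----------
    specimen_id : str
        Identifier of the scan/specimen.
    tooth : Tooth
        Tooth type the configuration belongs to.
    points : (n, 3) float array
        Coordinates in millimetres, canonical template order.
    roles : (n,) str array
        Per-point role, one of ``fixed``/``curve``/``surface``.
    curve_id : (n,) int array
        Index of the curve a ``curve`` point belongs to; -1 elsewhere.
    """

    specimen_id: str
    tooth: Tooth
    points: np.ndarray
    roles: np.ndarray
    curve_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.tooth = Tooth(self.tooth)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidInputError(
                f"points must be (n, 3), got {self.points.shape}"
            )
        if self.points.shape[0] < 4:
            raise InvalidInputError(
                f"a configuration needs >= 4 points, got {self.points.shape[0]}"
            )
        if not np.all(np.isfinite(self.points)):
            raise InvalidInputError(
                f"non-finite coordinates in specimen {self.specimen_id!r}"
            )
        self.roles = np.asarray(self.roles, dtype="U7")
        if self.roles.shape != (self.points.shape[0],):
            raise InvalidInputError("roles must align with points")
        unknown = set(self.roles) - set(ROLES)
        if unknown:
            raise InvalidInputError(f"unknown roles: {sorted(unknown)}")
        if self.curve_id is None:
            cid = np.full(self.points.shape[0], -1, dtype=int)
            cid[self.roles == ROLE_CURVE] = 0
            self.curve_id = cid
        else:
            self.curve_id = np.asarray(self.curve_id, dtype=int)
            if self.curve_id.shape != (self.points.shape[0],):
                raise InvalidInputError("curve_id must align with points")

    # -- convenience -------------------------------------------------------
    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def mask(self, role: str) -> np.ndarray:
        return self.roles == role

    @property
    def fixed_mask(self) -> np.ndarray:
        return self.mask(ROLE_FIXED)

    @property
    def curve_mask(self) -> np.ndarray:
        return self.mask(ROLE_CURVE)

    @property
    def surface_mask(self) -> np.ndarray:
        return self.mask(ROLE_SURFACE)

    @property
    def semilandmark_mask(self) -> np.ndarray:
        return self.roles != ROLE_FIXED

    def role_counts(self) -> dict:
        return {r: int(np.sum(self.roles == r)) for r in ROLES}

    def with_points(self, points: np.ndarray) -> "LandmarkConfiguration":
        """Same specimen/roles with replaced coordinates."""
        return replace(self, points=np.asarray(points, dtype=float).copy())

    def copy(self) -> "LandmarkConfiguration":
        return replace(
            self,
            points=self.points.copy(),
            roles=self.roles.copy(),
            curve_id=self.curve_id.copy(),
        )
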