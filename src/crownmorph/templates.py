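"""Canonical landmark schemes for the three tooth types.

Premolars (first and second) carry 4 fixed landmarks (buccal and lingual cusp
tips, mesial and distal fossae), 9 curve semilandmarks on two ridge curves
connecting the cusp tips, and 50 surface semilandmarks: 63 points.  The first
molar carries 4 fixed landmarks (the four cusp tips), 51 curve semilandmarks
across eleven named ridge/sulcus curves, and 210 surface semilandmarks: 265
points.  Canonical point order is fixed, then curve (per curve, in curve
order), then surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .errors import InvalidInputError, TemplateValidationError
from .geometry import SurfaceGeometry
from .tps import tps_fit, tps_warp
from .types import (
    ROLE_CURVE,
    ROLE_FIXED,
    ROLE_SURFACE,
    LandmarkConfiguration,
    Tooth,
)

PREMOLAR_FIXED_NAMES = ("buccal_cusp", "lingual_cusp", "mesial_fossa", "distal_fossa")
PREMOLAR_CURVES = ("mesial_ridge", "distal_ridge")
MOLAR_FIXED_NAMES = (
    "mesiobuccal_cusp",
    "mesiopalatal_cusp",
    "distobuccal_cusp",
    "distopalatal_cusp",
)
MOLAR_CURVES = (
    "mesial_marginal_ridge",
    "distal_marginal_ridge",
    "buccal_ridge",
    "palatal_ridge",
    "central_sulcus",
    "buccal_sulcus",
    "palatal_sulcus",
    "mesiobuccal_cusp_ridge",
    "mesiopalatal_cusp_ridge",
    "distobuccal_cusp_ridge",
    "distopalatal_cusp_ridge",
)

#: (n_fixed, total curve semilandmarks, n_surface) per tooth
ROLE_TOTALS = {
    Tooth.FP: (4, 9, 50),
    Tooth.SP: (4, 9, 50),
    Tooth.M: (4, 51, 210),
}


def expected_total(tooth: Tooth) -> int:
    return sum(ROLE_TOTALS[Tooth(tooth)])


@dataclass
class ToothTemplate:
    """Reference configuration plus the role/curve layout for one tooth."""

    tooth: Tooth
    n_fixed: int
    curve_specs: Dict[str, int]
    n_surface: int
    reference: LandmarkConfiguration
    reference_geometry: Optional[SurfaceGeometry] = field(default=None, repr=False)

    @property
    def n_curve(self) -> int:
        return sum(self.curve_specs.values())

    @property
    def total(self) -> int:
        return self.n_fixed + self.n_curve + self.n_surface

    @property
    def curve_names(self) -> tuple:
        return tuple(self.curve_specs)

    def canonical_roles(self) -> np.ndarray:
        roles = (
            [ROLE_FIXED] * self.n_fixed
            + [ROLE_CURVE] * self.n_curve
            + [ROLE_SURFACE] * self.n_surface
        )
        return np.asarray(roles, dtype="U7")

    def canonical_curve_ids(self) -> np.ndarray:
        cid = np.full(self.total, -1, dtype=int)
        pos = self.n_fixed
        for i, count in enumerate(self.curve_specs.values()):
            cid[pos : pos + count] = i
            pos += count
        return cid

    def validate(self, config: LandmarkConfiguration) -> None:
        """Raise :class:`TemplateValidationError` unless the configuration
        matches this template's counts and canonical ordering."""
        if Tooth(config.tooth) != self.tooth:
            raise TemplateValidationError(
                f"configuration is {config.tooth}, template is {self.tooth}"
            )
        if config.n_points != self.total:
            raise TemplateValidationError(
                f"{self.tooth} expects {self.total} points "
                f"({self.n_fixed} fixed + {self.n_curve} curve + {self.n_surface} "
                f"surface), got {config.n_points}"
            )
        counts = config.role_counts()
        expected = {
            ROLE_FIXED: self.n_fixed,
            ROLE_CURVE: self.n_curve,
            ROLE_SURFACE: self.n_surface,
        }
        if counts != expected:
            raise TemplateValidationError(
                f"{self.tooth} role counts {counts} do not match expected {expected}"
            )
        if not np.array_equal(config.roles, self.canonical_roles()):
            raise TemplateValidationError(
                "points are not in canonical order (fixed, curve, surface)"
            )
        if not np.array_equal(config.curve_id, self.canonical_curve_ids()):
            raise TemplateValidationError("curve ids do not follow the template layout")

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "tooth": self.tooth.value,
                "n_fixed": self.n_fixed,
                "curve_specs": dict(self.curve_specs),
                "n_surface": self.n_surface,
                "reference_points": self.reference.points.tolist(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ToothTemplate":
        doc = json.loads(text)
        tooth = Tooth(doc["tooth"])
        tpl = object.__new__(cls)
        reference = _make_reference_config(
            tooth, np.asarray(doc["reference_points"]), doc["curve_specs"]
        )
        tpl.__init__(
            tooth=tooth,
            n_fixed=doc["n_fixed"],
            curve_specs=dict(doc["curve_specs"]),
            n_surface=doc["n_surface"],
            reference=reference,
        )
        return tpl


def _make_reference_config(
    tooth: Tooth, points: np.ndarray, curve_specs: Dict[str, int]
) -> LandmarkConfiguration:
    n_fixed, n_curve, n_surface = ROLE_TOTALS[tooth]
    roles = np.asarray(
        [ROLE_FIXED] * n_fixed + [ROLE_CURVE] * n_curve + [ROLE_SURFACE] * n_surface,
        dtype="U7",
    )
    cid = np.full(len(roles), -1, dtype=int)
    pos = n_fixed
    for i, count in enumerate(curve_specs.values()):
        cid[pos : pos + count] = i
        pos += count
    return LandmarkConfiguration(
        specimen_id="reference", tooth=tooth, points=points, roles=roles, curve_id=cid
    )


def _build_template(
    tooth: Tooth,
    reference_config: LandmarkConfiguration,
    curve_specs: Dict[str, int],
    geometry: Optional[SurfaceGeometry],
) -> ToothTemplate:
    n_fixed, n_curve, n_surface = ROLE_TOTALS[tooth]
    if sum(curve_specs.values()) != n_curve:
        raise TemplateValidationError(
            f"curve semilandmark counts {curve_specs} must sum to {n_curve}"
        )
    tpl = ToothTemplate(
        tooth=tooth,
        n_fixed=n_fixed,
        curve_specs=dict(curve_specs),
        n_surface=n_surface,
        reference=reference_config,
        reference_geometry=geometry,
    )
    tpl.validate(reference_config)
    return tpl


def build_premolar_template(
    reference_config: LandmarkConfiguration,
    curve_split: tuple = (5, 4),
    geometry: Optional[SurfaceGeometry] = None,
) -> ToothTemplate:
    """Template for a first or second premolar (63 points: 4/9/50).

    ``curve_split`` apportions the 9 curve semilandmarks between the mesial
    and distal ridge curves (default 5/4).
    """
    tooth = Tooth(reference_config.tooth)
    if tooth not in (Tooth.FP, Tooth.SP):
        raise TemplateValidationError(f"{tooth} is not a premolar")
    if len(curve_split) != 2 or sum(curve_split) != 9:
        raise TemplateValidationError(
            f"premolar curve split must have two counts summing to 9, got {curve_split}"
        )
    specs = dict(zip(PREMOLAR_CURVES, curve_split))
    return _build_template(tooth, reference_config, specs, geometry)


def build_molar_template(
    reference_config: LandmarkConfiguration,
    curve_counts: Optional[Dict[str, int]] = None,
    geometry: Optional[SurfaceGeometry] = None,
) -> ToothTemplate:
    """Template for the first molar (265 points: 4/51/210).

    ``curve_counts`` apportions the 51 curve semilandmarks over the eleven
    named curves; by default the counts are taken from the reference
    configuration's own curve ids (the synthetic reference allocates them
    proportional to curve arc length).
    """
    if Tooth(reference_config.tooth) != Tooth.M:
        raise TemplateValidationError(f"{reference_config.tooth} is not a molar")
    if curve_counts is None:
        cids = reference_config.curve_id[reference_config.curve_mask]
        curve_counts = {
            name: int(np.sum(cids == i)) for i, name in enumerate(MOLAR_CURVES)
        }
    if tuple(curve_counts) != MOLAR_CURVES:
        raise TemplateValidationError(
            f"molar curves must be named {MOLAR_CURVES}, got {tuple(curve_counts)}"
        )
    return _build_template(Tooth.M, reference_config, curve_counts, geometry)


def allocate_curve_counts(lengths: Dict[str, float], total: int) -> Dict[str, int]:
    """Distribute ``total`` semilandmarks over curves proportional to arc
    length (largest-remainder rounding, at least one point per curve)."""
    names = list(lengths)
    ln = np.asarray([lengths[n] for n in names], dtype=float)
    if np.any(ln <= 0):
        raise InvalidInputError("curve lengths must be positive")
    quota = ln / ln.sum() * total
    counts = np.maximum(np.floor(quota).astype(int), 1)
    while counts.sum() > total:
        counts[np.argmax(counts - quota)] -= 1
    rem = quota - counts
    while counts.sum() < total:
        i = np.argmax(rem)
        counts[i] += 1
        rem[i] = -np.inf
    return dict(zip(names, counts.tolist()))


def transfer_surface_points(
    template: ToothTemplate,
    specimen_anchors: np.ndarray,
    specimen_mesh: SurfaceGeometry,
) -> LandmarkConfiguration:
    """Transpose the template's surface semilandmarks onto a specimen.

    Fits a TPS from the template's fixed+curve points to the specimen's
    anchors, warps the template surface points through it, and projects each
    warped point onto the specimen mesh.  Returns a full configuration in
    canonical order.
    """
    if specimen_mesh is None or len(specimen_mesh.faces) == 0:
        raise InvalidInputError("a specimen mesh is required for surface transfer")
    anchors = np.asarray(specimen_anchors, dtype=float)
    n_anchor = template.n_fixed + template.n_curve
    if anchors.shape != (n_anchor, 3):
        raise TemplateValidationError(
            f"expected {n_anchor} anchor points (fixed + curve), got {anchors.shape}"
        )
    ref = template.reference.points
    model = tps_fit(ref[:n_anchor], anchors)
    warped = tps_warp(model, ref[n_anchor:])
    projected, _, _ = specimen_mesh.project_to_surface(warped)
    points = np.vstack([anchors, projected])
    return LandmarkConfiguration(
        specimen_id="transferred",
        tooth=template.tooth,
        points=points,
        roles=template.canonical_roles(),
        curve_id=template.canonical_curve_ids(),
    )
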