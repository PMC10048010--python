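"""Synthetic sexually dimorphic tooth-crown datasets.

The study data (intraoral scans of first/second premolars and first molars)
are private, so this module procedurally generates crowns with the
statistical structure the analysis assumes: a smooth bumped-paraboloid
occlusal surface with 2 (premolar) or 4 (molar) cusps, fixed landmarks at
cusp apices and fossa minima, ridge/sulcus curves, and surface semilandmarks
laid out per the tooth templates.  Sexual dimorphism enters as

* a sex-linked mean-shape displacement along a fixed smooth (TPS) deformation
  field, expressed in Procrustes-distance units so it is template
  independent;
* a sex-linked centroid-size ratio (log-normal individual sizes);

plus per-specimen smooth shape variation, per-landmark digitization noise
with re-projection onto the geometry (emulating operator placement), and
random rigid motion of every scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import Delaunay
from scipy.stats import special_ortho_group

from .errors import InvalidInputError
from .geometry import Polyline, SurfaceGeometry
from .procrustes import procrustes_distance
from .templates import (
    MOLAR_CURVES,
    PREMOLAR_CURVES,
    ToothTemplate,
    allocate_curve_counts,
    build_molar_template,
    build_premolar_template,
)
from .tps import tps_fit, tps_warp
from .types import LandmarkConfiguration, Tooth

# ---------------------------------------------------------------------------
# analytic crown surfaces
# ---------------------------------------------------------------------------

# x: mesio(+)-distal(-) axis, y: bucco(+)-palatal(-) axis, z: occlusal height.
_CROWN_PARAMS = {
    Tooth.FP: dict(
        a=4.0, b=4.6, dome=1.8, ridge_amp=0.7, ridge_pos=0.85, ridge_w=0.08,
        cusps=[(0.0, 2.3, 1.7, 1.5), (0.0, -2.2, 1.35, 1.4)],
        mesh_step=0.25, bow=2.6,
    ),
    Tooth.SP: dict(
        a=3.8, b=4.4, dome=1.7, ridge_amp=0.65, ridge_pos=0.85, ridge_w=0.08,
        cusps=[(0.0, 2.1, 1.5, 1.45), (0.0, -2.1, 1.3, 1.4)],
        mesh_step=0.25, bow=2.4,
    ),
    Tooth.M: dict(
        a=5.3, b=5.5, dome=1.6, ridge_amp=0.7, ridge_pos=0.87, ridge_w=0.07,
        cusps=[(2.3, 2.6, 1.5, 1.6), (2.4, -2.7, 1.7, 1.7),
               (-2.3, 2.5, 1.4, 1.55), (-2.5, -2.5, 1.3, 1.5)],
        mesh_step=0.28, bow=2.8,
    ),
}


def _height(tooth: Tooth, x, y):
    p = _CROWN_PARAMS[tooth]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    e = np.sqrt((x / p["a"]) ** 2 + (y / p["b"]) ** 2)
    z = p["dome"] * (1.0 - e**2)
    z = z + p["ridge_amp"] * np.exp(-((e - p["ridge_pos"]) ** 2) / (2 * p["ridge_w"] ** 2))
    for cx, cy, amp, sig in p["cusps"]:
        z = z + amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sig**2))
    return z


def _lift(tooth: Tooth, xy: np.ndarray) -> np.ndarray:
    return np.column_stack([xy[:, 0], xy[:, 1], _height(tooth, xy[:, 0], xy[:, 1])])


def _refine_apex(tooth: Tooth, x0: float, y0: float, half: float = 1.2) -> np.ndarray:
    """Locate a cusp apex by local grid refinement of the height function."""
    g = np.linspace(-half, half, 121)
    xx, yy = np.meshgrid(x0 + g, y0 + g)
    zz = _height(tooth, xx, yy)
    i = np.unravel_index(np.argmax(zz), zz.shape)
    return np.array([xx[i], yy[i], zz[i]])


def _premolar_fossa(tooth: Tooth, sign: float) -> np.ndarray:
    """Fossa = local minimum of the height profile along the central groove."""
    p = _CROWN_PARAMS[tooth]
    x = sign * np.linspace(0.4, 0.92 * p["a"], 200)
    z = _height(tooth, x, np.zeros_like(x))
    i = int(np.argmin(z))
    return np.array([x[i], 0.0, z[i]])


def _bezier_2d(p0, p1, p2, n: int = 150) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _curve_on_crown(tooth: Tooth, start_xy, end_xy, bow_vec, n: int = 150) -> np.ndarray:
    p0 = np.asarray(start_xy, dtype=float)
    p2 = np.asarray(end_xy, dtype=float)
    p1 = (p0 + p2) / 2 + np.asarray(bow_vec, dtype=float)
    return _lift(tooth, _bezier_2d(p0, p1, p2, n))


def _interior_points(poly: Polyline, count: int) -> np.ndarray:
    """``count`` equally spaced points strictly inside the curve."""
    s = np.arange(1, count + 1) / (count + 1) * poly.total_length
    return poly.point_at(s)


def _sunflower_xy(tooth: Tooth, n: int, radius: float = 0.88) -> np.ndarray:
    """Evenly covering layout of n points inside the crown outline."""
    p = _CROWN_PARAMS[tooth]
    k = np.arange(1, n + 1)
    r = radius * np.sqrt((k - 0.5) / n)
    theta = k * 2.399963229728653  # golden angle
    return np.column_stack([p["a"] * r * np.cos(theta), p["b"] * r * np.sin(theta)])


def _crown_mesh(tooth: Tooth, mesh_step: float | None = None) -> Tuple[np.ndarray, np.ndarray]:
    p = _CROWN_PARAMS[tooth]
    step = mesh_step or p["mesh_step"]
    a, b = p["a"], p["b"]
    xs = np.arange(-a, a + step / 2, step)
    ys = np.arange(-b, b + step / 2, step)
    xx, yy = np.meshgrid(xs, ys)
    e = np.sqrt((xx / a) ** 2 + (yy / b) ** 2)
    inner = np.column_stack([xx[e < 0.985], yy[e < 0.985]])
    ang = np.linspace(0, 2 * np.pi, 120, endpoint=False)
    ring = np.column_stack([a * np.cos(ang), b * np.sin(ang)])
    xy = np.vstack([inner, ring])
    tri = Delaunay(xy)
    faces = tri.simplices
    v = xy[faces]
    area2 = (v[:, 1, 0] - v[:, 0, 0]) * (v[:, 2, 1] - v[:, 0, 1]) - (
        v[:, 2, 0] - v[:, 0, 0]
    ) * (v[:, 1, 1] - v[:, 0, 1])
    flip = area2 < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    faces = faces[np.abs(area2) > 1e-8]
    vertices = np.column_stack([xy, _height(tooth, xy[:, 0], xy[:, 1])])
    return vertices, faces


@lru_cache(maxsize=8)
def _reference_crown_cached(tooth: Tooth, mesh_step: float | None):
    tooth = Tooth(tooth)
    p = _CROWN_PARAMS[tooth]
    vertices, faces = _crown_mesh(tooth, mesh_step)

    cusps = [_refine_apex(tooth, cx, cy) for cx, cy, _, _ in p["cusps"]]
    if tooth in (Tooth.FP, Tooth.SP):
        buccal, lingual = cusps
        fixed = np.array(
            [buccal, lingual, _premolar_fossa(tooth, +1), _premolar_fossa(tooth, -1)]
        )
        bow = p["bow"]
        curves = {
            "mesial_ridge": _curve_on_crown(tooth, buccal[:2], lingual[:2], (+bow, 0.0)),
            "distal_ridge": _curve_on_crown(tooth, buccal[:2], lingual[:2], (-bow, 0.0)),
        }
        counts = dict(zip(PREMOLAR_CURVES, (5, 4)))
        n_surface = 50
    else:
        mb, mp_, db, dp = cusps
        fixed = np.array([mb, mp_, db, dp])
        bow = p["bow"]
        b_ax = p["b"]
        curves = {
            "mesial_marginal_ridge": _curve_on_crown(tooth, mb[:2], mp_[:2], (+bow, 0.0)),
            "distal_marginal_ridge": _curve_on_crown(tooth, db[:2], dp[:2], (-bow, 0.0)),
            "buccal_ridge": _curve_on_crown(tooth, mb[:2], db[:2], (0.0, +bow)),
            "palatal_ridge": _curve_on_crown(tooth, mp_[:2], dp[:2], (0.0, -bow)),
            "central_sulcus": _curve_on_crown(tooth, (2.0, 0.0), (-2.0, 0.0), (0.0, 0.0), n=80),
            "buccal_sulcus": _curve_on_crown(tooth, (0.0, 0.4), (0.0, 0.85 * b_ax), (0.0, 0.0), n=80),
            "palatal_sulcus": _curve_on_crown(tooth, (0.0, -0.4), (0.0, -0.85 * b_ax), (0.0, 0.0), n=80),
            "mesiobuccal_cusp_ridge": _curve_on_crown(tooth, mb[:2], 0.25 * mb[:2], (0.0, 0.0), n=80),
            "mesiopalatal_cusp_ridge": _curve_on_crown(tooth, mp_[:2], 0.25 * mp_[:2], (0.0, 0.0), n=80),
            "distobuccal_cusp_ridge": _curve_on_crown(tooth, db[:2], 0.25 * db[:2], (0.0, 0.0), n=80),
            "distopalatal_cusp_ridge": _curve_on_crown(tooth, dp[:2], 0.25 * dp[:2], (0.0, 0.0), n=80),
        }
        assert tuple(curves) == MOLAR_CURVES
        lengths = {name: Polyline(pts).total_length for name, pts in curves.items()}
        counts = allocate_curve_counts(lengths, 51)
        n_surface = 210

    geometry = SurfaceGeometry(vertices=vertices, faces=faces, curves=curves)
    curve_pts = np.vstack(
        [_interior_points(geometry.polyline(name), counts[name]) for name in curves]
    )
    surf_xy = _sunflower_xy(tooth, n_surface)
    surf_pts, _, _ = geometry.project_to_surface(_lift(tooth, surf_xy))

    points = np.vstack([fixed, curve_pts, surf_pts])
    roles = (
        ["fixed"] * 4
        + sum(([["curve"] * counts[name]][0] for name in curves), [])
        + ["surface"] * n_surface
    )
    cid = np.full(len(points), -1, dtype=int)
    pos = 4
    for i, name in enumerate(curves):
        cid[pos : pos + counts[name]] = i
        pos += counts[name]
    config = LandmarkConfiguration(
        specimen_id=f"{tooth.value}_reference",
        tooth=tooth,
        points=points,
        roles=np.asarray(roles, dtype="U7"),
        curve_id=cid,
    )
    return config, geometry


def make_reference_crown(
    tooth: Tooth, mesh_step: float | None = None
) -> Tuple[LandmarkConfiguration, SurfaceGeometry]:
    """Procedurally generated reference crown for one tooth type.

    Returns the reference landmark configuration (canonical template order,
    63 points for premolars / 265 for the molar) and the crown geometry
    (triangulated surface plus named ridge/sulcus polylines).  Deterministic:
    the crown is an analytic function of the tooth parameters.
    """
    config, geometry = _reference_crown_cached(Tooth(tooth), mesh_step)
    return config.copy(), geometry


def reference_template(tooth: Tooth) -> ToothTemplate:
    """Tooth template built from the synthetic reference crown."""
    config, geometry = make_reference_crown(tooth)
    if Tooth(tooth) is Tooth.M:
        return build_molar_template(config, geometry=geometry)
    return build_premolar_template(config, geometry=geometry)


# ---------------------------------------------------------------------------
# smooth deformation fields
# ---------------------------------------------------------------------------


def _field_controls(tooth: Tooth, rng: np.random.Generator, k: int = 14) -> np.ndarray:
    p = _CROWN_PARAMS[tooth]
    lo = np.array([-1.2 * p["a"], -1.2 * p["b"], -1.0])
    hi = np.array([1.2 * p["a"], 1.2 * p["b"], 4.5])
    return rng.uniform(lo, hi, size=(k, 3))


def _unit_field(ctrl: np.ndarray, disp: np.ndarray, probe: np.ndarray):
    """Smooth displacement field with unit RMS displacement at the probe
    points, built as a TPS warp of the control points."""
    model = tps_fit(ctrl, ctrl + disp)

    def raw(x: np.ndarray) -> np.ndarray:
        return tps_warp(model, x) - x

    rms = np.sqrt(np.mean(np.sum(raw(probe) ** 2, axis=1)))
    scale = 1.0 / rms if rms > 0 else 0.0
    return lambda x: scale * raw(x)


_SEX_FIELD_SEED = {Tooth.FP: 1181, Tooth.SP: 2383, Tooth.M: 3593}


@lru_cache(maxsize=8)
def _sex_field_cached(tooth: Tooth):
    """The fixed low-frequency deformation field carrying the sex signal."""
    config, _ = _reference_crown_cached(Tooth(tooth), None)
    rng = np.random.default_rng(_SEX_FIELD_SEED[Tooth(tooth)])
    ctrl = _field_controls(tooth, rng)
    disp = rng.normal(size=ctrl.shape)
    return _unit_field(ctrl, disp, config.points)


def _amplitude_for_effect(tooth: Tooth, shape_effect: float) -> float:
    """Field amplitude such that the Procrustes distance between the two sex
    mean shapes (reference displaced by +/- amplitude) equals shape_effect."""
    if shape_effect == 0:
        return 0.0
    config, _ = _reference_crown_cached(Tooth(tooth), None)
    f = _sex_field_cached(Tooth(tooth))
    ref = config.points
    amp = 1e-3
    for _ in range(2):
        d = procrustes_distance(ref + amp * f(ref), ref - amp * f(ref))
        amp *= shape_effect / d
    return amp


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class DimorphismSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate the study sample: 115 females and 115 males, three
    maxillary left teeth per subject.  ``shape_effect`` is the Procrustes
    distance between the sex mean shapes; ``None`` calibrates it so the
    between-sex distance is 1.5x the median within-sex pairwise distance.
    ``size_ratio`` is the male/female mean centroid-size ratio (~4 percent,
    the order of magnitude of reported dental size dimorphism).
    """

    teeth: Tuple[Tooth, ...] = (Tooth.FP, Tooth.SP, Tooth.M)
    n_f: int = 115
    n_m: int = 115
    shape_effect: Optional[float] = None
    size_ratio: float = 1.04
    individual_shape_sd: float = 0.08
    digitization_sd: float = 0.008
    size_log_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        self.teeth = tuple(Tooth(t) for t in self.teeth)
        if self.n_f < 0 or self.n_m < 0:
            raise InvalidInputError("specimen counts must be >= 0")
        if self.size_ratio <= 0:
            raise InvalidInputError("size_ratio must be positive")
        for name in ("individual_shape_sd", "digitization_sd", "size_log_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")


@dataclass
class Specimen:
    specimen_id: str
    sex: str
    configs: Dict[Tooth, LandmarkConfiguration]
    geometries: Dict[Tooth, SurfaceGeometry] = field(default_factory=dict)


@dataclass
class Cohort:
    spec: DimorphismSpec
    specimens: List[Specimen]
    shape_effect: float

    @property
    def specimen_ids(self) -> List[str]:
        return [s.specimen_id for s in self.specimens]

    def labels(self) -> Dict[str, str]:
        return {s.specimen_id: s.sex for s in self.specimens}

    def configs_for(self, tooth: Tooth) -> List[LandmarkConfiguration]:
        return [s.configs[Tooth(tooth)] for s in self.specimens]


def calibrate_shape_effect(spec: DimorphismSpec, ratio: float = 1.5, n_probe: int = 16) -> float:
    """Shape effect equal to ``ratio`` times the median within-sex pairwise
    Procrustes distance implied by the spec's noise levels."""
    rng = np.random.default_rng((spec.seed * 1000003 + 12345) % 2**31)
    medians = []
    for tooth in spec.teeth:
        config, _ = _reference_crown_cached(tooth, None)
        ref = config.points
        ctrl = _field_controls(tooth, np.random.default_rng(_SEX_FIELD_SEED[tooth] + 7))
        probes = []
        for _ in range(n_probe):
            f = _unit_field(ctrl, rng.normal(size=ctrl.shape), ref)
            pts = ref + spec.individual_shape_sd * f(ref)
            pts = pts + rng.normal(scale=spec.digitization_sd, size=pts.shape)
            probes.append(pts)
        d = [
            procrustes_distance(probes[i], probes[j])
            for i in range(n_probe)
            for j in range(i + 1, n_probe)
        ]
        medians.append(np.median(d))
    return float(ratio * np.mean(medians))


def _digitize(
    config: LandmarkConfiguration,
    geometry: Optional[SurfaceGeometry],
    sd: float,
    rng: np.random.Generator,
) -> LandmarkConfiguration:
    """Per-landmark digitization noise followed by re-projection of the
    semilandmarks onto the specimen geometry (when available)."""
    pts = config.points + rng.normal(scale=sd, size=config.points.shape) if sd > 0 else config.points.copy()
    if geometry is not None and sd > 0:
        curve_names = list(geometry.curves)
        for cid in sorted(set(config.curve_id[config.curve_mask])):
            sel = (config.roles == "curve") & (config.curve_id == cid)
            proj, _, _ = geometry.polyline(curve_names[cid]).project(pts[sel])
            pts[sel] = proj
        surf = config.surface_mask
        if surf.any():
            proj, _, _ = geometry.project_to_surface(pts[surf])
            pts[surf] = proj
    return config.with_points(pts)


def generate_cohort(spec: DimorphismSpec, include_meshes: bool = True) -> Cohort:
    """Generate a labeled synthetic cohort per the dimorphism spec.

    Per specimen and tooth: displace the reference by +/- half the sex effect
    along the fixed deformation field, add a smooth individual deformation,
    add digitization noise (re-projected onto the geometry), scale by a
    log-normal sex-specific size, and apply a random rigid motion.
    Reproducible: everything derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    effect = spec.shape_effect if spec.shape_effect is not None else calibrate_shape_effect(spec)

    refs = {t: make_reference_crown(t) for t in spec.teeth}
    fields = {t: _sex_field_cached(t) for t in spec.teeth}
    amps = {t: _amplitude_for_effect(t, effect) for t in spec.teeth}
    ind_ctrl = {
        t: _field_controls(t, np.random.default_rng(_SEX_FIELD_SEED[t] + 7))
        for t in spec.teeth
    }

    sexes = ["F"] * spec.n_f + ["M"] * spec.n_m
    ids = [f"F{i + 1:03d}" for i in range(spec.n_f)] + [
        f"M{i + 1:03d}" for i in range(spec.n_m)
    ]

    specimens: List[Specimen] = []
    for sid, sex in zip(ids, sexes):
        sex_sign = 1.0 if sex == "F" else -1.0
        mu = 0.0 if sex == "F" else np.log(spec.size_ratio)
        size_factor = float(np.exp(rng.normal(mu, spec.size_log_sd)))
        configs: Dict[Tooth, LandmarkConfiguration] = {}
        geometries: Dict[Tooth, SurfaceGeometry] = {}
        for tooth in spec.teeth:
            ref_config, ref_geom = refs[tooth]
            f_sex = fields[tooth]
            f_ind = _unit_field(
                ind_ctrl[tooth], rng.normal(size=ind_ctrl[tooth].shape), ref_config.points
            )
            rotation = special_ortho_group.rvs(3, random_state=rng)
            translation = rng.uniform(-15.0, 15.0, size=3)

            def morph(x, _fs=f_sex, _fi=f_ind, _s=sex_sign, _a=amps[tooth]):
                return x + _s * _a * _fs(x) + spec.individual_shape_sd * _fi(x)

            pts = morph(ref_config.points) * size_factor @ rotation + translation
            geom = None
            if include_meshes:
                geom = ref_geom.transformed(
                    scale=size_factor, rotation=rotation, translation=translation,
                    warp=morph,
                )
                geometries[tooth] = geom
            config = LandmarkConfiguration(
                specimen_id=sid,
                tooth=tooth,
                points=pts,
                roles=ref_config.roles.copy(),
                curve_id=ref_config.curve_id.copy(),
            )
            configs[tooth] = _digitize(config, geom, spec.digitization_sd, rng)
        specimens.append(Specimen(sid, sex, configs, geometries))
    return Cohort(spec=spec, specimens=specimens, shape_effect=effect)


def generate_repeat_round(
    cohort: Cohort,
    digitization_sd: float,
    seed: int,
    specimen_ids: Optional[Sequence[str]] = None,
) -> Dict[str, Dict[Tooth, LandmarkConfiguration]]:
    """Second digitization round: fresh per-landmark noise on each selected
    specimen, re-projected onto its geometry.  ``sd=0`` reproduces round 1."""
    if digitization_sd < 0:
        raise InvalidInputError("digitization_sd must be >= 0")
    rng = np.random.default_rng(seed)
    wanted = set(specimen_ids) if specimen_ids is not None else None
    out: Dict[str, Dict[Tooth, LandmarkConfiguration]] = {}
    for sp in cohort.specimens:
        if wanted is not None and sp.specimen_id not in wanted:
            continue
        out[sp.specimen_id] = {
            tooth: _digitize(cfg, sp.geometries.get(tooth), digitization_sd, rng)
            for tooth, cfg in sp.configs.items()
        }
    return out
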