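"""Readers and writers for landmark files, meshes and result tables.

Two landmark dialects are supported: the TPS record format (``LM3=<n>``
followed by n whitespace-separated coordinate triples and an ``ID=<name>``
line per specimen) and a long CSV format with one row per point
(``specimen_id, tooth, point_index, role, curve_id, x, y, z``).  Meshes are
read/written as triangulated PLY or OBJ via trimesh.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd
import trimesh

from .errors import ParseError, SchemaError
from .geometry import SurfaceGeometry
from .procrustes import AlignedSample
from .templates import ToothTemplate
from .types import ROLES, LandmarkConfiguration, Tooth

# -- TPS record format ------------------------------------------------------


def write_tps(configs: Iterable[LandmarkConfiguration], path) -> None:
    """Write configurations as TPS records (LM3= count, triples, ID= line)."""
    lines: List[str] = []
    for cfg in configs:
        lines.append(f"LM3={cfg.n_points}")
        for x, y, z in cfg.points:
            lines.append(f"{x:.10g} {y:.10g} {z:.10g}")
        lines.append(f"ID={cfg.specimen_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tps(
    path,
    tooth: Tooth = Tooth.FP,
    template: Optional[ToothTemplate] = None,
) -> List[LandmarkConfiguration]:
    """Parse a TPS-format landmark file.

    Roles/curve ids are taken from ``template`` when given (the file itself
    carries only coordinates); otherwise every point is tagged ``fixed``.
    Raises :class:`ParseError` with the offending line number on malformed
    records.
    """
    text = Path(path).read_text().splitlines()
    configs: List[LandmarkConfiguration] = []
    i = 0
    record = 0
    while i < len(text):
        line = text[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM3="):
            raise ParseError(f"line {i + 1}: expected 'LM3=<count>', got {line!r}")
        record += 1
        try:
            n = int(line.split("=", 1)[1])
        except ValueError:
            raise ParseError(f"line {i + 1}: bad LM3 count in {line!r}") from None
        i += 1
        pts = []
        while i < len(text) and len(pts) < n:
            row = text[i].strip()
            if not row:
                i += 1
                continue
            if "=" in row:
                break
            parts = row.split()
            if len(parts) != 3:
                raise ParseError(f"line {i + 1}: expected 3 coordinates, got {row!r}")
            try:
                pts.append([float(v) for v in parts])
            except ValueError:
                raise ParseError(f"line {i + 1}: non-numeric coordinate in {row!r}") from None
            i += 1
        if len(pts) != n:
            raise ParseError(
                f"record {record} (LM3={n}): found only {len(pts)} coordinate triples"
            )
        specimen_id = f"specimen_{record}"
        if i < len(text) and text[i].strip().upper().startswith("ID="):
            specimen_id = text[i].strip().split("=", 1)[1]
            i += 1
        pts = np.asarray(pts)
        if template is not None:
            template_roles = template.canonical_roles()
            if len(pts) != template.total:
                raise ParseError(
                    f"record {specimen_id!r}: {len(pts)} points, template "
                    f"expects {template.total}"
                )
            cfg = LandmarkConfiguration(
                specimen_id, template.tooth, pts, template_roles,
                template.canonical_curve_ids(),
            )
        else:
            cfg = LandmarkConfiguration(
                specimen_id, tooth, pts, np.asarray(["fixed"] * len(pts), dtype="U7")
            )
        configs.append(cfg)
    return configs


# -- long CSV format --------------------------------------------------------

CSV_COLUMNS = ["specimen_id", "tooth", "point_index", "role", "curve_id", "x", "y", "z"]


def write_landmarks_csv(configs: Iterable[LandmarkConfiguration], path) -> None:
    rows = []
    for cfg in configs:
        for i in range(cfg.n_points):
            rows.append(
                {
                    "specimen_id": cfg.specimen_id,
                    "tooth": cfg.tooth.value,
                    "point_index": i,
                    "role": cfg.roles[i],
                    "curve_id": int(cfg.curve_id[i]),
                    "x": cfg.points[i, 0],
                    "y": cfg.points[i, 1],
                    "z": cfg.points[i, 2],
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def read_landmarks_csv(path) -> List[LandmarkConfiguration]:
    """Read the long CSV dialect; rows may appear in any order (the
    ``point_index`` column restores the canonical ordering)."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"landmark CSV is missing columns: {missing}")
    bad_roles = set(df["role"].astype(str)) - set(ROLES)
    if bad_roles:
        raise SchemaError(f"unknown role tags: {sorted(bad_roles)}")
    configs = []
    for (sid, tooth), grp in df.groupby(["specimen_id", "tooth"], sort=False):
        grp = grp.sort_values("point_index")
        idx = grp["point_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise SchemaError(
                f"specimen {sid!r}/{tooth}: point_index must be 0..n-1 without gaps"
            )
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(sid),
                tooth=Tooth(tooth),
                points=grp[["x", "y", "z"]].to_numpy(dtype=float),
                roles=grp["role"].astype(str).to_numpy(),
                curve_id=grp["curve_id"].to_numpy(dtype=int),
            )
        )
    return configs


# -- meshes -----------------------------------------------------------------


def write_mesh(geometry: SurfaceGeometry, path) -> None:
    """Write the crown mesh as ASCII PLY (or OBJ, by extension)."""
    mesh = trimesh.Trimesh(vertices=geometry.vertices, faces=geometry.faces, process=False)
    path = Path(path)
    if path.suffix.lower() == ".ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
    else:
        mesh.export(path)


def read_mesh(path) -> SurfaceGeometry:
    mesh = trimesh.load(str(path), force="mesh", process=False)
    if mesh.faces.shape[1] != 3:
        raise ParseError("only triangulated meshes are supported")
    return SurfaceGeometry(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces))


# -- result tables ----------------------------------------------------------


def write_aligned_csv(sample: AlignedSample, path) -> None:
    """Aligned shape coordinates (one row per specimen point) plus the mean
    shape under the pseudo-specimen id ``__mean__``."""
    cfgs = [
        LandmarkConfiguration(
            sid, sample.tooth, sample.aligned[i],
            np.asarray(["fixed"] * sample.n_points, dtype="U7"),
        )
        for i, sid in enumerate(sample.specimen_ids)
    ]
    cfgs.append(
        LandmarkConfiguration(
            "__mean__", sample.tooth, sample.mean_shape,
            np.asarray(["fixed"] * sample.n_points, dtype="U7"),
        )
    )
    write_landmarks_csv(cfgs, path)


def write_roc_csv(roc, path) -> None:
    pd.DataFrame(
        {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
    ).to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=float) + "\n")
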