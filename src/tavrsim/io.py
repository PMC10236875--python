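"""File I/O: mesh/field export, landmark and cohort tables, YAML configs.

Geometry goes out as STL (via trimesh, geometry only) or legacy ASCII VTK
(geometry plus per-node / per-element scalars, viewable in ParaView).
Tables are plain CSV; single-run metrics are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .anatomy import AorticRootModel, RootParams
from .deployment import ContactPressureField


def _mesh_arrays(model: AorticRootModel):
    pts = model.node_coordinates().reshape(-1, 3)
    nz, nc = model.radius.shape
    idx = np.arange(nz * nc).reshape(nz, nc)
    quads = np.stack(
        [
            idx[:-1, :].ravel(),
            np.roll(idx, -1, axis=1)[:-1, :].ravel(),
            np.roll(idx, -1, axis=1)[1:, :].ravel(),
            idx[1:, :].ravel(),
        ],
        axis=1,
    )
    return pts, quads


def export_stl(model: AorticRootModel, path) -> None:
    """Write the wall surface as binary STL (geometry only)."""
    import trimesh

    pts, quads = _mesh_arrays(model)
    tris = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]])
    trimesh.Trimesh(vertices=pts, faces=tris, process=False).export(str(path))


def export_vtk(
    model: AorticRootModel,
    path,
    point_data: Optional[Dict[str, np.ndarray]] = None,
    cell_data: Optional[Dict[str, np.ndarray]] = None,
) -> None:
    """Write a legacy ASCII VTK PolyData file with optional scalars.

    ``point_data`` arrays must have shape (n_z, n_circ); ``cell_data``
    arrays shape (n_z - 1, n_circ).
    """
    pts, quads = _mesh_arrays(model)
    lines = [
        "# vtk DataFile Version 3.0",
        "tavrsim aortic root surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(pts)} float",
    ]
    lines += [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in pts]
    lines.append(f"POLYGONS {len(quads)} {5 * len(quads)}")
    lines += ["4 " + " ".join(str(i) for i in q) for q in quads]
    if point_data:
        lines.append(f"POINT_DATA {len(pts)}")
        for name, arr in point_data.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.6e}" for v in np.asarray(arr).ravel()]
    if cell_data:
        lines.append(f"CELL_DATA {len(quads)}")
        for name, arr in cell_data.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.6e}" for v in np.asarray(arr).ravel()]
    Path(path).write_text("\n".join(lines) + "\n")


def export_pressure_vtk(model: AorticRootModel, field: ContactPressureField, path) -> None:
    """Deployed state with the contact-pressure scalar per element."""
    export_vtk(
        model,
        path,
        point_data={"nodal_force_N": field.nodal_force},
        cell_data={"contact_pressure_MPa": field.pressure},
    )


def field_to_csv(model: AorticRootModel, field: ContactPressureField, path) -> None:
    """Per-element table: element id, theta (deg), z (mm), area, pressure."""
    df = pd.DataFrame(
        {
            "element_id": np.arange(field.pressure.size),
            "theta_deg": model.element_theta.ravel(),
            "z_mm": model.element_z.ravel(),
            "area_mm2": field.element_area.ravel(),
            "pressure_mpa": field.pressure.ravel(),
        }
    )
    df.to_csv(path, index=False)


def landmarks_to_csv(model: AorticRootModel, path) -> None:
    rows = [
        {"name": name, "theta_deg": th, "z_mm": z}
        for name, (th, z) in model.landmarks.items()
    ]
    rows += [
        {"name": f"ms_{k}", "theta_deg": th, "z_mm": -depth}
        for k, (th, depth) in model.ms_landmarks.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# RootParams round-trip
# ---------------------------------------------------------------------------

def root_params_to_dict(params: RootParams) -> dict:
    d = dataclasses.asdict(params)
    d["calcium_volumes"] = {
        f"{region}:{cusp}": float(v)
        for (region, cusp), v in params.calcium_volumes.items()
    }
    d["axial_heights"] = list(params.axial_heights)
    d["cusp_angles"] = list(params.cusp_angles)
    d["ms_angles"] = list(params.ms_angles)
    return d


def root_params_from_dict(d: dict) -> RootParams:
    d = dict(d)
    vols = {}
    for key, v in (d.pop("calcium_volumes", {}) or {}).items():
        region, cusp = key.split(":")
        vols[(region, cusp)] = float(v)
    for key in ("axial_heights", "cusp_angles", "ms_angles"):
        if key in d:
            d[key] = tuple(float(x) for x in d[key])
    return RootParams(calcium_volumes=vols, **d) if vols else RootParams(**d)


def save_root_params(params: RootParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(root_params_to_dict(params)))


def load_root_params(path) -> RootParams:
    return root_params_from_dict(yaml.safe_load(Path(path).read_text()))


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
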