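"""File formats: F-D curve text files, VTK mesh export, YAML run configs.

Curves travel as plain delimited text with ``#``-prefixed metadata header
lines and the exact column names ``displacement_nm, force_nN`` (processed
curves) or ``piezo_nm, force_nN`` (raw records).  Meshes and nodal fields
are written as legacy-ASCII VTK unstructured grids for visualization.
All physical quantities in configs carry unit-suffixed keys.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import FDCurve, RawFDCurve
from .geometry import build_geometry
from .mesh import HexMesh

__all__ = [
    "write_curve",
    "read_curve",
    "write_raw_curve",
    "read_raw_curve",
    "write_vtk",
    "load_config",
    "ConfigError",
]

_META_KEYS = ("treatment", "set_force_nN", "source", "k_N_per_m", "seed")


def _write_table(path, df: pd.DataFrame, meta: dict) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k in _META_KEYS:
            if k in meta and meta[k] is not None:
                fh.write(f"# {k} = {meta[k]}\n")
        df.to_csv(fh, index=False)


def _read_meta(path) -> dict:
    meta = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line.lstrip("# ").partition("=")
            k, v = k.strip(), v.strip()
            try:
                meta[k] = float(v) if "." in v or "e" in v.lower() else int(v)
            except ValueError:
                meta[k] = v
    return meta


def write_curve(path, curve: FDCurve) -> None:
    """Write a processed F-D curve (columns displacement_nm, force_nN)."""
    df = pd.DataFrame(
        {"displacement_nm": curve.displacement, "force_nN": curve.force}
    )
    _write_table(path, df, curve.meta)


def read_curve(path) -> FDCurve:
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    for col in ("displacement_nm", "force_nN"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return FDCurve(df["displacement_nm"].to_numpy(), df["force_nN"].to_numpy(), meta)


def write_raw_curve(path, raw: RawFDCurve) -> None:
    """Write a raw AFM record (columns piezo_nm, force_nN)."""
    meta = dict(raw.meta)
    meta["k_N_per_m"] = raw.cantilever_k
    df = pd.DataFrame({"piezo_nm": raw.piezo_position, "force_nN": raw.force})
    _write_table(path, df, meta)


def read_raw_curve(path) -> RawFDCurve:
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    for col in ("piezo_nm", "force_nN"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    k = float(meta.pop("k_N_per_m", np.inf))
    return RawFDCurve(df["piezo_nm"].to_numpy(), df["force_nN"].to_numpy(), k, meta)


def write_vtk(path, mesh: HexMesh, point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy-ASCII VTK unstructured grid with hexahedral cells."""
    path = Path(path)
    n, e = mesh.nodes, mesh.elements
    lines = [
        "# vtk DataFile Version 3.0",
        "nemaindent mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(n)} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in n]
    lines.append(f"CELLS {len(e)} {len(e) * 9}")
    lines += ["8 " + " ".join(str(i) for i in row) for row in e]
    lines.append(f"CELL_TYPES {len(e)}")
    lines += ["12"] * len(e)  # VTK_HEXAHEDRON

    if point_data:
        lines.append(f"POINT_DATA {len(n)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{v:.9g}" for v in p) for p in arr]
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.9g}" for v in arr.ravel()]
    cdata = dict(cell_data or {})
    if "compartment_id" not in cdata:
        names = sorted(set(mesh.element_compartment))
        ids = {nm: i for i, nm in enumerate(names)}
        cdata["compartment_id"] = np.array(
            [ids[c] for c in mesh.element_compartment], dtype=float
        )
    lines.append(f"CELL_DATA {len(e)}")
    for name, arr in cdata.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{float(v):.9g}" for v in np.asarray(arr).ravel()]
    path.write_text("\n".join(lines) + "\n")


class ConfigError(ValueError):
    pass


_CONFIG_SCHEMA = {
    "geometry": {
        "pseudocoelom_diameter_um": float,
        "muscle_width_um": float,
        "hypodermis_width_um": float,
        "cuticle_width_um": float,
        "length_um": float,
    },
    "materials": {
        "E_cuticle_kPa": float,
        "E_muscle_kPa": float,
        "E_pseudocoelom_kPa": float,
        "nu": float,
    },
    "solver": {
        "newton_tol": float,
        "max_newton_iters": int,
        "step_cutback": float,
    },
    "contact": {
        "sphere_radius_um": float,
        "penalty_factor": float,
        "support": str,
    },
    "protocol": {
        "set_force_nN": float,
        "max_depth_nm": float,
        "step_um": float,
        "level": int,
    },
    "seed": int,
}


def _validate(block: dict, schema: dict, path: str = "") -> None:
    for key, val in block.items():
        here = f"{path}.{key}" if path else key
        if key not in schema:
            raise ConfigError(f"unknown config field {here!r}")
        expect = schema[key]
        if isinstance(expect, dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here!r} must be a mapping")
            _validate(val, expect, here)
        else:
            if expect is float and isinstance(val, (int, float)):
                continue
            if not isinstance(val, expect):
                raise ConfigError(
                    f"{here!r} must be {expect.__name__}, got {type(val).__name__}"
                )


def load_config(path) -> dict:
    """Load and schema-validate a YAML/JSON run configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    _validate(cfg, _CONFIG_SCHEMA)
    return cfg


def geometry_from_config(cfg: dict):
    return build_geometry(**cfg.get("geometry", {}))
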