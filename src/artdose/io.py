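"""Grid/mask file I/O.

Grids and masks travel as NRRD files with ``encoding: ascii`` (text-only,
one file per grid or mask; masks as uint8), written and parsed by a minimal
NRRD0004 implementation restricted to what this pipeline emits.  Plan
metadata goes in a JSON sidecar: prescription, fraction counts, structure
roles and the tissue exponent registry.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .grids import Grid3D, Mask3D, StructureRole

__all__ = [
    "write_nrrd",
    "read_nrrd",
    "write_grid",
    "read_grid",
    "write_mask",
    "read_mask",
    "write_field",
    "read_field",
    "write_sidecar",
    "read_sidecar",
]

_TYPE_MAP = {"double": np.float64, "float": np.float32,
             "unsigned char": np.uint8, "uint8": np.uint8,
             "int": np.int32, "short": np.int16}


def write_nrrd(path: str | Path, array: np.ndarray,
               spacing: tuple[float, ...] | None = None,
               origin: tuple[float, ...] | None = None) -> None:
    """Write an array as ASCII-encoded NRRD0004.

    For 3D data, axis order is (z, y, x) with ``space directions`` rows
    matching; 4D data (e.g. displacement fields, leading component axis)
    gets a ``none`` direction on axis 0.
    """
    array = np.asarray(array)
    if array.dtype == np.uint8:
        dtype_name = "unsigned char"
    elif array.dtype == np.float32:
        dtype_name = "float"
    else:
        array = array.astype(np.float64)
        dtype_name = "double"
    lines = [
        "NRRD0004",
        f"type: {dtype_name}",
        f"dimension: {array.ndim}",
        f"sizes: {' '.join(str(s) for s in array.shape)}",
        "encoding: ascii",
    ]
    if spacing is not None:
        dirs = []
        spatial = len(spacing)
        lead = array.ndim - spatial
        for _ in range(lead):
            dirs.append("none")
        for i, s in enumerate(spacing):
            vec = [0.0] * spatial
            vec[i] = float(s)
            dirs.append("(" + ",".join(repr(v) for v in vec) + ")")
        lines.append(f"space dimension: {spatial}")
        lines.append("space directions: " + " ".join(dirs))
        if origin is not None:
            lines.append("space origin: (" + ",".join(repr(float(o)) for o in origin) + ")")
    header = "\n".join(lines)
    with open(path, "w") as fh:
        fh.write(header + "\n\n")
        flat = array.ravel()
        if dtype_name == "unsigned char":
            fh.write(" ".join(str(int(v)) for v in flat))
        else:
            fh.write(" ".join(repr(float(v)) for v in flat))
        fh.write("\n")


def read_nrrd(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ASCII-encoded NRRD written by :func:`write_nrrd`."""
    text = Path(path).read_text()
    header_text, _, data_text = text.partition("\n\n")
    lines = header_text.splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ValueError(f"{path}: not an NRRD file")
    fields: dict[str, str] = {}
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        fields[key.strip()] = value.strip()
    if fields.get("encoding") != "ascii":
        raise ValueError(f"{path}: only ascii encoding is supported")
    dtype = _TYPE_MAP[fields["type"]]
    shape = tuple(int(s) for s in fields["sizes"].split())
    data = np.array(data_text.split(), dtype=float).astype(dtype).reshape(shape)
    meta: dict = {}
    if "space directions" in fields:
        import re

        spacing = []
        for token in re.findall(r"none|\([^)]*\)", fields["space directions"]):
            if token == "none":
                continue
            vec = [float(v) for v in token.strip("()").split(",")]
            spacing.append(max(abs(v) for v in vec))
        meta["spacing"] = tuple(spacing)
    if "space origin" in fields:
        meta["origin"] = tuple(
            float(v) for v in fields["space origin"].strip("()").split(","))
    return data, meta


def write_grid(path: str | Path, grid: Grid3D) -> None:
    write_nrrd(path, grid.values, spacing=grid.spacing, origin=grid.origin)


def read_grid(path: str | Path) -> Grid3D:
    data, meta = read_nrrd(path)
    return Grid3D(data, spacing=meta.get("spacing", (1.0, 1.0, 1.0)),
                  origin=meta.get("origin", (0.0, 0.0, 0.0)))


def write_mask(path: str | Path, mask: Mask3D) -> None:
    write_nrrd(path, mask.flags.astype(np.uint8), spacing=mask.spacing,
               origin=mask.origin)


def read_mask(path: str | Path, name: str = "",
              role: StructureRole = StructureRole.DERIVED) -> Mask3D:
    data, meta = read_nrrd(path)
    return Mask3D(data > 0, name=name or Path(path).stem, role=role,
                  spacing=meta.get("spacing", (1.0, 1.0, 1.0)),
                  origin=meta.get("origin", (0.0, 0.0, 0.0)))


def write_field(path: str | Path, field: np.ndarray,
                spacing: tuple[float, float, float]) -> None:
    """Displacement field as 4D NRRD (component axis first, mm)."""
    if field.ndim != 4 or field.shape[0] != 3:
        raise ValueError("field must have shape (3, nz, ny, nx)")
    write_nrrd(path, field.astype(np.float32), spacing=spacing)


def read_field(path: str | Path) -> np.ndarray:
    data, _ = read_nrrd(path)
    return np.asarray(data, dtype=float)


def write_sidecar(path: str | Path, prescription_gy: float, fractions: int,
                  roles: dict[str, str], exponents: dict[str, float]) -> None:
    payload = {
        "prescription_Gy": prescription_gy,
        "fractions": fractions,
        "structure_roles": roles,
        "exponent_registry": exponents,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
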