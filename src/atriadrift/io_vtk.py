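"""Readers/writers for on-disk artifacts.

Field snapshots and geometries travel as legacy-VTK structured-points files
(ASCII header + big-endian binary payload by default, pure-ASCII optional),
openable by standard viewers.  Full field states round-trip through a
self-contained compressed npz.  Traces are plain CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import VoxelGeometry
from .errors import AtriaDriftError

__all__ = ["write_structured_points", "read_structured_points",
           "save_geometry", "load_geometry", "save_state", "load_state",
           "write_trace_csv", "read_trace_csv", "write_tips_csv",
           "write_summary_json", "ParseError"]

_VTK_TYPES = {
    "float": (">f4", np.float32),
    "double": (">f8", np.float64),
    "unsigned_char": (">u1", np.uint8),
    "int": (">i4", np.int32),
}
_NP_TO_VTK = {np.dtype(np.float32): "float", np.dtype(np.float64): "double",
              np.dtype(np.uint8): "unsigned_char", np.dtype(np.int32): "int",
              np.dtype(bool): "unsigned_char"}


class ParseError(AtriaDriftError):
    """Malformed file; message includes the byte offset."""


def write_structured_points(path, fields: dict, dx: float,
                            origin=(0.0, 0.0, 0.0), binary: bool = True,
                            title: str = "atriadrift field") -> None:
    """Write one or more 3D scalar fields sharing a grid to a legacy VTK file.

    All fields must have the same (nx, ny, nz) shape; data are stored in
    VTK's x-fastest node order, big-endian when binary.
    """
    names = list(fields)
    arrs = [np.asarray(fields[n]) for n in names]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all fields must share one grid shape")
    nx, ny, nz = shape
    with open(path, "wb") as fh:
        head = (
            "# vtk DataFile Version 3.0\n"
            f"{title}\n"
            f"{'BINARY' if binary else 'ASCII'}\n"
            "DATASET STRUCTURED_POINTS\n"
            f"DIMENSIONS {nx} {ny} {nz}\n"
            f"ORIGIN {origin[0]:.6g} {origin[1]:.6g} {origin[2]:.6g}\n"
            f"SPACING {dx:.6g} {dx:.6g} {dx:.6g}\n"
            f"POINT_DATA {nx * ny * nz}\n"
        )
        fh.write(head.encode())
        for name, arr in zip(names, arrs):
            if arr.dtype == bool:
                arr = arr.astype(np.uint8)
            if arr.dtype not in _NP_TO_VTK:
                arr = arr.astype(np.float32)
            vtk_t = _NP_TO_VTK[arr.dtype]
            fh.write(f"SCALARS {name} {vtk_t} 1\nLOOKUP_TABLE default\n".encode())
            flat = arr.ravel(order="F")       # x varies fastest in VTK
            if binary:
                fh.write(flat.astype(_VTK_TYPES[vtk_t][0]).tobytes())
                fh.write(b"\n")
            else:
                np.savetxt(fh, flat[None] if flat.ndim == 1 else flat,
                           fmt="%.9g", delimiter=" ")


def read_structured_points(path):
    """Read a legacy VTK structured-points file written by this package.

    Returns (fields: dict[str, 3D array], dx, origin).
    """
    raw = Path(path).read_bytes()
    pos = 0

    def next_line():
        nonlocal pos
        end = raw.find(b"\n", pos)
        if end < 0:
            raise ParseError(f"unexpected end of file at byte {pos}")
        line = raw[pos:end].decode("latin1").strip()
        pos = end + 1
        return line

    magic = next_line()
    if not magic.startswith("# vtk DataFile"):
        raise ParseError(f"not a VTK file (byte 0): {magic[:40]!r}")
    next_line()                                   # title
    mode = next_line().upper()
    if mode not in ("BINARY", "ASCII"):
        raise ParseError(f"unknown data mode {mode!r} at byte {pos}")
    if next_line() != "DATASET STRUCTURED_POINTS":
        raise ParseError(f"not STRUCTURED_POINTS at byte {pos}")
    dims = org = spc = None
    npts = None
    while npts is None:
        line = next_line()
        if line.startswith("DIMENSIONS"):
            dims = tuple(int(v) for v in line.split()[1:4])
        elif line.startswith("ORIGIN"):
            org = tuple(float(v) for v in line.split()[1:4])
        elif line.startswith("SPACING"):
            spc = tuple(float(v) for v in line.split()[1:4])
        elif line.startswith("POINT_DATA"):
            npts = int(line.split()[1])
    if dims is None or org is None or spc is None:
        raise ParseError(f"incomplete structured-points header (byte {pos})")
    nx, ny, nz = dims
    if npts != nx * ny * nz:
        raise ParseError(f"POINT_DATA {npts} != DIMENSIONS product (byte {pos})")
    fields = {}
    while pos < len(raw):
        if not raw[pos:].strip():
            break
        line = next_line()
        if not line:
            continue
        if not line.startswith("SCALARS"):
            raise ParseError(f"expected SCALARS at byte {pos}: {line[:40]!r}")
        _, name, vtk_t = line.split()[:3]
        if vtk_t not in _VTK_TYPES:
            raise ParseError(f"unsupported type {vtk_t!r} at byte {pos}")
        lut = next_line()
        if not lut.startswith("LOOKUP_TABLE"):
            raise ParseError(f"expected LOOKUP_TABLE at byte {pos}")
        dt, _ = _VTK_TYPES[vtk_t]
        if mode == "BINARY":
            nbytes = npts * np.dtype(dt).itemsize
            chunk = raw[pos : pos + nbytes]
            if len(chunk) < nbytes:
                raise ParseError(
                    f"truncated data for {name!r}: need {nbytes} bytes at "
                    f"byte {pos}, have {len(chunk)}"
                )
            flat = np.frombuffer(chunk, dtype=dt)
            pos += nbytes
            if pos < len(raw) and raw[pos : pos + 1] == b"\n":
                pos += 1
        else:
            vals = []
            while len(vals) < npts:
                if pos >= len(raw):
                    raise ParseError(
                        f"truncated ASCII data for {name!r} at byte {pos}"
                    )
                vals.extend(float(v) for v in next_line().split())
            flat = np.asarray(vals[:npts], dtype=np.dtype(dt).newbyteorder("="))
        arr = flat.astype(flat.dtype.newbyteorder("=")).reshape(
            (nx, ny, nz), order="F")
        fields[name] = arr
    return fields, float(spc[0]), org


def save_geometry(path, geom: VoxelGeometry, binary: bool = True) -> None:
    """Geometry as a VTK file (tissue/labels/epi scalars) + JSON sidecar."""
    write_structured_points(
        path,
        {"tissue": geom.mask.astype(np.uint8),
         "labels": geom.labels, "epi": geom.epi.astype(np.uint8)},
        dx=geom.dx, origin=geom.origin, binary=binary,
        title=f"atriadrift geometry {geom.name}",
    )
    side = Path(str(path) + ".json")
    side.write_text(json.dumps(
        {"name": geom.name, "meta": _jsonable(geom.meta)}, indent=1))


def load_geometry(path) -> VoxelGeometry:
    fields, dx, origin = read_structured_points(path)
    for key in ("tissue", "labels", "epi"):
        if key not in fields:
            raise ParseError(f"geometry file missing {key!r} field")
    name, meta = "custom", {}
    side = Path(str(path) + ".json")
    if side.exists():
        doc = json.loads(side.read_text())
        name, meta = doc.get("name", name), doc.get("meta", meta)
    return VoxelGeometry(mask=fields["tissue"].astype(bool), dx=dx,
                         origin=tuple(origin),
                         labels=fields["labels"].astype(np.uint8),
                         epi=fields["epi"].astype(bool), name=name, meta=meta)


def save_state(path, fs) -> None:
    """Self-contained field-state file (npz: geometry + full state + clock)."""
    g = fs.geom
    np.savez_compressed(
        path, S=fs.S, t=fs.t, mask=g.mask, labels=g.labels, epi=g.epi,
        dx=g.dx, origin=np.asarray(g.origin), name=np.asarray(g.name))


def load_state(path):
    from .tissue_solver import FieldState

    with np.load(path, allow_pickle=False) as z:
        geom = VoxelGeometry(mask=z["mask"], dx=float(z["dx"]),
                             origin=tuple(z["origin"]),
                             labels=z["labels"], epi=z["epi"],
                             name=str(z["name"]))
        return FieldState(geom, S=z["S"], t=float(z["t"]))


def write_trace_csv(path, t_ms, V_mV) -> None:
    pd.DataFrame({"t_ms": t_ms, "V_mV": V_mV}).to_csv(path, index=False)


def read_trace_csv(path):
    df = pd.read_csv(path)
    return df["t_ms"].to_numpy(), df["V_mV"].to_numpy()


def write_tips_csv(path, trace) -> None:
    """Raw tips plus (when available) the rotation-window index."""
    n = trace.t.size
    win = np.full(n, -1)
    if np.isfinite(trace.period) and n > 1:
        dt_sample = float(np.median(np.diff(trace.t)))
        w = max(1, int(round(trace.period / dt_sample)))
        win = np.arange(n) // w
    pd.DataFrame({
        "t_ms": trace.t, "x_mm": trace.xyz[:, 0], "y_mm": trace.xyz[:, 1],
        "z_mm": trace.xyz[:, 2], "window_index": win,
    }).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_summary_json(path, summary: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(summary), indent=1))
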