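"""VTK legacy ASCII unstructured-grid serialization of geometries.

Cell data arrays ``region_label`` (int), ``segment_id`` (int) and
``fiber_angle`` (float) are written alongside ``element_volume``; numeric
metadata entries travel in the dataset FIELD block so that a write/read
round trip reproduces the geometry bit-exactly for integer fields.
Unknown cell-data arrays found on read are preserved in
``VentricleGeometry.extra_cell_data`` with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

from .geometry import VentricleGeometry

__all__ = ["write_geometry", "read_geometry", "VTKParseError"]

_CELL_TYPE = {4: 9, 8: 12}  # quad, hexahedron
_CORE_ARRAYS = ("region_label", "segment_id", "fiber_angle",
                "element_volume")


class VTKParseError(ValueError):
    """Malformed VTK legacy file; message carries the offending line."""


def _fmt(x: float) -> str:
    return format(float(x), ".9g")


def write_geometry(geom: VentricleGeometry, path) -> None:
    """Serialize a geometry as a VTK legacy ASCII unstructured grid."""
    n_nodes = geom.nodes.shape[0]
    n_elem = geom.elements.shape[0]
    npe = geom.elements.shape[1]
    lines = ["# vtk DataFile Version 3.0",
             "reentryforge ventricular geometry",
             "ASCII",
             "DATASET UNSTRUCTURED_GRID"]

    meta_items = [("spacing", geom.spacing)]
    if geom.shape is not None:
        meta_items.append(("grid_shape", geom.shape))
    for k in sorted(geom.metadata):
        meta_items.append((f"meta_{k}", geom.metadata[k]))
    lines.append(f"FIELD FieldData {len(meta_items)}")
    for name, val in meta_items:
        arr = np.atleast_1d(np.asarray(val, dtype=float))
        lines.append(f"{name} 1 {arr.size} double")
        lines.append(" ".join(_fmt(v) for v in arr))

    lines.append(f"POINTS {n_nodes} double")
    pts = geom.nodes if geom.nodes.shape[1] == 3 else np.column_stack(
        [geom.nodes, np.zeros(n_nodes)])
    for p in pts:
        lines.append(" ".join(_fmt(v) for v in p))

    lines.append(f"CELLS {n_elem} {n_elem * (npe + 1)}")
    for e in geom.elements:
        lines.append(f"{npe} " + " ".join(str(v) for v in e))
    lines.append(f"CELL_TYPES {n_elem}")
    ct = _CELL_TYPE[npe]
    lines.extend([str(ct)] * n_elem)

    lines.append(f"CELL_DATA {n_elem}")
    extra = {k: v for k, v in geom.extra_cell_data.items()}
    for name in _CORE_ARRAYS:
        arr = getattr(geom, name)
        if np.issubdtype(arr.dtype, np.integer):
            lines.append(f"SCALARS {name} int 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(str(int(v)) for v in arr)
        else:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(_fmt(v) for v in arr)
    for name, arr in extra.items():
        arr = np.asarray(arr)
        if np.issubdtype(arr.dtype, np.integer):
            lines.append(f"SCALARS {name} int 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(str(int(v)) for v in arr)
        else:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(_fmt(v) for v in arr)

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


class _Reader:
    def __init__(self, path):
        with open(path) as fh:
            self.lines = fh.read().splitlines()
        self.pos = 0
        self.path = str(path)

    def next_line(self, context="") -> str:
        while self.pos < len(self.lines):
            line = self.lines[self.pos]
            self.pos += 1
            if line.strip():
                return line
        raise VTKParseError(
            f"{self.path}: unexpected end of file at line {self.pos}"
            + (f" while reading {context}" if context else ""))

    def read_numbers(self, count, dtype, context):
        vals = []
        while len(vals) < count:
            line = self.next_line(context)
            try:
                vals.extend(dtype(t) for t in line.split())
            except ValueError as exc:
                raise VTKParseError(
                    f"{self.path}:{self.pos}: bad token in {context}: "
                    f"{line!r}") from exc
        if len(vals) != count:
            raise VTKParseError(
                f"{self.path}:{self.pos}: expected {count} values for "
                f"{context}, got {len(vals)}")
        return np.array(vals)


def read_geometry(path) -> VentricleGeometry:
    """Read a geometry written by :func:`write_geometry`.

    Raises :class:`VTKParseError` with line context on malformed input;
    warns about (and preserves) unrecognized cell-data arrays.
    """
    r = _Reader(path)
    for expected in ("# vtk", None, "ASCII", "DATASET UNSTRUCTURED_GRID"):
        line = r.next_line("header")
        if expected and not line.startswith(expected):
            raise VTKParseError(
                f"{r.path}:{r.pos}: expected {expected!r}, got {line!r}")

    spacing = None
    shape = None
    metadata = {}
    nodes = elements = None
    cell_arrays = {}
    n_elem = None

    while r.pos < len(r.lines):
        try:
            line = r.next_line()
        except VTKParseError:
            break
        tok = line.split()
        key = tok[0].upper()
        if key == "FIELD":
            n_arrays = int(tok[2])
            for _ in range(n_arrays):
                hdr = r.next_line("field array header").split()
                name, ncomp, ntup = hdr[0], int(hdr[1]), int(hdr[2])
                vals = r.read_numbers(ncomp * ntup, float, f"field {name}")
                if name == "spacing":
                    spacing = float(vals[0])
                elif name == "grid_shape":
                    shape = tuple(int(v) for v in vals)
                elif name.startswith("meta_"):
                    k = name[5:]
                    v = vals[0] if vals.size == 1 else tuple(vals)
                    if isinstance(v, float) and v == int(v):
                        v = int(v)
                    metadata[k] = v
        elif key == "POINTS":
            n_pts = int(tok[1])
            nodes = r.read_numbers(3 * n_pts, float, "points").reshape(-1, 3)
        elif key == "CELLS":
            nc = int(tok[1])
            total = int(tok[2])
            raw = r.read_numbers(total, int, "cells")
            npe = int(raw[0])
            elements = raw.reshape(nc, npe + 1)[:, 1:].astype(np.int64)
        elif key == "CELL_TYPES":
            nc = int(tok[1])
            r.read_numbers(nc, int, "cell types")
        elif key == "CELL_DATA":
            n_elem = int(tok[1])
        elif key == "SCALARS":
            name, vtype = tok[1], tok[2]
            lut = r.next_line("lookup table")
            if not lut.upper().startswith("LOOKUP_TABLE"):
                raise VTKParseError(
                    f"{r.path}:{r.pos}: expected LOOKUP_TABLE after "
                    f"SCALARS {name}, got {lut!r}")
            if n_elem is None:
                raise VTKParseError(
                    f"{r.path}:{r.pos}: SCALARS before CELL_DATA")
            dtype = int if vtype in ("int", "long") else float
            cell_arrays[name] = r.read_numbers(n_elem, dtype,
                                               f"scalars {name}")
        else:
            raise VTKParseError(
                f"{r.path}:{r.pos}: unrecognized section {line!r}")

    for req, what in ((nodes, "POINTS"), (elements, "CELLS"),
                      (spacing, "FIELD spacing"), (n_elem, "CELL_DATA")):
        if req is None:
            raise VTKParseError(f"{r.path}: missing {what} section")
    for name in _CORE_ARRAYS:
        if name not in cell_arrays:
            raise VTKParseError(f"{r.path}: missing cell array {name!r}")

    extra = {}
    for name in list(cell_arrays):
        if name not in _CORE_ARRAYS:
            warnings.warn(f"unknown cell-data array {name!r} preserved "
                          f"in extra_cell_data", stacklevel=2)
            extra[name] = cell_arrays[name]

    is_2d = elements.shape[1] == 4
    if is_2d:
        nodes = nodes[:, :2]

    # Element centres from connectivity (uniform elements).
    centers = nodes[elements].mean(axis=1)

    geom = VentricleGeometry(
        nodes=nodes,
        elements=elements,
        spacing=spacing,
        region_label=cell_arrays["region_label"].astype(np.int64),
        fiber_angle=cell_arrays["fiber_angle"].astype(float),
        segment_id=cell_arrays["segment_id"].astype(np.int64),
        element_volume=cell_arrays["element_volume"].astype(float),
        centers=centers,
        shape=shape,
        metadata=metadata,
        extra_cell_data=extra,
    )
    return geom
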