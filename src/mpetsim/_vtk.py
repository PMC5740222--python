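"""Minimal legacy-VTK (ASCII DataFile 3.0) unstructured-grid reader/writer.

Only the subset needed here: POINTS, CELLS/CELL_TYPES, POINT_DATA and
CELL_DATA with SCALARS / VECTORS / FIELD arrays of float64 or int32.
"""

from __future__ import annotations

import numpy as np

VTK_TRIANGLE = 5
VTK_TETRA = 10


def write_vtk(path, nodes, cells, cell_types, point_data=None, cell_data=None,
              title="mpetsim output"):
    """Write one unstructured grid.

    cells: list of index arrays (ragged); cell_types: matching VTK type ids.
    Data arrays of shape (n,) are written as SCALARS, (n, 3) as VECTORS.
    """
    nodes = np.asarray(nodes, dtype=float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title[:255] + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for x, y, z in nodes:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        total = sum(len(c) + 1 for c in cells)
        fh.write(f"CELLS {len(cells)} {total}\n")
        for c in cells:
            fh.write(str(len(c)) + " " + " ".join(map(str, c)) + "\n")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        for ct in cell_types:
            fh.write(f"{ct}\n")
        for kind, data in (("POINT_DATA", point_data), ("CELL_DATA", cell_data)):
            if not data:
                continue
            n = len(nodes) if kind == "POINT_DATA" else len(cells)
            fh.write(f"{kind} {n}\n")
            for name, arr in data.items():
                arr = np.asarray(arr)
                if arr.shape[0] != n:
                    raise ValueError(
                        f"{kind} array {name!r} has length {arr.shape[0]}, "
                        f"expected {n}")
                is_int = np.issubdtype(arr.dtype, np.integer)
                vtype = "int" if is_int else "double"
                fmt = (lambda v: str(int(v))) if is_int else \
                      (lambda v: f"{v:.17g}")
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} {vtype} 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        fh.write(fmt(v) + "\n")
                elif arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} {vtype}\n")
                    for row in arr:
                        fh.write(" ".join(fmt(v) for v in row) + "\n")
                else:
                    raise ValueError(f"unsupported array shape {arr.shape} "
                                     f"for {name!r}")


def _tokens(fh):
    for line in fh:
        yield from line.split()


def read_vtk(path):
    """Read an unstructured grid written by :func:`write_vtk`.

    Returns dict with nodes, cells (list of arrays), cell_types,
    point_data, cell_data.
    """
    with open(path) as fh:
        header = [fh.readline() for _ in range(4)]
        if "UNSTRUCTURED_GRID" not in header[3]:
            raise ValueError(f"{path}: not an unstructured grid VTK file")
        tok = _tokens(fh)
        out = {"point_data": {}, "cell_data": {}}
        active = None   # which data block we are in
        try:
            while True:
                word = next(tok, None)
                if word is None:
                    break
                if word == "POINTS":
                    n = int(next(tok)); next(tok)
                    pts = np.fromiter((float(next(tok)) for _ in range(3 * n)),
                                      dtype=float, count=3 * n)
                    out["nodes"] = pts.reshape(n, 3)
                elif word == "CELLS":
                    nc = int(next(tok)); ntot = int(next(tok))
                    raw = np.fromiter((int(next(tok)) for _ in range(ntot)),
                                      dtype=np.int64, count=ntot)
                    cells, i = [], 0
                    for _ in range(nc):
                        ln = raw[i]
                        cells.append(raw[i + 1:i + 1 + ln].copy())
                        i += 1 + ln
                    out["cells"] = cells
                elif word == "CELL_TYPES":
                    nc = int(next(tok))
                    out["cell_types"] = np.fromiter(
                        (int(next(tok)) for _ in range(nc)),
                        dtype=np.int64, count=nc)
                elif word == "POINT_DATA":
                    active = ("point_data", int(next(tok)))
                elif word == "CELL_DATA":
                    active = ("cell_data", int(next(tok)))
                elif word in ("SCALARS", "VECTORS"):
                    name = next(tok)
                    vtype = next(tok)
                    ncomp = 1
                    if word == "SCALARS":
                        ncomp = int(next(tok))
                        next(tok); next(tok)   # LOOKUP_TABLE default
                    else:
                        ncomp = 3
                    block, n = active
                    count = n * ncomp
                    conv = int if vtype.startswith("int") else float
                    dt = np.int64 if vtype.startswith("int") else float
                    arr = np.fromiter((conv(next(tok)) for _ in range(count)),
                                      dtype=dt, count=count)
                    out[block][name] = arr.reshape(n, ncomp) if ncomp > 1 \
                        else arr
                # anything else: skip token
        except StopIteration as exc:
            raise ValueError(f"{path}: truncated VTK file") from exc
    return out
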