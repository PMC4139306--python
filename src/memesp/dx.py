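"""OpenDX regular-grid scalar export/import (interoperability with APBS,
PIPSA, VMD and friends).

OpenDX stores the data array with the last grid index (z) varying fastest,
i.e. C order for our ``values[ix, iy, iz]`` arrays.
"""

from __future__ import annotations

import io

import numpy as np

from .grid import GridError, GridSpec, PotentialGrid


def write_dx_grid(grid: PotentialGrid, target=None) -> str | None:
    """Write an OpenDX scalar field; returns the text when ``target`` is None."""
    if not np.all(np.isfinite(grid.values)):
        bad = np.argwhere(~np.isfinite(grid.values))[0]
        raise GridError(
            f"refusing to write non-finite value at voxel {tuple(int(i) for i in bad)}"
        )
    if isinstance(target, str):
        with open(target, "w") as fh:
            write_dx_grid(grid, fh)
        return None
    fh = target if target is not None else io.StringIO()
    nx, ny, nz = grid.dims
    h = grid.spacing
    ox, oy, oz = grid.origin
    fh.write(f"# {grid.label}\n" if grid.label else "# memesp potential grid\n")
    fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
    fh.write(f"origin {ox:.10g} {oy:.10g} {oz:.10g}\n")
    fh.write(f"delta {h:.10g} 0 0\n")
    fh.write(f"delta 0 {h:.10g} 0\n")
    fh.write(f"delta 0 0 {h:.10g}\n")
    fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
    fh.write(
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
    )
    flat = np.asarray(grid.values, dtype=float).ravel(order="C")
    for start in range(0, flat.size, 3):
        fh.write(" ".join(f"{v:.9e}" for v in flat[start:start + 3]) + "\n")
    fh.write('attribute "dep" string "positions"\n')
    fh.write('object "regular positions regular connections" class field\n')
    fh.write('component "positions" value 1\n')
    fh.write('component "connections" value 2\n')
    fh.write('component "data" value 3\n')
    if target is None:
        return fh.getvalue()
    return None


def read_dx_grid(source) -> PotentialGrid:
    """Read an OpenDX regular scalar grid (uniform axis-aligned deltas only)."""
    if isinstance(source, str):
        with open(source) as fh:
            return read_dx_grid(fh)
    dims = None
    origin = None
    deltas: list[list[float]] = []
    nitems = None
    values: list[float] = []
    label = ""
    in_data = False
    for line in source:
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if not label:
                label = s.lstrip("# ").strip()
            continue
        if in_data:
            if s.startswith(("attribute", "object", "component")):
                in_data = False
                continue
            values.extend(float(t) for t in s.split())
            if nitems is not None and len(values) >= nitems:
                in_data = False
            continue
        if s.startswith("object") and "gridpositions" in s:
            dims = tuple(int(t) for t in s.split()[-3:])
        elif s.startswith("origin"):
            origin = tuple(float(t) for t in s.split()[1:4])
        elif s.startswith("delta"):
            deltas.append([float(t) for t in s.split()[1:4]])
        elif s.startswith("object") and "data follows" in s:
            nitems = int(s.split("items")[1].split()[0])
            in_data = True
    if dims is None or origin is None or len(deltas) != 3:
        raise GridError("not a regular OpenDX scalar grid (missing header objects)")
    d = np.asarray(deltas)
    diag = np.diag(d)
    if not np.allclose(d, np.diag(diag)) or not np.allclose(diag, diag[0]):
        raise GridError("only uniform axis-aligned grids are supported")
    if nitems is None or len(values) != int(np.prod(dims)):
        raise GridError(
            f"payload has {len(values)} values, header promises {np.prod(dims)}"
        )
    spec = GridSpec(dims=dims, spacing=float(diag[0]), origin=origin)
    arr = np.asarray(values, dtype=float).reshape(dims, order="C")
    return PotentialGrid(spec=spec, values=arr, label=label)
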