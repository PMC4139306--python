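"""UHBD potential-grid files, binary and ASCII dialects.

Binary layout (the historical FORTRAN unformatted convention; see
docs/formats.md):

* every record is framed by 4-byte little-endian length sentinels;
* record 1: 72-byte space-padded title;
* record 2: 22 little-endian 4-byte fields —
  ``scale, dum2 : f4``, ``grdflg, idum2 : i4``,
  ``km1, one, km2, im, jm, km : i4``,
  ``h, ox, oy, oz : f4``, ``dum3..dum8 : f4``, ``idum3, idum4 : i4``;
* then for each z-plane k = 1..km: a record ``(k, im, jm) : i4`` followed by
  a record of ``im*jm`` float32 values, x fastest then y.

``(ox, oy, oz)`` follow the UHBD convention that grid point (1,1,1) lies at
``(ox+h, oy+h, oz+h)``; our 0-based origin is therefore ``ox + h`` etc.

The ASCII dialect carries the same record content in text form; values are
written with 9 significant digits so float32 payloads round-trip exactly.
"""

from __future__ import annotations

import io
import struct
from typing import BinaryIO, Union

import numpy as np

from .grid import GridError, GridSpec, PotentialGrid

_HEADER_FMT = "<2f2i6i4f6f2i"
_HEADER_SIZE = struct.calcsize(_HEADER_FMT)  # 88 bytes
_TITLE_LEN = 72


class UHBDParseError(GridError):
    """Malformed or truncated UHBD stream."""


def _read_record(fh: BinaryIO, expect: int | None = None) -> bytes:
    start = fh.tell()
    head = fh.read(4)
    if len(head) < 4:
        raise UHBDParseError(f"truncated stream: record length expected at byte {start}")
    (n,) = struct.unpack("<i", head)
    if n < 0 or (expect is not None and n != expect):
        raise UHBDParseError(
            f"integrity error at byte {start}: record length {n}"
            + (f" != expected {expect}" if expect is not None else "")
        )
    payload = fh.read(n)
    if len(payload) < n:
        raise UHBDParseError(
            f"truncated stream: {n}-byte record at byte {start + 4} has only {len(payload)} bytes"
        )
    tail = fh.read(4)
    if len(tail) < 4 or struct.unpack("<i", tail)[0] != n:
        raise UHBDParseError(f"integrity error: trailing sentinel mismatch at byte {fh.tell() - len(tail)}")
    return payload


def _write_record(fh: BinaryIO, payload: bytes) -> None:
    sentinel = struct.pack("<i", len(payload))
    fh.write(sentinel)
    fh.write(payload)
    fh.write(sentinel)


def _check_finite(grid: PotentialGrid) -> None:
    if not np.all(np.isfinite(grid.values)):
        bad = np.argwhere(~np.isfinite(grid.values))[0]
        raise GridError(
            f"refusing to write non-finite value at voxel {tuple(int(i) for i in bad)}"
        )


def write_uhbd_binary(grid: PotentialGrid, fh: BinaryIO) -> None:
    _check_finite(grid)
    im, jm, km = grid.dims
    h = grid.spacing
    ox, oy, oz = (o - h for o in grid.origin)
    title = grid.label[:_TITLE_LEN].ljust(_TITLE_LEN).encode("ascii", "replace")
    _write_record(fh, title)
    header = struct.pack(
        _HEADER_FMT,
        1.0, 0.0,            # scale, dum2
        1, 0,                # grdflg, idum2
        km, 1, km,           # km1, one, km2
        im, jm, km,          # im, jm, km
        h, ox, oy, oz,       # spacing and UHBD-convention origin
        0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
        0, 0,
    )
    _write_record(fh, header)
    vals = np.asarray(grid.values, dtype="<f4")
    for k in range(km):
        _write_record(fh, struct.pack("<3i", k + 1, im, jm))
        # plane stored x fastest then y: Fortran ravel of values[:, :, k]
        _write_record(fh, vals[:, :, k].tobytes(order="F"))


def read_uhbd_binary(fh: BinaryIO, tolerant: bool = True) -> PotentialGrid:
    title = _read_record(fh, expect=_TITLE_LEN).decode("ascii", "replace").rstrip()
    header = _read_record(fh, expect=_HEADER_SIZE)
    fields = struct.unpack(_HEADER_FMT, header)
    im, jm, km = fields[7], fields[8], fields[9]
    h, ox, oy, oz = fields[10:14]
    if im < 2 or jm < 2 or km < 2 or h <= 0:
        raise UHBDParseError(f"integrity error: implausible header dims ({im},{jm},{km}) spacing {h}")
    values = np.empty((im, jm, km), dtype=np.float32)
    for k in range(km):
        plane_hdr = _read_record(fh, expect=12)
        kk, pim, pjm = struct.unpack("<3i", plane_hdr)
        if (pim, pjm) != (im, jm):
            raise UHBDParseError(
                f"integrity error: plane {kk} declares {pim}x{pjm}, header says {im}x{jm}"
            )
        payload = _read_record(fh, expect=4 * im * jm)
        values[:, :, k] = np.frombuffer(payload, dtype="<f4").reshape((im, jm), order="F")
    if not tolerant:
        extra = fh.read(1)
        if extra:
            raise UHBDParseError(f"unexpected trailing data at byte {fh.tell() - 1}")
    spec = GridSpec(dims=(im, jm, km), spacing=float(h),
                    origin=(float(ox) + float(h), float(oy) + float(h), float(oz) + float(h)))
    return PotentialGrid(spec=spec, values=values, label=title)


def write_uhbd_ascii(grid: PotentialGrid, fh) -> None:
    _check_finite(grid)
    im, jm, km = grid.dims
    h = grid.spacing
    ox, oy, oz = (o - h for o in grid.origin)
    fh.write(grid.label[:_TITLE_LEN].ljust(_TITLE_LEN) + "\n")
    fh.write(f"{1.0:.8e} {0.0:.8e} {1} {0} {km} {1} {km}\n")
    fh.write(f"{im} {jm} {km} {h:.8e} {ox:.8e} {oy:.8e} {oz:.8e}\n")
    fh.write(f"{0.0:.8e} {0.0:.8e} {0.0:.8e} {0.0:.8e} {0.0:.8e} {0.0:.8e} {0} {0}\n")
    vals = np.asarray(grid.values, dtype=np.float32)
    for k in range(km):
        fh.write(f"{k + 1} {im} {jm}\n")
        plane = vals[:, :, k].ravel(order="F")
        for start in range(0, plane.size, 6):
            fh.write(" ".join(f"{v:.8e}" for v in plane[start:start + 6]) + "\n")


def read_uhbd_ascii(fh) -> PotentialGrid:
    title = fh.readline()
    if not title:
        raise UHBDParseError("truncated stream: missing title line at byte 0")
    title = title.rstrip("\n").rstrip()
    try:
        line2 = fh.readline().split()
        line3 = fh.readline().split()
        fh.readline()  # dummy line
        im, jm, km = int(line3[0]), int(line3[1]), int(line3[2])
        h, ox, oy, oz = (float(x) for x in line3[3:7])
    except (IndexError, ValueError) as exc:
        raise UHBDParseError(f"integrity error: malformed ASCII header ({exc})") from exc
    if im < 2 or jm < 2 or km < 2 or h <= 0:
        raise UHBDParseError(f"integrity error: implausible header dims ({im},{jm},{km}) spacing {h}")
    values = np.empty((im, jm, km), dtype=np.float32)
    for k in range(km):
        hdr = fh.readline().split()
        if len(hdr) != 3:
            raise UHBDParseError(f"truncated stream: missing plane header for k={k + 1}")
        if (int(hdr[1]), int(hdr[2])) != (im, jm):
            raise UHBDParseError(
                f"integrity error: plane {hdr[0]} declares {hdr[1]}x{hdr[2]}, header says {im}x{jm}"
            )
        need = im * jm
        buf: list[float] = []
        while len(buf) < need:
            line = fh.readline()
            if not line:
                raise UHBDParseError(
                    f"truncated stream: plane k={k + 1} has {len(buf)} of {need} values"
                )
            buf.extend(np.float32(tok) for tok in line.split())
        if len(buf) != need:
            raise UHBDParseError(
                f"integrity error: plane k={k + 1} has {len(buf)} values, expected {need}"
            )
        values[:, :, k] = np.asarray(buf, dtype=np.float32).reshape((im, jm), order="F")
    spec = GridSpec(dims=(im, jm, km), spacing=h, origin=(ox + h, oy + h, oz + h))
    return PotentialGrid(spec=spec, values=values, label=title)


def read_uhbd_grid(source: Union[str, bytes, BinaryIO, io.TextIOBase],
                   dialect: str = "auto") -> PotentialGrid:
    """Read a UHBD grid from a path, bytes, or open stream.

    ``dialect`` is one of ``binary``, ``ascii`` or ``auto`` (sniffed from the
    first record-length sentinel).
    """
    if isinstance(source, (str, bytes)) and not isinstance(source, bytes):
        with open(source, "rb") as fh:
            return read_uhbd_grid(fh, dialect=dialect)
    if isinstance(source, bytes):
        return read_uhbd_grid(io.BytesIO(source), dialect=dialect)
    if isinstance(source, io.TextIOBase):
        if dialect == "binary":
            raise UHBDParseError("binary dialect requires a byte stream")
        return read_uhbd_ascii(source)
    if dialect == "auto":
        pos = source.tell()
        head = source.read(4)
        source.seek(pos)
        dialect = (
            "binary"
            if len(head) == 4 and struct.unpack("<i", head)[0] == _TITLE_LEN
            else "ascii"
        )
    if dialect == "binary":
        return read_uhbd_binary(source)
    if dialect == "ascii":
        return read_uhbd_ascii(io.TextIOWrapper(source, encoding="ascii"))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_uhbd_grid(grid: PotentialGrid, target, dialect: str = "binary") -> None:
    """Write a grid to a path or open stream in the chosen dialect."""
    if isinstance(target, str):
        mode = "wb" if dialect == "binary" else "w"
        with open(target, mode) as fh:
            write_uhbd_grid(grid, fh, dialect=dialect)
        return
    if dialect == "binary":
        write_uhbd_binary(grid, target)
    elif dialect == "ascii":
        write_uhbd_ascii(grid, target)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
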