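# Grid file formats

`memesp` reads and writes electrostatic potential grids in two formats:
the UHBD grid format (binary and ASCII dialects, extension `.grd` by
convention) and OpenDX scalar fields (`.dx`).  All potentials are in
kcal/mol/e; all lengths are in Ångström.  Grids are cubic-voxel
(single spacing `h` on all three axes) and axis-aligned.

## UHBD binary dialect

The binary dialect follows the historical FORTRAN "unformatted
sequential" convention: the file is a sequence of records, each framed
by a 4-byte little-endian integer sentinel holding the record's byte
length, repeated after the payload.  All numeric fields are 4-byte
little-endian.

| record | payload | content |
|---|---|---|
| 1 | 72 bytes | title, space-padded ASCII |
| 2 | 88 bytes | header, `struct` layout `<2f 2i 6i 4f 6f 2i` |
| 3, 5, 7, … | 12 bytes | plane header `(k, im, jm)` as 3 × int32, `k` is 1-based |
| 4, 6, 8, … | `4*im*jm` bytes | plane `k` values, float32, x fastest then y |

Header fields, in order:

```
scale  dum2            : float32   (written 1.0, 0.0; scale is ignored on read)
grdflg idum2           : int32     (written 1, 0)
km1 one km2 im jm km   : int32     (km1=km2=km, one=1; im, jm, km are the dims)
h  ox  oy  oz          : float32   (spacing and grid corner, see below)
dum3 … dum8            : float32   (written 0)
idum3 idum4            : int32     (written 0)
```

`(ox, oy, oz)` follow the UHBD convention that grid point `(1,1,1)` sits
at `(ox+h, oy+h, oz+h)`.  The package's 0-based origin — the coordinate
of voxel `(0,0,0)` — is therefore `ox + h` per axis.

Values are stored one z-plane per record pair; within a plane, x varies
fastest, then y (Fortran order of `values[:, :, k]`).  The reader
verifies every sentinel, the plane headers against the file header, and
reports the byte offset of the first inconsistency.  Trailing bytes
after the last plane are tolerated by default (`tolerant=True`).

## UHBD ASCII dialect

The ASCII dialect carries the same record content in text form: title
line, header lines, then per-plane `(k, im, jm)` line followed by the
plane's values, six per line.  Floats are written with 9 significant
digits (`%.8e`) so that float32 payloads round-trip bit-exactly through
text.  `read_uhbd_grid` auto-detects the dialect (a binary file starts
with the sentinel value 72).

## OpenDX

`write_dx_grid`/`read_dx_grid` handle the "regularly gridded scalar"
subset of OpenDX: `gridpositions`/`gridconnections` objects with an
axis-aligned diagonal delta matrix, and the data array in C order (z
fastest).  Origins and deltas are written with `%.10g`.  The reader
rejects non-uniform or rotated axes and checks the payload count
against the declared shape.  Files written by this package are readable
by the `gridData` package and by common visualization tools.

## Conversion

```
memesp grid convert --in snapshot.grd --out snapshot.dx --out-format dx
memesp grid info snapshot.grd
```

Converting UHBD → DX → UHBD preserves values exactly (both store
float32-representable payloads; DX text carries enough digits).
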