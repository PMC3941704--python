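"""Readers and writers for connexel-visualization file formats.

Formats handled here:

``.cxls``
    Plain text, one connexel per line as seven whitespace-separated values
    ``px py pz qx qy qz c``.
``.asc``
    FreeSurfer ASCII surfaces: optional ``#!ascii`` comment line, a header
    line ``N M``, then N vertex lines ``x y z v`` and M face lines
    ``i j k v`` (0-based indices).
``.vtk`` / ``.fib``
    Legacy VTK POLYDATA line sets. Two-point lines are connexels
    (tractography-style ``.fib`` files), longer records are bundled
    polylines. ASCII and binary (big-endian float32, per the legacy VTK
    convention) are both read; writing defaults to ASCII for diffability.
``matrix binary``
    Raw square symmetric connectivity matrix: row-major float32,
    little-endian, no header. NOTE: the on-disk dialect (precision,
    endianness, order) is this package's declared convention; files from
    other tools may differ and should be converted.
``.glyphset`` / ``.set``
    Glyphset descriptor: line 1 = set-file path, line 2 = matrix path,
    line 3 = load-time minimum threshold; ``#`` comments ignored. The set
    file lists one surface path per line, optionally followed by a 3-vector
    translation offset in mm (e.g. to separate the hemispheres).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import ConnectivityMatrix, ConnexelSet, SurfaceMesh, SurfaceSet

__all__ = [
    "GlyphsetDescriptor",
    "SetFile",
    "read_cxls",
    "write_cxls",
    "read_surface_asc",
    "write_surface_asc",
    "read_vtk_polydata",
    "write_vtk_polydata",
    "read_matrix_binary",
    "write_matrix_binary",
    "read_glyphset",
    "read_set_file",
]


class FormatError(ValueError):
    """Raised when a file does not follow its declared layout."""


@dataclass
class GlyphsetDescriptor:
    set_file_path: Path
    matrix_file_path: Path
    load_min_threshold: float


@dataclass
class SetFile:
    """Ordered (surface path, offset mm) entries; offset None means zero."""
    entries: list  # of (Path, np.ndarray | None)


# ---------------------------------------------------------------------------
# .cxls
# ---------------------------------------------------------------------------

def read_cxls(path) -> ConnexelSet:
    """Read a whitespace-separated seven-column connexel list.

    Each non-blank line must hold exactly ``px py pz qx qy qz c``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 fields, got {len(fields)}"
                )
            try:
                rows.append([float(x) for x in fields])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from e
    if not rows:
        return ConnexelSet.empty(space_label=str(path))
    arr = np.array(rows)
    return ConnexelSet(arr[:, 0:3], arr[:, 3:6], arr[:, 6],
                       space_label=str(path))


def write_cxls(cset: ConnexelSet, path) -> None:
    """Write a connexel set in the seven-column text format (9 significant
    digits, so coordinates round-trip well below 1e-5 mm)."""
    with open(path, "w") as fh:
        for i in range(len(cset)):
            row = np.concatenate([cset.p[i], cset.q[i], [cset.values[i]]])
            fh.write(" ".join(f"{x:.9g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# FreeSurfer ASCII surfaces
# ---------------------------------------------------------------------------

def read_surface_asc(path, representation_name: str = "other") -> SurfaceMesh:
    """Read a FreeSurfer ASCII surface (.asc)."""
    with open(path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    body = [ln for ln in lines if not ln.startswith("#")]
    if not body:
        raise FormatError(f"{path}: empty surface file")
    header = body[0].split()
    if len(header) != 2:
        raise FormatError(f"{path}: header must be 'N M', got {body[0]!r}")
    n, m = int(header[0]), int(header[1])
    if len(body) - 1 != n + m:
        raise FormatError(
            f"{path}: header claims {n} vertices + {m} faces but "
            f"{len(body) - 1} data lines present"
        )
    verts = np.empty((n, 3))
    for i, ln in enumerate(body[1:1 + n]):
        f = ln.split()
        if len(f) < 3:
            raise FormatError(f"{path}: bad vertex line {ln!r}")
        verts[i] = [float(x) for x in f[:3]]
    faces = np.empty((m, 3), dtype=np.int64)
    for i, ln in enumerate(body[1 + n:1 + n + m]):
        f = ln.split()
        if len(f) < 3:
            raise FormatError(f"{path}: bad face line {ln!r}")
        faces[i] = [int(x) for x in f[:3]]
    return SurfaceMesh(verts, faces, representation_name)


def write_surface_asc(surface: SurfaceMesh, path) -> None:
    """Write a surface in FreeSurfer ASCII layout (trailing value column 0)."""
    with open(path, "w") as fh:
        fh.write("#!ascii version of surface\n")
        fh.write(f"{surface.n_vertices} {len(surface.faces)}\n")
        for v in surface.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} 0\n")
        for f in surface.faces:
            fh.write(f"{f[0]} {f[1]} {f[2]} 0\n")


# ---------------------------------------------------------------------------
# legacy VTK polydata (.vtk / .fib)
# ---------------------------------------------------------------------------

_VALUE_ARRAY_NAMES = ("connectivity", "value", "values", "scalars")


def _tokens_ascii(data: bytes):
    return data.decode("ascii", errors="replace").split()


def read_vtk_polydata(path):
    """Read a legacy VTK POLYDATA line set.

    Returns ``(connexels, polylines)``: two-point LINES records become a
    :class:`ConnexelSet` (value taken from a point/cell scalar array named
    like ``connectivity``/``value`` when present, else 1 -- binarized
    graphs), records with more than two points become raw (K, 3) polyline
    arrays.
    """
    raw = Path(path).read_bytes()
    # header: 2 text lines, then ASCII|BINARY, then DATASET line
    lines = raw.split(b"\n")
    if len(lines) < 4 or not lines[0].startswith(b"# vtk DataFile"):
        raise FormatError(f"{path}: not a legacy VTK file")
    mode = lines[2].strip().upper()
    if mode not in (b"ASCII", b"BINARY"):
        raise FormatError(f"{path}: unknown mode {mode!r}")
    dataset = lines[3].strip().upper().split()
    if len(dataset) != 2 or dataset[0] != b"DATASET" or dataset[1] != b"POLYDATA":
        raise FormatError(f"{path}: expected DATASET POLYDATA, got {lines[3]!r}")
    body = raw[len(b"\n".join(lines[:4])) + 1:]

    points = None
    records = []
    scalars = {}

    if mode == b"ASCII":
        toks = _tokens_ascii(body)
        i = 0
        n_data_points = None
        while i < len(toks):
            kw = toks[i].upper()
            if kw == "POINTS":
                n = int(toks[i + 1])
                vals = [float(t) for t in toks[i + 3:i + 3 + 3 * n]]
                points = np.array(vals).reshape(n, 3)
                i += 3 + 3 * n
            elif kw == "LINES":
                n_lines = int(toks[i + 1])
                total = int(toks[i + 2])
                i += 3
                flat = [int(t) for t in toks[i:i + total]]
                i += total
                j = 0
                for _ in range(n_lines):
                    k = flat[j]
                    records.append(flat[j + 1:j + 1 + k])
                    j += 1 + k
            elif kw in ("POINT_DATA", "CELL_DATA"):
                n_data_points = int(toks[i + 1])
                i += 2
            elif kw == "SCALARS":
                name = toks[i + 1].lower()
                i += 4  # SCALARS name type [numComp]
                if toks[i].upper() == "LOOKUP_TABLE":
                    i += 2
                vals = [float(t) for t in toks[i:i + n_data_points]]
                i += n_data_points
                scalars[name] = np.array(vals)
            else:
                i += 1
    else:
        pos = 0

        def next_line(p):
            end = body.index(b"\n", p)
            return body[p:end].decode("ascii").strip(), end + 1

        n_data_points = None
        while pos < len(body):
            try:
                header, pos2 = next_line(pos)
            except ValueError:
                break
            pos = pos2
            parts = header.split()
            if not parts:
                continue
            kw = parts[0].upper()
            if kw == "POINTS":
                n = int(parts[1])
                nbytes = 4 * 3 * n
                points = np.frombuffer(body[pos:pos + nbytes],
                                       dtype=">f4").astype(float).reshape(n, 3)
                pos += nbytes
            elif kw == "LINES":
                n_lines, total = int(parts[1]), int(parts[2])
                nbytes = 4 * total
                flat = np.frombuffer(body[pos:pos + nbytes], dtype=">i4")
                pos += nbytes
                j = 0
                for _ in range(n_lines):
                    k = int(flat[j])
                    records.append([int(x) for x in flat[j + 1:j + 1 + k]])
                    j += 1 + k
            elif kw in ("POINT_DATA", "CELL_DATA"):
                n_data_points = int(parts[1])
            elif kw == "SCALARS":
                name = parts[1].lower()
                lut, pos2 = next_line(pos)
                if lut.upper().startswith("LOOKUP_TABLE"):
                    pos = pos2
                nbytes = 4 * n_data_points
                scalars[name] = np.frombuffer(
                    body[pos:pos + nbytes], dtype=">f4").astype(float)
                pos += nbytes

    if points is None:
        raise FormatError(f"{path}: no POINTS section")

    value_array = None
    for name in _VALUE_ARRAY_NAMES:
        if name in scalars:
            value_array = scalars[name]
            break

    cx_p, cx_q, cx_v = [], [], []
    polylines = []
    for rec_idx, rec in enumerate(records):
        pts = points[rec]
        if len(rec) == 2:
            if value_array is not None:
                if len(value_array) == len(records):       # cell data
                    v = value_array[rec_idx]
                else:                                       # point data
                    v = value_array[rec[0]]
            else:
                v = 1.0
            cx_p.append(pts[0])
            cx_q.append(pts[1])
            cx_v.append(v)
        else:
            polylines.append(pts)
    if cx_p:
        cset = ConnexelSet(np.array(cx_p), np.array(cx_q), np.array(cx_v),
                           space_label=str(path))
    else:
        cset = ConnexelSet.empty(space_label=str(path))
    return cset, polylines


def write_vtk_polydata(polylines, path, mode: str = "ascii",
                       values=None) -> None:
    """Write polylines (each a (K, 3) array, K >= 2) as legacy VTK POLYDATA.

    ``values``, if given, is one scalar per polyline, written as CELL_DATA
    under the name ``connectivity`` so two-point lines round-trip as
    weighted connexels. Binary mode writes big-endian float32/int32 per the
    legacy VTK convention.
    """
    polylines = [np.asarray(pl, dtype=float).reshape(-1, 3) for pl in polylines]
    if mode not in ("ascii", "binary"):
        raise ValueError(f"mode must be 'ascii' or 'binary', got {mode!r}")
    points = (np.vstack(polylines) if polylines else np.zeros((0, 3)))
    counts = [len(pl) for pl in polylines]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total = sum(c + 1 for c in counts)

    with open(path, "wb") as fh:
        fh.write(b"# vtk DataFile Version 3.0\n")
        fh.write(b"connexel polylines\n")
        fh.write(b"ASCII\n" if mode == "ascii" else b"BINARY\n")
        fh.write(b"DATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n".encode())
        if mode == "ascii":
            for pt in points:
                fh.write(f"{pt[0]:.9g} {pt[1]:.9g} {pt[2]:.9g}\n".encode())
        else:
            fh.write(points.astype(">f4").tobytes())
            fh.write(b"\n")
        fh.write(f"LINES {len(polylines)} {total}\n".encode())
        if mode == "ascii":
            for i, c in enumerate(counts):
                idx = range(offsets[i], offsets[i] + c)
                fh.write((" ".join([str(c)] + [str(j) for j in idx]) + "\n").encode())
        else:
            flat = []
            for i, c in enumerate(counts):
                flat.append(c)
                flat.extend(range(offsets[i], offsets[i] + c))
            fh.write(np.array(flat, dtype=">i4").tobytes())
            fh.write(b"\n")
        if values is not None:
            values = np.asarray(values, dtype=float).reshape(-1)
            if len(values) != len(polylines):
                raise ValueError("one value per polyline required")
            fh.write(f"CELL_DATA {len(values)}\n".encode())
            fh.write(b"SCALARS connectivity float 1\n")
            fh.write(b"LOOKUP_TABLE default\n")
            if mode == "ascii":
                fh.write(("\n".join(f"{v:.9g}" for v in values) + "\n").encode())
            else:
                fh.write(values.astype(">f4").tobytes())
                fh.write(b"\n")


def connexels_to_vtk(cset: ConnexelSet, path, mode: str = "ascii") -> None:
    """Write a connexel set as two-point VTK lines with connectivity values."""
    polylines = [np.stack([cset.p[i], cset.q[i]]) for i in range(len(cset))]
    write_vtk_polydata(polylines, path, mode=mode, values=cset.values)


# ---------------------------------------------------------------------------
# binary connectivity matrix
# ---------------------------------------------------------------------------

def read_matrix_binary(path, n_nodes: int,
                       kind: str = "generic") -> ConnectivityMatrix:
    """Read a raw float32 little-endian row-major N x N matrix.

    The matrix is symmetrized as (M + M^T)/2; a warning is issued if the
    maximum asymmetry exceeds 1e-4.
    """
    expected = 4 * n_nodes * n_nodes
    raw = Path(path).read_bytes()
    if len(raw) != expected:
        raise FormatError(
            f"{path}: expected {expected} bytes for a {n_nodes}x{n_nodes} "
            f"float32 matrix, got {len(raw)}"
        )
    m = np.frombuffer(raw, dtype="<f4").astype(float).reshape(n_nodes, n_nodes)
    asym = np.abs(m - m.T).max() if m.size else 0.0
    if asym > 1e-4:
        warnings.warn(
            f"{path}: matrix asymmetry {asym:g} exceeds 1e-4; symmetrizing",
            stacklevel=2,
        )
    m = (m + m.T) / 2
    return ConnectivityMatrix(m, kind=kind, validate=False)


def write_matrix_binary(matrix: ConnectivityMatrix, path) -> None:
    """Write the matrix as raw float32 little-endian row-major bytes."""
    Path(path).write_bytes(matrix.values.astype("<f4").tobytes())


# ---------------------------------------------------------------------------
# glyphset / set files
# ---------------------------------------------------------------------------

def _meaningful_lines(path):
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if ln and not ln.startswith("#"):
                yield ln


_REP_NAMES = ("pial", "inflated", "sphere")


def _guess_representation(path: Path) -> str:
    stem = path.stem.lower()
    for name in _REP_NAMES:
        if name in stem:
            return name
    return "other"


def read_set_file(path) -> SetFile:
    """Parse a set file: one surface path per line, optional 3D offset."""
    base = Path(path).parent
    entries = []
    for ln in _meaningful_lines(path):
        fields = ln.split()
        offset = None
        if len(fields) >= 4:
            try:
                offset = np.array([float(x) for x in fields[-3:]])
                fields = fields[:-3]
            except ValueError:
                offset = None
        surf_path = base / " ".join(fields)
        entries.append((surf_path, offset))
    if not entries:
        raise FormatError(f"{path}: set file lists no surfaces")
    return SetFile(entries)


def read_glyphset(path):
    """Load a glyphset: (SurfaceSet, ConnectivityMatrix, load_min_threshold).

    Surfaces are loaded in set-file order with their offsets; the matrix
    dimension must equal the shared node count. The threshold is returned
    for callers to apply at load time.
    """
    base = Path(path).parent
    lines = list(_meaningful_lines(path))
    if len(lines) < 3:
        raise FormatError(
            f"{path}: glyphset needs set-file path, matrix path and threshold"
        )
    descriptor = GlyphsetDescriptor(
        set_file_path=base / lines[0],
        matrix_file_path=base / lines[1],
        load_min_threshold=float(lines[2]),
    )
    set_file = read_set_file(descriptor.set_file_path)
    surfaces, offsets = [], []
    for surf_path, offset in set_file.entries:
        surfaces.append(read_surface_asc(surf_path,
                                         _guess_representation(surf_path)))
        offsets.append(np.zeros(3) if offset is None else offset)
    sset = SurfaceSet(surfaces, offsets)
    matrix = read_matrix_binary(descriptor.matrix_file_path, sset.n_vertices)
    return sset, matrix, descriptor.load_min_threshold
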