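"""File I/O: MRC2014 volumes/stacks, parameter tables, FSC text, manifests.

The MRC reader/writer is a minimal self-contained MRC2014 implementation
(read modes 0/1/2, write mode 2) sufficient for cubic volumes and square
image stacks; the distinction between the two on disk follows the MRC2014
convention (``ISPG`` 0 for image stacks, 1 for volumes).

Parameter tables are self-describing whitespace-separated text with a header
row naming the columns.  Units are degrees and pixels; the shift convention
is the package-wide one (positive x/y moves the imaged object toward +x/+y
in the projection).  Angles are normalized to [0, 360) on read; round trips
preserve values to 6 decimals and keep unknown columns.
"""

from __future__ import annotations

import hashlib
import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError, ShapeMismatchError
from .geometry import OrientationParams
from .particles import ParticleRecord, ParticleStack
from .reconstruct import FSCCurve
from .volume_ops import DensityVolume

_MRC_HEADER_BYTES = 1024
_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32}
_MAP_ID = b"MAP "

REQUIRED_PARAM_COLUMNS = ("index", "phi", "theta", "psi", "x", "y")


# --------------------------------------------------------------------------
# MRC2014
# --------------------------------------------------------------------------

def read_mrc(path) -> DensityVolume | ParticleStack:
    """Read an MRC2014 file as a volume (ISPG >= 1) or image stack (ISPG 0).

    Supports modes 0 (int8), 1 (int16) and 2 (float32); data are returned as
    float32.  A single-section file (nz == 1) is returned as a volume-less
    one-image stack only when flagged as a stack; otherwise cubic volumes are
    required.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER_BYTES:
        raise FormatError(f"{path}: truncated MRC header "
                          f"({len(raw)} < {_MRC_HEADER_BYTES} bytes)")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    ispg = struct.unpack_from("<i", raw, 88)[0]
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    cella = struct.unpack_from("<3f", raw, 40)
    if raw[208:212] != _MAP_ID:
        raise FormatError(f"{path}: missing MAP identifier (not MRC2014?)")
    if mode not in _MRC_MODES:
        raise FormatError(f"{path}: unsupported MRC mode {mode}")
    if min(nx, ny, nz) < 1 or max(nx, ny, nz) > 100000:
        raise FormatError(f"{path}: implausible dimensions {(nx, ny, nz)}")
    if nsymbt < 0:
        raise FormatError(f"{path}: negative symmetry block size")
    dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
    start = _MRC_HEADER_BYTES + nsymbt
    count = nx * ny * nz
    need = start + count * dtype.itemsize
    if len(raw) < need:
        raise FormatError(f"{path}: truncated data ({len(raw)} < {need} bytes)")
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=start)
    data = data.reshape(nz, ny, nx).astype(np.float32)
    apix = cella[0] / nx if cella[0] > 0 else 1.0
    if ispg == 0:
        if nx != ny:
            raise FormatError(f"{path}: image stack sections must be square")
        records = [ParticleRecord(i, OrientationParams(0, 0, 0, 0, 0),
                                  OrientationParams(0, 0, 0, 0, 0))
                   for i in range(nz)]
        return ParticleStack(data, apix, records)
    if not (nx == ny == nz):
        raise FormatError(f"{path}: cubic volume required, got {(nx, ny, nz)}")
    return DensityVolume(data.astype(np.float64), apix)


def write_mrc(obj, path) -> None:
    """Write a volume or image stack as MRC2014 mode 2 (float32)."""
    if isinstance(obj, ParticleStack):
        data = np.asarray(obj.images, dtype="<f4")
        apix = obj.pixel_size
        ispg = 0
    elif hasattr(obj, "grid"):
        data = np.asarray(obj.grid, dtype="<f4")
        apix = getattr(obj, "pixel_size", 1.0)
        ispg = 1
    else:
        data = np.asarray(obj, dtype="<f4")
        apix = 1.0
        ispg = 1 if data.ndim == 3 and data.shape[0] == data.shape[2] else 0
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise InvalidParameterError("write_mrc expects 2D/3D data")
    nz, ny, nx = data.shape
    header = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)          # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * apix, ny * apix, nz * apix)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)    # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)             # axis order
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<i", header, 88, ispg)
    header[208:212] = _MAP_ID
    header[212:216] = b"\x44\x44\x00\x00"                    # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(data).tobytes())


# --------------------------------------------------------------------------
# Parameter tables
# --------------------------------------------------------------------------

def _norm_angle(a: float) -> float:
    return float(np.mod(a, 360.0))


def write_params(records, path, extra_columns: pd.DataFrame | None = None) -> None:
    """Write per-particle parameters as whitespace-separated text.

    Columns: index, phi, theta, psi (degrees), x, y (pixels), defocus_group,
    ccc; any ``extra_columns`` are appended and survive a round trip.
    """
    rows = []
    for r in records:
        p = OrientationParams(*r.params)
        rows.append({"index": int(r.image_index),
                     "phi": p.phi, "theta": p.theta, "psi": p.psi,
                     "x": p.x, "y": p.y,
                     "defocus_group": -1 if r.defocus_group is None else int(r.defocus_group),
                     "ccc": np.nan if r.best_ccc is None else float(r.best_ccc)})
    df = pd.DataFrame(rows, columns=["index", "phi", "theta", "psi", "x", "y",
                                     "defocus_group", "ccc"])
    if extra_columns is not None:
        for c in extra_columns.columns:
            df[c] = np.asarray(extra_columns[c])
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        fh.write("# per-particle projection parameters; angles deg, shifts px "
                 "(positive shift moves the object toward +x/+y)\n")
        fh.write(df.to_string(index=False, float_format=lambda v: f"{v:.6f}"))
        fh.write("\n")


def read_params(path) -> tuple[list[ParticleRecord], pd.DataFrame]:
    """Read a parameter table; returns (records, full dataframe).

    The header row must name at least ``index phi theta psi x y``.  Angles
    are normalized to [0, 360); unknown columns are kept in the dataframe.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable parameter table ({exc})") from exc
    missing = [c for c in REQUIRED_PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for c in ("phi", "theta", "psi"):
        df[c] = df[c].map(_norm_angle)
    records = []
    for _, row in df.iterrows():
        p = OrientationParams(float(row["phi"]), float(row["theta"]),
                              float(row["psi"]), float(row["x"]), float(row["y"]))
        group = None
        if "defocus_group" in df.columns and int(row["defocus_group"]) >= 0:
            group = int(row["defocus_group"])
        ccc = None
        if "ccc" in df.columns and np.isfinite(row["ccc"]):
            ccc = float(row["ccc"])
        records.append(ParticleRecord(int(row["index"]), p, p,
                                      defocus_group=group, best_ccc=ccc))
    return records, df


def attach_params(stack: ParticleStack, records) -> ParticleStack:
    """Bind a parameter table to a stack, checking the row/image pairing."""
    if len(records) != len(stack):
        raise ShapeMismatchError(
            f"parameter rows ({len(records)}) != stack size ({len(stack)})")
    by_index = {r.image_index: r for r in records}
    if len(by_index) != len(records):
        raise FormatError("duplicate particle indices in parameter table")
    ordered = []
    for r in stack.records:
        if r.image_index not in by_index:
            raise FormatError(f"no parameter row for particle {r.image_index}")
        src = by_index[r.image_index]
        ordered.append(ParticleRecord(r.image_index, src.params, src.params,
                                      defocus_group=src.defocus_group,
                                      best_ccc=src.best_ccc))
    return stack.with_records(ordered)


# --------------------------------------------------------------------------
# FSC text and manifests
# --------------------------------------------------------------------------

def write_fsc(curve: FSCCurve, path) -> None:
    """Two-column text: spatial frequency (cycles/A) and correlation."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        fh.write("# freq_cyc_per_A  fsc\n")
        for f, c in zip(curve.shell_freq, curve.correlation):
            fh.write(f"{f:.8f}  {c:.6f}\n")


def read_fsc(path) -> FSCCurve:
    try:
        arr = np.loadtxt(path, comments="#", ndmin=2)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable FSC table ({exc})") from exc
    if arr.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns, got {arr.shape[1]}")
    return FSCCurve(shell_freq=arr[:, 0], correlation=arr[:, 1])


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, command: str, seed: int | None, config: dict,
                   outputs) -> None:
    """JSON manifest recording the command, seed, config echo, library
    versions and sha256 of every declared output."""
    import numba
    import scipy
    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "numba": numba.__version__, "pandas": pd.__version__},
        "outputs": {str(o): sha256_of(o) for o in outputs},
    }
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
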