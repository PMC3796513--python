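"""Read and write Analyze 7.5 ``.hdr``/``.img`` volume pairs.

Analyze 7.5 is the two-file format the pipeline consumes: a 348-byte
header describing grid dimensions, element type and voxel spacing, and a
raw image file. nibabel does the header parsing and byte-order handling;
this module adds the validation the pipeline contract requires (header
sentinel check under both endiannesses, image byte-length consistency)
and applies the dialect-divergent scale factor explicitly.

Orientation: Analyze 7.5 carries no left/right convention. Axis 0 is
treated as the subject's left-to-right axis of the prone, arms-overhead
posture, but handedness is never inferred from data — the affected side
is always supplied as metadata downstream.
"""

from __future__ import annotations

import struct
from os import PathLike
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, InvariantError, TruncationError
from .volume import UNITS, VoxelVolume

#: Analyze data-type codes we accept: 8-bit unsigned, 16-bit signed, 32-bit float.
_SUPPORTED_DTYPES = {np.dtype(np.uint8), np.dtype(np.int16), np.dtype(np.float32)}

_HEADER_SIZE = 348
#: Byte offset of the SPM-dialect scale factor (funused1) in the header.
_SCALE_OFFSET = 112


def _check_sentinel(header_bytes: bytes) -> str:
    """Return '<' or '>' according to which byte order reads sizeof_hdr as 348."""
    if len(header_bytes) < _HEADER_SIZE:
        raise FormatError(
            f"header is {len(header_bytes)} bytes, expected at least {_HEADER_SIZE}"
        )
    for endian in ("<", ">"):
        (size,) = struct.unpack(endian + "i", header_bytes[:4])
        if size == _HEADER_SIZE:
            return endian
    raise FormatError(
        "header-size field does not read 348 under either byte order; "
        "not an Analyze 7.5 header"
    )


def read_analyze_pair(
    header_path: str | PathLike,
    image_path: str | PathLike,
    units: str = "Bq",
) -> VoxelVolume:
    """Load an Analyze 7.5 pair into a :class:`VoxelVolume`.

    Byte order is auto-detected via the header-size sentinel (348 in one
    of the two endiannesses). If the scale-factor field is present and
    nonzero it multiplies the stored values; otherwise raw values are
    used. Data are always promoted to float64 in memory.

    Parameters
    ----------
    header_path, image_path : path-like
        The ``.hdr`` and ``.img`` files of the pair.
    units : str
        Units tag for the returned volume, used when the header's
        description field does not carry one.

    Raises
    ------
    FormatError
        Malformed header or unsupported element type.
    TruncationError
        Image byte length inconsistent with dims x element size.
    """
    header_path, image_path = Path(header_path), Path(image_path)
    header_bytes = header_path.read_bytes()
    endian = _check_sentinel(header_bytes)

    try:
        hdr = nib.AnalyzeHeader.from_fileobj(_BytesReader(header_bytes), check=False)
    except Exception as exc:  # pragma: no cover - sentinel check catches most
        raise FormatError(f"nibabel could not parse header: {exc}") from exc

    shape = tuple(int(d) for d in hdr.get_data_shape()[:3])
    if len(shape) < 3 or any(d < 1 for d in shape):
        raise FormatError(f"header declares non-3D or empty grid {shape}")
    dtype = hdr.get_data_dtype()
    if np.dtype(dtype).newbyteorder("=") not in _SUPPORTED_DTYPES:
        raise FormatError(
            f"unsupported element type {dtype}; supported: uint8, int16, float32"
        )
    zooms = tuple(float(z) for z in hdr.get_zooms()[:3])

    expected = int(np.prod(shape)) * np.dtype(dtype).itemsize
    actual = image_path.stat().st_size
    if actual != expected:
        raise TruncationError(
            f"image file is {actual} bytes but header implies {expected} "
            f"({shape} x {np.dtype(dtype).itemsize}B)"
        )

    raw = np.fromfile(image_path, dtype=np.dtype(dtype).newbyteorder(endian))
    data = raw.reshape(shape, order="F").astype(np.float64)

    (scale,) = struct.unpack(
        endian + "f", header_bytes[_SCALE_OFFSET : _SCALE_OFFSET + 4]
    )
    if np.isfinite(scale) and scale != 0.0:
        data = data * float(scale)

    descrip = bytes(hdr["descrip"]).split(b"\x00", 1)[0].decode("ascii", "replace")
    units, description = _split_descrip(descrip, units)

    vol = VoxelVolume(data, zooms, units=units, description=description)
    vol.validate_finite()
    return vol


def write_analyze_pair(
    volume: VoxelVolume,
    header_path: str | PathLike,
    image_path: str | PathLike,
    dtype: str | np.dtype = np.float32,
) -> None:
    """Persist a volume as an Analyze 7.5 pair.

    The roundtrip through :func:`read_analyze_pair` is value-exact for
    data representable in the chosen element type (float32 is the
    default and is exact for phantoms generated by this package after
    their float32 cast). The units tag travels in the header description
    field.
    """
    dtype = np.dtype(dtype)
    if dtype not in _SUPPORTED_DTYPES:
        raise FormatError(
            f"unsupported element type {dtype}; supported: uint8, int16, float32"
        )
    if not isinstance(volume, VoxelVolume):
        raise InvariantError("write_analyze_pair requires a VoxelVolume")
    volume.validate_finite()

    img = nib.AnalyzeImage(
        volume.data.astype(dtype),
        affine=np.diag(list(volume.spacing_mm) + [1.0]),
    )
    img.header.set_zooms(volume.spacing_mm)
    img.header["descrip"] = _join_descrip(volume.units, volume.description)

    file_map = img.make_file_map()
    file_map["header"].filename = str(header_path)
    file_map["image"].filename = str(image_path)
    img.to_file_map(file_map)


def _split_descrip(descrip: str, fallback_units: str) -> tuple[str, str]:
    if descrip.startswith("units="):
        head, _, rest = descrip.partition(";")
        tag = head[len("units="):]
        if tag in UNITS:
            return tag, rest
    return fallback_units, descrip


def _join_descrip(units: str, description: str) -> bytes:
    return f"units={units};{description}".encode("ascii", "replace")[:80]


class _BytesReader:
    """Minimal file-object wrapper so nibabel can parse in-memory header bytes."""

    def __init__(self, data: bytes):
        self._data = data
        self._pos = 0

    def read(self, n: int = -1) -> bytes:
        if n < 0:
            n = len(self._data) - self._pos
        out = self._data[self._pos : self._pos + n]
        self._pos += len(out)
        return out

    def seek(self, pos: int, whence: int = 0) -> None:
        self._pos = pos if whence == 0 else self._pos + pos

    def tell(self) -> int:
        return self._pos
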