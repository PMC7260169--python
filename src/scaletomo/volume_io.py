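"""Reading, writing and bit-packing of 3-D volumes, plus size manifests.

On-disk conventions mirror the public beetle-scale tomography deposit:

* dense volumes as NPY, or a zip wrapper (NPZ) holding a single array under
  any key (``arr_0`` by default);
* TIFF stacks (one image per z-slice) for interchange;
* thresholded volumes bit-packed into uint8 bytes, MSB-first within each
  byte over a row-major flattening, with a JSON shape sidecar — unpack and
  reshape to recover the matrix;
* manifests listing, per file, the voxel shape, physical size in µm and the
  unpacked size in decimal GB (10⁹ bytes), as in the deposit's tables.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import tifffile

from .errors import PolarityError, ShapeMismatchError, UnsupportedFormatError
from .volumes import AIR, GREY_MAX, MATERIAL, BinaryVolume, GreyVolume, DEFAULT_PITCH_NM

_ALLOWED_DTYPES = ("uint8", "int8", "float32", "float64")


# ---------------------------------------------------------------------------
# bit packing

def pack_binary(vol: BinaryVolume) -> tuple[bytes, tuple[int, int, int]]:
    """Pack a binary volume into MSB-first uint8 bytes.

    The volume is flattened row-major over (x, y, z); each group of eight
    bits becomes one byte, most significant bit first; trailing bits of the
    final byte are zero.  Returns ``(payload, shape)``.
    """
    data = np.asarray(vol.data)
    bad = (data != MATERIAL) & (data != AIR)
    if bad.any():
        raise PolarityError("polarity violation: values outside {0, 1}")
    flat = data.astype(np.uint8).ravel(order="C")
    packed = np.packbits(flat, bitorder="big")
    return packed.tobytes(), tuple(data.shape)  # type: ignore[return-value]


def unpack_binary(payload: bytes, shape, pitch_nm: float = DEFAULT_PITCH_NM) -> BinaryVolume:
    """Inverse of :func:`pack_binary`; checks the byte count against ``shape``."""
    shape = tuple(int(s) for s in shape)
    n = int(np.prod(shape))
    expected = math.ceil(n / 8)
    if len(payload) != expected:
        raise ShapeMismatchError(
            f"packed payload is {len(payload)} bytes but shape {shape} "
            f"({n} voxels) requires {expected}"
        )
    bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8), bitorder="big")
    return BinaryVolume(bits[:n].reshape(shape), pitch_nm=pitch_nm)


# ---------------------------------------------------------------------------
# size arithmetic / manifests

def storage_size_gb(shape, bytes_per_element: float) -> float:
    """Unpacked matrix size in decimal gigabytes (10⁹ bytes).

    Reporting (manifests) rounds to three significant figures, matching the
    deposit's tables; this function returns the exact value.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 1 or bytes_per_element <= 0:
        raise ValueError("shape components and bytes_per_element must be positive")
    return float(np.prod([float(s) for s in shape]) * bytes_per_element / 1e9)


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass
class VolumeManifest:
    """One manifest row: file name, voxel shape, physical size, unpacked GB."""

    file_name: str
    shape_voxels: tuple[int, int, int]
    shape_um: tuple[float, float, float]
    size_gb: float
    image_type: str  # "greyscale" | "thresholded"

    def as_row(self) -> dict:
        d = asdict(self)
        d["shape_voxels"] = list(self.shape_voxels)
        d["shape_um"] = list(self.shape_um)
        d["size_gb"] = _round_sig(self.size_gb)
        return d


def manifest_entry(
    file_name: str,
    shape,
    bytes_per_element: float,
    image_type: str,
    pitch_nm: float = DEFAULT_PITCH_NM,
) -> VolumeManifest:
    """Build a manifest row from a voxel shape and element size."""
    shape = tuple(int(s) for s in shape)
    shape_um = tuple(s * pitch_nm / 1000.0 for s in shape)
    return VolumeManifest(
        file_name=file_name,
        shape_voxels=shape,  # type: ignore[arg-type]
        shape_um=shape_um,  # type: ignore[arg-type]
        size_gb=storage_size_gb(shape, bytes_per_element),
        image_type=image_type,
    )


def write_manifest(path, entries) -> None:
    """Write manifest rows as JSON (``.json``) or CSV (``.csv``)."""
    path = Path(path)
    rows = [e.as_row() for e in entries]
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=2))
    elif path.suffix == ".csv":
        cols = ["file_name", "shape_voxels", "shape_um", "size_gb", "image_type"]
        lines = [",".join(cols)]
        for r in rows:
            lines.append(
                ",".join(
                    [
                        r["file_name"],
                        "x".join(str(s) for s in r["shape_voxels"]),
                        "x".join(f"{s:g}" for s in r["shape_um"]),
                        f"{r['size_gb']:g}",
                        r["image_type"],
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise UnsupportedFormatError(f"manifest format {path.suffix!r} not supported")


# ---------------------------------------------------------------------------
# dense volume I/O

def _check_dtype(arr: np.ndarray, path) -> None:
    if arr.dtype.name not in _ALLOWED_DTYPES:
        raise UnsupportedFormatError(
            f"{path}: dtype {arr.dtype} outside supported set {_ALLOWED_DTYPES}"
        )


def _single_array_from_npz(npz, path) -> np.ndarray:
    names = list(npz.files)
    if len(names) == 1:
        return npz[names[0]]
    if "arr_0" in names:
        return npz["arr_0"]
    raise UnsupportedFormatError(
        f"{path}: archive holds {len(names)} arrays and none is 'arr_0'"
    )


def read_volume(path, pitch_nm: float = DEFAULT_PITCH_NM) -> GreyVolume:
    """Read a dense volume from ``.npy``, ``.npz`` or a TIFF stack."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        arr = np.load(path)
    elif suffix == ".npz":
        with np.load(path) as npz:
            arr = _single_array_from_npz(npz, path)
    elif suffix in (".tif", ".tiff"):
        pages = tifffile.imread(path)
        if pages.ndim != 3:
            raise ShapeMismatchError(f"{path}: TIFF stack is not 3-D")
        arr = np.ascontiguousarray(np.moveaxis(pages, 0, 2))  # pages are z-slices
    else:
        raise UnsupportedFormatError(f"unsupported volume extension {suffix!r}")
    _check_dtype(arr, path)
    if np.issubdtype(arr.dtype, np.integer) and arr.size and int(arr.max()) > GREY_MAX:
        warnings.warn(
            f"{path}: greyscale values exceed {GREY_MAX}; tolerating dialect",
            stacklevel=2,
        )
    return GreyVolume(arr, pitch_nm=pitch_nm)


def write_volume(path, vol: GreyVolume) -> Path:
    """Write a dense volume; format chosen by extension. Lossless round trip."""
    path = Path(path)
    data = np.asarray(vol.data)
    _check_dtype(data, path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        np.save(path, data)
    elif suffix == ".npz":
        np.savez_compressed(path, arr_0=data)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.ascontiguousarray(np.moveaxis(data, 2, 0)))
    else:
        raise UnsupportedFormatError(f"unsupported volume extension {suffix!r}")
    return path


# ---------------------------------------------------------------------------
# packed binary I/O

_PACKED_META = {"bit_order": "msb", "flatten_order": "C", "material": MATERIAL, "air": AIR}


def write_packed(path, vol: BinaryVolume) -> Path:
    """Write a bit-packed binary volume.

    ``.npz`` stores the packed bytes and shape inside one zip archive;
    any other path gets raw packed bytes plus a ``<path>.json`` sidecar
    recording the shape and packing convention.
    """
    path = Path(path)
    payload, shape = pack_binary(vol)
    if path.suffix.lower() == ".npz":
        np.savez_compressed(
            path,
            packed=np.frombuffer(payload, dtype=np.uint8),
            shape=np.asarray(shape, dtype=np.int64),
        )
    else:
        path.write_bytes(payload)
        meta = dict(_PACKED_META, shape=list(shape), pitch_nm=vol.pitch_nm)
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
    return path


def read_packed(path, pitch_nm: float = DEFAULT_PITCH_NM) -> BinaryVolume:
    """Read a bit-packed binary volume written by :func:`write_packed`."""
    path = Path(path)
    if path.suffix.lower() == ".npz":
        with np.load(path) as npz:
            payload = npz["packed"].tobytes()
            shape = tuple(int(s) for s in npz["shape"])
        return unpack_binary(payload, shape, pitch_nm=pitch_nm)
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise UnsupportedFormatError(f"missing shape sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    return unpack_binary(
        path.read_bytes(), meta["shape"], pitch_nm=meta.get("pitch_nm", pitch_nm)
    )
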