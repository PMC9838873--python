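"""Volume I/O: NRRD (primary) and NIfTI (optional, via nibabel).

The NRRD codec is a compact NRRD0004 implementation covering what atlas
volumes need: 3D arrays, ``raw``/``gzip`` encodings, little/big endian,
per-axis ``spacings`` (micrometres) and custom key/value pairs (used for the
semantic ``tag`` of scalar volumes).  Data follow the NRRD convention that
the first axis listed in ``sizes`` varies fastest on disk (Fortran layout),
so files interoperate with pynrrd/teem.
"""

from __future__ import annotations

import gzip
import os

import numpy as np

from .atlas import AnnotationVolume, ScalarVolume

__all__ = [
    "read_nrrd",
    "write_nrrd",
    "read_annotation",
    "write_annotation",
    "read_scalar",
    "write_scalar",
    "read_nifti",
    "write_nifti",
]

_NRRD_TYPES = {
    "signed char": np.int8, "int8": np.int8, "int8_t": np.int8,
    "uchar": np.uint8, "unsigned char": np.uint8, "uint8": np.uint8,
    "short": np.int16, "int16": np.int16,
    "ushort": np.uint16, "uint16": np.uint16,
    "int": np.int32, "int32": np.int32, "signed int": np.int32,
    "uint": np.uint32, "uint32": np.uint32, "unsigned int": np.uint32,
    "long long": np.int64, "int64": np.int64,
    "uint64": np.uint64, "unsigned long long": np.uint64,
    "float": np.float32, "float32": np.float32,
    "double": np.float64, "float64": np.float64,
}

_DTYPE_NAMES = {
    np.dtype(np.int8): "int8", np.dtype(np.uint8): "uint8",
    np.dtype(np.int16): "int16", np.dtype(np.uint16): "uint16",
    np.dtype(np.int32): "int32", np.dtype(np.uint32): "uint32",
    np.dtype(np.int64): "int64", np.dtype(np.uint64): "uint64",
    np.dtype(np.float32): "float", np.dtype(np.float64): "double",
}


def read_nrrd(path) -> tuple[np.ndarray, dict]:
    """Read an NRRD file; returns ``(array, header)``.

    ``header`` maps lower-cased field names to their string values plus
    parsed ``sizes`` / ``spacings`` entries and any ``key:=value`` pairs.
    """
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        header: dict = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", "replace").rstrip("\r\n")
            if text.startswith("#"):
                continue
            if ":=" in text:
                k, v = text.split(":=", 1)
                header[k.strip()] = v.strip()
            elif ": " in text or text.endswith(":"):
                k, _, v = text.partition(":")
                header[k.strip().lower()] = v.strip()
            else:
                raise ValueError(f"{path}: malformed header line {text!r}")
        payload = fh.read()

    if "data file" in header or "datafile" in header:
        raise ValueError("detached NRRD data files are not supported")
    dtype = np.dtype(_NRRD_TYPES[header["type"]])
    sizes = [int(s) for s in header["sizes"].split()]
    if int(header.get("dimension", len(sizes))) != len(sizes):
        raise ValueError(f"{path}: dimension/sizes mismatch")
    encoding = header.get("encoding", "raw").lower()
    if encoding in ("gzip", "gz"):
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise ValueError(f"unsupported NRRD encoding {encoding!r}")
    if dtype.itemsize > 1:
        endian = header.get("endian", "little")
        dtype = dtype.newbyteorder("<" if endian == "little" else ">")
    arr = np.frombuffer(payload, dtype=dtype, count=int(np.prod(sizes)))
    arr = arr.reshape(sizes, order="F")  # first listed axis fastest
    header["sizes"] = sizes
    if "spacings" in header and isinstance(header["spacings"], str):
        header["spacings"] = [float(s) for s in header["spacings"].split()]
    elif "space directions" in header:
        dirs = header["space directions"]
        vecs = [v for v in dirs.replace("(", " ").replace(")", " ").split() if v]
        mat = np.asarray([float(v.strip(",")) for v in vecs], dtype=float)
        mat = mat.reshape(len(sizes), len(sizes))
        header["spacings"] = list(np.linalg.norm(mat, axis=1))
    return np.asarray(arr.newbyteorder("=") if arr.dtype.byteorder == ">" else arr), header


def write_nrrd(path, array: np.ndarray, spacings=None, encoding: str = "gzip",
               keyvalues: dict | None = None) -> None:
    array = np.ascontiguousarray(array)
    name = _DTYPE_NAMES.get(array.dtype)
    if name is None:
        raise ValueError(f"unsupported dtype {array.dtype} for NRRD output")
    lines = [
        "NRRD0004",
        f"type: {name}",
        f"dimension: {array.ndim}",
        f"sizes: {' '.join(str(s) for s in array.shape)}",
        f"encoding: {encoding}",
    ]
    if array.dtype.itemsize > 1:
        lines.append("endian: little")
    if spacings is not None:
        sp = np.atleast_1d(np.asarray(spacings, dtype=float))
        if sp.size == 1:
            sp = np.repeat(sp, array.ndim)
        lines.append("spacings: " + " ".join(f"{s:.17g}" for s in sp))
    for k, v in (keyvalues or {}).items():
        lines.append(f"{k}:={v}")
    payload = array.astype(array.dtype.newbyteorder("<")).flatten(order="F").tobytes()
    if encoding == "gzip":
        payload = gzip.compress(payload, compresslevel=4)
    elif encoding != "raw":
        raise ValueError(f"unsupported NRRD encoding {encoding!r}")
    with open(path, "wb") as fh:
        fh.write(("\n".join(lines) + "\n\n").encode("ascii"))
        fh.write(payload)


def _spacings(header, ndim: int) -> tuple[float, ...]:
    sp = header.get("spacings")
    if sp is None:
        return tuple([25.0] * ndim)
    return tuple(float(s) for s in sp)


def read_annotation(path) -> AnnotationVolume:
    arr, header = read_nrrd(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: annotation volume must be integer-typed")
    return AnnotationVolume(arr, voxel_size=_spacings(header, arr.ndim))


def write_annotation(path, annotation: AnnotationVolume) -> None:
    write_nrrd(path, annotation.grid.astype(np.int32), spacings=annotation.voxel_size)


def read_scalar(path) -> ScalarVolume:
    arr, header = read_nrrd(path)
    tag = header.get("gabatlas:tag", "nissl-intensity")
    return ScalarVolume(arr.astype(float), voxel_size=_spacings(header, arr.ndim), tag=tag)


def write_scalar(path, volume: ScalarVolume) -> None:
    write_nrrd(path, volume.grid.astype(np.float64), spacings=volume.voxel_size,
               keyvalues={"gabatlas:tag": volume.tag})


# -- optional NIfTI path ----------------------------------------------------

def read_nifti(path, tag: str = "nissl-intensity"):
    """Read a NIfTI volume; voxel sizes converted from mm to micrometres."""
    import nibabel as nib

    img = nib.load(os.fspath(path))
    arr = np.asanyarray(img.dataobj)
    vox_um = tuple(float(z) * 1000.0 for z in img.header.get_zooms()[:3])
    if np.issubdtype(arr.dtype, np.integer):
        return AnnotationVolume(arr, voxel_size=vox_um)
    return ScalarVolume(arr.astype(float), voxel_size=vox_um, tag=tag)


def write_nifti(path, volume) -> None:
    import nibabel as nib

    affine = np.diag([v / 1000.0 for v in volume.voxel_size] + [1.0])
    grid = volume.grid
    if np.issubdtype(grid.dtype, np.integer):
        grid = grid.astype(np.int32)
    nib.save(nib.Nifti1Image(grid, affine), os.fspath(path))
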