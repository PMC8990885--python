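"""Minimal MetaImage-style (.mhd + .raw) voxel-image reader/writer.

Only the subset needed for dose grids is supported: 3D arrays, uncompressed
local or sidecar raw payload, MET_FLOAT / MET_DOUBLE / MET_SHORT / MET_UCHAR
element types, element spacing in mm. Arrays use Fortran-order index
convention (x fastest) on disk, matching the format's definition; in memory
we keep (nx, ny, nz) C-indexable arrays.
"""
from __future__ import annotations

import os

import numpy as np

from .errors import ConfigurationError

_DTYPES = {
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
    "MET_SHORT": np.int16,
    "MET_UCHAR": np.uint8,
}
_NAMES = {np.dtype(v): k for k, v in _DTYPES.items()}


def write_mhd(path: str, array: np.ndarray, spacing_mm, origin_mm=(0.0, 0.0, 0.0)):
    """Write a 3D array as header `path` (.mhd) plus raw sidecar (.raw)."""
    array = np.ascontiguousarray(array)
    if array.ndim != 3:
        raise ConfigurationError("only 3D arrays are supported")
    dt = np.dtype(array.dtype)
    if dt not in _NAMES:
        array = array.astype(np.float64)
        dt = array.dtype
    base = os.path.splitext(path)[0]
    raw_name = os.path.basename(base) + ".raw"
    header = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        "TransformMatrix = 1 0 0 0 1 0 0 0 1",
        f"Offset = {origin_mm[0]:.9g} {origin_mm[1]:.9g} {origin_mm[2]:.9g}",
        "CenterOfRotation = 0 0 0",
        f"ElementSpacing = {spacing_mm[0]:.9g} {spacing_mm[1]:.9g} {spacing_mm[2]:.9g}",
        f"DimSize = {array.shape[0]} {array.shape[1]} {array.shape[2]}",
        f"ElementType = {_NAMES[dt]}",
        f"ElementDataFile = {raw_name}",
    ]
    with open(path, "w") as f:
        f.write("\n".join(header) + "\n")
    # disk layout: x fastest -> store transposed C buffer
    array.transpose(2, 1, 0).tofile(base + ".raw")


def read_mhd(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read header + raw; returns (array (nx,ny,nz), spacing_mm, origin_mm)."""
    meta = {}
    with open(path) as f:
        for line in f:
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip()] = v.strip()
    try:
        shape = tuple(int(x) for x in meta["DimSize"].split())
        spacing = np.array([float(x) for x in meta["ElementSpacing"].split()])
        dtype = _DTYPES[meta["ElementType"]]
        datafile = meta["ElementDataFile"]
    except KeyError as e:
        raise ConfigurationError(f"missing MetaImage key: {e}") from None
    origin = np.array(
        [float(x) for x in meta.get("Offset", "0 0 0").split()]
    )
    raw_path = os.path.join(os.path.dirname(os.path.abspath(path)), datafile)
    data = np.fromfile(raw_path, dtype=dtype)
    if data.size != int(np.prod(shape)):
        raise ConfigurationError(
            f"raw size {data.size} does not match DimSize {shape}"
        )
    array = data.reshape(shape[::-1]).transpose(2, 1, 0)
    return array, spacing, origin
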