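"""Minimal NRRD0004 reader/writer for dense 3D scalar volumes.

Supports the subset of the format this package emits and consumes:
C-ordered arrays, ``raw`` or ``gzip`` encoding, little-endian, and voxel
size carried either in ``spacings`` or diagonal ``space directions``.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np

_TYPE_MAP = {
    "signed char": np.int8, "int8": np.int8, "uchar": np.uint8,
    "unsigned char": np.uint8, "uint8": np.uint8,
    "short": np.int16, "int16": np.int16, "ushort": np.uint16, "uint16": np.uint16,
    "int": np.int32, "int32": np.int32, "uint": np.uint32, "uint32": np.uint32,
    "long long": np.int64, "int64": np.int64, "uint64": np.uint64,
    "float": np.float32, "double": np.float64,
}
_INV_TYPE = {np.dtype(np.uint8): "uint8", np.dtype(np.int16): "int16",
             np.dtype(np.uint16): "uint16", np.dtype(np.int32): "int32",
             np.dtype(np.float32): "float", np.dtype(np.float64): "double"}


def read(path) -> tuple[np.ndarray, dict]:
    """Read an NRRD file; returns (array, header dict)."""
    path = Path(path)
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        magic = fh.readline().decode("ascii", "replace").strip()
        if not magic.startswith("NRRD"):
            raise ValueError(f"{path}: not an NRRD file (magic {magic!r})")
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated NRRD header")
            text = line.decode("ascii", "replace").strip()
            if text == "":
                break
            if text.startswith("#"):
                continue
            if ":" not in text:
                raise ValueError(f"{path}: malformed header line {text!r}")
            key, _, value = text.partition(":")
            header[key.strip().lower()] = value.lstrip("=").strip()
        payload = fh.read()

    if "type" not in header or "sizes" not in header:
        raise ValueError(f"{path}: NRRD header missing 'type' or 'sizes'")
    dtype = np.dtype(_TYPE_MAP[header["type"]])
    sizes = [int(s) for s in header["sizes"].split()]
    encoding = header.get("encoding", "raw").lower()
    if encoding in ("gzip", "gz"):
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    endian = header.get("endian", "little")
    dtype = dtype.newbyteorder("<" if endian == "little" else ">")
    arr = np.frombuffer(payload, dtype=dtype, count=int(np.prod(sizes)))
    # NRRD sizes are fastest-first; C-order numpy shape is the reverse.
    arr = arr.reshape(sizes[::-1])
    return np.ascontiguousarray(arr), header


def spacing_from_header(header: dict) -> tuple[float, ...] | None:
    """Per-axis spacing in header units, ordered like the numpy axes (slowest first)."""
    if "spacings" in header:
        vals = [float(v) for v in header["spacings"].split()]
        return tuple(vals[::-1])
    if "space directions" in header:
        vecs = []
        for token in header["space directions"].replace("(", " ").split(")"):
            token = token.strip().replace(",", " ")
            if token:
                vecs.append([float(v) for v in token.split()])
        if vecs:
            diag = [float(np.linalg.norm(v)) for v in vecs]
            return tuple(diag[::-1])
    return None


def write(path, array: np.ndarray, spacing=None, encoding: str = "raw") -> None:
    """Write ``array`` (C order) as NRRD0004; ``spacing`` ordered like numpy axes."""
    path = Path(path)
    array = np.ascontiguousarray(array)
    if array.dtype not in _INV_TYPE:
        raise ValueError(f"unsupported dtype {array.dtype} for NRRD output")
    lines = [
        "NRRD0004",
        f"type: {_INV_TYPE[array.dtype]}",
        f"dimension: {array.ndim}",
        "sizes: " + " ".join(str(s) for s in array.shape[::-1]),
        f"encoding: {encoding}",
        "endian: little",
    ]
    if spacing is not None:
        lines.append("spacings: " + " ".join(f"{s:.10g}" for s in spacing[::-1]))
    payload = array.astype(array.dtype.newbyteorder("<")).tobytes()
    if encoding == "gzip":
        payload = gzip.compress(payload)
    elif encoding != "raw":
        raise ValueError(f"unsupported NRRD encoding {encoding!r}")
    with open(path, "wb") as fh:
        fh.write(("\n".join(lines) + "\n\n").encode("ascii"))
        fh.write(payload)
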