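"""Minimal NRRD0004 reader/writer (raw little-endian encoding only).

Covers exactly what the phantom I/O needs: 3-D arrays of float32 or int16
with axis spacings and an origin. Not a general NRRD implementation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_TYPES = {"float": np.float32, "short": np.int16, "int": np.int32,
          "double": np.float64}
_NAMES = {np.dtype(np.float32): "float", np.dtype(np.int16): "short",
          np.dtype(np.int32): "int", np.dtype(np.float64): "double"}


def write(path: str | Path, array: np.ndarray, spacing, origin) -> None:
    array = np.ascontiguousarray(array)
    if array.dtype not in _NAMES:
        raise ValueError(f"unsupported dtype {array.dtype}")
    spacings = " ".join(f"{s:.9g}" for s in spacing)
    org = ",".join(f"{o:.9g}" for o in origin)
    header = (
        "NRRD0004\n"
        f"type: {_NAMES[array.dtype]}\n"
        f"dimension: {array.ndim}\n"
        f"sizes: {' '.join(str(s) for s in array.shape)}\n"
        f"spacings: {spacings}\n"
        "endian: little\n"
        "encoding: raw\n"
        f"space origin: ({org})\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode())
        # NRRD raw data is fastest-axis-first; our arrays are C-ordered with
        # the last axis fastest, so write Fortran order to keep sizes[0] fastest.
        fh.write(np.asfortranarray(array).tobytes(order="F"))


def read(path: str | Path):
    with open(path, "rb") as fh:
        blob = fh.read()
    head, _, data = blob.partition(b"\n\n")
    fields: dict[str, str] = {}
    lines = head.decode().splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ValueError(f"{path}: not an NRRD file")
    for line in lines[1:]:
        if ":" in line and not line.startswith("#"):
            key, _, val = line.partition(":")
            fields[key.strip()] = val.strip()
    if fields.get("encoding") != "raw":
        raise ValueError("only raw encoding is supported")
    dtype = _TYPES[fields["type"]]
    sizes = tuple(int(s) for s in fields["sizes"].split())
    spacing = np.array([float(s) for s in fields.get("spacings", "1 1 1").split()])
    origin = np.zeros(len(sizes))
    if "space origin" in fields:
        origin = np.array(
            [float(v) for v in fields["space origin"].strip("()").split(",")]
        )
    arr = np.frombuffer(data, dtype=dtype, count=int(np.prod(sizes)))
    return arr.reshape(sizes, order="F").copy(), spacing, origin
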