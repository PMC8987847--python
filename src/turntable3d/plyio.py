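"""Minimal binary-little-endian PLY reader/writer for provenance-tagged clouds.

Vertices carry x, y, z as float64 millimeters plus two uchar provenance
fields: the source camera id and the point kind code.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_HEADER = """ply
format binary_little_endian 1.0
comment units mm
element vertex {n}
property double x
property double y
property double z
property uchar camera
property uchar kind
end_header
"""

_DTYPE = np.dtype(
    [("x", "<f8"), ("y", "<f8"), ("z", "<f8"), ("camera", "u1"), ("kind", "u1")]
)


def write_ply(
    path: str | Path, xyz_mm: np.ndarray, camera: np.ndarray, kind: np.ndarray
) -> None:
    xyz_mm = np.asarray(xyz_mm, dtype=float).reshape(-1, 3)
    n = len(xyz_mm)
    rec = np.empty(n, dtype=_DTYPE)
    rec["x"], rec["y"], rec["z"] = xyz_mm[:, 0], xyz_mm[:, 1], xyz_mm[:, 2]
    rec["camera"] = np.asarray(camera, dtype=np.uint8)
    rec["kind"] = np.asarray(kind, dtype=np.uint8)
    with open(path, "wb") as fh:
        fh.write(_HEADER.format(n=n).encode("ascii"))
        fh.write(rec.tobytes())


def read_ply(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (xyz (N,3) float64, camera (N,) uint8, kind (N,) uint8)."""
    raw = Path(path).read_bytes()
    end = raw.index(b"end_header\n") + len(b"end_header\n")
    header = raw[:end].decode("ascii")
    if "format binary_little_endian 1.0" not in header:
        raise ValueError("unsupported PLY format")
    n = 0
    for line in header.splitlines():
        if line.startswith("element vertex"):
            n = int(line.split()[-1])
    rec = np.frombuffer(raw[end : end + n * _DTYPE.itemsize], dtype=_DTYPE)
    xyz = np.stack([rec["x"], rec["y"], rec["z"]], axis=1)
    return xyz, rec["camera"].copy(), rec["kind"].copy()
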