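"""Voltage-movie container: space x time membrane-potential recordings.

Movies are stored on disk as a flat little-endian binary array plus a JSON
sidecar carrying shape, sampling metadata and provenance; the same format
is produced by the solver and by the synthetic fixture generators, so every
analysis accepts either interchangeably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SCHEMA_VERSION = 1


class MovieIOError(IOError):
    pass


@dataclass
class VoltageMovie:
    """Membrane potential sampled on a regular lattice.

    ``data`` has shape ``(n_frames, *spatial_shape)``; frame ``k`` is the
    potential at time ``t0 + k * sample_dt`` (ms).  ``dx`` is the node
    spacing in cm (0 for a single cell).
    """

    data: np.ndarray
    sample_dt: float
    dx: float = 0.04
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[1:]

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.spatial_shape))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.sample_dt * np.arange(self.n_frames)

    @property
    def duration(self) -> float:
        return self.sample_dt * (self.n_frames - 1)

    def trace(self, node) -> np.ndarray:
        """Voltage time course at one node (flat index or index tuple)."""
        flat = self.data.reshape(self.n_frames, -1)
        if isinstance(node, tuple):
            node = int(np.ravel_multi_index(node, self.spatial_shape))
        return np.asarray(flat[:, node], float)

    def window(self, t_start: float, t_end: float) -> "VoltageMovie":
        """Sub-movie covering [t_start, t_end] (ms, absolute times)."""
        i0 = int(np.ceil((t_start - self.t0) / self.sample_dt - 1e-9))
        i1 = int(np.floor((t_end - self.t0) / self.sample_dt + 1e-9)) + 1
        if i0 < 0 or i1 > self.n_frames:
            raise ValueError("requested window outside the recording")
        return VoltageMovie(self.data[i0:i1], self.sample_dt, self.dx,
                            self.t0 + i0 * self.sample_dt, dict(self.meta))

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        arr = np.ascontiguousarray(self.data)
        arr.astype(arr.dtype.newbyteorder("<")).tofile(path.with_suffix(".bin"))
        sidecar = {
            "schema_version": SCHEMA_VERSION,
            "shape": list(arr.shape),
            "dtype": arr.dtype.str.replace(">", "<"),
            "sample_dt": self.sample_dt,
            "dx": self.dx,
            "t0": self.t0,
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "VoltageMovie":
        path = Path(path)
        side = path.with_suffix(".json")
        if not side.exists():
            raise MovieIOError(f"missing sidecar {side}")
        sc = json.loads(side.read_text())
        version = sc.get("schema_version")
        if version != SCHEMA_VERSION:
            raise MovieIOError(
                f"unsupported movie schema version {version!r} "
                f"(expected {SCHEMA_VERSION})")
        shape = tuple(sc["shape"])
        dtype = np.dtype(sc["dtype"])
        binpath = path.with_suffix(".bin")
        expected = int(np.prod(shape)) * dtype.itemsize
        actual = binpath.stat().st_size if binpath.exists() else -1
        if actual != expected:
            raise MovieIOError(
                f"corrupt movie data {binpath}: expected {expected} bytes, "
                f"found {actual}")
        data = np.fromfile(binpath, dtype=dtype).reshape(shape)
        return cls(data=data, sample_dt=sc["sample_dt"], dx=sc["dx"],
                   t0=sc.get("t0", 0.0), meta=sc.get("meta", {}))

    def to_csv(self, path, node=0) -> None:
        """Export a single-node trace as CSV (time_ms, v_mV)."""
        import pandas as pd

        pd.DataFrame({"time_ms": self.times,
                      "v_mV": self.trace(node)}).to_csv(path, index=False)
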