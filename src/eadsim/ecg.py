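"""Pseudo-ECG: far-field potentials in an infinite homogeneous conductor.

A torso-free surrogate for body-surface ECG: the unipolar potential of an
electrode at position e is the volume sum of the transmembrane current
dipole density against the lead field of a point electrode,

    phi(e, t) = - sum_nodes D grad V(x, t) . grad_x (1 / |x - e|) dV,

which is linear in V, vanishes for uniform fields, and decays as 1/r^2
for a compact dipolar source.  It reproduces amplitude and rhythm
contrasts between excitation regimes but carries no torso anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .movie import VoltageMovie
from .tissue import ConductivityField, TissueGrid

__all__ = ["ElectrodeSet", "hemisphere_electrodes", "compute_pseudo_ecg"]


@dataclass
class ElectrodeSet:
    """Named electrode positions (cm), outside the tissue bounding box."""

    positions: np.ndarray  # (n, 3)
    names: list

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        if self.positions.shape[1] != 3:
            raise ValueError("electrode positions must be 3D (cm)")
        if len(self.names) != len(self.positions):
            raise ValueError("one name per electrode required")


def validate_electrodes(electrodes: ElectrodeSet, grid: TissueGrid) -> None:
    lo = -grid.dx
    hi = np.array([(s - 1) * grid.dx + grid.dx for s in grid.shape] + [grid.dx] * (3 - grid.ndim))
    for pos, name in zip(electrodes.positions, electrodes.names):
        inside = all(lo < pos[a] < hi[a] for a in range(3))
        if inside:
            raise ValueError(f"electrode {name!r} lies inside the tissue "
                             "bounding box")


def hemisphere_electrodes(grid: TissueGrid, height: float = 4.0,
                          n: int = 9) -> ElectrodeSet:
    """n electrodes on a spherical cap ``height`` cm above the tissue center.

    The layout loosely mirrors a 9-lead concept (one zenith electrode plus
    a ring) but carries no torso-anatomical meaning.
    """
    center = np.array([(s - 1) * grid.dx / 2 for s in grid.shape]
                      + [0.0] * (3 - grid.ndim))
    top = center + np.array([0.0, 0.0, height])
    positions = [top]
    names = ["E0"]
    ring = n - 1
    for k in range(ring):
        ang = 2 * np.pi * k / ring
        positions.append(center + np.array([
            0.6 * height * np.cos(ang), 0.6 * height * np.sin(ang),
            0.8 * height]))
        names.append(f"E{k + 1}")
    return ElectrodeSet(positions=np.array(positions), names=names)


def compute_pseudo_ecg(movie: VoltageMovie, grid: TissueGrid,
                       cond: ConductivityField,
                       electrodes: ElectrodeSet) -> dict:
    """Electrogram trace per electrode (arbitrary units, time as the movie).

    Returns ``{name: np.ndarray}``; the sign convention makes a plane wave
    travelling toward an electrode produce a positive deflection during
    its approach.
    """
    validate_electrodes(electrodes, grid)
    shape = grid.shape
    nd = grid.ndim
    dx = grid.dx
    flat_in = grid.inside.ravel()
    tens = cond.tensors.reshape(grid.n_nodes, 3, 3)

    coords = np.stack(np.meshgrid(
        *[np.arange(s) * dx for s in shape], indexing="ij"),
        axis=-1).reshape(-1, nd)
    coords3 = np.zeros((grid.n_nodes, 3))
    coords3[:, :nd] = coords

    out = {name: np.zeros(movie.n_frames) for name in electrodes.names}
    lead = []
    for pos in electrodes.positions:
        rvec = coords3 - pos[None, :]
        r = np.linalg.norm(rvec, axis=1)
        lead.append(rvec / r[:, None] ** 3)   # (x - e)/r^3 = -grad(1/r)

    dV = grid.dx ** nd
    frames = np.asarray(movie.data.reshape(movie.n_frames, *shape), float)
    for k in range(movie.n_frames):
        grads = np.gradient(frames[k], dx) if nd > 1 else \
            [np.gradient(frames[k], dx)]
        g3 = np.zeros((grid.n_nodes, 3))
        for a in range(nd):
            g3[:, a] = grads[a].reshape(-1)
        j = np.einsum("nij,nj->ni", tens, g3)   # D grad V
        j[~flat_in] = 0.0
        for name, lf in zip(electrodes.names, lead):
            out[name][k] = float(np.sum(j * lf) * dV)
    return out


def ecg_to_csv(traces: dict, times: np.ndarray, path) -> None:
    import pandas as pd

    df = pd.DataFrame({"time_ms": times, **traces})
    df.to_csv(path, index=False)
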