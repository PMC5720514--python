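"""Initiation protocols and the tissue-decoupling experiment.

Two protocols generate the excitation patterns:

* **burst pacing** -- an S1 stimulus is delivered to an edge region every
  time a probe point (adjacent to the stimulated region, so it reflects
  propagated recovery) falls below -60 mV during the first 4 s; the
  pattern then evolves freely for 2 more seconds.  The pacing frequency is
  therefore set by the local action-potential duration.  A refractory
  lockout (default 100 ms) bounds the retry rate when a stimulus fails to
  capture partially recovered tissue.
* **S1S2** -- a plane wave from one edge followed by a cross-field S2 over
  a quarter-plane inside the S1 wake, producing a free spiral tip when the
  S2 lands in the vulnerable window.

The decoupling experiment continues a running pattern after severing all
links across orthogonal planes: diffusion-mediated (real) waves are
absorbed at the new impermeable walls and sealed compartments without a
source fall silent, while phase waves -- apparent propagation across a
field of autonomous oscillators -- continue across the walls with
unchanged activation lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell_model import ModelParams
from .movie import VoltageMovie
from .tissue import (StimEvent, TissueGrid, conductivity_from_fibers,
                     insert_walls, run_simulation)

__all__ = ["ProtocolSpec", "run_burst_pacing", "run_s1s2", "S1S2Result",
           "run_decoupling_test", "classify_decoupling", "DecouplingResult"]


@dataclass
class ProtocolSpec:
    """Configuration of one initiation protocol."""

    kind: str = "burst"              # burst | s1s2 | decouple
    probe: tuple | int | None = None
    pace_window: float = 4000.0      # ms of triggered S1 pacing
    free_window: float = 2000.0      # ms of free evolution afterwards
    stim_amplitude: float = -52.0    # pA/pF
    stim_duration: float = 2.0       # ms
    stim_width: float = 0.2          # cm depth of the S1 edge region
    lockout: float = 100.0           # ms between S1 trigger attempts
    s2_timing: float | None = None   # ms; scanned automatically when None
    sample_dt: float = 1.0

    def __post_init__(self):
        if self.kind == "burst" and self.pace_window + self.free_window < 6000.0:
            raise ValueError("burst protocol requires a total of >= 6 s")


def _edge_region(grid: TissueGrid, width_cm: float) -> np.ndarray:
    """Flat indices of the first-axis edge strip of the given depth."""
    n = max(1, int(round(width_cm / grid.dx)))
    idx = np.arange(grid.n_nodes).reshape(grid.shape)
    return idx[:n].ravel() if grid.ndim == 1 else idx[:n].reshape(-1)


def _default_probe(grid: TissueGrid, width_cm: float):
    """A node just beyond the stimulated strip, centered transversally."""
    if grid.n_nodes == 1:
        return 0
    n = max(1, int(round(width_cm / grid.dx)))
    coord = [min(n + 2, grid.shape[0] - 1)]
    coord += [s // 2 for s in grid.shape[1:]]
    return grid.flat_index(tuple(coord))


def run_burst_pacing(grid: TissueGrid, params: ModelParams,
                     spec: ProtocolSpec | None = None, *, cond=None,
                     dt: float = 0.02):
    """Run the burst-pacing protocol; returns the full-length SimResult."""
    spec = spec or ProtocolSpec(kind="burst")
    if spec.kind != "burst":
        raise ValueError("spec.kind must be 'burst'")
    stim_nodes = _edge_region(grid, spec.stim_width)
    probe = spec.probe
    if probe is None:
        probe = _default_probe(grid, spec.stim_width)
    elif isinstance(probe, tuple):
        probe = grid.flat_index(probe)
    if not grid.inside.ravel()[probe]:
        raise ValueError("probe outside the tissue mask")
    duration = spec.pace_window + spec.free_window
    return run_simulation(
        grid, params, duration, cond=cond, dt=dt, sample_dt=spec.sample_dt,
        burst=dict(nodes=stim_nodes, probe=probe,
                   pace_window=spec.pace_window,
                   amplitude=spec.stim_amplitude,
                   stim_duration=spec.stim_duration,
                   lockout=spec.lockout),
    )


@dataclass
class S1S2Result:
    movie: VoltageMovie
    states: np.ndarray
    success: bool
    s2_timing: float | None
    n_singularities: int = 0


def _quarter_region(grid: TissueGrid) -> np.ndarray:
    """Lower-left quadrant (first halves of the first two axes)."""
    idx = np.arange(grid.n_nodes).reshape(grid.shape)
    sl = [slice(None)] * grid.ndim
    sl[0] = slice(0, grid.shape[0] // 2)
    sl[1] = slice(0, grid.shape[1] // 2)
    return idx[tuple(sl)].ravel()


def run_s1s2(grid: TissueGrid, params: ModelParams,
             spec: ProtocolSpec | None = None, *, cond=None,
             duration: float = 5000.0, dt: float = 0.02,
             scan: tuple = (240.0, 400.0, 20.0)) -> S1S2Result:
    """S1 plane wave plus cross-field S2; spiral when S2 hits the window.

    If ``spec.s2_timing`` is None the S1 wake is scanned (coarse steps of
    ``scan``) until an S2 produces a persistent phase singularity.  A
    failed S2 is reported via ``success=False``, not an error.
    """
    from .phase import phase_movie, track_filaments

    if grid.ndim < 2:
        raise ValueError("S1S2 needs a 2D sheet or 3D slab")
    spec = spec or ProtocolSpec(kind="s1s2")
    s1_nodes = _edge_region(grid, spec.stim_width)
    s2_nodes = _quarter_region(grid)
    timings = ([spec.s2_timing] if spec.s2_timing is not None
               else list(np.arange(*scan)))
    best = None
    for t2 in timings:
        events = (
            StimEvent(nodes=s1_nodes, start=1.0,
                      duration=spec.stim_duration,
                      amplitude=spec.stim_amplitude),
            StimEvent(nodes=s2_nodes, start=t2,
                      duration=spec.stim_duration,
                      amplitude=spec.stim_amplitude),
        )
        res = run_simulation(grid, params, duration, cond=cond, dt=dt,
                             sample_dt=spec.sample_dt, events=events)
        mov = res.movie
        try:
            pm = phase_movie(mov.window(duration - 1000.0, duration))
            fils = track_filaments(pm)
        except ValueError:
            fils = []
        success = len(fils) >= 1
        out = S1S2Result(movie=mov, states=res.states, success=success,
                         s2_timing=t2, n_singularities=len(fils))
        if success:
            return out
        best = out
    return best


@dataclass
class DecouplingResult:
    label: str                       # real_wave | phase_wave
    compartment_active: list = field(default_factory=list)
    max_lag_shift_ms: float = 0.0


def classify_decoupling(walled: VoltageMovie, planes,
                        control: VoltageMovie | None = None,
                        amp_threshold: float = 10.0,
                        active_fraction: float = 0.5) -> DecouplingResult:
    """Decide real-wave vs phase-wave from the post-decoupling recording.

    Phase waves require (a) every wall-bounded compartment to stay active
    (peak-to-peak amplitude >= ``amp_threshold`` mV at >= ``active_fraction``
    of its nodes) and (b), when a no-wall ``control`` continuation is
    supplied, the activation sequence of node pairs straddling each wall to
    be unchanged within one sample interval.  Diffusion-mediated activity
    fails (a): it cannot re-enter a sealed compartment lacking a source.
    """
    shape = walled.spatial_shape
    nd = len(shape)
    # compartment decomposition from the wall planes
    edges = [[0, s] for s in shape]
    for axis, pos in planes:
        cut = int(np.floor(pos / walled.dx)) + 1
        edges[axis].append(cut)
    slabs = [sorted(set(e)) for e in edges]
    flat = np.asarray(walled.data.reshape(walled.n_frames, -1), float)
    ptp = (flat.max(axis=0) - flat.min(axis=0)).reshape(shape)

    active = []
    for corner in np.ndindex(*[len(s) - 1 for s in slabs]):
        sl = tuple(slice(slabs[a][corner[a]], slabs[a][corner[a] + 1])
                   for a in range(nd))
        frac = (ptp[sl] >= amp_threshold).mean()
        active.append(bool(frac >= active_fraction))
    if not all(active):
        return DecouplingResult("real_wave", compartment_active=active)

    max_shift = 0.0
    if control is not None:
        cflat = np.asarray(control.data.reshape(control.n_frames, -1), float)
        for axis, pos in planes:
            cut = int(np.floor(pos / walled.dx))
            for other in np.ndindex(*[s for a, s in enumerate(shape)
                                      if a != axis]):
                ia = list(other)
                ia.insert(axis, cut)
                ib = list(other)
                ib.insert(axis, cut + 1)
                fa = int(np.ravel_multi_index(ia, shape))
                fb = int(np.ravel_multi_index(ib, shape))
                lag_w = _xcorr_lag(flat[:, fa], flat[:, fb])
                lag_c = _xcorr_lag(cflat[:, fa], cflat[:, fb])
                max_shift = max(max_shift,
                                abs(lag_w - lag_c) * walled.sample_dt)
        if max_shift > walled.sample_dt + 1e-9:
            return DecouplingResult("real_wave", compartment_active=active,
                                    max_lag_shift_ms=max_shift)
    return DecouplingResult("phase_wave", compartment_active=active,
                            max_lag_shift_ms=max_shift)


def _xcorr_lag(a, b, max_lag: int = 100) -> int:
    a = a - a.mean()
    b = b - b.mean()
    lags = range(-max_lag, max_lag + 1)
    vals = [np.dot(a[max(0, -k):len(a) - max(0, k)],
                   b[max(0, k):len(b) - max(0, -k)]) for k in lags]
    return list(lags)[int(np.argmax(vals))]


def run_decoupling_test(states: np.ndarray, grid: TissueGrid,
                        params: ModelParams, planes, *,
                        duration: float = 1000.0, cond=None,
                        with_control: bool = True,
                        dt: float = 0.02) -> DecouplingResult:
    """Insert impermeable walls into a running pattern and classify it.

    ``states`` is the final state array of a previous simulation.  The
    simulation is continued for ``duration`` ms with the walls in place
    (and, optionally, once more without walls as the lag-control run).
    """
    walled_grid = insert_walls(grid, planes)
    if cond is None:
        cond = conductivity_from_fibers(grid)
    walled = run_simulation(walled_grid, params, duration, cond=cond, dt=dt,
                            states=states.copy(), sample_dt=1.0)
    control = None
    if with_control:
        control = run_simulation(grid, params, duration, cond=cond, dt=dt,
                                 states=states.copy(), sample_dt=1.0).movie
    return classify_decoupling(walled.movie, planes, control=control)
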