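"""Hilbert-phase reconstruction, singularity detection, filament tracking.

EAD-deformed action potentials make the classical isopotential/zero-
derivative definition of a spiral core ambiguous, so the phase is built to
be robust to plateau oscillations:

1. the trace is smoothed by a local 3rd-order polynomial (Savitzky-Golay)
   over a 102 ms frame;
2. the relative minima and maxima of the smoothed trace are joined by
   monotone piecewise-cubic Hermite envelopes and their midline is
   subtracted from the raw trace, pulling every oscillation (full AP or
   EAD) around a common equilibrium;
3. the phase is the angle of the analytic signal (trace, Hilbert(trace)),
   in [-pi, pi], so each AP and each EAD contributes one full 2 pi cycle.

Phase singularities are points where all phases meet; they are located per
2D slice as lattice plaquettes whose wrapped phase circulation is +/- 2 pi
(topological charge +/- 1), then clustered and linked over time into
filaments.  Only filaments outliving one rotation (200 ms) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks, hilbert, savgol_filter

from .movie import VoltageMovie

__all__ = [
    "PhaseMovie", "Filament",
    "detrend_trace", "compute_phase", "phase_movie",
    "detect_singularities", "track_filaments", "filament_table",
]

SMOOTH_FRAME_MS = 102.0
POLY_ORDER = 3


def detrend_trace(trace: np.ndarray, sample_dt: float = 1.0):
    """Center a voltage trace on its oscillation midline.

    Returns ``(centered, fallback)``; ``fallback`` is True when fewer than
    two maxima/minima were found and plain mean subtraction was used.
    """
    trace = np.asarray(trace, float)
    if trace.size * sample_dt < 300.0:
        raise ValueError("trace shorter than 300 ms")
    win = int(round(SMOOTH_FRAME_MS / sample_dt))
    if win % 2 == 0:
        win += 1  # odd sample count centred on each point
    win = min(win, trace.size - (trace.size + 1) % 2)
    smooth = savgol_filter(trace, win, POLY_ORDER)

    # find_peaks is plateau-aware: symmetric sampling around an extremum
    # produces equal neighbours that strict comparisons would miss
    imax = find_peaks(smooth)[0]
    imin = find_peaks(-smooth)[0]
    if imax.size < 2 or imin.size < 2:
        return trace - trace.mean(), True
    t = np.arange(trace.size)
    upper = PchipInterpolator(imax, smooth[imax], extrapolate=False)(t)
    lower = PchipInterpolator(imin, smooth[imin], extrapolate=False)(t)
    # hold envelope values constant outside the outermost extrema
    upper = _fill_edges(upper, smooth[imax][0], smooth[imax][-1])
    lower = _fill_edges(lower, smooth[imin][0], smooth[imin][-1])
    midline = 0.5 * (upper + lower)
    return trace - midline, False


def _fill_edges(arr, left, right):
    out = arr.copy()
    isnan = np.isnan(out)
    if isnan.any():
        first = np.argmax(~isnan)
        last = len(out) - 1 - np.argmax(~isnan[::-1])
        out[:first] = left
        out[last + 1:] = right
    return out


def compute_phase(centered: np.ndarray) -> np.ndarray:
    """Instantaneous phase in [-pi, pi] of a zero-mean trace."""
    return np.angle(hilbert(np.asarray(centered, float)))


def phase_movie(movie: VoltageMovie) -> "PhaseMovie":
    """Per-node detrended Hilbert phase of a voltage movie."""
    flat = np.asarray(movie.data.reshape(movie.n_frames, -1), float)
    ph = np.empty_like(flat)
    for j in range(flat.shape[1]):
        centered, _ = detrend_trace(flat[:, j], movie.sample_dt)
        ph[:, j] = compute_phase(centered)
    return PhaseMovie(data=ph.reshape(movie.data.shape),
                      sample_dt=movie.sample_dt, dx=movie.dx, t0=movie.t0)


@dataclass
class PhaseMovie:
    """Phase per node per sample, values in [-pi, pi]."""

    data: np.ndarray
    sample_dt: float
    dx: float = 0.04
    t0: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[1:]


def _wrap(a):
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def detect_singularities(phase_slice: np.ndarray, charge_min: float = 0.9):
    """Phase singularities of a 2D phase field.

    The topological charge of every lattice plaquette is the closed-loop
    sum of wrapped phase differences around its four edges divided by
    2 pi; plaquettes with |charge| >= ``charge_min`` are reported as
    ``(location, charge)`` with the location at the plaquette center
    (fractional node coordinates).
    """
    p = np.asarray(phase_slice, float)
    if p.ndim != 2:
        raise ValueError("expected a 2D phase slice")
    dx0 = _wrap(np.diff(p, axis=0))  # p[i+1,j] - p[i,j]
    dx1 = _wrap(np.diff(p, axis=1))
    # counter-clockwise circulation around plaquette (i..i+1, j..j+1)
    circ = (dx0[:, :-1]            # (i,j)   -> (i+1,j)
            + dx1[1:, :]           # (i+1,j) -> (i+1,j+1)
            - dx0[:, 1:]           # (i+1,j+1) -> (i,j+1)
            - dx1[:-1, :])         # (i,j+1) -> (i,j)
    charge = circ / (2.0 * np.pi)
    ii, jj = np.nonzero(np.abs(charge) >= charge_min)
    return [((float(i) + 0.5, float(j) + 0.5), int(np.sign(charge[i, j])))
            for i, j in zip(ii, jj)]


@dataclass
class Filament:
    """A tracked phase singularity: birth/death times and trajectory."""

    track: list = field(default_factory=list)  # [(time_ms, location array)]
    charge: int = 0

    @property
    def birth(self) -> float:
        return self.track[0][0]

    @property
    def death(self) -> float:
        return self.track[-1][0]

    @property
    def lifetime(self) -> float:
        return self.death - self.birth

    @property
    def mean_location(self) -> np.ndarray:
        return np.mean([loc for _, loc in self.track], axis=0)


def _frame_points(phase: PhaseMovie, frame: int, slice_stride: int,
                  charge_min: float):
    """Singular points (possibly 3D) of one frame, before clustering."""
    data = phase.data[frame]
    if data.ndim == 2:
        return [(np.array(loc), q)
                for loc, q in detect_singularities(data, charge_min)]
    pts = []
    nd = data.ndim
    for axis in range(nd):
        for k in range(0, data.shape[axis], slice_stride):
            sl = [slice(None)] * nd
            sl[axis] = k
            plane = data[tuple(sl)]
            for loc, q in detect_singularities(plane, charge_min):
                full = np.empty(3)
                other = [a for a in range(nd) if a != axis]
                full[axis] = k
                full[other[0]] = loc[0]
                full[other[1]] = loc[1]
                pts.append((full, q))
    return pts


def _cluster(points, radius: float):
    """Greedy spatial clustering; returns (centroid, charge) per cluster."""
    out = []
    used = [False] * len(points)
    for i, (loc, q) in enumerate(points):
        if used[i]:
            continue
        members = [loc]
        charges = [q]
        used[i] = True
        for j in range(i + 1, len(points)):
            if used[j]:
                continue
            if np.linalg.norm(points[j][0] - loc) <= radius:
                members.append(points[j][0])
                charges.append(points[j][1])
                used[j] = True
        out.append((np.mean(members, axis=0), int(np.sign(sum(charges)) or q)))
    return out


def track_filaments(phase: PhaseMovie, slice_stride: int = 5,
                    window: tuple = (200.0, 800.0), min_life: float = 200.0,
                    cluster_radius: float = 2.0, link_radius: float = 3.0,
                    max_gap_ms: float = 10.0, charge_min: float = 0.9):
    """Track phase singularities through time and keep long-lived filaments.

    Works on the [200, 800] ms interior of a 1 s phase movie by default
    (edge effects of the Hilbert transform are excluded).  Per-frame
    singular points are clustered within ``cluster_radius`` nodes and
    linked to the nearest active track within ``link_radius`` nodes;
    tracks that survive longer than ``min_life`` ms are returned.
    """
    if phase.n_frames * phase.sample_dt < 1000.0 - 1e-9:
        raise ValueError("phase movie must cover at least 1 s")
    i0 = int(round(window[0] / phase.sample_dt))
    i1 = int(round(window[1] / phase.sample_dt))
    max_gap = max(1, int(round(max_gap_ms / phase.sample_dt)))

    active: list[Filament] = []
    gaps: list[int] = []
    done: list[Filament] = []
    for frame in range(i0, min(i1 + 1, phase.n_frames)):
        t = phase.t0 + frame * phase.sample_dt
        pts = _cluster(_frame_points(phase, frame, slice_stride, charge_min),
                       cluster_radius)
        unmatched = list(range(len(pts)))
        for k, fil in enumerate(active):
            last_loc = fil.track[-1][1]
            best, best_d = None, link_radius
            for m in unmatched:
                d = np.linalg.norm(pts[m][0] - last_loc)
                if d <= best_d:
                    best, best_d = m, d
            if best is not None:
                fil.track.append((t, pts[best][0]))
                gaps[k] = 0
                unmatched.remove(best)
            else:
                gaps[k] += 1
        # retire stale tracks
        keep = [g <= max_gap for g in gaps]
        done.extend(f for f, k in zip(active, keep) if not k)
        active = [f for f, k in zip(active, keep) if k]
        gaps = [g for g, k in zip(gaps, keep) if k]
        for m in unmatched:
            active.append(Filament(track=[(t, pts[m][0])], charge=pts[m][1]))
            gaps.append(0)
    done.extend(active)
    return [f for f in done if f.lifetime > min_life]


def filament_table(filaments):
    """Filament statistics as a DataFrame (CSV-ready)."""
    import pandas as pd

    rows = []
    for i, f in enumerate(filaments):
        loc = f.mean_location
        rows.append({
            "id": i, "birth_ms": f.birth, "death_ms": f.death,
            "lifetime_ms": f.lifetime, "charge": f.charge,
            **{f"mean_{ax}": float(x) for ax, x in zip("xyz", loc)},
        })
    return pd.DataFrame(rows)
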