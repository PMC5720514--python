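"""Synthetic voltage fields with known ground truth.

These generators emulate the statistical structure the analyses assume --
rotating spiral phase fields with known cores, plane waves, spatially
graded autonomous oscillators, and stylized AP traces with a prescribed
number of full action potentials and EAD oscillations -- so every analysis
stage can be tested exactly and cheaply, without tissue simulations.
All outputs are deterministic for a fixed spec; ``seed`` only drives
optional additive jitter.
"""

from __future__ import annotations

import numpy as np

from .movie import VoltageMovie

__all__ = ["spiral_phase_movie", "plane_wave_movie", "oscillator_field",
           "ap_trace"]


def _finalize(v, sample_dt, dx, seed, jitter, meta):
    if jitter > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, jitter, v.shape)
    return VoltageMovie(data=v.astype(np.float32), sample_dt=sample_dt,
                        dx=dx, meta=meta)


def spiral_phase_movie(shape=(60, 60), period: float = 200.0,
                       wavenumber: float = 0.2, cores=((30.0, 30.0, +1),),
                       drift=(0.0, 0.0), duration: float = 1000.0,
                       sample_dt: float = 1.0, amplitude: float = 25.0,
                       offset: float = -40.0, dx: float = 0.04,
                       seed: int = 0, jitter: float = 0.0):
    """Rotating Archimedean-spiral voltage movie with known core track.

    ``v(x, t) = offset + A cos(sum_c chi_c atan2(y-yc, x-xc) + k r - w t)``
    with rotation period ``period`` ms and radial wavenumber ``wavenumber``
    rad/node.  ``cores`` is a list of ``(x0, y0, chirality)`` in node
    units; ``drift`` (nodes/ms) moves every core linearly.  Returns
    ``(movie, truth)`` where ``truth["cores"][frame]`` lists the exact core
    positions.
    """
    nx, ny = shape
    t = np.arange(0.0, duration + sample_dt / 2, sample_dt)
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    omega = 2.0 * np.pi / period
    v = np.empty((t.size, nx, ny))
    truth = []
    for k, tk in enumerate(t):
        phase = -omega * tk
        ph = np.zeros((nx, ny))
        frame_cores = []
        for (x0, y0, chi) in cores:
            xc = x0 + drift[0] * tk
            yc = y0 + drift[1] * tk
            # sign such that the analytic (Hilbert) phase winds by +chi
            ph = ph - chi * np.arctan2(y - yc, x - xc)
            frame_cores.append((xc, yc, chi))
        r = np.hypot(x - frame_cores[0][0], y - frame_cores[0][1])
        v[k] = offset + amplitude * np.cos(ph + wavenumber * r + phase)
        truth.append(frame_cores)
    movie = _finalize(v, sample_dt, dx, seed, jitter,
                      {"kind": "synthetic_spiral", "period": period})
    return movie, {"cores": truth}


def plane_wave_movie(shape=(60, 60), period: float = 200.0,
                     wavelength_nodes: float = 30.0, axis: int = 0,
                     duration: float = 1000.0, sample_dt: float = 1.0,
                     amplitude: float = 25.0, offset: float = -40.0,
                     dx: float = 0.04, seed: int = 0, jitter: float = 0.0):
    """Sinusoidal plane wave travelling along a lattice axis (no cores)."""
    t = np.arange(0.0, duration + sample_dt / 2, sample_dt)
    coord = np.arange(shape[axis])
    k = 2.0 * np.pi / wavelength_nodes
    omega = 2.0 * np.pi / period
    prof = (k * coord)[None, :, None] if axis == 0 \
        else (k * coord)[None, None, :]
    v = offset + amplitude * np.cos(prof - omega * t[:, None, None])
    v = np.broadcast_to(v, (t.size,) + tuple(shape)).copy()
    return _finalize(v, sample_dt, dx, seed, jitter,
                     {"kind": "synthetic_plane_wave", "period": period})


def oscillator_field(shape=(60, 60), period: float = 200.0,
                     phase_gradient: float = 0.1, axis: int = 0,
                     duration: float = 1000.0, sample_dt: float = 1.0,
                     amplitude: float = 20.0, offset: float = -30.0,
                     dx: float = 0.04, seed: int = 0, jitter: float = 0.0):
    """Independent oscillators with a linear spatial phase gradient.

    Every node oscillates with the same ``period`` around ``offset``
    (floor above -60 mV by default: non-repolarizing), phase shifted by
    ``phase_gradient`` rad/node along ``axis``.  The field shows apparent
    traveling (phase) waves although no diffusive coupling exists, which
    is exactly the oscillatory-regime structure the decoupling test probes.
    """
    if offset - amplitude <= -59.0:
        raise ValueError("oscillator floor must stay above -59 mV")
    shape = tuple(np.atleast_1d(shape))
    t = np.arange(0.0, duration + sample_dt / 2, sample_dt)
    omega = 2.0 * np.pi / period
    coord = np.arange(shape[axis], dtype=float)
    ph = phase_gradient * coord
    full = ph.reshape([-1 if a == axis else 1 for a in range(len(shape))])
    v = offset + amplitude * np.sin(
        omega * t.reshape((-1,) + (1,) * len(shape)) - full[None])
    v = np.broadcast_to(v, (t.size,) + shape).copy()
    return _finalize(v, sample_dt, dx, seed, jitter,
                     {"kind": "synthetic_oscillators", "period": period})


def ap_trace(n_aps: int, n_eads_per_ap: int = 0, duration: float = 1000.0,
             sample_dt: float = 1.0, rest: float = -86.0, peak: float = 30.0,
             apd: float | None = None, seed: int = 0, jitter: float = 0.0):
    """Stylized single-cell trace with exact AP and EAD counts.

    Each AP: a half-cosine upstroke from rest to ``peak`` (5 ms), a plateau
    carrying ``n_eads_per_ap`` cosine oscillations that stay above -59 mV,
    and a half-cosine repolarization back to rest (20 ms) -- so the
    -60 +/- 1 mV band is crossed exactly once upward and once downward per
    AP, and every AP or EAD contributes one oscillation cycle.  APs are
    placed uniformly; overlap raises ValueError.
    """
    if n_aps < 0:
        raise ValueError("n_aps must be >= 0")
    t = np.arange(0.0, duration - sample_dt / 2, sample_dt)
    v = np.full(t.size, rest)
    if n_aps == 0:
        return _finalize(v.reshape(-1, 1), sample_dt, 0.0, seed, jitter,
                         {"kind": "synthetic_ap_trace", "n_aps": 0})
    spacing = duration / n_aps
    up, down = 20.0, 40.0
    ead_lo, ead_hi = -30.0, -5.0
    if apd is None:
        apd = 120.0 if n_eads_per_ap == 0 else 130.0 * n_eads_per_ap
    # monotone half-cosine segments (zero slope at both ends -> C1 chain):
    # rest -> peak, then per EAD a down/up swing, then back to rest
    if n_eads_per_ap > 0:
        seg_t = apd / (2 * n_eads_per_ap)
        values = [rest, peak]
        durs = [up]
        for _ in range(n_eads_per_ap):
            values += [ead_lo, ead_hi]
            durs += [seg_t, seg_t]
        values += [rest]
        durs += [down]
    else:
        values = [rest, peak, ead_lo, rest]
        durs = [up, apd, down]
    total = sum(durs)
    if total > spacing - 10.0:
        raise ValueError("APs would overlap: reduce apd or n_aps")
    for a in range(n_aps):
        t0 = a * spacing + 5.0
        for val0, val1, d in zip(values[:-1], values[1:], durs):
            m = (t >= t0) & (t < t0 + d)
            tau = (t[m] - t0) / d
            v[m] = val0 + (val1 - val0) * 0.5 * (1 - np.cos(np.pi * tau))
            t0 += d
    movie = _finalize(v.reshape(-1, 1), sample_dt, 0.0, seed, jitter,
                      {"kind": "synthetic_ap_trace", "n_aps": n_aps,
                       "n_eads_per_ap": n_eads_per_ap})
    return movie
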