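"""Quantitative pattern characterization.

Implements the toolkit used to tell the excitation regimes apart:

* the node-averaged temporal amplitude spectrum of the last second, with
  the beta (AP-to-AP) and alpha (EAD-to-EAD) peaks;
* the eta index, eta = x / (2 n): the number of -60 +/- 1 mV band transits
  per node per analysis window, halved to count one AP as one event.  A
  fully repolarizing 1 Hz-paced cell scores eta = number of APs; a
  non-repolarizing oscillator scores 0;
* the regime classifier (EE / S / MS / SB / B / A / O);
* the two tissue calibration measurements: planar conduction velocity and
  the electrotonic space constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.stats import linregress

from .movie import VoltageMovie

__all__ = [
    "SpectrumSummary", "EtaResult", "PatternLabel",
    "average_spectrum", "eta_index", "classify_pattern",
    "measure_cv", "measure_space_constant", "activation_time",
    "PropagationFailure",
]


class PropagationFailure(RuntimeError):
    pass


@dataclass
class SpectrumSummary:
    """Node-averaged amplitude spectrum with labelled peaks.

    ``peaks`` is a list of ``(frequency_Hz, prominence)`` sorted by
    prominence (descending).  ``beta_peak`` is the AP-to-AP peak (the
    lower-frequency member of the two leading sub-``fmax`` peaks) and
    ``alpha_peak`` the EAD-to-EAD peak (the higher-frequency member, or the
    single dominant peak of a pure oscillation).
    """

    freqs: np.ndarray
    mean_amplitude: np.ndarray
    peaks: list
    alpha_peak: float | None
    beta_peak: float | None

    @property
    def dominant_frequency(self) -> float | None:
        return self.peaks[0][0] if self.peaks else None


def average_spectrum(movie: VoltageMovie, n_sample: int = 2983,
                     window: float = 1000.0, fmax_pair: float = 6.5
                     ) -> SpectrumSummary:
    """Mean-subtracted amplitude spectrum averaged over sampled nodes.

    The spectrum is computed per node over the final ``window`` ms of the
    movie and averaged across ``n_sample`` equidistant nodes (flat index
    order).  Frequency resolution is 1/window, hence the 1 s minimum.
    """
    if window < 1000.0:
        raise ValueError("window must be at least 1 s (1 Hz resolution)")
    n_win = int(round(window / movie.sample_dt))
    if n_win > movie.n_frames:
        raise ValueError("window longer than the recording")
    flat = movie.data.reshape(movie.n_frames, -1)[-n_win:]
    n_nodes = flat.shape[1]
    n_sample = min(int(n_sample), n_nodes)
    sel = np.linspace(0, n_nodes - 1, n_sample).round().astype(int)
    seg = np.asarray(flat[:, sel], float)
    seg = seg - seg.mean(axis=0, keepdims=True)
    amp = np.abs(np.fft.rfft(seg, axis=0)) / n_win
    mean_amp = amp.mean(axis=1)
    freqs = np.fft.rfftfreq(n_win, movie.sample_dt * 1e-3)

    idx, props = signal.find_peaks(mean_amp, prominence=1e-3 * mean_amp.max()
                                   if mean_amp.max() > 0 else None)
    order = np.argsort(props["prominences"])[::-1] if idx.size else []
    peaks = [(float(freqs[idx[k]]), float(props["prominences"][k]))
             for k in order]

    # alpha/beta: the two most prominent peaks below fmax_pair
    low = [p for p in peaks if 0.0 < p[0] <= fmax_pair]
    alpha = beta = None
    if len(low) >= 2:
        f1, f2 = low[0][0], low[1][0]
        beta, alpha = (f1, f2) if f1 < f2 else (f2, f1)
    elif len(low) == 1:
        alpha = low[0][0]  # single peak: pure (EAD-like) oscillation
    return SpectrumSummary(freqs=freqs, mean_amplitude=mean_amp, peaks=peaks,
                           alpha_peak=alpha, beta_peak=beta)


@dataclass
class EtaResult:
    eta: float
    crossings_total: int
    n_nodes: int
    threshold: float = -60.0
    band: float = 1.0
    window: tuple = (0.0, 0.0)


def eta_index(movie: VoltageMovie, window: float = 1000.0,
              threshold: float = -60.0, band: float = 1.0,
              n_sample: int | None = None) -> EtaResult:
    """Count -60 +/- 1 mV band transits per node: eta = x / (2 n).

    A transit is a move from below ``threshold - band`` to above
    ``threshold + band`` or the reverse; the hysteresis band prevents
    double-counting sampling jitter on the threshold line.
    """
    n_win = int(round(window / movie.sample_dt))
    if n_win > movie.n_frames:
        raise ValueError("window longer than the recording")
    flat = np.asarray(movie.data.reshape(movie.n_frames, -1)[-n_win:], float)
    if n_sample is not None and n_sample < flat.shape[1]:
        sel = np.linspace(0, flat.shape[1] - 1, n_sample).round().astype(int)
        flat = flat[:, sel]
    lo = threshold - band
    hi = threshold + band
    n = flat.shape[1]
    # vectorized hysteresis counter: state +1 above hi, -1 below lo,
    # carried forward through the dead band; transits = state flips
    state = np.where(flat >= hi, 1, np.where(flat <= lo, -1, 0))
    x = 0
    cur = state[0].copy()
    for k in range(1, state.shape[0]):
        s = state[k]
        flip = (s != 0) & (cur != 0) & (s != cur)
        init = (s != 0) & (cur == 0)
        x += int(flip.sum())
        cur[flip | init] = s[flip | init]
    t1 = movie.t0 + movie.duration
    return EtaResult(eta=x / (2.0 * n), crossings_total=int(x), n_nodes=n,
                     threshold=threshold, band=band,
                     window=(t1 - window, t1))


@dataclass
class PatternLabel:
    label: str
    low_confidence: bool = False
    reasons: list = field(default_factory=list)


def classify_pattern(movie: VoltageMovie | None,
                     spectrum: SpectrumSummary | None = None,
                     eta: EtaResult | None = None,
                     filaments=None,
                     decouple_result=None,
                     *,
                     activity_threshold: float = 1.0,
                     eta_fraction: float = 0.5,
                     core_displacement_nodes: float = 2.0) -> PatternLabel:
    """Combine the pattern analyses into one regime label.

    Decision rules (applied in order):

    * **EE** -- no activity in the final window (peak-to-peak below
      ``activity_threshold`` mV everywhere);
    * **O** -- eta = 0 and the decoupling test reports phase waves (or, if
      no decoupling result is supplied, no node repolarizes below -60 mV);
    * **S / MS / SB** -- a single long-lived filament with small / large
      core displacement, or a filament count growing from one;
    * **A** -- the EAD (alpha) peak dominates the AP (beta) peak and eta is
      below ``eta_fraction`` of the beat count implied by the beta peak;
    * **B** -- eta positive with the beta peak at least as prominent as the
      alpha peak (typically alongside several short-lived filaments).

    Conflicting ingredients yield a best-effort label flagged
    ``low_confidence``.
    """
    reasons = []
    if movie is not None:
        flat = np.asarray(movie.data.reshape(movie.n_frames, -1), float)
        ptp = flat.max(axis=0) - flat.min(axis=0)
        if ptp.max() < activity_threshold:
            return PatternLabel("EE", reasons=["no activity in final window"])

    phase_wave = getattr(decouple_result, "label", decouple_result)
    if eta is not None and eta.eta == 0.0:
        if phase_wave == "phase_wave":
            return PatternLabel("O", reasons=["eta = 0", "phase waves"])
        if phase_wave is None and movie is not None:
            vmin = flat.min(axis=0)
            if (vmin > eta.threshold).all():
                return PatternLabel(
                    "O", reasons=["eta = 0", "no repolarization below -60 mV"])
        reasons.append("eta = 0 but decoupling does not show phase waves")

    if filaments is not None:
        fils = list(filaments)
        if len(fils) == 1:
            f = fils[0]
            track = np.asarray([loc for _, loc in f.track], float)
            disp = np.linalg.norm(track - track.mean(axis=0), axis=1).max() \
                if len(track) else 0.0
            if disp < core_displacement_nodes:
                return PatternLabel("S", reasons=["single stationary filament"])
            return PatternLabel("MS", reasons=["single meandering filament"])
        if len(fils) > 1:
            births = sorted(f.birth for f in fils)
            if births[0] == min(births) and len(set(births)) > 1 and \
                    sum(b == births[0] for b in births) == 1:
                reasons.append("filament count grew from a single spiral")
                if eta is None and spectrum is None:
                    return PatternLabel("SB", reasons=reasons)

    if spectrum is None or eta is None:
        return PatternLabel("unclassified", low_confidence=True,
                            reasons=reasons + ["missing ingredients"])

    alpha_prom = beta_prom = 0.0
    for f, prom in spectrum.peaks:
        if spectrum.alpha_peak is not None and f == spectrum.alpha_peak:
            alpha_prom = prom
        if spectrum.beta_peak is not None and f == spectrum.beta_peak:
            beta_prom = prom

    window_s = (eta.window[1] - eta.window[0]) * 1e-3
    if spectrum.beta_peak is not None:
        implied_beats = spectrum.beta_peak * window_s
    elif spectrum.alpha_peak is not None:
        implied_beats = spectrum.alpha_peak * window_s
    else:
        implied_beats = 0.0

    if spectrum.beta_peak is None and spectrum.alpha_peak is not None:
        # single sub-6 Hz peak without full repolarization anywhere: A-like
        label = "A" if eta.eta < eta_fraction * implied_beats else "B"
        return PatternLabel(label, low_confidence=True,
                            reasons=reasons + ["single spectral peak"])

    alpha_dominant = alpha_prom > beta_prom
    eta_low = eta.eta < eta_fraction * implied_beats
    if alpha_dominant and eta_low:
        return PatternLabel("A", reasons=reasons + [
            "alpha peak dominant", f"eta {eta.eta:.2f} below "
            f"{eta_fraction} x {implied_beats:.1f}"])
    if not alpha_dominant and eta.eta > 0:
        return PatternLabel("B", reasons=reasons + [
            "beta peak dominant", f"eta {eta.eta:.2f} > 0"])
    # ingredients disagree
    label = "A" if alpha_dominant else "B"
    return PatternLabel(label, low_confidence=True, reasons=reasons + [
        f"conflicting: alpha_dominant={alpha_dominant}, eta={eta.eta:.2f}"])


def activation_time(movie: VoltageMovie, node, threshold: float = -20.0):
    """First upstroke crossing of ``threshold`` (ms), linearly interpolated.

    Returns None if the node never activates.
    """
    v = movie.trace(node)
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    if up.size == 0:
        return None
    i = up[0]
    f = (threshold - v[i]) / (v[i + 1] - v[i])
    return float(movie.t0 + (i + f) * movie.sample_dt)


def measure_cv(cable_movie: VoltageMovie, x1: float, x2: float,
               threshold: float = -20.0) -> float:
    """Planar conduction velocity (cm/s) between two cable positions (cm)."""
    dx = cable_movie.dx
    n1 = int(round(x1 / dx))
    n2 = int(round(x2 / dx))
    t1 = activation_time(cable_movie, n1, threshold)
    t2 = activation_time(cable_movie, n2, threshold)
    if t1 is None or t2 is None:
        raise PropagationFailure("no activation at a probe position")
    if t2 == t1:
        raise PropagationFailure("zero conduction delay between probes")
    return float((n2 - n1) * dx / (t2 - t1) * 1000.0)


def measure_space_constant(grid, params, i_sub: float = -0.3,
                           *, cond=None, dl: float | None = None,
                           max_duration: float = 2000.0,
                           drift_tol: float = 0.01,
                           sub_threshold: float = -70.0) -> float:
    """Electrotonic space constant (um) of the resting cable.

    A sustained subthreshold current ``i_sub`` (pA/pF) is injected at the
    first node until steady state (|dV/dt| < ``drift_tol`` mV/ms at every
    node), then the decay length is fitted as the slope of ln(deflection)
    versus distance over the 10-90 % deflection range.
    """
    from .tissue import (StimEvent, conductivity_from_fibers, run_simulation)

    if cond is None:
        cond = conductivity_from_fibers(
            grid, dl=dl if dl is not None else 0.00154)
    ev = StimEvent(nodes=np.arange(1), start=0.0, duration=max_duration,
                   amplitude=i_sub)
    chunk = 200.0
    t = 0.0
    states = None
    while t < max_duration:
        res = run_simulation(grid, params, chunk, cond=cond, events=(
            StimEvent(nodes=ev.nodes, start=0.0, duration=chunk,
                      amplitude=i_sub),),
            states=states, sample_dt=chunk / 2)
        states = res.states
        mov = res.movie
        v_now = np.asarray(mov.data[-1], float).ravel()
        if (v_now > sub_threshold).any():
            raise ValueError("stimulus is suprathreshold: tissue exceeded "
                             f"{sub_threshold} mV")
        drift = np.abs(v_now - np.asarray(mov.data[-2], float).ravel()).max() \
            / (chunk / 2)
        t += chunk
        if drift < drift_tol:
            break
    # deflection relative to the simultaneous far-end level: the whole
    # cable drifts slowly, so the t=0 potential is not a valid reference
    dv = v_now - v_now[-1]
    dv_max = np.abs(dv).max()
    mask = (np.abs(dv) >= 0.1 * dv_max) & (np.abs(dv) <= 0.9 * dv_max)
    x = np.arange(grid.shape[0]) * grid.dx
    fit = linregress(x[mask], np.log(np.abs(dv[mask])))
    lam_cm = -1.0 / fit.slope
    return float(lam_cm * 1e4)  # um
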