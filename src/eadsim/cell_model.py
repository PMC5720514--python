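"""Modified TP06 human ventricular (endocardial) cell model.

The model is the ten Tusscher-Panfilov 2006 endocardial cell with a reduced
repolarization reserve: the L-type inactivation (f) gate time constant is
halved and the maximal L-type conductance G_CaL doubled, which together
leave the baseline action potential close to the original model while
making early afterdepolarizations (EADs) accessible.  Two dimensionless
multipliers, ``gkr_mult`` on G_Kr and ``gcal_mult`` on G_CaL, are then
applied *on top of this modified default* to scan the repolarization
reserve; ``(1.0, 1.0)`` is the default model.

Depending on the multipliers a paced cell shows one of three behaviours:
normal APs, APs deformed by EADs that still repolarize below -60 mV, or a
non-repolarizing oscillation around a depolarized equilibrium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from . import _kernels as K
from .movie import VoltageMovie

__all__ = [
    "ModelParams",
    "CellState",
    "CurrentBreakdown",
    "build_params",
    "resting_state",
    "step_cell",
    "simulate_cell",
    "classify_cell_regime",
    "BlowupError",
]

# Original TP06 maximal conductances (nS/pF) / permeability (cm^3 uF^-1 s^-1)
GNA_TP06 = 14.838
GK1_TP06 = 5.405
GTO_ENDO_TP06 = 0.073
GKR_TP06 = 0.153
GKS_ENDO_TP06 = 0.392
GCAL_TP06 = 3.980e-5
GPCA_TP06 = 0.1238
GPK_TP06 = 0.0146
GBNA_TP06 = 0.00029
GBCA_TP06 = 0.000592

#: TP06 steady resting state of the unpaced endocardial cell.
_REST = {
    "v": -86.2,
    "m": 0.0, "h": 0.75, "j": 0.75,
    "xr1": 0.0, "xr2": 1.0, "xs": 0.0,
    "r": 0.0, "s": 1.0,
    "d": 0.0, "f": 1.0, "f2": 1.0, "fcass": 1.0,
    "cai": 7.0e-5, "casr": 1.3, "cass": 7.0e-5,
    "nai": 7.67, "ki": 138.3, "r_quench": 1.0,
}

GATE_NAMES = ("m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2",
              "fcass")
CONC_NAMES = ("cai", "casr", "cass", "nai", "ki")


class BlowupError(RuntimeError):
    """Raised when the integrator produces a non-finite membrane potential."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"numerical blow-up at step {step}")


@dataclass(frozen=True)
class ModelParams:
    """Conductance set of the modified TP06 endocardial model.

    ``gkr_mult`` / ``gcal_mult`` are the repolarization-reserve multipliers;
    ``f_tau_scale`` and ``gcal_base_scale`` define the modified default
    model and are normally left alone.
    """

    gkr_mult: float = 1.0
    gcal_mult: float = 1.0
    f_tau_scale: float = 0.5
    gcal_base_scale: float = 2.0
    cm: float = 1.0  # uF/cm^2; currents are per unit capacitance
    g_na: float = GNA_TP06
    g_k1: float = GK1_TP06
    g_to: float = GTO_ENDO_TP06
    g_kr_base: float = GKR_TP06
    g_ks: float = GKS_ENDO_TP06
    g_cal_base: float = GCAL_TP06
    g_pca: float = GPCA_TP06
    g_pk: float = GPK_TP06
    g_bna: float = GBNA_TP06
    g_bca: float = GBCA_TP06
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.gkr_mult < 0 or self.gcal_mult < 0:
            raise ValueError("conductance multipliers must be non-negative")
        if self.f_tau_scale <= 0:
            raise ValueError("f_tau_scale must be positive")
        for name in ("g_na", "g_k1", "g_to", "g_kr_base", "g_ks",
                     "g_cal_base", "g_pca", "g_pk", "g_bna", "g_bca"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def g_kr(self) -> float:
        """Effective G_Kr (nS/pF)."""
        return self.gkr_mult * self.g_kr_base

    @property
    def g_cal(self) -> float:
        """Effective G_CaL: base permeability x default doubling x sweep."""
        return self.gcal_base_scale * self.gcal_mult * self.g_cal_base

    def kernel_array(self) -> np.ndarray:
        cp = np.empty(K.N_CP)
        cp[K.CP_GNA] = self.g_na
        cp[K.CP_GK1] = self.g_k1
        cp[K.CP_GTO] = self.g_to
        cp[K.CP_GKR] = self.g_kr
        cp[K.CP_GKS] = self.g_ks
        cp[K.CP_GCAL] = self.g_cal
        cp[K.CP_GPCA] = self.g_pca
        cp[K.CP_GPK] = self.g_pk
        cp[K.CP_GBNA] = self.g_bna
        cp[K.CP_GBCA] = self.g_bca
        return cp


def build_params(gkr_mult: float = 1.0, gcal_mult: float = 1.0,
                 **overrides) -> ModelParams:
    """Build parameters for a point of the repolarization-reserve sweep.

    The multipliers act on the modified default model, i.e. the effective
    L-type conductance is ``2.0 * gcal_mult`` times the original TP06 value
    and the effective G_Kr is ``gkr_mult`` times the TP06 value.  Values
    outside the study's sweep range (gkr_mult in [0, 1], gcal_mult in
    [1, 7]) are allowed but flagged with a warning.
    """
    if gkr_mult < 0 or gcal_mult < 0:
        raise ValueError("multipliers must be non-negative")
    if gkr_mult > 1.0 or gcal_mult > 7.0:
        warnings.warn(
            "multipliers outside the studied sweep range "
            f"(gkr_mult={gkr_mult}, gcal_mult={gcal_mult})",
            stacklevel=2,
        )
    p = ModelParams(gkr_mult=gkr_mult, gcal_mult=gcal_mult, **overrides)
    p.meta.update(
        multiplier_convention="applied to the modified default model",
        g_kr_effective=p.g_kr,
        g_cal_effective=p.g_cal,
    )
    return p


@dataclass
class CellState:
    """Full state of one cell: potential, HH gates, ionic concentrations."""

    v: float
    gates: dict
    concentrations: dict
    r_quench: float = 1.0  # closed fraction of ryanodine-release gates

    def as_array(self) -> np.ndarray:
        y = np.empty(K.N_VARS)
        y[K.IV] = self.v
        for i, g in enumerate(GATE_NAMES):
            y[K.IM + i] = self.gates[g]
        for i, c in enumerate(CONC_NAMES):
            y[K.ICAI + i] = self.concentrations[c]
        y[K.IRQ] = self.r_quench
        return y

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CellState":
        return cls(
            v=float(y[K.IV]),
            gates={g: float(y[K.IM + i]) for i, g in enumerate(GATE_NAMES)},
            concentrations={c: float(y[K.ICAI + i])
                            for i, c in enumerate(CONC_NAMES)},
            r_quench=float(y[K.IRQ]),
        )

    def validate(self):
        for g, val in self.gates.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"gate {g}={val} outside [0, 1]")
        for c, val in self.concentrations.items():
            if val <= 0:
                raise ValueError(f"concentration {c}={val} not positive")
        if not -100.0 <= self.v <= 80.0:
            raise ValueError(f"membrane potential {self.v} mV out of range")


def resting_state() -> CellState:
    """The published TP06 resting state, the standard initial condition."""
    return CellState(
        v=_REST["v"],
        gates={g: _REST[g] for g in GATE_NAMES},
        concentrations={c: _REST[c] for c in CONC_NAMES},
        r_quench=_REST["r_quench"],
    )


#: Quiescent equilibrium of the *modified default* model, obtained by
#: letting the cell settle for 60 s without stimulation.  The published
#: TP06 state is a paced steady state, so it relaxes slightly (~0.2 mV and
#: slow Na+/SR-load drift) when left unpaced.
_EQUILIBRIUM = {
    "v": -86.52066881,
    "m": 0.001303247196, "h": 0.7785445686, "j": 0.7785393574,
    "xr1": 0.000175834983, "xr2": 0.4845951525, "xs": 0.002950325485,
    "r": 1.948849587e-08, "s": 0.9999917365,
    "d": 2.839067185e-05, "f": 0.9999253707, "f2": 0.9995740418,
    "fcass": 0.9999955491,
    "cai": 3.410570802e-05, "casr": 0.3927219088, "cass": 0.0001361691163,
    "nai": 6.556111722, "ki": 139.8751076, "r_quench": 0.9970624572,
}


def equilibrium_state() -> CellState:
    """Quiescent equilibrium of the unpaced modified default model."""
    return CellState(
        v=_EQUILIBRIUM["v"],
        gates={g: _EQUILIBRIUM[g] for g in GATE_NAMES},
        concentrations={c: _EQUILIBRIUM[c] for c in CONC_NAMES},
        r_quench=_EQUILIBRIUM["r_quench"],
    )


@dataclass
class CurrentBreakdown:
    """All twelve membrane currents (pA/pF) plus their sum and the stimulus."""

    i_na: float
    i_k1: float
    i_to: float
    i_kr: float
    i_ks: float
    i_cal: float
    i_naca: float
    i_nak: float
    i_pca: float
    i_pk: float
    i_bca: float
    i_bna: float
    i_stim: float = 0.0

    @property
    def i_ion(self) -> float:
        return (self.i_na + self.i_k1 + self.i_to + self.i_kr + self.i_ks
                + self.i_cal + self.i_naca + self.i_nak + self.i_pca
                + self.i_pk + self.i_bca + self.i_bna)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "i_na", "i_k1", "i_to", "i_kr", "i_ks", "i_cal", "i_naca",
            "i_nak", "i_pca", "i_pk", "i_bca", "i_bna")}
        d["i_ion"] = self.i_ion
        d["i_stim"] = self.i_stim
        return d


def membrane_currents(state: CellState, params: ModelParams,
                      i_stim: float = 0.0) -> CurrentBreakdown:
    """Evaluate all membrane currents at the given state (plain numpy)."""
    v = state.v
    g = state.gates
    c = state.concentrations
    e = np.exp
    rtonf = K.RTONF

    ena = rtonf * np.log(K.NA_O / c["nai"])
    ek = rtonf * np.log(K.K_O / c["ki"])
    eks = rtonf * np.log((K.K_O + K.P_KNA * K.NA_O)
                         / (c["ki"] + K.P_KNA * c["nai"]))
    eca = 0.5 * rtonf * np.log(K.CA_O / c["cai"])

    i_na = params.g_na * g["m"] ** 3 * g["h"] * g["j"] * (v - ena)
    u = v - ek
    ak1 = 0.1 / (1.0 + e(0.06 * (u - 200.0)))
    bk1 = (3.0 * e(0.0002 * (u + 100.0)) + e(0.1 * (u - 10.0))) / (
        1.0 + e(-0.5 * u))
    i_k1 = params.g_k1 * K.SQRT_KO * ak1 / (ak1 + bk1) * u
    i_to = params.g_to * g["r"] * g["s"] * u
    i_kr = params.g_kr * K.SQRT_KO * g["xr1"] * g["xr2"] * u
    i_ks = params.g_ks * g["xs"] ** 2 * (v - eks)

    z = 2.0 * (v - 15.0) / rtonf
    if abs(z) < 1e-6:
        drive = 2.0 * K.FARADAY * (0.25 * c["cass"] - K.CA_O)
    else:
        ez = e(z)
        drive = (4.0 * (v - 15.0) * K.FARADAY / rtonf
                 * (0.25 * c["cass"] * ez - K.CA_O) / (ez - 1.0))
    i_cal = params.g_cal * g["d"] * g["f"] * g["f2"] * g["fcass"] * drive

    e1 = e(K.GAMMA_NACA * v / rtonf)
    e2 = e((K.GAMMA_NACA - 1.0) * v / rtonf)
    i_naca = (K.K_NACA
              * (e1 * c["nai"] ** 3 * K.CA_O
                 - e2 * K.NA_O ** 3 * c["cai"] * K.ALPHA_NACA)
              / ((K.KM_NAI ** 3 + K.NA_O ** 3) * (K.KM_CA + K.CA_O)
                 * (1.0 + K.K_SAT * e2)))
    fnak = 1.0 / (1.0 + 0.1245 * e(-0.1 * v / rtonf) + 0.0353 * e(-v / rtonf))
    i_nak = (K.P_NAK * K.K_O / (K.K_O + K.KM_K)
             * c["nai"] / (c["nai"] + K.KM_NA) * fnak)
    i_pca = params.g_pca * c["cai"] / (K.K_PCA + c["cai"])
    i_pk = params.g_pk * (v - ek) / (1.0 + e((25.0 - v) / 5.98))
    i_bna = params.g_bna * (v - ena)
    i_bca = params.g_bca * (v - eca)

    return CurrentBreakdown(
        i_na=float(i_na), i_k1=float(i_k1), i_to=float(i_to),
        i_kr=float(i_kr), i_ks=float(i_ks), i_cal=float(i_cal),
        i_naca=float(i_naca), i_nak=float(i_nak), i_pca=float(i_pca),
        i_pk=float(i_pk), i_bca=float(i_bca), i_bna=float(i_bna),
        i_stim=float(i_stim),
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------
_TABLE_CACHE: dict = {}


def get_tables(params: ModelParams, dt: float):
    key = (round(dt, 9), round(params.f_tau_scale, 9))
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = K.build_tables(dt, params.f_tau_scale)
    return _TABLE_CACHE[key]


_NO_LINKS = (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0))
_NO_CROSS = (
    False,
    np.empty((0, 0)),
    np.empty((0, 0, 2), np.int64),
    np.empty((0, 0, 2), np.int64),
    0.0,
)


def _single_cell_run(y, params, dt, n_steps, ev_start, ev_end, ev_amp,
                     rec_every, burst=False, burst_amp=-52.0,
                     burst_dur_steps=0, lockout_steps=0,
                     pace_window_steps=0):
    tab, xk1 = get_tables(params, dt)
    S = y.reshape(K.N_VARS, 1).copy()
    n_frames = (n_steps // rec_every + 1) if rec_every > 0 else 0
    rec = np.empty((n_frames, 1), np.float32)
    stim_log = np.empty(4096)
    status, n_stims = K.integrate(
        S, n_steps, dt, params.kernel_array(), tab, xk1,
        *_NO_LINKS, *_NO_CROSS,
        ev_start, ev_end, np.zeros(len(ev_start), np.int64), ev_amp,
        np.array([0, 1], np.int64), np.zeros(1, np.int64),
        burst, 0, burst_amp, burst_dur_steps, lockout_steps,
        pace_window_steps,
        rec_every, np.zeros(1, np.int64), rec, stim_log,
    )
    if status < 0:
        raise BlowupError(-status)
    return S[:, 0], rec, stim_log[:n_stims].copy()


def step_cell(state: CellState, params: ModelParams, dt: float = 0.02,
              i_stim: float = 0.0) -> CellState:
    """Advance one cell a single step (Rush-Larsen gates, Euler otherwise)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    tab, xk1 = get_tables(params, dt)
    S = state.as_array().reshape(K.N_VARS, 1).copy()
    dvdt = np.empty(1)
    ok = K._reaction_step(S, params.kernel_array(), tab, xk1, dt,
                          np.array([i_stim]), dvdt)
    S[K.IV, 0] += dt * dvdt[0]
    if not ok or not np.isfinite(S[K.IV, 0]):
        raise BlowupError(1)
    return CellState.from_array(S[:, 0])


def simulate_cell(params: ModelParams, stim_times=(), duration: float = 1000.0,
                  sample_dt: float = 1.0, dt: float = 0.02,
                  stim_amp: float = -52.0, stim_dur: float = 1.0,
                  init: CellState | None = None):
    """Simulate a single cell with stimuli at the given times (ms).

    Returns ``(movie, final_state)`` where the movie is a one-node
    :class:`VoltageMovie` sampled every ``sample_dt`` ms.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_dt < dt:
        raise ValueError("sample_dt must be >= dt")
    n_steps = int(round(duration / dt))
    rec_every = int(round(sample_dt / dt))
    stim_times = np.asarray(list(stim_times), float)
    ev_start = np.asarray(np.round(stim_times / dt), np.int64)
    ev_end = ev_start + int(round(stim_dur / dt))
    ev_amp = np.full(len(ev_start), stim_amp)
    y0 = (init or resting_state()).as_array()
    y, rec, _ = _single_cell_run(y0, params, dt, n_steps, ev_start, ev_end,
                                 ev_amp, rec_every)
    movie = VoltageMovie(
        data=rec.reshape(-1, 1),
        sample_dt=rec_every * dt,
        dx=0.0,
        meta={"gkr_mult": params.gkr_mult, "gcal_mult": params.gcal_mult,
              "kind": "single_cell"},
    )
    return movie, CellState.from_array(y)


def burst_pace_cell(params: ModelParams, duration: float = 6000.0,
                    pace_window: float = 4000.0, dt: float = 0.02,
                    sample_dt: float = 1.0, stim_amp: float = -52.0,
                    stim_dur: float = 1.0, lockout: float = 100.0,
                    init: CellState | None = None):
    """Single-cell burst pacing: an S1 fires whenever v < -60 mV.

    The stimulated node doubles as the probe, so the pacing interval is set
    by the cell's own recovery (its action-potential duration); a lockout
    bounds the retry rate when an S1 fails to trigger a full AP.  Stimuli
    stop after ``pace_window`` ms and the cell evolves freely.  Returns
    ``(movie, final_state, stim_times)``.
    """
    n_steps = int(round(duration / dt))
    rec_every = int(round(sample_dt / dt))
    y0 = (init or resting_state()).as_array()
    y, rec, stims = _single_cell_run(
        y0, params, dt, n_steps,
        np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0),
        rec_every, burst=True, burst_amp=stim_amp,
        burst_dur_steps=int(round(stim_dur / dt)),
        lockout_steps=int(round(lockout / dt)),
        pace_window_steps=int(round(pace_window / dt)))
    movie = VoltageMovie(
        data=rec.reshape(-1, 1), sample_dt=rec_every * dt, dx=0.0,
        meta={"gkr_mult": params.gkr_mult, "gcal_mult": params.gcal_mult,
              "kind": "single_cell_burst"},
    )
    return movie, CellState.from_array(y), stims


def classify_cell_regime(trace, window: float = 1000.0,
                         threshold: float = -60.0, ead_rise: float = 2.0,
                         ead_window: float = 100.0,
                         upstroke_guard: float = 100.0) -> str:
    """Classify a single-cell trace into the three sweep regimes.

    ``normal``: the potential returns below the sodium-recovery threshold
    between excitations and repolarization is monotone (no plateau
    reversal).  ``ead_repolarizing``: still recovers below threshold but at
    least one plateau reversal (a local minimum above the threshold followed
    by a rise of at least ``ead_rise`` mV within ``ead_window`` ms) occurs.
    ``non_repolarizing_oscillation``: the potential never reaches the
    threshold inside the window.
    """
    if isinstance(trace, VoltageMovie):
        v = trace.trace(0)
        sample_dt = trace.sample_dt
    else:
        v, sample_dt = trace
        v = np.asarray(v, float)
    n_win = int(round(window / sample_dt))
    if n_win > len(v):
        raise ValueError("window longer than trace")
    if window < 1000.0:
        raise ValueError("need at least 1 s of trace to classify")
    v = v[-n_win:]
    if v.min() > threshold:
        return "non_repolarizing_oscillation"
    # plateau reversals: troughs above threshold followed by a rise.
    # The guard skips the spike-notch transient right after each upstroke,
    # which is not an EAD; find_peaks is plateau-aware where strict
    # local-minimum tests fail.
    mins = find_peaks(-v, prominence=0.5)[0]
    ups = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    horizon = int(round(ead_window / sample_dt))
    guard = int(round(upstroke_guard / sample_dt))
    for i in mins:
        if v[i] <= threshold:
            continue
        prev_up = ups[ups <= i]
        if prev_up.size:
            ref = prev_up[-1]
        elif v[0] > threshold:  # window opens mid-AP: upstroke at its edge
            ref = 0
        else:
            continue
        if i - ref < guard:
            continue
        seg = v[i:i + horizon]
        if seg.size > 1 and seg.max() - v[i] >= ead_rise:
            return "ead_repolarizing"
    return "normal"


def apd90(v: np.ndarray, sample_dt: float, threshold: float = -60.0):
    """APD90 (ms) of the last complete AP in a trace; None if no AP."""
    v = np.asarray(v, float)
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    if up.size == 0:
        return None
    i0 = up[-1]
    seg = v[i0:]
    peak = seg.max()
    rest = v.min()
    level = peak - 0.9 * (peak - rest)
    below = np.flatnonzero(seg < level)
    below = below[below > np.argmax(seg)]
    if below.size == 0:
        return None
    return float(below[0] * sample_dt)
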