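"""Compiled numerical core: TP06 reaction kinetics and the monodomain stepper.

The ionic right-hand side follows the ten Tusscher-Panfilov 2006 human
ventricular model (endocardial variant) with two structural modifications
that favour early-afterdepolarization formation: the voltage-dependent
inactivation (f) gate time constant is scaled (default halved) and the
maximal L-type conductance is rescaled (default doubled) to compensate.

Hodgkin-Huxley gates advance by the Rush-Larsen exponential update with the
voltage-dependent steady states and exp(-dt/tau) factors precomputed on a
uniform voltage grid (25 uV spacing, linear interpolation); membrane
potential and ionic concentrations advance by forward Euler.  Diffusion is
a conservative link (face-flux) sum plus an optional mixed-derivative
correction used when fibers are off-axis.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Physical constants and fixed TP06 parameters (units: mV, ms, mM, pA/pF)
# ---------------------------------------------------------------------------
R_GAS = 8314.472        # mJ/(mol K)
TEMP = 310.0            # K
FARADAY = 96485.3415    # C/mol
RTONF = R_GAS * TEMP / FARADAY  # ~26.71 mV

K_O = 5.4               # mM extracellular K+
NA_O = 140.0            # mM extracellular Na+
CA_O = 2.0              # mM extracellular Ca2+

V_C = 0.016404          # cytoplasmic volume (um^3 scale of TP06)
V_SR = 0.001094
V_SS = 0.00005468
CAPACITANCE = 0.185     # uF/cm^2 (TP06 bookkeeping constant)

BUF_C = 0.2
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3
BUF_SS = 0.4
K_BUF_SS = 0.00025

VMAX_UP = 0.006375
K_UP = 0.00025
V_REL = 0.102
K1_PRIME = 0.15
K2_PRIME = 0.045
K3 = 0.060
K4 = 0.005
EC_SR = 1.5
MAX_SR = 2.5
MIN_SR = 1.0
V_LEAK = 0.00036
V_XFER = 0.0038

P_KNA = 0.03
KM_NAI = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA_NACA = 0.35
ALPHA_NACA = 2.5
K_NACA = 1000.0
KM_K = 1.0
KM_NA = 40.0
P_NAK = 2.724
K_PCA = 0.0005

SQRT_KO = np.sqrt(K_O / 5.4)

# State-vector layout (rows of the (N_VARS, n_nodes) state array)
IV, IM, IH, IJ, IXR1, IXR2, IXS, IR, IS, ID, IF, IF2, IFCASS, \
    ICAI, ICASR, ICASS, INAI, IKI, IRQ = range(19)
N_VARS = 19

# Conductance-vector layout (see ModelParams.kernel_array)
CP_GNA, CP_GK1, CP_GTO, CP_GKR, CP_GKS, CP_GCAL, CP_GPCA, CP_GPK, \
    CP_GBNA, CP_GBCA = range(10)
N_CP = 10

# Voltage table grid
V_TAB_MIN = -100.0
V_TAB_MAX = 100.0
N_V_TAB = 8001
# (V - E_K) grid for the inward-rectifier gating factor
U_TAB_MIN = -60.0
U_TAB_MAX = 260.0
N_U_TAB = 8001

# Table row order: inf/rl pairs for the 11 voltage gates, then current factors
_GATE_ORDER = ("m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2")
ROW_ACAL = 22
ROW_BCAL = 23
ROW_E1 = 24     # exp(gamma V F/RT) of I_NaCa
ROW_E2 = 25     # exp((gamma-1) V F/RT)
ROW_FNAK = 26   # voltage factor of I_NaK
ROW_FPK = 27    # voltage factor of I_pK
N_TAB_ROWS = 28


def _gate_rates(v: np.ndarray, f_tau_scale: float):
    """Steady states and time constants of the 11 voltage-dependent gates."""
    e = np.exp
    out = {}

    m_inf = 1.0 / (1.0 + e((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + e((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + e((v + 35.0) / 5.0)) + 0.1 / (1.0 + e((v - 50.0) / 200.0))
    out["m"] = (m_inf, am * bm)

    h_inf = 1.0 / (1.0 + e((v + 71.55) / 7.43)) ** 2
    low = v < -40.0
    ah = np.where(low, 0.057 * e(-(v + 80.0) / 6.8), 0.0)
    bh = np.where(
        low,
        2.7 * e(0.079 * v) + 3.1e5 * e(0.3485 * v),
        0.77 / (0.13 * (1.0 + e(-(v + 10.66) / 11.1))),
    )
    out["h"] = (h_inf, 1.0 / (ah + bh))

    with np.errstate(over="ignore"):
        aj = np.where(
            low,
            (-2.5428e4 * e(0.2444 * v) - 6.948e-6 * e(-0.04391 * v))
            * (v + 37.78) / (1.0 + e(0.311 * (v + 79.23))),
            0.0,
        )
    bj = np.where(
        low,
        0.02424 * e(-0.01052 * v) / (1.0 + e(-0.1378 * (v + 40.14))),
        0.6 * e(0.057 * v) / (1.0 + e(-0.1 * (v + 32.0))),
    )
    out["j"] = (h_inf, 1.0 / (aj + bj))

    xr1_inf = 1.0 / (1.0 + e((-26.0 - v) / 7.0))
    a = 450.0 / (1.0 + e((-45.0 - v) / 10.0))
    b = 6.0 / (1.0 + e((v + 30.0) / 11.5))
    out["xr1"] = (xr1_inf, a * b)

    xr2_inf = 1.0 / (1.0 + e((v + 88.0) / 24.0))
    a = 3.0 / (1.0 + e((-60.0 - v) / 20.0))
    b = 1.12 / (1.0 + e((v - 60.0) / 20.0))
    out["xr2"] = (xr2_inf, a * b)

    xs_inf = 1.0 / (1.0 + e((-5.0 - v) / 14.0))
    a = 1400.0 / np.sqrt(1.0 + e((5.0 - v) / 6.0))
    b = 1.0 / (1.0 + e((v - 35.0) / 15.0))
    out["xs"] = (xs_inf, a * b + 80.0)

    r_inf = 1.0 / (1.0 + e((20.0 - v) / 6.0))
    out["r"] = (r_inf, 9.5 * e(-((v + 40.0) ** 2) / 1800.0) + 0.8)

    # endocardial s gate
    s_inf = 1.0 / (1.0 + e((v + 28.0) / 5.0))
    out["s"] = (s_inf, 1000.0 * e(-((v + 67.0) ** 2) / 1000.0) + 8.0)

    d_inf = 1.0 / (1.0 + e((-8.0 - v) / 7.5))
    a = 1.4 / (1.0 + e((-35.0 - v) / 13.0)) + 0.25
    b = 1.4 / (1.0 + e((v + 5.0) / 5.0))
    g = 1.0 / (1.0 + e((50.0 - v) / 20.0))
    out["d"] = (d_inf, a * b + g)

    f_inf = 1.0 / (1.0 + e((v + 20.0) / 7.0))
    tau_f = (
        1102.5 * e(-((v + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + e((13.0 - v) / 10.0))
        + 180.0 / (1.0 + e((v + 30.0) / 10.0))
        + 20.0
    )
    out["f"] = (f_inf, tau_f * f_tau_scale)

    f2_inf = 0.67 / (1.0 + e((v + 35.0) / 7.0)) + 0.33
    tau_f2 = (
        562.0 * e(-((v + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + e((25.0 - v) / 10.0))
        + 80.0 / (1.0 + e((v + 30.0) / 10.0))
    )
    out["f2"] = (f2_inf, tau_f2)

    return out


def build_tables(dt: float, f_tau_scale: float):
    """Precompute Rush-Larsen gate tables and voltage-only current factors.

    Returns ``(tab, xk1_tab)`` where ``tab`` has shape ``(N_TAB_ROWS, N_V_TAB)``
    and ``xk1_tab`` holds the I_K1 rectification factor on a (V - E_K) grid.
    """
    v = np.linspace(V_TAB_MIN, V_TAB_MAX, N_V_TAB)
    tab = np.empty((N_TAB_ROWS, N_V_TAB))
    rates = _gate_rates(v, f_tau_scale)
    for i, name in enumerate(_GATE_ORDER):
        inf, tau = rates[name]
        tab[2 * i] = inf
        tab[2 * i + 1] = np.exp(-dt / tau)

    # I_CaL voltage factors: I = G*d*f*f2*fcass*(a(V)*Ca_ss - b(V))
    z = 2.0 * (v - 15.0) / RTONF
    pref = 4.0 * (v - 15.0) * FARADAY / RTONF  # 4 (V-15) F^2 / (R T)
    ez = np.exp(z)
    with np.errstate(invalid="ignore", divide="ignore"):
        a_cal = pref * 0.25 * ez / (ez - 1.0)
        b_cal = pref * CA_O / (ez - 1.0)
    tiny = np.abs(z) < 1e-6
    # z -> 0 limit: pref/z = 2 F, so a -> 0.5 F, b -> 2 F Ca_o
    a_cal[tiny] = 0.25 * 2.0 * FARADAY
    b_cal[tiny] = CA_O * 2.0 * FARADAY
    tab[ROW_ACAL] = a_cal
    tab[ROW_BCAL] = b_cal

    tab[ROW_E1] = np.exp(GAMMA_NACA * v / RTONF)
    tab[ROW_E2] = np.exp((GAMMA_NACA - 1.0) * v / RTONF)
    tab[ROW_FNAK] = 1.0 / (
        1.0 + 0.1245 * np.exp(-0.1 * v / RTONF) + 0.0353 * np.exp(-v / RTONF)
    )
    tab[ROW_FPK] = 1.0 / (1.0 + np.exp((25.0 - v) / 5.98))

    u = np.linspace(U_TAB_MIN, U_TAB_MAX, N_U_TAB)
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (u - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (u + 100.0)) + np.exp(0.1 * (u - 10.0))) / (
        1.0 + np.exp(-0.5 * u)
    )
    xk1_tab = ak1 / (ak1 + bk1)
    return tab, xk1_tab


@njit(inline="always")
def _interp(row, x, xmin, inv_dx, n):
    t = (x - xmin) * inv_dx
    if t <= 0.0:
        return row[0]
    if t >= n - 1:
        return row[n - 1]
    i = int(t)
    f = t - i
    return row[i] * (1.0 - f) + row[i + 1] * f


@njit
def _reaction_step(S, cp, tab, xk1, dt, istim, dvdt_out):
    """One forward-Euler/Rush-Larsen reaction step for every node.

    ``istim`` is the per-node stimulus (pA/pF, depolarizing negative).
    Writes dV/dt from the reaction (``-(I_ion + I_stim)``) into ``dvdt_out``;
    gates and concentrations are updated in place.  Returns False on a
    non-finite membrane potential.
    """
    n = S.shape[1]
    inv_dv = (N_V_TAB - 1) / (V_TAB_MAX - V_TAB_MIN)
    inv_du = (N_U_TAB - 1) / (U_TAB_MAX - U_TAB_MIN)
    ok = True
    for i in range(n):
        v = S[IV, i]
        if not np.isfinite(v):
            ok = False
            continue

        cai = S[ICAI, i]
        casr = S[ICASR, i]
        cass = S[ICASS, i]
        nai = S[INAI, i]
        ki = S[IKI, i]

        ena = RTONF * np.log(NA_O / nai)
        ek = RTONF * np.log(K_O / ki)
        eks = RTONF * np.log((K_O + P_KNA * NA_O) / (ki + P_KNA * nai))
        eca = 0.5 * RTONF * np.log(CA_O / cai)

        # --- gate updates (Rush-Larsen from tables) -----------------------
        t = (v - V_TAB_MIN) * inv_dv
        if t <= 0.0:
            idx = 0
            f = 0.0
        elif t >= N_V_TAB - 1:
            idx = N_V_TAB - 2
            f = 1.0
        else:
            idx = int(t)
            f = t - idx
        g = 1.0 - f
        for gi in range(11):
            inf = tab[2 * gi, idx] * g + tab[2 * gi, idx + 1] * f
            rl = tab[2 * gi + 1, idx] * g + tab[2 * gi + 1, idx + 1] * f
            S[IM + gi, i] = inf + (S[IM + gi, i] - inf) * rl

        # fcass depends on subspace Ca, not voltage
        q = 1.0 / (1.0 + (cass / 0.05) ** 2)
        fcass_inf = 0.6 * q + 0.4
        tau_fcass = 80.0 * q + 2.0
        S[IFCASS, i] = fcass_inf + (S[IFCASS, i] - fcass_inf) * np.exp(-dt / tau_fcass)

        m = S[IM, i]
        h = S[IH, i]
        j = S[IJ, i]
        xr1 = S[IXR1, i]
        xr2 = S[IXR2, i]
        xs = S[IXS, i]
        rr = S[IR, i]
        ss = S[IS, i]
        d = S[ID, i]
        ff = S[IF, i]
        f2 = S[IF2, i]
        fcass = S[IFCASS, i]

        # --- membrane currents (pA/pF) ------------------------------------
        a_cal = tab[ROW_ACAL, idx] * g + tab[ROW_ACAL, idx + 1] * f
        b_cal = tab[ROW_BCAL, idx] * g + tab[ROW_BCAL, idx + 1] * f
        e1 = tab[ROW_E1, idx] * g + tab[ROW_E1, idx + 1] * f
        e2 = tab[ROW_E2, idx] * g + tab[ROW_E2, idx + 1] * f
        fnak = tab[ROW_FNAK, idx] * g + tab[ROW_FNAK, idx + 1] * f
        fpk = tab[ROW_FPK, idx] * g + tab[ROW_FPK, idx + 1] * f

        i_na = cp[CP_GNA] * m * m * m * h * j * (v - ena)
        xk1inf = _interp(xk1, v - ek, U_TAB_MIN, inv_du, N_U_TAB)
        i_k1 = cp[CP_GK1] * SQRT_KO * xk1inf * (v - ek)
        i_to = cp[CP_GTO] * rr * ss * (v - ek)
        i_kr = cp[CP_GKR] * SQRT_KO * xr1 * xr2 * (v - ek)
        i_ks = cp[CP_GKS] * xs * xs * (v - eks)
        i_cal = cp[CP_GCAL] * d * ff * f2 * fcass * (a_cal * cass - b_cal)
        i_naca = (
            K_NACA
            * (e1 * nai ** 3 * CA_O - e2 * NA_O ** 3 * cai * ALPHA_NACA)
            / (
                (KM_NAI ** 3 + NA_O ** 3)
                * (KM_CA + CA_O)
                * (1.0 + K_SAT * e2)
            )
        )
        i_nak = P_NAK * K_O / (K_O + KM_K) * nai / (nai + KM_NA) * fnak
        i_pca = cp[CP_GPCA] * cai / (K_PCA + cai)
        i_pk = cp[CP_GPK] * fpk * (v - ek)
        i_bna = cp[CP_GBNA] * (v - ena)
        i_bca = cp[CP_GBCA] * (v - eca)

        i_ion = (
            i_na + i_k1 + i_to + i_kr + i_ks + i_cal + i_naca + i_nak
            + i_pca + i_pk + i_bna + i_bca
        )

        # --- calcium dynamics ---------------------------------------------
        kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / casr) ** 2)
        k1 = K1_PRIME / kcasr
        k2 = K2_PRIME * kcasr
        rq = S[IRQ, i]
        rq += dt * (-k2 * cass * rq + K4 * (1.0 - rq))
        o_rel = k1 * cass * cass * rq / (K3 + k1 * cass * cass)
        i_rel = V_REL * o_rel * (casr - cass)
        i_leak = V_LEAK * (casr - cai)
        i_up = VMAX_UP / (1.0 + (K_UP / cai) ** 2)
        i_xfer = V_XFER * (cass - cai)

        d_casr = i_up - i_rel - i_leak
        bsr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / ((casr + K_BUF_SR) ** 2))
        casr += dt * bsr * d_casr

        d_cass = (
            -i_xfer * V_C / V_SS
            + i_rel * V_SR / V_SS
            - i_cal * CAPACITANCE / (2.0 * V_SS * FARADAY)
        )
        bss = 1.0 / (1.0 + BUF_SS * K_BUF_SS / ((cass + K_BUF_SS) ** 2))
        cass += dt * bss * d_cass

        d_cai = (
            (i_leak - i_up) * V_SR / V_C
            + i_xfer
            - (i_bca + i_pca - 2.0 * i_naca) * CAPACITANCE / (2.0 * V_C * FARADAY)
        )
        bc = 1.0 / (1.0 + BUF_C * K_BUF_C / ((cai + K_BUF_C) ** 2))
        cai += dt * bc * d_cai

        stim = istim[i]
        nai += dt * (
            -(i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca)
            * CAPACITANCE / (V_C * FARADAY)
        )
        ki += dt * (
            -(stim + i_k1 + i_to + i_kr + i_ks - 2.0 * i_nak + i_pk)
            * CAPACITANCE / (V_C * FARADAY)
        )

        S[ICAI, i] = cai
        S[ICASR, i] = casr
        S[ICASS, i] = cass
        S[INAI, i] = nai
        S[IKI, i] = ki
        S[IRQ, i] = rq

        dvdt_out[i] = -(i_ion + stim)
    return ok


@njit
def _diffusion(v, la, lb, lw, out):
    """Conservative link-flux divergence: out[i] += sum of face fluxes."""
    out[:] = 0.0
    for k in range(la.shape[0]):
        a = la[k]
        b = lb[k]
        flux = lw[k] * (v[b] - v[a])
        out[a] += flux
        out[b] -= flux


@njit(inline="always")
def _central_diff(v, nbrs, idx):
    """Centered difference along one axis; mirrored (zero) at boundaries."""
    p = nbrs[idx, 0]
    m = nbrs[idx, 1]
    if p >= 0 and m >= 0:
        return 0.5 * (v[p] - v[m])
    return 0.0


@njit
def _cross_terms(v, dxy, pairs_i, pairs_j, out, inv_dx2):
    """Mixed-derivative terms d/dxi(Dij d/dxj V) + d/dxj(Dij d/dxi V).

    Face-flux form: the flux through each lattice face is the face-averaged
    Dij times the face-averaged transverse centered derivative, added to
    one cell and subtracted from its neighbour, so the scheme conserves the
    spatial mean exactly (boundary faces carry zero flux).  ``pairs_i`` /
    ``pairs_j`` hold the +/- neighbour indices along the two axes of the
    off-diagonal pair (-1 outside the tissue).
    """
    n = v.shape[0]
    for a in range(n):
        # i-direction faces: flux = Dij * dV/dj evaluated on the face
        b = pairs_i[a, 0]
        if b >= 0:
            f = (0.25 * (dxy[a] + dxy[b])
                 * (_central_diff(v, pairs_j, a) + _central_diff(v, pairs_j, b))
                 * inv_dx2)
            out[a] += f
            out[b] -= f
        # j-direction faces: flux = Dij * dV/di on the face
        b = pairs_j[a, 0]
        if b >= 0:
            f = (0.25 * (dxy[a] + dxy[b])
                 * (_central_diff(v, pairs_i, a) + _central_diff(v, pairs_i, b))
                 * inv_dx2)
            out[a] += f
            out[b] -= f


@njit
def integrate(
    S,
    n_steps,
    dt,
    cp,
    tab,
    xk1,
    la,
    lb,
    lw,
    has_cross,
    cross_d,      # (n_pairs, n_nodes) off-diagonal tensor entries
    cross_ni,     # (n_pairs, n_nodes, 2) +/- neighbours along axis i
    cross_nj,     # (n_pairs, n_nodes, 2) +/- neighbours along axis j
    inv_4dx2,
    ev_start,
    ev_end,
    ev_set,
    ev_amp,
    set_offsets,  # node-set CSR offsets into set_nodes
    set_nodes,
    burst,
    probe,
    burst_amp,
    burst_dur_steps,
    burst_lockout_steps,
    pace_window_steps,
    rec_every,
    rec_nodes,
    rec_out,      # (n_frames, len(rec_nodes)) float32
    stim_log,     # preallocated float64 buffer for S1 trigger times
):
    """Advance the reaction-diffusion system ``n_steps`` of size ``dt``.

    Returns ``(status, n_stims)``; status < 0 flags a numerical blow-up at
    step ``-status``.
    """
    n = S.shape[1]
    dvdt = np.empty(n)
    diff = np.zeros(n)
    istim = np.zeros(n)
    n_frames = rec_out.shape[0]
    frame = 0

    stim_until = -1
    lockout_until = -1
    armed = True
    n_stims = 0

    for step in range(n_steps):
        # --- record (state at the beginning of the step) -------------------
        if rec_every > 0 and step % rec_every == 0 and frame < n_frames:
            for k in range(rec_nodes.shape[0]):
                rec_out[frame, k] = S[IV, rec_nodes[k]]
            frame += 1

        # --- stimulus bookkeeping -----------------------------------------
        istim[:] = 0.0
        if burst:
            vp = S[IV, probe]
            if vp > -60.0:
                armed = True
            if (
                step < pace_window_steps
                and armed
                and step >= lockout_until
                and step >= stim_until
                and vp < -60.0
            ):
                stim_until = step + burst_dur_steps
                lockout_until = step + burst_lockout_steps
                armed = False
                if n_stims < stim_log.shape[0]:
                    stim_log[n_stims] = step * dt
                n_stims += 1
            if step < stim_until:
                s0 = set_offsets[0]
                s1 = set_offsets[1]
                for k in range(s0, s1):
                    istim[set_nodes[k]] += burst_amp
        for ev in range(ev_start.shape[0]):
            if ev_start[ev] <= step < ev_end[ev]:
                s0 = set_offsets[ev_set[ev]]
                s1 = set_offsets[ev_set[ev] + 1]
                for k in range(s0, s1):
                    istim[set_nodes[k]] += ev_amp[ev]

        # --- diffusion on the old voltage ---------------------------------
        if la.shape[0] > 0:
            _diffusion(S[IV], la, lb, lw, diff)
            if has_cross:
                for p in range(cross_d.shape[0]):
                    _cross_terms(
                        S[IV], cross_d[p], cross_ni[p], cross_nj[p],
                        diff, inv_4dx2,
                    )
        else:
            diff[:] = 0.0

        # --- reaction ------------------------------------------------------
        ok = _reaction_step(S, cp, tab, xk1, dt, istim, dvdt)
        if not ok:
            return -(step + 1), n_stims
        for i in range(n):
            S[IV, i] += dt * (dvdt[i] + diff[i])

    if rec_every > 0 and frame < n_frames:
        for k in range(rec_nodes.shape[0]):
            rec_out[frame, k] = S[IV, rec_nodes[k]]
    return 0, n_stims
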