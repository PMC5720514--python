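"""Independent reference integration of the modified TP06 endocardial cell.

A deliberately straightforward formulation used as the oracle for the
production stepper: every equation evaluated directly (no lookup tables),
every state variable advanced by plain forward Euler at a small time step
(default 0.001 ms).  Shares no code with eadsim._kernels.
"""

import numpy as np
from numba import njit

R = 8314.472
T = 310.0
F = 96485.3415
RTF = R * T / F

Ko = 5.4
Nao = 140.0
Cao = 2.0
Vc = 0.016404
Vsr = 0.001094
Vss = 0.00005468
Cap = 0.185

Bufc, Kbufc = 0.2, 0.001
Bufsr, Kbufsr = 10.0, 0.3
Bufss, Kbufss = 0.4, 0.00025
Vmaxup, Kup = 0.006375, 0.00025
Vrel, k1p, k2p, k3, k4 = 0.102, 0.15, 0.045, 0.060, 0.005
EC, maxsr, minsr = 1.5, 2.5, 1.0
Vleak, Vxfer = 0.00036, 0.0038
pKNa = 0.03
KmNai, KmCa, ksat, gam = 87.5, 1.38, 0.1, 0.35
knaca, alp = 1000.0, 2.5
KmK, KmNa, PNaK = 1.0, 40.0, 2.724
KpCa = 0.0005

GNa = 14.838
GK1 = 5.405
Gto = 0.073       # endocardial
GKr0 = 0.153
GKs = 0.392       # endocardial
GCaL0 = 3.980e-5
GpCa = 0.1238
GpK = 0.0146
GbNa = 0.00029
GbCa = 0.000592

# state order: v, m, h, j, xr1, xr2, xs, r, s, d, f, f2, fcass,
#              cai, casr, cass, nai, ki, rq
Y0 = np.array([-86.2, 0.0, 0.75, 0.75, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 1.0,
               1.0, 1.0, 7.0e-5, 1.3, 7.0e-5, 7.67, 138.3, 1.0])


@njit
def rhs(y, gkr_mult, gcal_mult, f_tau_scale, istim):
    v, m, h, j, xr1, xr2, xs, r, s, d, f, f2, fcass, \
        cai, casr, cass, nai, ki, rq = y
    e = np.exp

    ena = RTF * np.log(Nao / nai)
    ek = RTF * np.log(Ko / ki)
    eks = RTF * np.log((Ko + pKNa * Nao) / (ki + pKNa * nai))
    eca = 0.5 * RTF * np.log(Cao / cai)

    ina = GNa * m ** 3 * h * j * (v - ena)
    u = v - ek
    ak1 = 0.1 / (1.0 + e(0.06 * (u - 200.0)))
    bk1 = (3.0 * e(0.0002 * (u + 100.0)) + e(0.1 * (u - 10.0))) / (
        1.0 + e(-0.5 * u))
    ik1 = GK1 * np.sqrt(Ko / 5.4) * ak1 / (ak1 + bk1) * u
    ito = Gto * r * s * u
    ikr = gkr_mult * GKr0 * np.sqrt(Ko / 5.4) * xr1 * xr2 * u
    iks = GKs * xs * xs * (v - eks)
    z = 2.0 * (v - 15.0) / RTF
    if abs(z) < 1e-7:
        drive = 2.0 * F * (0.25 * cass - Cao)
    else:
        ez = e(z)
        drive = 4.0 * (v - 15.0) * F / RTF * (0.25 * cass * ez - Cao) / (ez - 1.0)
    ical = 2.0 * gcal_mult * GCaL0 * d * f * f2 * fcass * drive
    e1 = e(gam * v / RTF)
    e2 = e((gam - 1.0) * v / RTF)
    inaca = knaca * (e1 * nai ** 3 * Cao - e2 * Nao ** 3 * cai * alp) / (
        (KmNai ** 3 + Nao ** 3) * (KmCa + Cao) * (1.0 + ksat * e2))
    inak = PNaK * Ko / (Ko + KmK) * nai / (nai + KmNa) / (
        1.0 + 0.1245 * e(-0.1 * v / RTF) + 0.0353 * e(-v / RTF))
    ipca = GpCa * cai / (KpCa + cai)
    ipk = GpK * u / (1.0 + e((25.0 - v) / 5.98))
    ibna = GbNa * (v - ena)
    ibca = GbCa * (v - eca)
    iion = (ina + ik1 + ito + ikr + iks + ical + inaca + inak + ipca + ipk
            + ibna + ibca)

    dy = np.empty(19)
    dy[0] = -(iion + istim)

    m_inf = 1.0 / (1.0 + e((-56.86 - v) / 9.03)) ** 2
    tau_m = (1.0 / (1.0 + e((-60.0 - v) / 5.0))) * (
        0.1 / (1.0 + e((v + 35.0) / 5.0)) + 0.1 / (1.0 + e((v - 50.0) / 200.0)))
    dy[1] = (m_inf - m) / tau_m

    h_inf = 1.0 / (1.0 + e((v + 71.55) / 7.43)) ** 2
    if v < -40.0:
        ah = 0.057 * e(-(v + 80.0) / 6.8)
        bh = 2.7 * e(0.079 * v) + 3.1e5 * e(0.3485 * v)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + e(-(v + 10.66) / 11.1)))
    dy[2] = (h_inf - h) * (ah + bh)

    if v < -40.0:
        aj = ((-2.5428e4 * e(0.2444 * v) - 6.948e-6 * e(-0.04391 * v))
              * (v + 37.78) / (1.0 + e(0.311 * (v + 79.23))))
        bj = 0.02424 * e(-0.01052 * v) / (1.0 + e(-0.1378 * (v + 40.14)))
    else:
        aj = 0.0
        bj = 0.6 * e(0.057 * v) / (1.0 + e(-0.1 * (v + 32.0)))
    dy[3] = (h_inf - j) * (aj + bj)

    xr1_inf = 1.0 / (1.0 + e((-26.0 - v) / 7.0))
    tau_xr1 = (450.0 / (1.0 + e((-45.0 - v) / 10.0))) * (
        6.0 / (1.0 + e((v + 30.0) / 11.5)))
    dy[4] = (xr1_inf - xr1) / tau_xr1

    xr2_inf = 1.0 / (1.0 + e((v + 88.0) / 24.0))
    tau_xr2 = (3.0 / (1.0 + e((-60.0 - v) / 20.0))) * (
        1.12 / (1.0 + e((v - 60.0) / 20.0)))
    dy[5] = (xr2_inf - xr2) / tau_xr2

    xs_inf = 1.0 / (1.0 + e((-5.0 - v) / 14.0))
    tau_xs = (1400.0 / np.sqrt(1.0 + e((5.0 - v) / 6.0))) * (
        1.0 / (1.0 + e((v - 35.0) / 15.0))) + 80.0
    dy[6] = (xs_inf - xs) / tau_xs

    r_inf = 1.0 / (1.0 + e((20.0 - v) / 6.0))
    tau_r = 9.5 * e(-(v + 40.0) ** 2 / 1800.0) + 0.8
    dy[7] = (r_inf - r) / tau_r

    s_inf = 1.0 / (1.0 + e((v + 28.0) / 5.0))
    tau_s = 1000.0 * e(-(v + 67.0) ** 2 / 1000.0) + 8.0
    dy[8] = (s_inf - s) / tau_s

    d_inf = 1.0 / (1.0 + e((-8.0 - v) / 7.5))
    tau_d = (1.4 / (1.0 + e((-35.0 - v) / 13.0)) + 0.25) * (
        1.4 / (1.0 + e((v + 5.0) / 5.0))) + 1.0 / (1.0 + e((50.0 - v) / 20.0))
    dy[9] = (d_inf - d) / tau_d

    f_inf = 1.0 / (1.0 + e((v + 20.0) / 7.0))
    tau_f = f_tau_scale * (
        1102.5 * e(-(v + 27.0) ** 2 / 225.0)
        + 200.0 / (1.0 + e((13.0 - v) / 10.0))
        + 180.0 / (1.0 + e((v + 30.0) / 10.0)) + 20.0)
    dy[10] = (f_inf - f) / tau_f

    f2_inf = 0.67 / (1.0 + e((v + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * e(-(v + 27.0) ** 2 / 240.0)
              + 31.0 / (1.0 + e((25.0 - v) / 10.0))
              + 80.0 / (1.0 + e((v + 30.0) / 10.0)))
    dy[11] = (f2_inf - f2) / tau_f2

    fca_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fca = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0
    dy[12] = (fca_inf - fcass) / tau_fca

    kcasr = maxsr - (maxsr - minsr) / (1.0 + (EC / casr) ** 2)
    k1 = k1p / kcasr
    k2 = k2p * kcasr
    dy[18] = -k2 * cass * rq + k4 * (1.0 - rq)
    orel = k1 * cass ** 2 * rq / (k3 + k1 * cass ** 2)
    irel = Vrel * orel * (casr - cass)
    ileak = Vleak * (casr - cai)
    iup = Vmaxup / (1.0 + (Kup / cai) ** 2)
    ixfer = Vxfer * (cass - cai)

    bc = 1.0 / (1.0 + Bufc * Kbufc / (cai + Kbufc) ** 2)
    dy[13] = bc * ((ileak - iup) * Vsr / Vc + ixfer
                   - (ibca + ipca - 2.0 * inaca) * Cap / (2.0 * Vc * F))
    bsr = 1.0 / (1.0 + Bufsr * Kbufsr / (casr + Kbufsr) ** 2)
    dy[14] = bsr * (iup - irel - ileak)
    bss = 1.0 / (1.0 + Bufss * Kbufss / (cass + Kbufss) ** 2)
    dy[15] = bss * (-ixfer * Vc / Vss + irel * Vsr / Vss
                    - ical * Cap / (2.0 * Vss * F))
    dy[16] = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * Cap / (Vc * F)
    dy[17] = -(istim + ik1 + ito + ikr + iks - 2.0 * inak + ipk) * Cap / (Vc * F)
    return dy


@njit
def integrate_reference(gkr_mult, gcal_mult, duration, dt, stim_starts,
                        stim_amp, stim_dur, sample_every, f_tau_scale=0.5):
    """Forward-Euler reference trace; returns sampled v(t)."""
    y = Y0.copy()
    n = int(round(duration / dt))
    n_out = n // sample_every + 1
    out = np.empty(n_out)
    frame = 0
    for step in range(n):
        if step % sample_every == 0:
            out[frame] = y[0]
            frame += 1
        t = step * dt
        istim = 0.0
        for s in stim_starts:
            if s <= t < s + stim_dur:
                istim = stim_amp
        y = y + dt * rhs(y, gkr_mult, gcal_mult, f_tau_scale, istim)
    out[frame] = y[0]
    return out
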