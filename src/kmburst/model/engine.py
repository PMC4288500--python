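"""Numba integration kernels for the burst model.

State vector ``y`` (length 9):
    0 V (mV), 1 h (Na inact), 2 a (K_DR act), 3 d (A-type inact),
    4 w (M gate), 5 n (T-type act, slow), 6 o (K_Ca act, slow),
    7 q (AHP Ca gate), 8 Ca_i (uM)

Parameter vector ``P`` (length 18):
    0 Cm (uF/cm2), 1 g_Na, 2 g_CaT, 3 g_CaL, 4 g_CaN, 5 g_KDR, 6 g_A,
    7 g_M, 8 g_KCa, 9 g_Kahp, 10 g_leak (all mS/cm2), 11 I_app (uA/cm2),
    12 V_Na, 13 V_K, 14 V_Leak (mV), 15 Ca_ext (uM),
    16 ca influx factor (uM cm2 / (uA ms)), 17 ca removal tau (ms)

Current vector order: I_Na, I_CaT, I_CaL, I_CaN, I_KDR, I_A, I_KCa,
I_AHP, I_M, I_Leak (uA/cm2; outward positive).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import kinetics as kin

N_STATE = 9
N_CURRENT = 10

# unpack kinetics indices as plain ints for numba
(M_HALF, M_K, H_HALF, H_K, TAUH_BASE, TAUH_AMP, TAUH_HALF, TAUH_K,
 A_HALF, A_K, TAUA_BASE, TAUA_AMP, TAUA_HALF, TAUA_K,
 CA_HALF, CA_K, D_HALF, D_K, TAUD, N_HALF, N_K, TAUN,
 ML_HALF, ML_K, MN_HALF, MN_K, O_CA_HALF, O_HILL, TAUO,
 Q_CA_HALF, Q_HILL, TAUQ, W_HALF, W_K, TAUW, RT2F, CA_SCALE,
 HT_HALF, HT_K) = (
    kin.M_HALF, kin.M_K, kin.H_HALF, kin.H_K, kin.TAUH_BASE, kin.TAUH_AMP,
    kin.TAUH_HALF, kin.TAUH_K, kin.A_HALF, kin.A_K, kin.TAUA_BASE,
    kin.TAUA_AMP, kin.TAUA_HALF, kin.TAUA_K, kin.CA_HALF, kin.CA_K,
    kin.D_HALF, kin.D_K, kin.TAUD, kin.N_HALF, kin.N_K, kin.TAUN,
    kin.ML_HALF, kin.ML_K, kin.MN_HALF, kin.MN_K, kin.O_CA_HALF,
    kin.O_HILL, kin.TAUO, kin.Q_CA_HALF, kin.Q_HILL, kin.TAUQ,
    kin.W_HALF, kin.W_K, kin.TAUW, kin.RT2F, kin.CA_SCALE,
    kin.HT_HALF, kin.HT_K)


@njit(cache=True, inline="always")
def _sig(x):
    return 1.0 / (1.0 + math.exp(-x))


@njit(cache=True, inline="always")
def ghk_drive(v, cai, cao, rt2f):
    """Normalized constant-field Ca2+ driving term (mV-like units): behaves
    as the linear driving force V at hyperpolarized V and reverses at
    (RT/2F) ln(Ca_o/Ca_i)."""
    u = v / rt2f
    if abs(u) < 1e-4:
        return rt2f * (cai - cao) / cao + 0.5 * v * (cai + cao) / cao
    eu = math.exp(u)
    return v * (cai * eu - cao) / (cao * (eu - 1.0))


@njit(cache=True, inline="always")
def _ca_gate(ca, half, hill):
    r = (ca / half) ** hill
    return r / (1.0 + r)


@njit(cache=True)
def eval_currents(y, P, K, cur):
    """Fill ``cur`` with the ten membrane currents at state ``y``."""
    v, h, a, d, w, n, o, q, ca = y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7], y[8]
    vna, vk, vleak, cao = P[12], P[13], P[14], P[15]
    m = _sig((v - K[M_HALF]) / K[M_K])
    ca_act = _sig((v - K[CA_HALF]) / K[CA_K])
    ml = _sig((v - K[ML_HALF]) / K[ML_K])
    mn = _sig((v - K[MN_HALF]) / K[MN_K])
    drive = K[CA_SCALE] * ghk_drive(v, ca, cao, K[RT2F])
    ht = _sig(-(v - K[HT_HALF]) / K[HT_K])
    cur[0] = P[1] * m * m * m * h * (v - vna)       # I_Na
    cur[1] = P[2] * n * ht * drive                  # I_CaT
    cur[2] = P[3] * ml * drive                      # I_CaL
    cur[3] = P[4] * mn * drive                      # I_CaN
    cur[4] = P[5] * a * a * (v - vk)                # I_KDR
    cur[5] = P[6] * ca_act * d * (v - vk)           # I_A
    cur[6] = P[8] * o * (v - vk)                    # I_KCa
    cur[7] = P[9] * q * (v - vk)                    # I_AHP
    cur[8] = P[7] * w * (v - vk)                    # I_M
    cur[9] = P[10] * (v - vleak)                    # I_Leak


@njit(cache=True)
def deriv(y, P, K, dy, cur):
    """Time derivatives of the full state; also fills ``cur``."""
    eval_currents(y, P, K, cur)
    v, ca = y[0], y[8]
    total = 0.0
    for i in range(N_CURRENT):
        total += cur[i]
    dy[0] = (-total + P[11]) / P[0]

    h_inf = _sig(-(v - K[H_HALF]) / K[H_K])
    tau_h = K[TAUH_BASE] + K[TAUH_AMP] * _sig(-(v - K[TAUH_HALF]) / K[TAUH_K])
    dy[1] = (h_inf - y[1]) / tau_h

    a_inf = _sig((v - K[A_HALF]) / K[A_K])
    tau_a = K[TAUA_BASE] + K[TAUA_AMP] * _sig(-(v - K[TAUA_HALF]) / K[TAUA_K])
    dy[2] = (a_inf - y[2]) / tau_a

    d_inf = _sig(-(v - K[D_HALF]) / K[D_K])
    dy[3] = (d_inf - y[3]) / K[TAUD]

    w_inf = _sig((v - K[W_HALF]) / K[W_K])
    dy[4] = (w_inf - y[4]) / K[TAUW]

    n_inf = _sig((v - K[N_HALF]) / K[N_K])
    dy[5] = (n_inf - y[5]) / K[TAUN]

    o_inf = _ca_gate(ca, K[O_CA_HALF], K[O_HILL])
    dy[6] = (o_inf - y[6]) / K[TAUO]

    q_inf = _ca_gate(ca, K[Q_CA_HALF], K[Q_HILL])
    dy[7] = (q_inf - y[7]) / K[TAUQ]

    ica = cur[1] + cur[2] + cur[3]
    dy[8] = -P[16] * ica - (ca - 1e-4) / P[17]


@njit(cache=True)
def steady_gates(v, ca, K, y):
    """Fill gate entries of ``y`` with their steady states at (v, ca)."""
    y[0] = v
    y[1] = _sig(-(v - K[H_HALF]) / K[H_K])
    y[2] = _sig((v - K[A_HALF]) / K[A_K])
    y[3] = _sig(-(v - K[D_HALF]) / K[D_K])
    y[4] = _sig((v - K[W_HALF]) / K[W_K])
    y[5] = _sig((v - K[N_HALF]) / K[N_K])
    y[6] = _ca_gate(ca, K[O_CA_HALF], K[O_HILL])
    y[7] = _ca_gate(ca, K[Q_CA_HALF], K[Q_HILL])
    y[8] = ca


@njit(cache=True)
def f_steady(v, n, o, ca, P, K):
    """Quasi-steady membrane current balance F(V; n, o) of the fast
    subsystem: all gates at their voltage steady state except the frozen
    slow pair (n, o); Ca_i frozen.  Roots are fast-subsystem equilibria;
    F > 0 depolarizes."""
    y = np.empty(N_STATE)
    steady_gates(v, ca, K, y)
    y[5] = n
    y[6] = o
    cur = np.empty(N_CURRENT)
    eval_currents(y, P, K, cur)
    total = 0.0
    for i in range(N_CURRENT):
        total += cur[i]
    return -total + P[11]


@njit(cache=True)
def integrate(y0, P, K, dt, n_steps, stride, use_rk4):
    """Explicit Euler (or classical RK4) integration with stride recording.

    Returns (t_rec, states_rec, currents_rec, dvdt_rec, y_final, status)
    where status is -1 on success or the step index at which |V| exceeded
    200 mV / went non-finite.
    """
    n_rec = n_steps // stride + 1
    t_rec = np.empty(n_rec)
    states = np.empty((n_rec, N_STATE))
    currents = np.empty((n_rec, N_CURRENT))
    dvdt = np.empty(n_rec)

    y = y0.copy()
    dy = np.empty(N_STATE)
    cur = np.empty(N_CURRENT)
    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    k4 = np.empty(N_STATE)
    yt = np.empty(N_STATE)

    rec = 0
    status = -1
    for step in range(n_steps + 1):
        if step % stride == 0 and rec < n_rec:
            deriv(y, P, K, dy, cur)
            t_rec[rec] = step * dt
            for j in range(N_STATE):
                states[rec, j] = y[j]
            for j in range(N_CURRENT):
                currents[rec, j] = cur[j]
            dvdt[rec] = dy[0]
            rec += 1
        if step == n_steps:
            break
        if use_rk4:
            deriv(y, P, K, k1, cur)
            for j in range(N_STATE):
                yt[j] = y[j] + 0.5 * dt * k1[j]
            deriv(yt, P, K, k2, cur)
            for j in range(N_STATE):
                yt[j] = y[j] + 0.5 * dt * k2[j]
            deriv(yt, P, K, k3, cur)
            for j in range(N_STATE):
                yt[j] = y[j] + dt * k3[j]
            deriv(yt, P, K, k4, cur)
            for j in range(N_STATE):
                y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        else:
            deriv(y, P, K, dy, cur)
            for j in range(N_STATE):
                y[j] += dt * dy[j]
        if y[8] < 0.0:
            y[8] = 0.0
        if not math.isfinite(y[0]) or abs(y[0]) > 200.0:
            status = step
            break
    return t_rec[:rec], states[:rec], currents[:rec], dvdt[:rec], y, status


@njit(cache=True)
def integrate_fast(v0, n, o, ca, P, K, dt, n_steps, stride):
    """Integrate the fast subsystem (V, h, a, d dynamic; m/cA/mL/mN and the
    M gate slaved to their voltage steady states; n, o, Ca_i, AHP gate
    frozen).  Returns (t_rec, v_rec, v_final)."""
    n_rec = n_steps // stride + 1
    t_rec = np.empty(n_rec)
    v_rec = np.empty(n_rec)

    y = np.empty(N_STATE)
    steady_gates(v0, ca, K, y)
    y[5] = n
    y[6] = o
    dy = np.empty(N_STATE)
    cur = np.empty(N_CURRENT)

    rec = 0
    for step in range(n_steps + 1):
        if step % stride == 0 and rec < n_rec:
            t_rec[rec] = step * dt
            v_rec[rec] = y[0]
            rec += 1
        if step == n_steps:
            break
        # slave the M gate and re-freeze slow variables before each step
        y[4] = _sig((y[0] - K[W_HALF]) / K[W_K])
        deriv(y, P, K, dy, cur)
        y[0] += dt * dy[0]
        y[1] += dt * dy[1]
        y[2] += dt * dy[2]
        y[3] += dt * dy[3]
        if not math.isfinite(y[0]) or abs(y[0]) > 200.0:
            break
    return t_rec[:rec], v_rec[:rec], y[0]
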