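"""Numba forward-Euler kernels for the network and uncoupled populations.

The state layout matches ``cell.STATE_NAMES`` and the parameter layout
``cell.PARAM_NAMES``; both are packed into 2-D float arrays so the whole
population advances inside one compiled loop.  Gap junctions couple the
dendritic compartments through a CSR adjacency with the saturating
conductance normalization g_c * (0.8 exp(-dV^2/100) + 0.2).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# state indices (keep in sync with cell.CellState field order)
VS, VD, VA = 0, 1, 2
KCAT, LCAT, HNAS, XKDR, NKS, QH = 3, 4, 5, 6, 7, 8
RCAPQ, SKCA, CADEND = 9, 10, 11
HNAA, XKA = 12, 13
N_STATE = 14

# parameter indices (keep in sync with cell.PARAM_NAMES)
G_CAT, G_NA_S, G_KDR_S, G_K_S, G_H, G_LS = 0, 1, 2, 3, 4, 5
G_CAPQ, G_KCA, G_LD = 6, 7, 8
G_NA_A, G_K_A, G_LA = 9, 10, 11
G_INT, P_SD, P_SA = 12, 13, 14
CA_DECAY, CA_SCALE, SK_OFF, SK_CAP = 15, 16, 17, 18
E_NA, E_K, E_CA, E_H, E_LEAK = 19, 20, 21, 22, 23

C_M = 1.0
V_BLOWUP = 200.0


@njit(cache=True)
def _step_cell(S, P, i, dt, i_soma, i_dend, g_syn, e_syn):
    """Advance cell i by one Euler step.  Returns False on blow-up."""
    vs = S[i, VS]
    vd = S[i, VD]
    va = S[i, VA]

    # ---- soma ----
    k_inf = 1.0 / (1.0 + math.exp(-(vs + 61.0) / 4.2))
    l_inf = 1.0 / (1.0 + math.exp((vs + 85.5) / 8.5))
    tau_l = 20.0 * math.exp((vs + 160.0) / 30.0) / (
        1.0 + math.exp((vs + 84.0) / 7.3)) + 35.0
    h_inf = 1.0 / (1.0 + math.exp((vs + 70.0) / 5.8))
    tau_h = 3.0 * math.exp(-(vs + 40.0) / 33.0)
    n_inf = 1.0 / (1.0 + math.exp(-(vs + 3.0) / 10.0))
    tau_n = 5.0 + 47.0 * math.exp(-(vs + 50.0) / 900.0)
    dv25 = vs + 25.0
    if abs(dv25) < 1e-9:
        alpha_x = 1.3
    else:
        alpha_x = 0.13 * dv25 / (1.0 - math.exp(-dv25 / 10.0))
    beta_x = 1.69 * math.exp(-0.0125 * (vs + 35.0))
    q_inf = 1.0 / (1.0 + math.exp((vs + 80.0) / 4.0))
    tau_q = 1.0 / (math.exp(-0.086 * vs - 14.6)
                   + math.exp(0.070 * vs - 1.87))
    m_inf = 1.0 / (1.0 + math.exp(-(vs + 30.0) / 5.5))

    I_CaT = P[i, G_CAT] * S[i, KCAT] ** 3 * S[i, LCAT] * (vs - P[i, E_CA])
    I_Na_s = P[i, G_NA_S] * m_inf ** 3 * S[i, HNAS] * (vs - P[i, E_NA])
    I_Kdr = P[i, G_KDR_S] * S[i, XKDR] ** 4 * (vs - P[i, E_K])
    I_Ks = P[i, G_K_S] * S[i, NKS] ** 4 * (vs - P[i, E_K])
    I_h = P[i, G_H] * S[i, QH] * (vs - P[i, E_H])
    I_ls = P[i, G_LS] * (vs - P[i, E_LEAK])
    I_ds = (P[i, G_INT] / P[i, P_SD]) * (vs - vd)
    I_as = (P[i, G_INT] / (1.0 - P[i, P_SA])) * (vs - va)
    I_syn = g_syn * (vs - e_syn)
    dvs = (-(I_CaT + I_Na_s + I_Kdr + I_Ks + I_h + I_ls + I_ds + I_as
             + I_syn) + i_soma) / C_M

    # ---- dendrite ----
    alpha_r = 1.7 / (1.0 + math.exp(-(vd - 5.0) / 13.9))
    dv85 = vd + 8.5
    if abs(dv85) < 1e-9:
        beta_r = 0.1
    else:
        beta_r = 0.02 * dv85 / (math.exp(dv85 / 5.0) - 1.0)
    ca = S[i, CADEND]
    alpha_s = 2.0e-5 * ca
    if alpha_s > P[i, SK_CAP]:
        alpha_s = P[i, SK_CAP]
    I_CaPQ = P[i, G_CAPQ] * S[i, RCAPQ] ** 2 * (vd - P[i, E_CA])
    I_KCa = P[i, G_KCA] * S[i, SKCA] * (vd - P[i, E_K])
    I_ld = P[i, G_LD] * (vd - P[i, E_LEAK])
    I_sd = (P[i, G_INT] / (1.0 - P[i, P_SD])) * (vd - vs)
    dvd = (-(I_CaPQ + I_KCa + I_ld + I_sd) + i_dend) / C_M

    # ---- axon ----
    h_inf_a = 1.0 / (1.0 + math.exp((va + 60.0) / 5.8))
    tau_h_a = 1.5 * math.exp(-(va + 40.0) / 33.0)
    dva25 = va + 25.0
    if abs(dva25) < 1e-9:
        alpha_xa = 1.3
    else:
        alpha_xa = 0.13 * dva25 / (1.0 - math.exp(-dva25 / 10.0))
    beta_xa = 1.69 * math.exp(-0.0125 * (va + 35.0))
    m_inf_a = 1.0 / (1.0 + math.exp(-(va + 30.0) / 5.5))
    I_Na_a = P[i, G_NA_A] * m_inf_a ** 3 * S[i, HNAA] * (va - P[i, E_NA])
    I_K_a = P[i, G_K_A] * S[i, XKA] ** 4 * (va - P[i, E_K])
    I_la = P[i, G_LA] * (va - P[i, E_LEAK])
    I_sa = (P[i, G_INT] / P[i, P_SA]) * (va - vs)
    dva = (-(I_Na_a + I_K_a + I_la + I_sa)) / C_M

    # ---- Euler update ----
    S[i, VS] = vs + dt * dvs
    S[i, VD] = vd + dt * dvd
    S[i, VA] = va + dt * dva
    S[i, KCAT] += dt * (k_inf - S[i, KCAT]) / 1.0
    S[i, LCAT] += dt * (l_inf - S[i, LCAT]) / tau_l
    S[i, HNAS] += dt * (h_inf - S[i, HNAS]) / tau_h
    S[i, XKDR] += dt * (alpha_x * (1.0 - S[i, XKDR]) - beta_x * S[i, XKDR])
    S[i, NKS] += dt * (n_inf - S[i, NKS]) / tau_n
    S[i, QH] += dt * (q_inf - S[i, QH]) / tau_q
    S[i, RCAPQ] += dt * (alpha_r * (1.0 - S[i, RCAPQ])
                         - beta_r * S[i, RCAPQ])
    S[i, SKCA] += dt * (alpha_s * (1.0 - S[i, SKCA])
                        - P[i, SK_OFF] * S[i, SKCA])
    S[i, CADEND] += dt * (-P[i, CA_SCALE] * I_CaPQ
                          - P[i, CA_DECAY] * S[i, CADEND])
    if S[i, CADEND] < 0.0:
        S[i, CADEND] = 0.0
    S[i, HNAA] += dt * (h_inf_a - S[i, HNAA]) / tau_h_a
    S[i, XKA] += dt * (alpha_xa * (1.0 - S[i, XKA]) - beta_xa * S[i, XKA])

    v = S[i, VS]
    if not (-V_BLOWUP < v < V_BLOWUP) or v != v:
        return False
    v = S[i, VD]
    if not (-V_BLOWUP < v < V_BLOWUP) or v != v:
        return False
    v = S[i, VA]
    if not (-V_BLOWUP < v < V_BLOWUP) or v != v:
        return False
    return True


@njit(cache=True)
def integrate_uncoupled(S, P, dt, n_steps, i_soma, i_dend):
    """Integrate n independent cells, recording every step.

    ``i_soma``/``i_dend``: (n_steps+1, n) external current densities.
    Returns (V_soma, V_dend, V_axon, Ca) records of shape (n_steps+1, n)
    and the index of the first blow-up step (-1 if none).
    """
    n = S.shape[0]
    rec_vs = np.empty((n_steps + 1, n))
    rec_vd = np.empty((n_steps + 1, n))
    rec_va = np.empty((n_steps + 1, n))
    rec_ca = np.empty((n_steps + 1, n))
    for i in range(n):
        rec_vs[0, i] = S[i, VS]
        rec_vd[0, i] = S[i, VD]
        rec_va[0, i] = S[i, VA]
        rec_ca[0, i] = S[i, CADEND]
    for t in range(n_steps):
        for i in range(n):
            ok = _step_cell(S, P, i, dt, i_soma[t, i], i_dend[t, i],
                            0.0, 0.0)
            if not ok:
                return rec_vs, rec_vd, rec_va, rec_ca, t
            rec_vs[t + 1, i] = S[i, VS]
            rec_vd[t + 1, i] = S[i, VD]
            rec_va[t + 1, i] = S[i, VA]
            rec_ca[t + 1, i] = S[i, CADEND]
    return rec_vs, rec_vd, rec_va, rec_ca, -1


@njit(cache=True)
def integrate_network_chunk(
    S, P, dt,
    ou,                 # (n_steps, n) somatic or dendritic OU current
    ou_to_soma,         # bool: OU into soma (else dendrite)
    stim_g,             # (n_steps,) AMPA conductance waveform, mS/cm^2
    stim_mask,          # (n,) 0/1 mask of stimulated cells
    e_syn,              # AMPA reversal, mV
    dc_soma, dc_dend,   # (n,) constant extra currents
    indptr, indices, weights,   # CSR gap adjacency over dendrites
    rec_stride,         # record every rec_stride-th step
    rec_vs, rec_vd,     # (n_rec, n) output buffers
    rec_offset,         # first row to fill in the record buffers
    step0,              # absolute index of the chunk's first step
    v_thresh, min_isi_steps,
    last_spike, spike_cell, spike_step, spike_count,
):
    """Advance the coupled network by one chunk of steps.

    Spikes are upward threshold crossings of V_soma at full resolution,
    with crossings closer than ``min_isi_steps`` to the previous spike of
    the same cell suppressed.  Returns the absolute blow-up step or -1.
    """
    n = S.shape[0]
    n_steps = ou.shape[0]
    gap = np.empty(n)
    r = rec_offset
    for t in range(n_steps):
        # gap currents from current dendritic potentials (Eq-1 saturation)
        for i in range(n):
            acc = 0.0
            vi = S[i, VD]
            for jj in range(indptr[i], indptr[i + 1]):
                j = indices[jj]
                dv = S[j, VD] - vi
                f = 0.8 * math.exp(-dv * dv / 100.0) + 0.2
                acc += weights[jj] * f * dv
            gap[i] = acc
        g_now = stim_g[t]
        for i in range(n):
            v_prev = S[i, VS]
            if ou_to_soma:
                i_soma = ou[t, i] + dc_soma[i]
                i_dend = dc_dend[i] + gap[i]
            else:
                i_soma = dc_soma[i]
                i_dend = ou[t, i] + dc_dend[i] + gap[i]
            ok = _step_cell(S, P, i, dt, i_soma, i_dend,
                            g_now * stim_mask[i], e_syn)
            if not ok:
                return step0 + t
            if v_prev < v_thresh <= S[i, VS]:
                if step0 + t - last_spike[i] >= min_isi_steps:
                    k = spike_count[0]
                    if k < spike_cell.shape[0]:
                        spike_cell[k] = i
                        spike_step[k] = step0 + t
                        spike_count[0] = k + 1
                    last_spike[i] = step0 + t
        if (step0 + t + 1) % rec_stride == 0:
            for i in range(n):
                rec_vs[r, i] = S[i, VS]
                rec_vd[r, i] = S[i, VD]
            r += 1
    return -1
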