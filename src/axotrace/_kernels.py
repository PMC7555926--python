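"""Numba inner loop of the node/internode integrator.

The stepper is a staggered semi-implicit scheme standard for
Hodgkin-Huxley-type threshold simulations: gating variables advance by
exponential Euler against rate tables sampled on a fine voltage grid, then
the two membrane potentials advance by backward Euler of the 2x2 linear
system obtained by freezing conductances at the new gate values.  The
scheme is unconditionally stable and bitwise deterministic.

State vector layout: [V_n, V_i, m, h, p, s_n, s_i, nf_n, nf_i, q].
``consts`` layout: [C_n, C_i, G_NaT, f_NaP, G_Ks_n, G_Ks_i, G_Kf_n,
G_Kf_i, G_H, G_Lk_n, G_Lk_i, G_BB, E_Na, E_K, E_H, E_Lk, Ip_n, Ip_i].
"""

import math

import numpy as np
from numba import njit

# gate j -> kinetic family row in the rate tables (m,h,p,s,nf,q)
GATE_FAM = np.array([0, 1, 2, 3, 3, 4, 4, 5], dtype=np.int64)
# gate j -> compartment whose potential drives it (0 node, 1 internode)
GATE_COMP = np.array([0, 0, 0, 0, 1, 0, 1, 1], dtype=np.int64)


@njit(cache=True, inline="always")
def _lerp(table, fam, pos, i0):
    w = pos - i0
    return table[fam, i0] * (1.0 - w) + table[fam, i0 + 1] * w


@njit(cache=True, inline="always")
def _step(y, dt, nominal, xinf, rate, decay, v0, inv_dv, nv, consts, i_stim):
    # gates: exponential Euler toward x_inf at the driving potential
    for j in range(8):
        v = y[0] if GATE_COMP[j] == 0 else y[1]
        pos = (v - v0) * inv_dv
        if pos < 0.0:
            pos = 0.0
        elif pos > nv - 2.0:
            pos = nv - 2.0
        i0 = int(pos)
        fam = GATE_FAM[j]
        xi = _lerp(xinf, fam, pos, i0)
        if nominal:
            dec = _lerp(decay, fam, pos, i0)
        else:
            r = _lerp(rate, fam, pos, i0)
            dec = math.exp(-r * dt)
        y[2 + j] = xi + (y[2 + j] - xi) * dec

    m = y[2]
    h = y[3]
    p = y[4]
    s_n = y[5]
    s_i = y[6]
    nf_n = y[7]
    nf_i = y[8]
    q = y[9]

    g_nat = consts[2] * m * m * m * h
    g_nap = consts[2] * consts[3] * p * p * p
    nf_n4 = nf_n * nf_n * nf_n * nf_n
    nf_i4 = nf_i * nf_i * nf_i * nf_i

    g_n = g_nat + g_nap + consts[4] * s_n + consts[6] * nf_n4 + consts[9]
    b_n = ((g_nat + g_nap) * consts[12]
           + (consts[4] * s_n + consts[6] * nf_n4) * consts[13]
           + consts[9] * consts[15]
           - consts[16] + i_stim)

    g_hq = consts[8] * q
    g_i = consts[5] * s_i + consts[7] * nf_i4 + g_hq + consts[10]
    b_i = ((consts[5] * s_i + consts[7] * nf_i4) * consts[13]
           + g_hq * consts[14]
           + consts[10] * consts[15]
           - consts[17])

    gbb = consts[11]
    a11 = consts[0] / dt + g_n + gbb
    a22 = consts[1] / dt + g_i + gbb
    r1 = consts[0] / dt * y[0] + b_n
    r2 = consts[1] / dt * y[1] + b_i
    det = a11 * a22 - gbb * gbb
    y[0] = (r1 * a22 + gbb * r2) / det
    y[1] = (a11 * r2 + gbb * r1) / det


@njit(cache=True)
def run_segments(y, t0, edges, amps, dt_nom, xinf, rate, decay, v0, inv_dv,
                 consts, rec_t, rec_y, win_lo, win_hi, early_stop):
    """Integrate over piecewise-constant stimulus segments.

    Records every step into ``rec_t``/``rec_y`` when they are non-empty.
    Returns (n_recorded, vmax) where vmax is the maximum nodal potential
    observed at step ends inside [win_lo, win_hi].  With ``early_stop``
    the loop exits as soon as V_n exceeds 0 mV inside the window.
    """
    nv = xinf.shape[1]
    record = rec_t.shape[0] > 0
    n_rec = 0
    if record:
        rec_t[0] = t0
        for c in range(10):
            rec_y[0, c] = y[c]
        n_rec = 1
    vmax = -1.0e30
    seg_start = t0
    for k in range(amps.shape[0]):
        seg_end = edges[k + 1]
        amp = amps[k]
        seg_len = seg_end - seg_start
        n_full = int(math.floor(seg_len / dt_nom + 1e-9))
        rem = seg_len - n_full * dt_nom
        if rem < 1e-9:
            rem = 0.0
        n_steps = n_full + (1 if rem > 0.0 else 0)
        for i in range(n_steps):
            if i < n_full:
                dt = dt_nom
                nominal = True
                t = seg_start + (i + 1) * dt_nom
            else:
                dt = rem
                nominal = False
                t = seg_end
            _step(y, dt, nominal, xinf, rate, decay, v0, inv_dv, nv, consts, amp)
            if record:
                rec_t[n_rec] = t
                for c in range(10):
                    rec_y[n_rec, c] = y[c]
                n_rec += 1
            if win_lo <= t <= win_hi and y[0] > vmax:
                vmax = y[0]
                if early_stop and vmax > 0.0:
                    return n_rec, vmax
        seg_start = seg_end
    return n_rec, vmax
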