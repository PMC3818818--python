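"""Fixed-step RK4 integrator for the delayed NF-κB network.

The two lagged terms (TRAF1 and p100 translation reading their mRNA at
t - tau) are evaluated by linear interpolation of a per-step history
buffer; the pre-stimulus history is the constant steady state. The inner
loop is numba-compiled when numba is importable and falls back to pure
Python otherwise.
"""

from __future__ import annotations

import numpy as np

#: Packing order of the parameter vector handed to the compiled core.
#: Must equal ``ModelParameters.field_names()`` (asserted in model.py).
PACK_ORDER = (
    "tau_traf1_min",
    "tau_nfkb2_min",
    "ikk_act_rate",
    "ikk_inact_rate",
    "txn_max_ikba",
    "txn_max_traf1",
    "txn_max_p100",
    "txn_max_canon_reporter",
    "txn_max_tnip1",
    "txn_fb_p100",
    "txn_fb_traf1",
    "hill_K_rela",
    "hill_K_p52",
    "hill_K_p52_traf1",
    "hill_h",
    "tln_rate_ikba",
    "tln_rate_traf1",
    "tln_rate_p100",
    "deg_mrna",
    "deg_ikba",
    "deg_traf1",
    "deg_p100",
    "deg_p52",
    "nik_synth_rate",
    "nik_fast_deg",
    "nik_stable_deg",
    "traf1_nik_bind",
    "proc_rate",
    "proc_K",
    "ikba_rela_assoc",
    "ikba_deg_by_ikk",
    "rela_total",
    "basal_txn",
)

# status codes returned by the core
OK = 0
NONFINITE = 1


def _hill(x, K, h):
    if x <= 0.0:
        return 0.0
    xn = x**h
    return xn / (K**h + xn)


def _rhs(a_ikk, y, tr_lag, p1_lag, p, dy):
    """Right-hand side; ``a_ikk`` is the gated IKK activation rate."""
    Hr = _hill(y[4], p[11], p[14])  # RelA_nuclear drive
    Hp = _hill(y[12], p[12], p[14])  # p52 drive on the p100/TNIP1 promoters
    Hpt = _hill(y[12], p[13], p[14])  # p52 drive on the TRAF1 promoter
    basal = p[32]
    deg_m = p[18]
    dy[0] = a_ikk * (1.0 - y[0]) - p[3] * y[0]
    dy[1] = basal + p[4] * Hr - deg_m * y[1]
    dy[2] = p[15] * y[1] - p[29] * y[2] * y[4] - p[19] * y[2]
    dy[3] = p[29] * y[2] * y[4] - p[30] * y[0] * y[3]
    dy[4] = p[30] * y[0] * y[3] - p[29] * y[2] * y[4]
    dy[5] = basal + p[7] * Hr - deg_m * y[5]
    dy[6] = basal + p[5] * Hr + p[10] * Hpt - deg_m * y[6]
    dy[7] = p[16] * tr_lag - p[20] * y[7] - p[26] * y[7] * y[8]
    dy[8] = p[23] - p[24] * y[8] - p[26] * y[7] * y[8]
    dy[9] = p[26] * y[7] * y[8] - p[25] * y[9]
    dy[10] = basal + p[6] * Hr + p[9] * Hp - deg_m * y[10]
    proc = p[27] * y[9] / (p[28] + y[9])  # saturable processing by TRAF1-NIK
    dy[11] = p[17] * p1_lag - proc * y[11] - p[21] * y[11]
    dy[12] = proc * y[11] - p[22] * y[12]
    dy[13] = basal + p[8] * Hp - deg_m * y[13]


def _lagged(buf, filled, t_stage, tau, dt, h0, cur):
    """mRNA value at ``t_stage - tau`` (constant ``h0`` before t=0)."""
    if tau <= 0.0:
        return cur
    u = t_stage - tau
    if u <= 0.0:
        return h0
    x = u / dt
    j = int(x)
    if j >= filled:
        return buf[filled]
    w = x - j
    return (1.0 - w) * buf[j] + w * buf[j + 1]


def _integrate(p, y0, stim_kind, onset, amplitude, t_end, dt, out_every):
    """RK4 with delayed reads; returns (out, status, worst_neg, t_bad).

    out has one row per sampled time (every ``out_every`` internal steps,
    including t=0 and t_end); worst_neg is the most negative pre-clamp
    excursion seen (0.0 if none).
    """
    tau1 = p[0]
    tau2 = p[1]
    n_steps = int(round(t_end / dt))
    n_out = n_steps // out_every + 1
    out = np.empty((n_out, 14))
    tr_buf = np.empty(n_steps + 1)
    p1_buf = np.empty(n_steps + 1)
    y = y0.copy()
    k1 = np.empty(14)
    k2 = np.empty(14)
    k3 = np.empty(14)
    k4 = np.empty(14)
    yt = np.empty(14)
    h_tr = y0[6]
    h_p1 = y0[10]
    tr_buf[0] = y[6]
    p1_buf[0] = y[10]
    out[0] = y
    worst_neg = 0.0
    act = p[2]
    half = 0.5 * dt
    for i in range(n_steps):
        t = i * dt
        # stage gating of the stimulus step
        a0 = act * amplitude if (stim_kind == 1 and t >= onset) else 0.0
        am = act * amplitude if (stim_kind == 1 and t + half >= onset) else 0.0
        a1 = act * amplitude if (stim_kind == 1 and t + dt >= onset) else 0.0

        tr = _lagged(tr_buf, i, t, tau1, dt, h_tr, y[6])
        pl = _lagged(p1_buf, i, t, tau2, dt, h_p1, y[10])
        _rhs(a0, y, tr, pl, p, k1)

        for j in range(14):
            yt[j] = y[j] + half * k1[j]
        tr = _lagged(tr_buf, i, t + half, tau1, dt, h_tr, yt[6])
        pl = _lagged(p1_buf, i, t + half, tau2, dt, h_p1, yt[10])
        _rhs(am, yt, tr, pl, p, k2)

        for j in range(14):
            yt[j] = y[j] + half * k2[j]
        tr = _lagged(tr_buf, i, t + half, tau1, dt, h_tr, yt[6])
        pl = _lagged(p1_buf, i, t + half, tau2, dt, h_p1, yt[10])
        _rhs(am, yt, tr, pl, p, k3)

        for j in range(14):
            yt[j] = y[j] + dt * k3[j]
        tr = _lagged(tr_buf, i, t + dt, tau1, dt, h_tr, yt[6])
        pl = _lagged(p1_buf, i, t + dt, tau2, dt, h_p1, yt[10])
        _rhs(a1, yt, tr, pl, p, k4)

        sixth = dt / 6.0
        ok = True
        for j in range(14):
            v = y[j] + sixth * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            if not np.isfinite(v):
                ok = False
                v = np.nan
            elif v < 0.0:
                if v < worst_neg:
                    worst_neg = v
                v = 0.0
            y[j] = v
        if not ok:
            return out, NONFINITE, worst_neg, t + dt
        tr_buf[i + 1] = y[6]
        p1_buf[i + 1] = y[10]
        if (i + 1) % out_every == 0:
            out[(i + 1) // out_every] = y
    return out, OK, worst_neg, 0.0


try:  # optional JIT of the hot loop
    from numba import njit

    _hill = njit(cache=True)(_hill)
    _rhs = njit(cache=True)(_rhs)
    _lagged = njit(cache=True)(_lagged)
    _integrate = njit(cache=True)(_integrate)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba present in supported envs
    HAVE_NUMBA = False
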