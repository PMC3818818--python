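"""Independent reference implementations used only by the tests.

These are deliberately written from the model's stated rate equations and
textbook definitions, not from the package's own integrator or clustering
code, so agreement is a genuine two-route check.
"""

from __future__ import annotations

import math

import numpy as np


def euler_dde(params, tau1, tau2, t_end, dt, y0, sample_every):
    """First-order fixed-step integration with ring-buffer history.

    ``y0`` doubles as the constant pre-stimulus history. Returns an array
    of states sampled every ``sample_every`` steps (including t=0).
    """
    p = params
    h = p.hill_h

    def hill(x, K):
        if x <= 0:
            return 0.0
        xn = x**h
        return xn / (K**h + xn)

    n = int(round(t_end / dt))
    lag1 = int(round(tau1 / dt))
    lag2 = int(round(tau2 / dt))
    buf_len = max(lag1, lag2) + 1
    tr_buf = [y0[6]] * buf_len
    p1_buf = [y0[10]] * buf_len
    y = list(map(float, y0))
    out = [list(y)]
    for i in range(n):
        head = i % buf_len
        tr_lag = y[6] if lag1 == 0 else tr_buf[(i - lag1) % buf_len] if i >= lag1 else y0[6]
        p1_lag = y[10] if lag2 == 0 else p1_buf[(i - lag2) % buf_len] if i >= lag2 else y0[10]
        Hr = hill(y[4], p.hill_K_rela)
        Hp = hill(y[12], p.hill_K_p52)
        Hpt = hill(y[12], p.hill_K_p52_traf1)
        proc = p.proc_rate * y[9] / (p.proc_K + y[9])
        dy = [
            p.ikk_act_rate * (1.0 - y[0]) - p.ikk_inact_rate * y[0],
            p.basal_txn + p.txn_max_ikba * Hr - p.deg_mrna * y[1],
            p.tln_rate_ikba * y[1] - p.ikba_rela_assoc * y[2] * y[4]
            - p.deg_ikba * y[2],
            p.ikba_rela_assoc * y[2] * y[4] - p.ikba_deg_by_ikk * y[0] * y[3],
            p.ikba_deg_by_ikk * y[0] * y[3] - p.ikba_rela_assoc * y[2] * y[4],
            p.basal_txn + p.txn_max_canon_reporter * Hr - p.deg_mrna * y[5],
            p.basal_txn + p.txn_max_traf1 * Hr + p.txn_fb_traf1 * Hpt
            - p.deg_mrna * y[6],
            p.tln_rate_traf1 * tr_lag - p.deg_traf1 * y[7]
            - p.traf1_nik_bind * y[7] * y[8],
            p.nik_synth_rate - p.nik_fast_deg * y[8]
            - p.traf1_nik_bind * y[7] * y[8],
            p.traf1_nik_bind * y[7] * y[8] - p.nik_stable_deg * y[9],
            p.basal_txn + p.txn_max_p100 * Hr + p.txn_fb_p100 * Hp
            - p.deg_mrna * y[10],
            p.tln_rate_p100 * p1_lag - proc * y[11] - p.deg_p100 * y[11],
            proc * y[11] - p.deg_p52 * y[12],
            p.basal_txn + p.txn_max_tnip1 * Hp - p.deg_mrna * y[13],
        ]
        for j in range(14):
            v = y[j] + dt * dy[j]
            y[j] = v if v > 0.0 else 0.0
        tr_buf[(i + 1) % buf_len] = y[6]
        p1_buf[(i + 1) % buf_len] = y[10]
        if (i + 1) % sample_every == 0:
            out.append(list(y))
    return np.array(out)


def brute_force_upgma(matrix):
    """Naive UPGMA: average cross-pair distance recomputed from leaves.

    Distances use pairwise-complete Euclidean coordinates rescaled by
    sqrt(p_total / p_observed); ties break toward the smallest (a, b)
    cluster-index pair. Returns a list of (a, b, height, size) merges
    with scipy-style indices.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    p_total = x.shape[1]

    def leaf_dist(i, j):
        mask = ~(np.isnan(x[i]) | np.isnan(x[j]))
        p = int(mask.sum())
        if p == 0:
            return math.inf
        return math.sqrt(np.sum((x[i][mask] - x[j][mask]) ** 2) * p_total / p)

    D = [[leaf_dist(i, j) for j in range(n)] for i in range(n)]
    clusters = {i: [i] for i in range(n)}
    merges = []
    nxt = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                cross = [D[i][j] for i in clusters[a] for j in clusters[b]]
                d = sum(cross) / len(cross)
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        members = clusters.pop(a) + clusters.pop(b)
        clusters[nxt] = members
        merges.append((a, b, d, len(members)))
        nxt += 1
    return merges
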