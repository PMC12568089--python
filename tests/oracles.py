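"""Independent brute-force oracles used by the test suite only.

Each function recomputes a package operation by direct enumeration over
all sample pairs / sign assignments, deliberately ignoring the package's
vectorised implementations.
"""

from itertools import product

import numpy as np


def brute_pair_per_second(rt, rv, dt, dv):
    """O(n*m) scan: pairs at equal floored-second timestamps."""
    out = []
    for i, t in enumerate(rt):
        for j, u in enumerate(dt):
            if int(np.floor(t)) == int(np.floor(u)):
                out.append((int(np.floor(t)), rv[i], dv[j]))
    return out


def brute_pair_trailing(rt, rv, dt, dv, window):
    """For each reference timestamp t: mean of device samples in (t-w, t]."""
    out = []
    for i, t in enumerate(rt):
        vals = [dv[j] for j, u in enumerate(dt) if (t - window) < u <= t]
        if vals:
            out.append((t, rv[i], float(np.mean(vals))))
    return out


def brute_pair_sync(rt, rv, dt, dv, window):
    """Consecutive [k*w, (k+1)*w) bins from t=0; drop bins empty on a side."""
    bins = sorted({int(np.floor(t / window)) for t in rt} | {int(np.floor(t / window)) for t in dt})
    out = []
    for k in bins:
        r = [rv[i] for i, t in enumerate(rt) if k * window <= t < (k + 1) * window]
        d = [dv[j] for j, u in enumerate(dt) if k * window <= u < (k + 1) * window]
        if r and d:
            out.append((k * window, float(np.mean(r)), float(np.mean(d))))
    return out


def exact_wilcoxon_p(d):
    """Two-sided signed-rank p by full 2^n enumeration (no ties, no zeros)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = float(ranks[d > 0].sum())
    total = ranks.sum()
    # null: each rank positive with probability 1/2
    count = 0
    for signs in product([0, 1], repeat=n):
        w = float(np.dot(signs, ranks))
        if min(w, total - w) <= min(w_obs, total - w_obs):
            count += 1
    return count / 2**n


def lin_ccc_by_hand(x, y):
    """Moment form evaluated step by step with sample (n-1) moments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    mx, my = x.sum() / n, y.sum() / n
    sx = ((x - mx) ** 2).sum() / (n - 1)
    sy = ((y - my) ** 2).sum() / (n - 1)
    sxy = ((x - mx) * (y - my)).sum() / (n - 1)
    return 2 * sxy / (sx + sy + (mx - my) ** 2)
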