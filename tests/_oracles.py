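"""Brute-force oracles, independent of the package implementation.

Each oracle recomputes a statistic by direct enumeration or the literal
textbook product/sum, for comparison against the vectorized implementations.
"""

from itertools import combinations
from math import comb

import numpy as np


def km_oracle(times, events):
    """Product-limit estimate by a literal product over event times.

    Returns dict time -> S(time).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    out = {}
    s = 1.0
    for t in sorted(set(times[events])):
        n_risk = int(np.sum(times >= t))
        d = int(np.sum(events & (times == t)))
        s *= 1 - d / n_risk
        out[t] = s
    return out


def logrank_oracle(t1, e1, t2, e2):
    """Two-group Mantel-Cox chi-square via the event-table sum (O-E)^2 / V."""
    t1, e1 = np.asarray(t1, float), np.asarray(e1, bool)
    t2, e2 = np.asarray(t2, float), np.asarray(e2, bool)
    t_all = np.concatenate([t1, t2])
    e_all = np.concatenate([e1, e2])
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(t_all[e_all])):
        n1 = int(np.sum(t1 >= t))
        n2 = int(np.sum(t2 >= t))
        n = n1 + n2
        d = int(np.sum(e_all & (t_all == t)))
        d1 = int(np.sum(e1 & (t1 == t)))
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def auc_oracle(conc, is_case):
    """Mann-Whitney AUC: fraction of (case, control) pairs correctly ordered,
    half credit for ties."""
    conc = np.asarray(conc, float)
    is_case = np.asarray(is_case, bool)
    cases = conc[is_case]
    ctrls = conc[~is_case]
    wins = sum(
        1.0 if c > k else (0.5 if c == k else 0.0) for c in cases for k in ctrls
    )
    return wins / (len(cases) * len(ctrls))


def fisher_oracle(table):
    """Two-sided Fisher p by enumerating all tables with the observed margins
    using exact binomial coefficients."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(p for x in range(0, min(r1, c1) + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-9))


def permutation_ttest_p(a, b):
    """Exact permutation p for the difference of means (two-sided),
    enumerating every regrouping of the pooled sample."""
    a, b = list(a), list(b)
    pooled = a + b
    n = len(a)
    obs = abs(np.mean(a) - np.mean(b))
    total = 0
    extreme = 0
    idx = range(len(pooled))
    for pick in combinations(idx, n):
        ga = [pooled[i] for i in pick]
        gb = [pooled[i] for i in idx if i not in pick]
        total += 1
        if abs(np.mean(ga) - np.mean(gb)) >= obs - 1e-12:
            extreme += 1
    return extreme / total


def youden_scan_oracle(conc, is_case):
    """Exhaustive scan of every observed threshold for max sens+spec;
    ties toward the lower cutoff."""
    conc = np.asarray(conc, float)
    is_case = np.asarray(is_case, bool)
    best = None
    for thr in sorted(set(conc)):
        called = conc >= thr
        sens = np.sum(called & is_case) / np.sum(is_case)
        spec = np.sum(~called & ~is_case) / np.sum(~is_case)
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and thr < best[1]
        ):
            best = (j, thr, sens, spec)
    return {"cutoff": best[1], "sensitivity": best[2], "specificity": best[3]}
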