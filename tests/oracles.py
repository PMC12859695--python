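"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, quadrature, nested
loops) and shares no logic with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad


def exact_wilcoxon_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every assignment of
    the pooled ranks to the first sample (tie-free inputs only)."""
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n1 = len(x)
    ranks_x = [pooled.index(v) + 1 for v in x]
    u_obs = sum(ranks_x) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, len(pooled) + 1), n1):
        us.append(sum(combo) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the step-up definition
    applied literally to the sorted vector."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        val = p[order[rank - 1]] * m / rank
        running_min = min(running_min, val)
        adj_sorted[rank - 1] = min(running_min, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def kruskal_h(groups) -> float:
    """Kruskal-Wallis H from the explicit rank-sum formula (no ties)."""
    pooled = sorted(v for g in groups for v in g)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n = len(pooled)
    h = 0.0
    for g in groups:
        r = sum(pooled.index(v) + 1 for v in g)
        h += r * r / len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


def multinomial_ci_expectation(p, n: int) -> float:
    """E[(B - A)/(A + B) | A + B > 0] for (A, B, C) ~ Multinomial(n, p),
    by direct enumeration of all outcomes."""
    pc, po, pz = p
    num = 0.0
    denom = 0.0
    for a in range(n + 1):
        for b in range(n + 1 - a):
            c = n - a - b
            if a + b == 0:
                continue
            w = (math.factorial(n)
                 / (math.factorial(a) * math.factorial(b) * math.factorial(c))
                 * pc ** a * po ** b * pz ** c)
            num += w * (b - a) / (a + b)
            denom += w
    return num / denom


def sinusoid_arc_ratio(amplitude: float, wavelength: float,
                       span: float) -> float:
    """Arc-length ratio of y = A sin(2 pi x / L) over [0, span] to the
    straight baseline, by numerical quadrature."""
    k = 2 * math.pi / wavelength

    def integrand(x):
        return math.sqrt(1.0 + (amplitude * k * math.cos(k * x)) ** 2)

    length, _ = quad(integrand, 0.0, span, limit=500)
    return length / span


def brute_force_pirouettes(hs, window=3.0, angle_threshold=120.0,
                           drop_threshold=0.40, baseline=2.0,
                           merge_gap=1.0, mode="net",
                           min_baseline_frac=0.5):
    """Exhaustive sub-interval scan over a HeadingSeries, followed by a
    naive merge.  Returns (t_start, t_end, net_turn, event_speed,
    baseline_speed) tuples."""
    m = len(hs.times)
    ok = [not math.isnan(h) for h in hs.headings]
    cands = []
    for i in range(m):
        if not ok[i]:
            continue
        bstart = hs.times[i] - baseline
        if bstart < hs.times[0] - 1e-9:
            continue
        bidx = [b for b in range(i)
                if hs.times[b] >= bstart - 1e-9]
        if not bidx:
            continue
        bvalid = [b for b in bidx if hs.valid[b]]
        if len(bvalid) == 0 or len(bvalid) < math.ceil(
                min_baseline_frac * len(bidx)):
            continue
        bmean = sum(hs.speeds[b] for b in bvalid) / len(bvalid)
        for j in range(i + 1, m):
            if hs.end_times[j] - hs.times[i] > window + 1e-9:
                break
            if not all(ok[k] for k in range(i, j + 1)):
                continue
            incs = [hs.turn_increments[k] for k in range(i + 1, j + 1)]
            turn = sum(incs) if mode == "net" else sum(abs(v) for v in incs)
            if abs(turn) <= angle_threshold:
                continue
            vmean = sum(hs.speeds[k] for k in range(i, j + 1)) / (j - i + 1)
            if vmean <= (1.0 - drop_threshold) * bmean:
                cands.append((hs.times[i], hs.end_times[j], turn, vmean,
                              bmean))
    # naive merge: union candidates closer than merge_gap, keep the
    # maximal-|net_turn| member of each group
    cands.sort(key=lambda c: (c[0], c[1]))
    groups = []
    for c in cands:
        if groups and c[0] - groups[-1]["end"] < merge_gap:
            groups[-1]["members"].append(c)
            groups[-1]["end"] = max(groups[-1]["end"], c[1])
        else:
            groups.append({"members": [c], "end": c[1]})
    events = []
    for g in groups:
        best = max(g["members"],
                   key=lambda c: (round(abs(c[2]), 6), -c[0], -c[1]))
        events.append(best)
    return events
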