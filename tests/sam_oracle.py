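"""Independent brute-force reference for the SAM procedure.

Pure-Python, per-gene loops and exhaustive permutation enumeration;
shares no code with the package implementation.
"""

import itertools
import math
import statistics


def oracle_scatter(g1, g2):
    n1, n2 = len(g1), len(g2)
    m1 = sum(g1) / n1
    m2 = sum(g2) / n2
    ss = sum((x - m1) ** 2 for x in g1) + sum((x - m2) ** 2 for x in g2)
    return math.sqrt((1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2) * ss)


def oracle_d(g1, g2, s0):
    m1 = sum(g1) / len(g1)
    m2 = sum(g2) / len(g2)
    denom = oracle_scatter(g1, g2) + s0
    if denom == 0:
        return 0.0
    return (m2 - m1) / denom


def oracle_null(rows, n1, s0):
    """All relabelings of the pooled columns; returns (expected order
    statistics, list of per-permutation d lists)."""
    n = len(rows[0])
    null_d = []
    for combo in itertools.combinations(range(n), n1):
        rest = [i for i in range(n) if i not in combo]
        d = [
            oracle_d([row[i] for i in combo], [row[i] for i in rest], s0)
            for row in rows
        ]
        null_d.append(d)
    n_genes = len(rows)
    expected = []
    for i in range(n_genes):
        expected.append(statistics.mean(sorted(d)[i] for d in null_d))
    return expected, null_d


def oracle_calls(d, expected, null_d, delta):
    """Delta-threshold rule and median-exceedance FDR, evaluated naively."""
    pairs = sorted(zip(sorted(d), expected))
    up_candidates = [di for di, ei in pairs if di > 0 and di - ei >= delta]
    cut_up = min(up_candidates) if up_candidates else float("inf")
    low_candidates = [di for di, ei in pairs if di < 0 and ei - di >= delta]
    cut_low = max(low_candidates) if low_candidates else float("-inf")
    called = [di >= cut_up or di <= cut_low for di in d]
    n_called = sum(called)
    if n_called == 0:
        return called, 0.0, cut_low, cut_up
    counts = sorted(
        sum(1 for v in perm if v >= cut_up or v <= cut_low) for perm in null_d
    )
    fdr = statistics.median(counts) / n_called
    return called, fdr, cut_low, cut_up


def oracle_s0_cv_search(scatters, diffs, grid):
    """Exhaustive search over the percentile grid using an independently
    coded evaluation of the window-CV criterion (about 20 genes per
    quantile window, at most 100 windows; MAD/0.6745 spread; sample CV)."""
    import numpy as np

    s = list(scatters)
    n = len(s)
    n_windows = int(min(100, max(2, n // 20)))
    edges = [float(np.quantile(s, q)) for q in np.linspace(0, 1, n_windows + 1)]

    def window_of(value):
        w = 0
        for k in range(n_windows):
            if value >= edges[k]:
                w = k
        return w

    best = None
    for alpha in sorted(grid):
        s0 = float(np.quantile(s, alpha))
        d = [
            (diff / (si + s0)) if si + s0 > 0 else 0.0
            for diff, si in zip(diffs, s)
        ]
        mads = []
        for w in range(n_windows):
            dw = [di for di, si in zip(d, s) if window_of(si) == w]
            if not dw:
                continue
            med = statistics.median(dw)
            mads.append(statistics.median(abs(x - med) for x in dw) / 0.6745)
        mean = statistics.mean(mads)
        if mean == 0 or len(mads) < 2:
            cv = float("inf")
        else:
            cv = statistics.stdev(mads) / mean
        if best is None or cv < best[0] - 1e-12:
            best = (cv, s0)
    return best[1]
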