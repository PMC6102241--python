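"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementations they
check: the changepoint oracle is a plain O(n^2) dynamic program over
naively-computed segment costs, and the liftover oracle projects one
base at a time through chain blocks.
"""

from __future__ import annotations

import numpy as np


def dp_changepoints(y, penalty: float, min_segment: int = 1):
    """Exact optimal partitioning by full dynamic programming.

    Minimizes sum of within-segment squared errors + penalty per
    changepoint. Returns (breakpoints, objective).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)

    def sse(i, j):
        seg = y[i:j]
        return float(np.sum((seg - seg.mean()) ** 2))

    INF = float("inf")
    F = [INF] * (n + 1)
    F[0] = -penalty
    arg = [0] * (n + 1)
    for t in range(min_segment, n + 1):
        for s in range(0, t - min_segment + 1):
            if F[s] == INF:
                continue
            v = F[s] + sse(s, t) + penalty
            if v < F[t]:
                F[t] = v
                arg[t] = s
    bkps = []
    t = n
    while t > 0:
        s = arg[t]
        if s > 0:
            bkps.append(s)
        t = s
    return sorted(bkps), F[n]


def project_base(chrom: str, pos: int, chains):
    """Map one source base through chain blocks; None in a gap."""
    for c in chains:
        if c.source_interval.chrom != chrom:
            continue
        for s_off, t_off, ln in c.blocks:
            s = c.source_interval.start + s_off
            if s <= pos < s + ln:
                return (c.target_interval.chrom,
                        c.target_interval.start + t_off + (pos - s))
    return None


def brute_liftover(iv, chains, min_match: float = 0.5):
    """Per-base projection of an interval; mirrors the liftover contract."""
    hits = []
    for p in range(iv.start, iv.end):
        m = project_base(iv.chrom, p, chains)
        if m is not None:
            hits.append(m)
    if not hits:
        return None
    chroms = {c for c, _ in hits}
    if len(chroms) > 1:
        return None
    if len(hits) / iv.length < min_match:
        return None
    ps = [p for _, p in hits]
    return (chroms.pop(), min(ps), max(ps) + 1)
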