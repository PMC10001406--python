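"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: the burst checker
enumerates windows instead of scanning, and the dissimilarity oracle
evaluates the defining pointwise formula with naive searches and integrates
the piecewise-linear profile through segment midpoints.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np


def brute_force_bursts(times, params) -> List[Tuple[int, int]]:
    """Enumerate-all-windows max-interval checker (O(n^2) in spikes)."""
    t = np.asarray(times, dtype=float)
    n = t.size
    satisfying = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            isis = np.diff(t[i : j + 1])
            if isis[0] <= params.max_start_isi and np.all(isis <= params.max_end_isi):
                satisfying.append((i, j))
    maximal = [
        w
        for w in satisfying
        if not any(
            a <= w[0] and w[1] <= b and (a, b) != w for (a, b) in satisfying
        )
    ]
    maximal.sort()
    merged: List[List[int]] = []
    for i, j in maximal:
        if merged and t[i] - t[merged[-1][1]] < params.min_ibi:
            merged[-1][1] = j
        else:
            merged.append([i, j])
    return [
        (i, j)
        for i, j in merged
        if t[j] - t[i] >= params.min_duration and j - i + 1 >= params.min_spikes
    ]


def _aug(train, t0, t1):
    s = [float(x) for x in train]
    if not s or s[0] > t0:
        s = [t0] + s
    if s[-1] < t1:
        s = s + [t1]
    return s


def _dissim_at(t, ta, tb):
    """The instantaneous dissimilarity at a non-spike time t, from scratch."""

    def side_terms(ts, other):
        tP = max(s for s in ts if s <= t)
        tF = min(s for s in ts if s > t)
        xisi = tF - tP
        dtP = min(abs(tP - o) for o in other)
        dtF = min(abs(tF - o) for o in other)
        xP = t - tP
        xF = tF - t
        return (dtP * xF + dtF * xP) / xisi, xisi

    Sa, xa = side_terms(ta, tb)
    Sb, xb = side_terms(tb, ta)
    return (Sa * xb + Sb * xa) / (2.0 * ((xa + xb) / 2.0) ** 2)


def spike_distance_oracle(a, b, t0: float, t1: float) -> float:
    """Exact time-averaged dissimilarity via midpoint evaluation.

    The profile is linear between corner points (pooled spike times), so the
    midpoint value times the segment width integrates each segment exactly.
    """
    ta = _aug(a, t0, t1)
    tb = _aug(b, t0, t1)
    corners = sorted(set(ta) | set(tb))
    total = 0.0
    for c0, c1 in zip(corners[:-1], corners[1:]):
        total += _dissim_at((c0 + c1) / 2.0, ta, tb) * (c1 - c0)
    return total / (t1 - t0)
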