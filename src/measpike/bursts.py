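"""Max-interval burst detection and per-train burst features.

The max-interval method classifies bursts with five parameters: a burst opens
at an inter-spike interval (ISI) at or below ``max_start_isi`` and extends
while ISIs stay at or below ``max_end_isi``; adjacent candidates closer than
``min_ibi`` (last spike to first spike) are merged; finally candidates
shorter than ``min_duration`` or with fewer than ``min_spikes`` spikes are
discarded.  The defaults are the standard 0.1 / 0.25 / 0.5 / 0.05 s and six
spikes.  The operation order detect -> merge -> filter is pinned: merged
candidates are re-measured before filtering, so two sub-threshold clusters
can survive as one merged burst.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

__all__ = ["BurstParams", "BurstSet", "detect_bursts", "burst_summary"]


@dataclass(frozen=True)
class BurstParams:
    max_start_isi: float = 0.1  # s, ISI that opens a burst
    max_end_isi: float = 0.25  # s, ISI that keeps a burst open
    min_ibi: float = 0.5  # s, minimum inter-burst interval
    min_duration: float = 0.05  # s
    min_spikes: int = 6

    def __post_init__(self) -> None:
        if not (0 < self.max_start_isi <= self.max_end_isi):
            raise ValueError("require 0 < max_start_isi <= max_end_isi")
        if min(self.min_ibi, self.min_duration) <= 0 or self.min_spikes < 1:
            raise ValueError("min_ibi, min_duration and min_spikes must be positive")


@dataclass
class BurstSet:
    """Detected bursts as (first, last) spike-index pairs into the train."""

    indices: np.ndarray  # (n_bursts, 2) inclusive spike indices
    train: np.ndarray  # the spike times the indices refer to

    @property
    def n_bursts(self) -> int:
        return self.indices.shape[0]

    def __len__(self) -> int:
        return self.n_bursts

    @property
    def durations(self) -> np.ndarray:
        """Last spike time minus first spike time, per burst (s)."""
        if self.n_bursts == 0:
            return np.empty(0)
        return self.train[self.indices[:, 1]] - self.train[self.indices[:, 0]]

    @property
    def spike_counts(self) -> np.ndarray:
        if self.n_bursts == 0:
            return np.empty(0, dtype=int)
        return self.indices[:, 1] - self.indices[:, 0] + 1

    @property
    def intervals(self) -> np.ndarray:
        """(n_bursts, 2) start/end times (s)."""
        if self.n_bursts == 0:
            return np.empty((0, 2))
        return self.train[self.indices]

    def n_spikes_in_bursts(self) -> int:
        return int(self.spike_counts.sum())


def detect_bursts(train: np.ndarray, params: Optional[BurstParams] = None) -> BurstSet:
    """Run the max-interval scan on a sorted spike train.

    Raises ``ValueError`` if the train is not strictly increasing.
    """
    if params is None:
        params = BurstParams()
    t = np.asarray(train, dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("spike train must be strictly increasing")
    n = t.size
    # 1. scan: open at ISI <= max_start_isi, extend while ISI <= max_end_isi
    candidates: List[Tuple[int, int]] = []
    i = 0
    while i < n - 1:
        if t[i + 1] - t[i] <= params.max_start_isi:
            j = i + 1
            while j < n - 1 and t[j + 1] - t[j] <= params.max_end_isi:
                j += 1
            candidates.append((i, j))
            i = j + 1
        else:
            i += 1
    # 2. merge candidates separated (last spike to first spike) by < min_ibi
    merged: List[Tuple[int, int]] = []
    for c in candidates:
        if merged and t[c[0]] - t[merged[-1][1]] < params.min_ibi:
            merged[-1] = (merged[-1][0], c[1])
        else:
            merged.append(c)
    # 3. re-measure and filter
    final = [
        c
        for c in merged
        if (t[c[1]] - t[c[0]]) >= params.min_duration
        and (c[1] - c[0] + 1) >= params.min_spikes
    ]
    idx = np.asarray(final, dtype=int).reshape(-1, 2)
    return BurstSet(indices=idx, train=t)


def burst_summary(
    train: np.ndarray, bursts: BurstSet
) -> Tuple[float, float, float]:
    """Per-train burst features.

    Returns ``(pct_spikes_in_bursts, mean_burst_duration, mean_within_burst_isi)``.
    The within-burst ISI mean pools all intra-burst ISIs across bursts.  An
    empty burst set yields ``(0.0, nan, nan)``.
    """
    t = np.asarray(train, dtype=float)
    if bursts.n_bursts == 0:
        return 0.0, float("nan"), float("nan")
    pct = 100.0 * bursts.n_spikes_in_bursts() / t.size
    mean_dur = float(bursts.durations.mean())
    isis = np.concatenate(
        [np.diff(t[a : b + 1]) for a, b in bursts.indices]
    )
    return float(pct), mean_dur, float(isis.mean())
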