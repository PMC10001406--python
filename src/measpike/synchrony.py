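"""SPIKE-distance spike-train dissimilarity and multivariate synchrony.

The SPIKE-distance is a parameter-free, time-resolved dissimilarity between
two spike trains.  At every time t each train contributes a locally weighted
term built from the distances of its preceding and following spikes to the
nearest spikes of the other train, normalized by the local inter-spike
intervals:

    S_n(t) = (dtP_n * xF_n(t) + dtF_n * xP_n(t)) / xISI_n

where xP/xF are the times since/until the train's preceding/following spike,
xISI their sum, and dtP/dtF the distances from those spikes to the nearest
spike of the other train.  The two terms combine, weighted by the opposite
train's local ISI, into the instantaneous dissimilarity

    S(t) = (S_1(t) * xISI_2 + S_2(t) * xISI_1) / (2 * ((xISI_1 + xISI_2)/2)^2)

which is 0 exactly when the trains coincide locally and stays within [0, 1].
The distance is the time average of S(t) over the recording interval.
Auxiliary spikes at the interval edges define the profile for sparse trains.
S(t) is piecewise linear between "corner points" (the pooled spike times), so
the time average is computed exactly.

Synchrony, as used for MEA network maturation, is 1 minus the mean pairwise
SPIKE-distance over the active electrodes: 1 for perfectly coincident
trains, near 0 for maximally dissimilar ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "DissimilarityProfile",
    "pairwise_spike_distance",
    "multivariate_spike_distance",
    "multivariate_synchrony",
]

logger = logging.getLogger(__name__)


@dataclass
class DissimilarityProfile:
    """Piecewise-linear dissimilarity profile S(t) with jumps at its knots.

    ``knots`` are the m+1 corner times spanning the interval; segment k runs
    from ``knots[k]`` to ``knots[k+1]`` with value ``left[k]`` at its left
    edge and ``right[k]`` at its right edge (the profile may jump across a
    knot, so adjacent segments carry their own endpoint values).
    """

    knots: np.ndarray  # (m+1,)
    left: np.ndarray  # (m,) value just inside the left edge of each segment
    right: np.ndarray  # (m,) value just inside the right edge

    @property
    def interval(self) -> Tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def average(self) -> float:
        """Exact time average of the piecewise-linear profile."""
        widths = np.diff(self.knots)
        total = float(np.sum(0.5 * (self.left + self.right) * widths))
        return total / float(self.knots[-1] - self.knots[0])

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the profile at times ``t`` (segment-interior linear values)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        seg = np.clip(np.searchsorted(self.knots, t, side="right") - 1, 0, len(self.left) - 1)
        t0 = self.knots[seg]
        t1 = self.knots[seg + 1]
        w = np.where(t1 > t0, (t - t0) / np.where(t1 > t0, t1 - t0, 1.0), 0.0)
        return self.left[seg] * (1 - w) + self.right[seg] * w


def _augment(train: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Add auxiliary edge spikes and validate the train."""
    s = np.asarray(train, dtype=float)
    if s.size and (not np.all(np.diff(s) > 0)):
        raise ValueError("spike train must be strictly increasing")
    if s.size and (s[0] < t0 or s[-1] > t1):
        raise ValueError("spikes outside the analysis interval")
    parts = []
    if s.size == 0 or s[0] > t0:
        parts.append([t0])
    parts.append(s)
    if s.size == 0 or s[-1] < t1:
        parts.append([t1])
    return np.concatenate(parts)


def _nearest_dist(points: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest element of ``other``."""
    idx = np.searchsorted(other, points)
    left = other[np.clip(idx - 1, 0, other.size - 1)]
    right = other[np.clip(idx, 0, other.size - 1)]
    return np.minimum(np.abs(points - left), np.abs(points - right))


def pairwise_spike_distance(
    train_a: np.ndarray,
    train_b: np.ndarray,
    interval: Tuple[float, float],
) -> Tuple[DissimilarityProfile, float]:
    """SPIKE-distance between two trains over ``interval``.

    Returns the piecewise-linear profile and its time average.  Symmetric in
    its arguments; 0 exactly for identical trains.
    """
    t0, t1 = float(interval[0]), float(interval[1])
    if not t1 > t0:
        raise ValueError("interval must have positive length")
    ta = _augment(train_a, t0, t1)
    tb = _augment(train_b, t0, t1)
    corners = np.union1d(ta, tb)
    left_edges = corners[:-1]
    right_edges = corners[1:]

    nn_a = _nearest_dist(ta, tb)  # distance of each a-spike to nearest b-spike
    nn_b = _nearest_dist(tb, ta)

    def train_terms(ts, nn):
        # preceding spike for t in the open segment = last spike <= left edge;
        # following spike = first spike >= right edge
        iP = np.searchsorted(ts, left_edges, side="right") - 1
        iF = np.searchsorted(ts, right_edges, side="left")
        tP = ts[iP]
        tF = ts[iF]
        xisi = tF - tP
        dtP = nn[iP]
        dtF = nn[iF]

        def S_at(t):
            xP = t - tP
            xF = tF - t
            return (dtP * xF + dtF * xP) / xisi

        return xisi, S_at

    xisi_a, Sa_at = train_terms(ta, nn_a)
    xisi_b, Sb_at = train_terms(tb, nn_b)

    denom = 2.0 * ((xisi_a + xisi_b) / 2.0) ** 2

    def S(t):
        return (Sa_at(t) * xisi_b + Sb_at(t) * xisi_a) / denom

    profile = DissimilarityProfile(
        knots=corners, left=S(left_edges), right=S(right_edges)
    )
    return profile, profile.average()


def multivariate_spike_distance(
    trains: Sequence[np.ndarray], interval: Tuple[float, float]
) -> float:
    """Mean SPIKE-distance over all unordered train pairs."""
    if len(trains) < 2:
        raise ValueError("need at least two trains")
    dists = [
        pairwise_spike_distance(a, b, interval)[1]
        for a, b in combinations(trains, 2)
    ]
    return float(np.mean(dists))


def multivariate_synchrony(
    trains: Sequence[np.ndarray], interval: Tuple[float, float]
) -> float:
    """Device synchrony: 1 minus the mean pairwise SPIKE-distance.

    Values near 1 indicate coincident firing across electrodes.  With fewer
    than two trains the measure is undefined and NaN is returned (with a
    logged reason), mirroring sessions whose active-channel census leaves
    too few electrodes.
    """
    if len(trains) < 2:
        logger.info(
            "synchrony undefined: %d active train(s), need >= 2", len(trains)
        )
        return float("nan")
    return 1.0 - multivariate_spike_distance(trains, interval)
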