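"""Active-channel census, firing rates, and per-device aggregation.

A channel counts as active when it registers at least ``min_spikes`` spikes
in the recording (10 per 10-minute session by default).  Per-electrode
features are averaged into one row per device and session; all means are
taken over active electrodes only, and burst features over active electrodes
that contain at least one burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DeviceSessionSummary",
    "compute_active_channels",
    "per_electrode_rate",
    "aggregate_device",
]

SUMMARY_FEATURES = (
    "percent_active",
    "mean_rate",
    "pct_spikes_in_bursts",
    "mean_burst_duration",
    "mean_within_burst_isi",
    "synchrony",
)


@dataclass
class DeviceSessionSummary:
    """One device at one session: the feature vector the statistics stage uses."""

    device: str
    session: float
    culture: str = ""
    condition: str = ""
    percent_active: float = 0.0
    mean_rate: float = float("nan")
    pct_spikes_in_bursts: float = float("nan")
    mean_burst_duration: float = float("nan")
    mean_within_burst_isi: float = float("nan")
    synchrony: float = float("nan")
    n_active: int = 0
    n_burst_electrodes: int = 0
    duration: float = 600.0

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compute_active_channels(
    trains: Sequence[np.ndarray],
    min_spikes: int = 10,
    duration: Optional[float] = None,
    rate_scaled: bool = False,
    reference_duration: float = 600.0,
) -> Tuple[np.ndarray, float]:
    """Active mask and percent active.

    A channel is active iff its spike count is at least ``min_spikes``
    (an absolute count, the printed >=10-per-10-min rule).  With
    ``rate_scaled=True`` the threshold is prorated by
    ``duration / reference_duration`` for sessions that are not 600 s.
    """
    if len(trains) == 0:
        raise ValueError("no channels")
    threshold = float(min_spikes)
    if rate_scaled:
        if duration is None:
            raise ValueError("rate_scaled thresholding requires duration")
        threshold = min_spikes * duration / reference_duration
    counts = np.array([np.asarray(t).size for t in trains])
    mask = counts >= threshold
    return mask, 100.0 * mask.mean()


def per_electrode_rate(train: np.ndarray, duration: float) -> float:
    """Mean firing rate (Hz) of one electrode over the recording."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return np.asarray(train).size / duration


def aggregate_device(
    features: pd.DataFrame,
    active: np.ndarray,
    device: str = "",
    session: float = 0.0,
    culture: str = "",
    condition: str = "",
    synchrony: float = float("nan"),
    duration: float = 600.0,
) -> DeviceSessionSummary:
    """Collapse per-electrode features into one device-session summary.

    ``features`` has one row per channel, aligned with ``active``, and
    columns ``rate``, ``pct_spikes_in_bursts``, ``mean_burst_duration``,
    ``mean_within_burst_isi`` and ``n_bursts``.  Rates are unweighted means
    over active electrodes; burst features are averaged over active
    electrodes with at least one burst (electrodes without bursts are
    excluded rather than imputed as zero), with the contributing count
    recorded.  With no active electrodes, percent_active is 0 and every
    mean is missing.
    """
    active = np.asarray(active, dtype=bool)
    if len(features) != active.size:
        raise ValueError("features and active mask are not aligned")
    out = DeviceSessionSummary(
        device=device,
        session=session,
        culture=culture,
        condition=condition,
        percent_active=100.0 * active.mean() if active.size else 0.0,
        n_active=int(active.sum()),
        duration=duration,
    )
    if out.n_active == 0:
        return out
    act = features.loc[active]
    out.mean_rate = float(act["rate"].mean())
    bursting = act[act["n_bursts"] >= 1]
    out.n_burst_electrodes = int(len(bursting))
    # pct_spikes_in_bursts is defined (0) on burst-free electrodes too
    out.pct_spikes_in_bursts = float(act["pct_spikes_in_bursts"].mean())
    if len(bursting):
        out.mean_burst_duration = float(bursting["mean_burst_duration"].mean())
        out.mean_within_burst_isi = float(bursting["mean_within_burst_isi"].mean())
    out.synchrony = synchrony
    return out
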