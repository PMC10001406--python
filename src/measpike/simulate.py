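"""Ground-truthed synthetic MEA recordings.

This module generates the kinds of data the analysis stages assume: per-device
multichannel spike trains with a two-state (tonic/burst) renewal structure,
inter-train synchrony induced by a jittered mother process on burst onsets,
two waveform classes (narrow-spiking ~220 us and broad-spiking ~380 us
trough-to-peak), and multi-session study designs emulating culture maturation
across days in vitro (DIV) and an LPS neuroinflammation challenge.

Every generated object carries its ground truth (active flags, unit classes,
spike times, burst episode intervals), so detector and classifier outputs can
be scored against a known answer.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import INTAN_VOLTS_PER_LSB, RawRecording

__all__ = [
    "WaveformTemplate",
    "SimulationConfig",
    "ChannelTruth",
    "DeviceGroundTruth",
    "StudySession",
    "StudyDataset",
    "make_waveform_template",
    "simulate_device_trains",
    "synthesize_raw",
    "simulate_study",
    "MATURATION_DIVS",
    "LPS_HOURS",
]

MATURATION_DIVS = (7.0, 10.0, 14.0, 17.0, 21.0)
LPS_HOURS = (0.0, 3.0, 12.0, 24.0, 48.0, 72.0)

# Trough-to-peak centers of the two waveform classes (us).
NARROW_TTP_US = 220.0
BROAD_TTP_US = 380.0


@dataclass(frozen=True)
class WaveformTemplate:
    """Unit-amplitude extracellular spike shape on the sampling grid.

    The shape is negative-first (depolarization trough, then repolarization
    peak), normalized so the trough depth is exactly 1; ``amplitude`` scales
    it in multiples of the recording noise SD when placed into a trace.
    """

    kind: str  # "narrow" or "broad"
    trough_to_peak: float  # requested width, us
    sampling_rate: float
    amplitude: float  # trough depth in noise-SD multiples
    shape: np.ndarray  # unitless, min exactly -1

    @property
    def length(self) -> int:
        return self.shape.size

    @property
    def trough_index(self) -> int:
        return int(np.argmin(self.shape))

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.shape))

    @property
    def measured_trough_to_peak(self) -> float:
        """Width measured on the sampled shape, us."""
        return (self.peak_index - self.trough_index) / self.sampling_rate * 1e6


def make_waveform_template(
    kind: str,
    trough_to_peak: float,
    sampling_rate: float,
    amplitude: float,
) -> WaveformTemplate:
    """Build a biphasic template with the requested trough-to-peak width.

    Parameters
    ----------
    kind:
        ``"narrow"`` (putative inhibitory) or ``"broad"`` (putative
        excitatory); a free label, the width is what matters.
    trough_to_peak:
        Requested width in microseconds (trough to subsequent peak).
    sampling_rate:
        Hz; the discrete extrema land on this grid, so the measured width
        matches the request to within half a sample period.
    amplitude:
        Trough depth in multiples of the target noise SD; must be > 0.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    d = trough_to_peak * 1e-6 * sampling_rate  # width in samples
    if d < 2.0:
        raise ValueError(
            f"trough_to_peak={trough_to_peak} us is under 2 sample periods at "
            f"{sampling_rate} Hz"
        )
    n_pre = int(round(0.6e-3 * sampling_rate))
    length = int(round(1.6e-3 * sampling_rate))
    if n_pre < d / 2 or length - 1 - n_pre < 1.6 * d:
        # very low sampling rates: widen the window so the shape fits
        n_pre = int(np.ceil(d))
        length = int(np.ceil(3.5 * d)) + 1
    x = np.arange(length, dtype=float)
    t_trough = float(n_pre)
    t_peak = t_trough + d
    # Difference-of-Gaussians; the components interfere slightly, so sharpen
    # until the sampled extrema land within half a sample of the request.
    sharp = 1.0
    for _ in range(8):
        sd_trough = d / (3.5 * sharp)
        sd_peak = d / (3.2 * sharp)
        shape = -np.exp(-0.5 * ((x - t_trough) / sd_trough) ** 2)
        shape += 0.35 * np.exp(-0.5 * ((x - t_peak) / sd_peak) ** 2)
        shape /= -shape.min()
        drift = abs(int(np.argmax(shape)) - int(np.argmin(shape)) - d)
        edge = max(abs(shape[0]), abs(shape[-1]))
        if drift <= 0.5 + 1e-9 and edge < 0.01:
            break
        sharp *= 1.3
    tpl = WaveformTemplate(
        kind=kind,
        trough_to_peak=trough_to_peak,
        sampling_rate=sampling_rate,
        amplitude=amplitude,
        shape=shape,
    )
    if not tpl.trough_index < tpl.peak_index:
        raise AssertionError("template trough must precede its peak")
    if abs(tpl.peak_index - tpl.trough_index - d) > 0.5 + 1e-9:
        raise AssertionError("sampled width drifted more than half a sample")
    if max(abs(shape[0]), abs(shape[-1])) >= 0.01:
        raise AssertionError("template does not decay to <1% at the window edges")
    return tpl


def default_templates(sampling_rate: float, amplitude: float) -> Dict[str, WaveformTemplate]:
    """Narrow/broad template pair at the canonical 220/380 us widths."""
    return {
        "inhibitory": make_waveform_template("narrow", NARROW_TTP_US, sampling_rate, amplitude),
        "excitatory": make_waveform_template("broad", BROAD_TTP_US, sampling_rate, amplitude),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated device recording.

    Defaults mirror the study conditions this generator emulates: 32-channel
    arrays sampled at 30 kHz for 10-minute sessions, a mostly excitatory unit
    population (~80%, the in vivo cortical proportion), tonic firing with
    superimposed burst episodes that satisfy the max-interval burst criteria
    by construction, and partially synchronized burst onsets.
    """

    n_channels: int = 32
    sampling_rate: float = 30_000.0
    duration: float = 600.0
    p_active: float = 0.6
    p_excitatory: float = 0.8
    tonic_rate: float = 0.5  # Hz, homogeneous Poisson background
    burst_onset_rate: float = 0.1  # Hz, burst episodes per second
    spikes_per_burst: Tuple[int, int] = (6, 12)
    within_burst_isi: Tuple[float, float] = (0.02, 0.08)  # s, uniform
    sync_copy_prob: float = 0.5  # probability a burst onset copies the mother process
    sync_jitter_sd: float = 0.005  # s, jitter applied to copied onsets
    noise_sd: float = 5e-6  # V
    amplitude_snr: float = 12.0  # template trough depth in noise-SD multiples
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_active", "p_excitatory", "sync_copy_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.duration <= 0 or self.sampling_rate <= 0 or self.n_channels < 1:
            raise ValueError("duration, sampling_rate and n_channels must be positive")
        if self.tonic_rate < 0 or self.burst_onset_rate < 0:
            raise ValueError("rates must be non-negative")
        lo, hi = self.spikes_per_burst
        ilo, ihi = self.within_burst_isi
        if not (0 < ilo <= ihi):
            raise ValueError("within_burst_isi must satisfy 0 < lo <= hi")
        if not (0 < lo <= hi):
            raise ValueError("spikes_per_burst must satisfy 0 < lo <= hi")
        if self.burst_onset_rate > 0:
            # guarantee every generated episode is detectable under the
            # max-interval criteria (0.1 s start ISI, 0.25 s end ISI,
            # 0.5 s inter-burst interval, 0.05 s duration, 6 spikes)
            if hi and ihi >= 0.1:
                raise ValueError(
                    "within_burst_isi upper bound must be < 0.1 s for bursts "
                    "to open under the max-interval start criterion"
                )
            if lo < 6:
                raise ValueError("spikes_per_burst minimum must be >= 6")
            if (lo - 1) * ilo < 0.05:
                raise ValueError(
                    "shortest burst (min spikes x min ISI) under the 0.05 s "
                    "minimum duration"
                )
            span = (hi - 1) * ihi
            if 1.0 / self.burst_onset_rate - span <= 0.5:
                raise ValueError(
                    "burst onsets too frequent: expected spacing minus the "
                    "maximum burst span must exceed 0.5 s"
                )


@dataclass
class ChannelTruth:
    """Ground truth for one channel: activity flag, unit class, events."""

    channel: int
    active: bool
    unit_class: str  # "excitatory" | "inhibitory"
    spike_times: np.ndarray  # strictly increasing, s
    burst_intervals: np.ndarray  # (n_bursts, 2): first/last spike time of each episode


@dataclass
class DeviceGroundTruth:
    """Per-channel ground truth plus the shared mother onset process."""

    config: SimulationConfig
    channels: List[ChannelTruth]
    mother_onsets: np.ndarray

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def trains(self) -> List[np.ndarray]:
        return [c.spike_times for c in self.channels]

    def active_fraction(self) -> float:
        return float(np.mean([c.active for c in self.channels]))


def _poisson_times(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _burst_episode(
    rng: np.random.Generator, onset: float, cfg: SimulationConfig
) -> np.ndarray:
    lo, hi = cfg.spikes_per_burst
    n = int(rng.integers(lo, hi + 1))
    isis = rng.uniform(cfg.within_burst_isi[0], cfg.within_burst_isi[1], size=n - 1)
    return onset + np.concatenate([[0.0], np.cumsum(isis)])


def simulate_device_trains(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    active_mask: Optional[np.ndarray] = None,
    unit_classes: Optional[Sequence[str]] = None,
) -> DeviceGroundTruth:
    """Generate one device's spike trains with full ground truth.

    Each active channel superposes a homogeneous tonic train at
    ``tonic_rate`` with burst episodes whose onsets arrive at
    ``burst_onset_rate``.  With probability ``sync_copy_prob`` an onset is a
    jittered copy of a device-wide mother event, which couples the channels;
    the remaining rate is channel-private, so the per-channel onset rate is
    preserved.  Onsets that would violate the 0.5 s inter-burst separation
    (accounting for the maximum episode span) are dropped.

    ``active_mask`` and ``unit_classes`` override the per-channel Bernoulli
    draws; study scenarios use them to keep channel identity persistent
    across a device's sessions (electrode recruitment, cell death).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    max_span = (config.spikes_per_burst[1] - 1) * config.within_burst_isi[1]
    min_onset_gap = max_span + 0.5 + 1e-3
    mother = _poisson_times(rng, config.burst_onset_rate, config.duration)
    channels: List[ChannelTruth] = []
    for ch in range(config.n_channels):
        active = (
            bool(active_mask[ch])
            if active_mask is not None
            else bool(rng.random() < config.p_active)
        )
        unit_class = (
            unit_classes[ch]
            if unit_classes is not None
            else ("excitatory" if rng.random() < config.p_excitatory else "inhibitory")
        )
        if not active:
            channels.append(
                ChannelTruth(ch, False, unit_class, np.empty(0), np.empty((0, 2)))
            )
            continue
        copied = mother[rng.random(mother.size) < config.sync_copy_prob]
        if config.sync_jitter_sd > 0 and copied.size:
            copied = copied + rng.normal(0.0, config.sync_jitter_sd, size=copied.size)
        own = _poisson_times(
            rng, config.burst_onset_rate * (1.0 - config.sync_copy_prob), config.duration
        )
        onsets = np.sort(np.concatenate([copied, own]))
        onsets = onsets[(onsets >= 0) & (onsets < config.duration)]
        kept: List[float] = []
        for t in onsets:
            if not kept or t - kept[-1] >= min_onset_gap:
                kept.append(float(t))
        burst_spikes: List[np.ndarray] = []
        intervals: List[Tuple[float, float]] = []
        for t in kept:
            ep = _burst_episode(rng, t, config)
            if ep[-1] >= config.duration:
                continue
            burst_spikes.append(ep)
            intervals.append((ep[0], ep[-1]))
        tonic = _poisson_times(rng, config.tonic_rate, config.duration)
        parts = [tonic] + burst_spikes
        times = np.sort(np.concatenate(parts)) if parts else np.empty(0)
        # exact duplicates (measure-zero, but seeds are arbitrary)
        times = np.unique(times)
        channels.append(
            ChannelTruth(
                ch,
                True,
                unit_class,
                times,
                np.asarray(intervals, dtype=float).reshape(-1, 2),
            )
        )
    return DeviceGroundTruth(config=config, channels=channels, mother_onsets=mother)


def synthesize_raw(
    truth: DeviceGroundTruth,
    templates: Optional[Dict[str, WaveformTemplate]] = None,
    noise_sd: Optional[float] = None,
    volts_per_lsb: float = INTAN_VOLTS_PER_LSB,
    on_collision: str = "superpose",
    rng: Optional[np.random.Generator] = None,
) -> RawRecording:
    """Render ground-truth trains into a quantized multichannel voltage trace.

    Additive white Gaussian noise (SD ``noise_sd``) plus each channel's class
    template placed trough-aligned at every ground-truth spike time, stored
    as int16 at ``volts_per_lsb`` (Intan-style 0.195 uV/bit by default).

    ``on_collision`` controls what happens when two spikes on one channel
    fall closer than the template span: ``"superpose"`` adds them linearly
    with a warning, ``"error"`` rejects the truth object.
    """
    cfg = truth.config
    if noise_sd is None:
        noise_sd = cfg.noise_sd
    if templates is None:
        templates = default_templates(cfg.sampling_rate, cfg.amplitude_snr)
    if on_collision not in ("superpose", "error"):
        raise ValueError("on_collision must be 'superpose' or 'error'")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    fs = cfg.sampling_rate
    n_samples = int(round(cfg.duration * fs))
    data = np.empty((truth.n_channels, n_samples), dtype=np.int16)
    for ci, ch in enumerate(truth.channels):
        x = (
            rng.normal(0.0, noise_sd, size=n_samples).astype(np.float32)
            if noise_sd > 0
            else np.zeros(n_samples, dtype=np.float32)
        )
        tpl = templates[ch.unit_class]
        span = tpl.length / fs
        if ch.spike_times.size > 1:
            n_coll = int(np.sum(np.diff(ch.spike_times) < span))
            if n_coll:
                msg = f"channel {ch.channel}: {n_coll} spike pair(s) within the template span"
                if on_collision == "error":
                    raise ValueError(msg)
                warnings.warn(msg + "; superposing linearly", stacklevel=2)
        # noiseless synthesis keeps a 1 uV nominal scale so quantization is sane
        amp_volts = tpl.amplitude * (noise_sd if noise_sd > 0 else 1e-6)
        scaled = (tpl.shape * amp_volts).astype(np.float32)
        for t in ch.spike_times:
            start = int(round(t * fs)) - tpl.trough_index
            lo = max(start, 0)
            hi = min(start + tpl.length, n_samples)
            if hi > lo:
                x[lo:hi] += scaled[lo - start : hi - start]
        np.clip(np.rint(x / volts_per_lsb), -32768, 32767, out=x)
        data[ci] = x.astype(np.int16)
    return RawRecording(
        data=data,
        sampling_rate=fs,
        volts_per_lsb=volts_per_lsb,
        channel_ids=[c.channel for c in truth.channels],
    )


# ---------------------------------------------------------------------------
# Study-level scenarios


@dataclass
class StudySession:
    """One device at one session of a study, with its generated ground truth."""

    device: str
    session: float  # DIV (maturation) or hours post-exposure (lps)
    culture: str  # "co" | "tri"
    condition: str  # "control" | "lps"
    truth: DeviceGroundTruth


@dataclass
class StudyDataset:
    scenario: str
    sessions: List[StudySession]
    session_grid: Tuple[float, ...]

    def __iter__(self):
        return iter(self.sessions)


# Maturation trajectories: monotone-increasing activity, firing and coupling
# from DIV 7 to DIV 21, the canonical in vitro network-formation picture.
MATURATION_TRAJECTORIES = {
    "p_active": {7.0: 0.30, 10.0: 0.45, 14.0: 0.60, 17.0: 0.70, 21.0: 0.80},
    "tonic_rate": {7.0: 0.30, 10.0: 0.40, 14.0: 0.50, 17.0: 0.55, 21.0: 0.60},
    "burst_onset_rate": {7.0: 0.04, 10.0: 0.07, 14.0: 0.10, 17.0: 0.12, 21.0: 0.14},
    "sync_copy_prob": {7.0: 0.10, 10.0: 0.30, 14.0: 0.50, 17.0: 0.65, 21.0: 0.80},
}

# LPS challenge: baseline = mature (DIV-21-like) cultures; in the treated
# tri-culture arm channels die with a constant hazard and surviving channels'
# rates decay, so firing falls faster than the active-channel count.
LPS_BASELINE = {
    "p_active": 0.80,
    "tonic_rate": 0.60,
    "burst_onset_rate": 0.12,
    "sync_copy_prob": 0.70,
}
LPS_DEATH_HAZARD = 0.032  # per hour; survival ~10% at 72 h
LPS_RATE_DECAY = 0.05  # per hour; firing falls faster than the channel census


def _device_effects(rng: np.random.Generator, device_sd: float) -> Dict[str, float]:
    """Per-device multiplicative frailties, constant across sessions."""
    return {
        "activity": float(np.exp(rng.normal(0.0, device_sd))),
        "rate": float(np.exp(rng.normal(0.0, device_sd))),
    }


def simulate_study(
    scenario: str,
    n_devices: Optional[int] = None,
    base_config: Optional[SimulationConfig] = None,
    device_sd: float = 0.15,
    death_hazard: float = LPS_DEATH_HAZARD,
    rate_decay: float = LPS_RATE_DECAY,
    seed: int = 0,
) -> StudyDataset:
    """Generate a longitudinal multi-device study dataset.

    ``"maturation"``: co- and tri-cultures recorded at DIV {7,10,14,17,21}
    (8 devices per culture by default) with monotone increasing activity,
    firing, bursting and synchrony trajectories.

    ``"lps"``: co/tri x control/treated arms at {0,3,12,24,48,72} hours
    post-exposure (4 devices per arm by default).  Only the treated
    tri-culture arm responds: each channel has an exponential death time
    (hazard ``death_hazard``/h) and surviving channels' firing and burst
    rates decay as ``exp(-rate_decay * t)``; all other arms stay at baseline.

    Device-level variability is a lognormal frailty (SD ``device_sd`` on the
    log scale) applied to activity and rate parameters, constant across a
    device's sessions (the random intercept the mixed model targets).

    Channel identity persists within a device: each channel draws one
    recruitment quantile (it is active at a session when the session's
    activation probability exceeds it, so maturing devices recruit
    electrodes monotonically), one unit class, and -- in the treated
    tri-culture LPS arm -- one exponential death time after which it stays
    silent.
    """
    if base_config is None:
        base_config = SimulationConfig()
    root = np.random.SeedSequence(
        [seed, zlib.crc32(scenario.encode()) & 0x7FFFFFFF]
    )
    if scenario == "maturation":
        grid = MATURATION_DIVS
        n_dev = 8 if n_devices is None else n_devices
        arms = [("co", "control"), ("tri", "control")]
    elif scenario == "lps":
        grid = LPS_HOURS
        n_dev = 4 if n_devices is None else n_devices
        arms = [
            ("co", "control"),
            ("co", "lps"),
            ("tri", "control"),
            ("tri", "lps"),
        ]
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    sessions: List[StudySession] = []
    dev_seeds = root.spawn(len(arms) * n_dev)
    idx = 0
    for culture, condition in arms:
        for d in range(n_dev):
            dev_rng = np.random.default_rng(dev_seeds[idx])
            idx += 1
            device = f"{culture}-{condition}-{d:02d}"
            fx = _device_effects(dev_rng, device_sd)
            n_ch = base_config.n_channels
            # persistent per-channel structure
            recruit_q = dev_rng.random(n_ch)  # activation quantile per channel
            unit_classes = [
                "excitatory" if u < base_config.p_excitatory else "inhibitory"
                for u in dev_rng.random(n_ch)
            ]
            treated = scenario == "lps" and culture == "tri" and condition == "lps"
            death_times = (
                dev_rng.exponential(1.0 / death_hazard, size=n_ch)
                if treated and death_hazard > 0
                else np.full(n_ch, np.inf)
            )
            for t in grid:
                if scenario == "maturation":
                    p_active = min(MATURATION_TRAJECTORIES["p_active"][t] * fx["activity"], 1.0)
                    mask = recruit_q < p_active
                    cfg = replace(
                        base_config,
                        p_active=p_active,
                        tonic_rate=MATURATION_TRAJECTORIES["tonic_rate"][t] * fx["rate"],
                        burst_onset_rate=MATURATION_TRAJECTORIES["burst_onset_rate"][t]
                        * fx["rate"],
                        sync_copy_prob=MATURATION_TRAJECTORIES["sync_copy_prob"][t],
                    )
                else:
                    decay = float(np.exp(-rate_decay * t)) if treated else 1.0
                    p_active = min(LPS_BASELINE["p_active"] * fx["activity"], 1.0)
                    mask = (recruit_q < p_active) & (death_times > t)
                    cfg = replace(
                        base_config,
                        p_active=p_active,
                        tonic_rate=LPS_BASELINE["tonic_rate"] * fx["rate"] * decay,
                        burst_onset_rate=LPS_BASELINE["burst_onset_rate"]
                        * fx["rate"]
                        * decay,
                        sync_copy_prob=LPS_BASELINE["sync_copy_prob"],
                    )
                truth = simulate_device_trains(
                    cfg, rng=dev_rng, active_mask=mask, unit_classes=unit_classes
                )
                sessions.append(StudySession(device, float(t), culture, condition, truth))
    return StudyDataset(scenario=scenario, sessions=sessions, session_grid=tuple(grid))
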