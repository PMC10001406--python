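"""End-to-end orchestration: simulate -> detect -> analyze -> stats -> report.

The pipeline is staged around a tidy spike table (device, session, culture,
condition, channel, time_s).  The table can come from the synthetic study
generator, from raw recordings run through the detector, or from a
user-supplied CSV (pre-detected spikes), which enters the flow at the
analyze stage.  Every output CSV carries a config-hash provenance header and
rerunning with the same config and seed reproduces the tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .bursts import BurstParams, burst_summary, detect_bursts
from .detection import DetectionParams, process_channel
from .io import RawRecording, config_hash, read_raw, read_table, write_table
from .metrics import aggregate_device, compute_active_channels, per_electrode_rate
from .simulate import StudyDataset, simulate_study
from .stats import emm_contrasts_holm, fit_spline_lme
from .synchrony import multivariate_synchrony

__all__ = ["RunConfig", "run_pipeline", "study_to_spike_table", "analyze_spike_table", "detect_raw"]

logger = logging.getLogger(__name__)

STAT_FEATURES = (
    "percent_active",
    "mean_rate",
    "pct_spikes_in_bursts",
    "mean_burst_duration",
    "mean_within_burst_isi",
    "synchrony",
)


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    scenario: Optional[str] = "maturation"  # or "lps"; None with spike_csv/raw input
    spike_csv: Optional[str] = None  # pre-detected spike table entry point
    raw_stems: Tuple[str, ...] = ()  # raw recording stems for the detect stage
    n_devices: Optional[int] = None
    n_channels: int = 32
    duration: float = 600.0
    detection: DetectionParams = field(default_factory=DetectionParams)
    bursts: BurstParams = field(default_factory=BurstParams)
    min_spikes_active: int = 10
    features: Tuple[str, ...] = STAT_FEATURES
    group_col: str = "culture"
    seed: int = 0
    outdir: str = "measpike_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("detection"), dict):
            d["detection"] = DetectionParams(**d["detection"])
        if isinstance(d.get("bursts"), dict):
            d["bursts"] = BurstParams(**d["bursts"])
        if "raw_stems" in d and d["raw_stems"] is not None:
            d["raw_stems"] = tuple(d["raw_stems"])
        if "features" in d and d["features"] is not None:
            d["features"] = tuple(d["features"])
        return cls(**d)


def study_to_spike_table(study: StudyDataset) -> pd.DataFrame:
    """Flatten a study's ground-truth trains into the tidy spike table."""
    rows = []
    for sess in study.sessions:
        for ch in sess.truth.channels:
            for t in ch.spike_times:
                rows.append(
                    (
                        sess.device,
                        sess.session,
                        sess.culture,
                        sess.condition,
                        ch.channel,
                        ch.unit_class,
                        t,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["device", "session", "culture", "condition", "channel", "unit_class", "time_s"],
    )


def study_truth_bursts(study: StudyDataset) -> pd.DataFrame:
    rows = []
    for sess in study.sessions:
        for ch in sess.truth.channels:
            for bi, (t_start, t_end) in enumerate(ch.burst_intervals):
                rows.append((sess.device, sess.session, ch.channel, bi, t_start, t_end))
    return pd.DataFrame(
        rows, columns=["device", "session", "channel", "burst_index", "t_start_s", "t_end_s"]
    )


def detect_raw(
    recording: RawRecording,
    params: Optional[DetectionParams] = None,
    device: str = "dev00",
    session: float = 0.0,
    snippets_out: Optional[dict] = None,
) -> pd.DataFrame:
    """Run the detector on every channel of a raw recording.

    Returns an event table (device, session, channel, time_s, polarity,
    amplitude_v); channel traces are processed one at a time so long
    recordings stay within memory.  When ``snippets_out`` (a dict) is
    given, each channel's aligned snippet stack is stored under
    ``(device, session, channel)`` for HDF5 export via
    :func:`measpike.io.write_snippets`.
    """
    params = params or DetectionParams()
    rows = []
    for i, cid in enumerate(recording.channel_ids):
        res = process_channel(recording.channel_volts(i), recording.sampling_rate, params)
        ev = res["events"]
        logger.info("device %s ch %s: %d events (sigma=%.3g V)", device, cid, len(ev), res["sigma"])
        if snippets_out is not None and res["snippets"].shape[0]:
            snippets_out[(device, float(session), int(cid))] = res["snippets"]
        for t, pol, amp in zip(ev.times, ev.polarities, ev.amplitudes):
            rows.append((device, session, cid, t, int(pol), amp))
    return pd.DataFrame(
        rows, columns=["device", "session", "channel", "time_s", "polarity", "amplitude_v"]
    )


def analyze_spike_table(
    spikes: pd.DataFrame,
    n_channels: int,
    duration: float,
    burst_params: Optional[BurstParams] = None,
    min_spikes_active: int = 10,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-device-session feature extraction from a tidy spike table.

    Returns ``(summary, burst_table)``: one summary row per device x session
    (active census, mean rate, burst features, synchrony over active
    electrodes) and the detected-burst table.
    """
    required = {"device", "session", "channel", "time_s"}
    missing = required - set(spikes.columns)
    if missing:
        raise ValueError(f"spike table lacks column(s): {sorted(missing)}")
    burst_params = burst_params or BurstParams()
    summaries = []
    burst_rows = []
    for (device, session), g in spikes.groupby(["device", "session"], sort=True):
        culture = str(g["culture"].iloc[0]) if "culture" in g else ""
        condition = str(g["condition"].iloc[0]) if "condition" in g else ""
        trains = [
            np.sort(g.loc[g["channel"] == ch, "time_s"].to_numpy())
            for ch in range(n_channels)
        ]
        active, _ = compute_active_channels(trains, min_spikes=min_spikes_active)
        feats = []
        for ch, train in enumerate(trains):
            bs = detect_bursts(train, burst_params)
            pct, mdur, misi = burst_summary(train, bs)
            feats.append(
                {
                    "rate": per_electrode_rate(train, duration),
                    "pct_spikes_in_bursts": pct,
                    "mean_burst_duration": mdur,
                    "mean_within_burst_isi": misi,
                    "n_bursts": bs.n_bursts,
                }
            )
            for bi, ((t0, t1), n_sp) in enumerate(zip(bs.intervals, bs.spike_counts)):
                burst_rows.append((device, session, ch, bi, t0, t1, int(n_sp)))
        active_trains = [t for t, a in zip(trains, active) if a]
        sync = multivariate_synchrony(active_trains, (0.0, duration))
        summary = aggregate_device(
            pd.DataFrame(feats),
            active,
            device=str(device),
            session=float(session),
            culture=culture,
            condition=condition,
            synchrony=sync,
            duration=duration,
        )
        summaries.append(summary.as_row())
    summary_df = pd.DataFrame(summaries)
    burst_df = pd.DataFrame(
        burst_rows,
        columns=["device", "session", "channel", "burst_index", "t_start_s", "t_end_s", "n_spikes"],
    )
    return summary_df, burst_df


def _stats_stage(summary: pd.DataFrame, config: RunConfig) -> Tuple[pd.DataFrame, dict]:
    """Fit the spline mixed model and EMM/Holm contrasts per feature."""
    group_col = config.group_col
    if config.scenario == "lps":
        # arm = culture x condition; contrasts within culture: control vs lps
        summary = summary.copy()
        summary["arm"] = summary["culture"] + "/" + summary["condition"]
        group_col = "arm"
    contrast_frames = []
    report: Dict[str, dict] = {}
    for feature in config.features:
        if feature not in summary.columns:
            continue
        usable = summary.dropna(subset=[feature])
        if usable.empty or usable[group_col].nunique() < 1:
            report[feature] = {"fitted": False, "reason": "no usable observations"}
            continue
        try:
            fit = fit_spline_lme(usable, feature, group_col=group_col)
            contrasts = emm_contrasts_holm(fit)
        except Exception as exc:  # non-convergence, singular fits
            report[feature] = {"fitted": False, "reason": str(exc)}
            continue
        contrast_frames.append(contrasts)
        sig = contrasts[contrasts["p_adj"] < 0.05]
        report[feature] = {
            "fitted": True,
            "groups": fit.groups,
            "n_obs": fit.n_obs,
            "n_devices": fit.n_devices,
            "significant_contrasts": sig["contrast"].tolist(),
        }
    contrasts_df = (
        pd.concat(contrast_frames, ignore_index=True)
        if contrast_frames
        else pd.DataFrame()
    )
    return contrasts_df, report


def run_pipeline(config: RunConfig, entry_stage: Optional[str] = None) -> dict:
    """Run the staged pipeline and write all output tables.

    Stages run in order simulate -> detect -> analyze -> stats -> report,
    starting from ``entry_stage`` (inferred from the config when omitted:
    a ``spike_csv`` enters at analyze, ``raw_stems`` at detect, otherwise a
    scenario is simulated).  Returns the run record, which is also written
    to ``run_record.json`` in the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # provenance hash covers the scientific config only, not the run location,
    # so identical analyses are byte-identical wherever they are written
    hash_src = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    chash = config_hash(hash_src)
    record: Dict[str, object] = {
        "config": config.to_dict(),
        "config_sha256": chash,
        "measpike_version": __version__,
        "stages": [],
        "counts": {},
    }

    if entry_stage is None:
        if config.spike_csv:
            entry_stage = "analyze"
        elif config.raw_stems:
            entry_stage = "detect"
        else:
            entry_stage = "simulate"

    spikes: Optional[pd.DataFrame] = None
    if entry_stage == "simulate":
        if config.scenario is None:
            raise ValueError("simulate stage requires a scenario")
        study = simulate_study(
            config.scenario, n_devices=config.n_devices, seed=config.seed
        )
        spikes = study_to_spike_table(study)
        write_table(spikes, outdir / "spikes.csv", provenance=chash)
        write_table(study_truth_bursts(study), outdir / "truth_bursts.csv", provenance=chash)
        record["stages"].append("simulate")
        record["counts"]["spikes"] = int(len(spikes))
    elif entry_stage == "detect":
        from .io import write_snippets

        frames = []
        snippet_stacks: Dict[tuple, np.ndarray] = {}
        for stem in config.raw_stems:
            rec = read_raw(stem)
            frames.append(
                detect_raw(
                    rec, config.detection, device=Path(stem).name,
                    snippets_out=snippet_stacks,
                )
            )
        spikes = pd.concat(frames, ignore_index=True)
        write_table(spikes, outdir / "spikes.csv", provenance=chash)
        if snippet_stacks:
            write_snippets(snippet_stacks, outdir / "snippets.h5")
        record["stages"].append("detect")
        record["counts"]["spikes"] = int(len(spikes))
    elif entry_stage == "analyze":
        if config.spike_csv is None:
            raise ValueError("analyze entry stage requires spike_csv")
        spikes = read_table(config.spike_csv)
        logger.info("detection stage skipped: spike table supplied")
    else:
        raise ValueError(f"unknown entry stage {entry_stage!r}")

    summary, burst_df = analyze_spike_table(
        spikes,
        n_channels=config.n_channels,
        duration=config.duration,
        burst_params=config.bursts,
        min_spikes_active=config.min_spikes_active,
    )
    write_table(summary, outdir / "summary.csv", provenance=chash)
    write_table(burst_df, outdir / "bursts.csv", provenance=chash)
    record["stages"].append("analyze")
    record["counts"]["device_sessions"] = int(len(summary))
    record["counts"]["bursts"] = int(len(burst_df))
    record["counts"]["active_channels"] = int(summary["n_active"].sum())

    contrasts, stats_report = _stats_stage(summary, config)
    if not contrasts.empty:
        write_table(contrasts, outdir / "contrasts.csv", provenance=chash)
    record["stages"].append("stats")
    record["stats"] = stats_report

    (outdir / "report.json").write_text(json.dumps(record, indent=1, default=str))
    record["stages"].append("report")
    return record
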