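"""Synthetic-recording generator: template geometry, train statistics,
detectability by construction, study scenarios and reproducibility."""

import numpy as np
import pytest

from measpike.bursts import BurstParams, detect_bursts
from measpike.simulate import (
    LPS_HOURS,
    MATURATION_DIVS,
    SimulationConfig,
    make_waveform_template,
    simulate_device_trains,
    simulate_study,
    synthesize_raw,
)
from measpike.waveforms import mean_waveform_and_ptd


@pytest.mark.parametrize(
    "kind,ttp,lo,hi",
    [("narrow", 220.0, 6, 7), ("broad", 380.0, 11, 12)],
)
def test_template_sample_geometry(kind, ttp, lo, hi):
    tpl = make_waveform_template(kind, ttp, 30_000.0, 12.0)
    offset = tpl.peak_index - tpl.trough_index
    assert lo <= offset <= hi
    assert tpl.trough_index < tpl.peak_index
    assert tpl.shape.min() == pytest.approx(-1.0)
    assert max(abs(tpl.shape[0]), abs(tpl.shape[-1])) < 0.01
    # half-sample agreement with the request
    assert abs(tpl.measured_trough_to_peak - ttp) <= 0.5 / 30_000.0 * 1e6 + 1e-9


def test_template_roundtrip_through_width_measurement():
    tpl = make_waveform_template("narrow", 220.0, 30_000.0, 12.0)
    _, _, ptd = mean_waveform_and_ptd(tpl.shape[None, :], 30_000.0)
    assert ptd == pytest.approx(220.0, abs=1e6 / 30_000.0)  # one sample period


def test_template_rejects_subsample_widths():
    with pytest.raises(ValueError):
        make_waveform_template("narrow", 50.0, 30_000.0, 12.0)  # 1.5 samples
    with pytest.raises(ValueError):
        make_waveform_template("narrow", 220.0, 30_000.0, -1.0)


def test_config_validation_rejects_undetectable_bursts():
    with pytest.raises(ValueError):
        SimulationConfig(within_burst_isi=(0.05, 0.12)).validate()  # ISI >= 0.1 s
    with pytest.raises(ValueError):
        SimulationConfig(spikes_per_burst=(4, 8)).validate()  # under 6 spikes
    with pytest.raises(ValueError):
        SimulationConfig(p_active=1.4).validate()
    with pytest.raises(ValueError):
        SimulationConfig(burst_onset_rate=1.0).validate()  # onsets too dense


def test_tonic_poisson_spike_count():
    cfg = SimulationConfig(
        n_channels=16, duration=600.0, p_active=1.0, tonic_rate=1.0,
        burst_onset_rate=0.0, seed=11,
    )
    truth = simulate_device_trains(cfg)
    counts = [ch.spike_times.size for ch in truth.channels]
    assert abs(np.mean(counts) - 600) < 3 * np.sqrt(600)


def test_unit_class_proportion():
    cfg = SimulationConfig(n_channels=100, duration=1.0, p_active=1.0,
                           tonic_rate=0.0, burst_onset_rate=0.0, p_excitatory=0.8, seed=3)
    truth = simulate_device_trains(cfg)
    frac = np.mean([ch.unit_class == "excitatory" for ch in truth.channels])
    half_ci = 2.576 * np.sqrt(0.8 * 0.2 / 100)
    assert abs(frac - 0.8) <= half_ci


def test_trains_strictly_increasing_and_bounded():
    cfg = SimulationConfig(n_channels=8, duration=120.0, p_active=1.0, seed=5)
    truth = simulate_device_trains(cfg)
    for ch in truth.channels:
        t = ch.spike_times
        assert np.all(np.diff(t) > 0)
        if t.size:
            assert t[0] >= 0 and t[-1] <= cfg.duration


def test_generated_episodes_satisfy_burst_criteria_by_construction():
    cfg = SimulationConfig(n_channels=8, duration=300.0, p_active=1.0,
                           tonic_rate=0.0, burst_onset_rate=0.12, seed=6)
    truth = simulate_device_trains(cfg)
    p = BurstParams()
    for ch in truth.channels:
        got = detect_bursts(ch.spike_times, p)
        # burst-only trains: the max-interval scan recovers every episode exactly
        assert got.n_bursts == ch.burst_intervals.shape[0]
        assert np.allclose(got.intervals, ch.burst_intervals)


def test_seed_reproducibility_bit_for_bit():
    cfg = SimulationConfig(n_channels=6, duration=60.0, seed=123)
    t1 = simulate_device_trains(cfg)
    t2 = simulate_device_trains(cfg)
    for a, b in zip(t1.channels, t2.channels):
        assert np.array_equal(a.spike_times, b.spike_times)
        assert a.unit_class == b.unit_class and a.active == b.active
    r1 = synthesize_raw(t1)
    r2 = synthesize_raw(t2)
    assert np.array_equal(r1.data, r2.data)


def test_noise_floor_of_spikeless_synthesis():
    cfg = SimulationConfig(n_channels=1, duration=60.0, p_active=0.0,
                           noise_sd=5e-6, seed=8)
    truth = simulate_device_trains(cfg)
    rec = synthesize_raw(truth)
    sd = rec.channel_volts(0).std()
    assert sd == pytest.approx(5e-6, rel=0.02)


def test_noiseless_single_spike_lands_on_the_ground_truth_sample():
    from dataclasses import replace
    cfg = SimulationConfig(n_channels=1, duration=2.0, p_active=1.0,
                           tonic_rate=0.0, burst_onset_rate=0.0, noise_sd=0.0, seed=1)
    truth = simulate_device_trains(cfg)
    truth.channels[0].spike_times = np.array([1.0])
    rec = synthesize_raw(truth, noise_sd=0.0)
    x = rec.channel_volts(0)
    assert int(np.argmin(x)) == int(round(1.0 * cfg.sampling_rate))


def test_collision_policy():
    cfg = SimulationConfig(n_channels=1, duration=2.0, p_active=1.0,
                           tonic_rate=0.0, burst_onset_rate=0.0, seed=1)
    truth = simulate_device_trains(cfg)
    truth.channels[0].spike_times = np.array([1.0, 1.0005])  # within template span
    with pytest.warns(UserWarning, match="template span"):
        synthesize_raw(truth)
    with pytest.raises(ValueError, match="template span"):
        synthesize_raw(truth, on_collision="error")


def test_maturation_defaults_percent_active_strictly_increasing():
    study = simulate_study("maturation", n_devices=4, seed=1)
    assert study.session_grid == MATURATION_DIVS
    by_div = {}
    for s in study.sessions:
        by_div.setdefault(s.session, []).append(s.truth.active_fraction())
    means = [np.mean(by_div[t]) for t in MATURATION_DIVS]
    assert np.all(np.diff(means) > 0)


def test_lps_null_effect_matches_control():
    study = simulate_study("lps", n_devices=3, death_hazard=0.0, rate_decay=0.0, seed=4)
    rows = {}
    for s in study.sessions:
        rows.setdefault((s.culture, s.condition), []).append(s.truth.active_fraction())
    # no hazard/decay: the treated tri-culture arm is statistically flat
    treated = np.asarray(rows[("tri", "lps")]).reshape(3, len(LPS_HOURS))
    assert np.all(treated == treated[:, :1])  # persistent recruitment, no death


def test_lps_defaults_collapse_active_fraction_by_72h():
    study = simulate_study("lps", seed=2)
    treated = [
        s.truth.active_fraction()
        for s in study.sessions
        if s.culture == "tri" and s.condition == "lps"
    ]
    treated = np.asarray(treated).reshape(4, len(LPS_HOURS))
    baseline = treated[:, 0].mean()
    final = treated[:, -1].mean()
    assert final < 0.2 * baseline


def test_unknown_scenario_rejected():
    with pytest.raises(ValueError, match="scenario"):
        simulate_study("sleep-deprivation")
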