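"""Filtering, robust noise estimation and threshold detection."""

import numpy as np
import pytest

from measpike.detection import (
    DetectionParams,
    SpikeEvents,
    detect_spikes,
    estimate_noise_sigma,
    extract_snippets,
    highpass_channel,
    process_channel,
)
from measpike.simulate import SimulationConfig, make_waveform_template, simulate_device_trains, synthesize_raw

FS = 30_000.0


def _sine(freq, duration=2.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestHighpass:
    def test_dc_rejection(self):
        x = np.full(int(2 * FS), 3.3)
        y = highpass_channel(x, FS)
        core = y[int(0.5 * FS) : -int(0.5 * FS)]
        assert np.max(np.abs(core)) < 1e-6 * 3.3

    def test_passband_preserves_1khz(self):
        y = highpass_channel(_sine(1000.0), FS)
        core = y[int(0.5 * FS) : -int(0.5 * FS)]
        assert np.max(np.abs(core)) == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuates_10hz(self):
        y = highpass_channel(_sine(10.0), FS)
        core = y[int(0.5 * FS) : -int(0.5 * FS)]
        assert np.max(np.abs(core)) < 0.1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            highpass_channel(np.zeros(100), 1000.0, cutoff=600.0)


class TestNoiseSigma:
    def test_gaussian_consistency(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 5e-6, int(60 * FS))
        assert estimate_noise_sigma(x, FS) == pytest.approx(5e-6, rel=0.01)

    def test_all_zero_signal(self):
        assert estimate_noise_sigma(np.zeros(int(FS)), FS) == 0.0

    def test_robust_to_contaminating_spikes(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 5e-6, int(60 * FS))
        n_spk = int(0.01 * x.size)
        idx = rng.choice(x.size, n_spk, replace=False)
        x[idx] += rng.choice([-1, 1], n_spk) * 100e-6
        assert estimate_noise_sigma(x, FS) == pytest.approx(5e-6, rel=0.03)
        assert x.std() > 1.1 * 5e-6  # the plain SD is blown up

    def test_too_short_or_empty(self):
        with pytest.raises(ValueError):
            estimate_noise_sigma(np.array([]), FS)
        with pytest.raises(ValueError):
            estimate_noise_sigma(np.zeros(100), FS)


class TestDetect:
    def test_flat_signal_no_events(self):
        ev = detect_spikes(np.zeros(1000), sigma=1.0, sampling_rate=FS)
        assert len(ev) == 0

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros(10), sigma=0.0, sampling_rate=FS)

    def test_biphasic_spike_collapses_to_one_event(self):
        tpl = make_waveform_template("narrow", 220.0, FS, 12.0)
        x = np.zeros(3000)
        # scale so both phases cross 8 sigma: peak/trough ratio is 0.35
        x[1000 : 1000 + tpl.length] = tpl.shape * 30.0
        ev = detect_spikes(x, sigma=1.0, sampling_rate=FS)
        assert len(ev) == 1
        assert ev.polarities[0] == -1  # trough dominates

    def test_gain_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1.0, int(5 * FS))
        x[::15000] += 20.0
        e1 = detect_spikes(x, 1.0, FS)
        e2 = detect_spikes(x * 7.5, 7.5, FS)
        assert np.array_equal(e1.times, e2.times)
        assert np.array_equal(e1.polarities, e2.polarities)

    def test_events_respect_threshold_and_dead_time(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1.0, int(10 * FS))
        idx = rng.choice(np.arange(int(FS), x.size - int(FS)), 40, replace=False)
        x[idx] -= 15.0
        params = DetectionParams()
        ev = detect_spikes(x, 1.0, FS, params)
        assert np.all(np.abs(ev.amplitudes) >= params.threshold_multiplier * 1.0)
        if len(ev) > 1:
            assert np.min(np.diff(ev.times)) >= params.dead_time

    def test_templates_in_noise_recovered(self):
        rng = np.random.default_rng(4)
        sigma = 5e-6
        x = rng.normal(0, sigma, int(30 * FS))
        tpl = make_waveform_template("broad", 380.0, FS, 12.0)
        true_samples = np.arange(50) * int(0.55 * FS) + int(FS)
        for s in true_samples:
            x[s : s + tpl.length] += tpl.shape * 12.0 * sigma
        ev = detect_spikes(x, estimate_noise_sigma(x, FS), FS)
        true_times = (true_samples + tpl.trough_index) / FS
        matched = sum(np.min(np.abs(ev.times - t)) <= 2e-4 for t in true_times)
        false_pos = sum(np.min(np.abs(true_times - t)) > 2e-4 for t in ev.times)
        assert matched >= 48
        assert false_pos <= 1


class TestSnippets:
    def test_boundary_event_dropped(self):
        ev = SpikeEvents(times=np.array([0.0, 0.05]), polarities=np.array([-1, -1]),
                         amplitudes=np.array([-10.0, -10.0]))
        stack, kept, dropped = extract_snippets(np.zeros(int(0.1 * FS)), ev, FS)
        assert dropped == 1
        assert kept.tolist() == [False, True]
        assert stack.shape == (1, int(round(1.6e-3 * FS)))

    def test_noiseless_snippet_matches_template(self):
        tpl = make_waveform_template("narrow", 220.0, FS, 12.0)
        x = np.zeros(int(0.2 * FS))
        s0 = 3000
        x[s0 : s0 + tpl.length] += tpl.shape
        ev = detect_spikes(x, sigma=0.1 / 8, sampling_rate=FS)
        stack, _, _ = extract_snippets(x, ev, FS)
        assert stack.shape[0] == 1
        # detection aligns at the trough; the cut window equals the template window
        assert np.allclose(stack[0], x[s0 : s0 + tpl.length])


def test_end_to_end_recall_precision_small_scale(small_truth):
    """simulate -> synthesize -> detect at 12 sigma on a 4-channel minute."""
    rec = synthesize_raw(small_truth)
    n_true = n_matched = n_det = n_fp = 0
    for i, ch in enumerate(small_truth.channels):
        res = process_channel(rec.channel_volts(i), rec.sampling_rate)
        det = res["events"].times
        n_true += ch.spike_times.size
        n_det += det.size
        if det.size:
            n_matched += sum(np.min(np.abs(det - t)) <= 2e-4 for t in ch.spike_times)
            n_fp += sum(np.min(np.abs(ch.spike_times - t)) > 2e-4 for t in det)
    assert n_matched / n_true >= 0.95
    assert 1 - n_fp / n_det >= 0.99
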