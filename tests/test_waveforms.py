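"""Unit assignment, trough-to-peak measurement and E/I classification."""

import numpy as np
import pytest

from measpike.simulate import make_waveform_template
from measpike.waveforms import (
    TooFewSnippetsError,
    assign_units,
    classify_ei,
    device_ei_ratio,
    mean_waveform_and_ptd,
    sort_channel,
    UnitWaveform,
)

FS = 30_000.0


def _snippets(tpl, n, noise, rng, flip=False):
    base = -tpl.shape if flip else tpl.shape
    return base * 12.0 + rng.normal(0, noise, size=(n, tpl.length))


class TestPTD:
    def test_arithmetic_on_known_extrema(self):
        w = np.zeros(48)
        w[18] = -1.0
        w[29] = 0.4
        _, _, ptd = mean_waveform_and_ptd(w[None, :], FS)
        assert ptd == pytest.approx(11 / FS * 1e6)  # 366.7 us

    @pytest.mark.parametrize("ttp", [220.0, 380.0])
    def test_template_roundtrip_within_one_sample(self, ttp):
        tpl = make_waveform_template("x", ttp, FS, 12.0)
        _, _, ptd = mean_waveform_and_ptd(tpl.shape[None, :], FS)
        assert abs(ptd - ttp) <= 1e6 / FS

    def test_gain_invariance(self):
        rng = np.random.default_rng(0)
        tpl = make_waveform_template("x", 220.0, FS, 12.0)
        snips = _snippets(tpl, 30, 0.5, rng)
        _, _, p1 = mean_waveform_and_ptd(snips, FS)
        _, _, p2 = mean_waveform_and_ptd(snips * 37.0, FS)
        assert p1 == p2

    def test_unmeasurable_waveform_flagged(self):
        w = np.linspace(1.0, -1.0, 48)  # trough at the last sample
        _, _, ptd = mean_waveform_and_ptd(w[None, :], FS)
        assert np.isnan(ptd)


class TestClassify:
    def test_canonical_widths(self):
        assert classify_ei(220.0).label == "inhibitory"
        assert classify_ei(380.0).label == "excitatory"

    def test_boundary_is_excitatory_with_tie_flag(self):
        res = classify_ei(280.0)
        assert res.label == "excitatory" and res.tie
        assert not classify_ei(280.1).tie

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            classify_ei(0.0)


class TestAssignUnits:
    def test_single_template_gives_one_unit(self):
        rng = np.random.default_rng(1)
        tpl = make_waveform_template("narrow", 220.0, FS, 12.0)
        labels = assign_units(_snippets(tpl, 80, 1.0, rng))
        assert np.unique(labels).size == 1

    def test_too_few_snippets_excluded(self):
        rng = np.random.default_rng(2)
        tpl = make_waveform_template("narrow", 220.0, FS, 12.0)
        with pytest.raises(TooFewSnippetsError):
            assign_units(_snippets(tpl, 5, 1.0, rng))

    def test_dual_threshold_duplicates_merged(self):
        # the same unit detected twice with a small alignment shift and
        # near-coincident spike times collapses to one unit
        rng = np.random.default_rng(3)
        tpl = make_waveform_template("broad", 380.0, FS, 12.0)
        a = _snippets(tpl, 40, 0.3, rng)
        shifted = np.roll(tpl.shape, 5) * 12.0
        b = shifted + rng.normal(0, 0.3, size=(40, tpl.length))
        snips = np.vstack([a, b])
        t_a = np.sort(rng.uniform(0, 60, 40))
        times = np.concatenate([t_a, t_a + 5 / FS])
        labels = assign_units(snips, spike_times=times)
        assert np.unique(labels).size == 1

    def test_opposite_polarity_mixture_separates(self):
        rng = np.random.default_rng(4)
        tpl = make_waveform_template("narrow", 220.0, FS, 12.0)
        a = _snippets(tpl, 60, 1.0, rng)
        b = _snippets(tpl, 60, 1.0, rng, flip=True)
        truth = np.array([0] * 60 + [1] * 60)
        labels = assign_units(np.vstack([a, b]))
        assert np.unique(labels).size == 2
        # majority-vote accuracy against ground truth
        acc = max(
            np.mean(labels == truth), np.mean(labels == 1 - truth)
        )
        assert acc >= 0.95


class TestDeviceRatio:
    def test_ratio_arithmetic(self):
        units = [UnitWaveform(0, np.zeros((1, 4)), np.zeros(4), np.zeros(4), 300.0,
                              ei_label="excitatory")] * 8
        units += [UnitWaveform(0, np.zeros((1, 4)), np.zeros(4), np.zeros(4), 200.0,
                               ei_label="inhibitory")] * 2
        assert device_ei_ratio(units) == pytest.approx(80.0)

    def test_all_narrow_is_zero_percent(self):
        units = [UnitWaveform(0, np.zeros((1, 4)), np.zeros(4), np.zeros(4), 200.0,
                              ei_label="inhibitory")] * 3
        assert device_ei_ratio(units) == 0.0

    def test_no_units_is_missing(self):
        assert np.isnan(device_ei_ratio([]))


def test_sort_channel_classifies_templates_perfectly():
    """At SNR 12 the 220/380 us templates classify without error."""
    rng = np.random.default_rng(5)
    for ttp, expected in ((220.0, "inhibitory"), (380.0, "excitatory")):
        tpl = make_waveform_template("t", ttp, FS, 12.0)
        units = sort_channel(_snippets(tpl, 50, 1.0, rng), channel=0, sampling_rate=FS)
        assert len(units) == 1
        assert units[0].ei_label == expected


def test_bimodal_width_histogram_recovers_both_modes():
    """A 50/50 narrow/broad population yields a bimodal width histogram with
    modes at the template widths, within one sample period."""
    from collections import Counter

    rng = np.random.default_rng(6)
    widths = []
    for _ in range(30):
        for ttp in (220.0, 380.0):
            tpl = make_waveform_template("t", ttp, FS, 12.0)
            _, _, ptd = mean_waveform_and_ptd(_snippets(tpl, 60, 1.0, rng), FS)
            widths.append(ptd)
    widths = np.asarray(widths)
    one_sample = 1e6 / FS
    narrow = widths[widths < 280]
    broad = widths[widths >= 280]
    assert narrow.size == broad.size == 30
    mode_narrow = Counter(np.round(narrow, 6)).most_common(1)[0][0]
    mode_broad = Counter(np.round(broad, 6)).most_common(1)[0][0]
    assert abs(mode_narrow - 220.0) <= one_sample
    assert abs(mode_broad - 380.0) <= one_sample
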