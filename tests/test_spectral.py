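"""Spectral analysis: Parseval consistency, layer localization, group PSD
comparison, and the two epileptiform event detectors against injected
ground truth."""

import numpy as np
import pytest

from ca1lamina import spectral as SP
from ca1lamina import synth as S
from ca1lamina.types import LaminarLFP
from conftest import make_unit


class TestLayerLocalization:
    @staticmethod
    def _wideband_with_spikes(channel=7, n_channels=12, fs=32000.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(fs * 5)
        wb = rng.standard_normal((n_channels, n)) * 5.0
        tmpl = -80.0 * np.exp(-0.5 * ((np.arange(-48, 49)) / 6.0) ** 2)
        for st in rng.integers(0, n - 100, 400):
            wb[channel, st : st + 97] += tmpl
        return wb, fs

    def test_finds_spiking_channel(self):
        wb, fs = self._wideband_with_spikes(channel=7)
        loc = SP.locate_pyramidal_layer(wb, fs)
        assert loc.channel == 7
        assert loc.informative

    def test_flat_profile_flagged(self):
        rng = np.random.default_rng(1)
        wb = rng.standard_normal((12, 60000)) * 5.0
        assert not SP.locate_pyramidal_layer(wb, 32000.0).informative

    def test_scale_invariance(self):
        wb, fs = self._wideband_with_spikes(channel=4)
        a = SP.locate_pyramidal_layer(wb, fs)
        b = SP.locate_pyramidal_layer(2.0 * wb, fs)
        assert a.channel == b.channel

    def test_low_sampling_rate_raises(self):
        with pytest.raises(ValueError):
            SP.locate_pyramidal_layer(np.zeros((4, 40000)), 2000.0)


class TestPSD:
    def test_sine_parseval(self):
        t = np.arange(120000) / 2000.0
        a = 50.0
        lfp = LaminarLFP(data=(a * np.cos(2 * np.pi * 40 * t))[None, :], fs=2000.0)
        psd = SP.compute_psd(lfp)
        p = psd.power.to_numpy()[0]
        assert psd.freqs[np.argmax(p)] == pytest.approx(40.0, abs=0.5)
        assert np.trapezoid(p, psd.freqs) == pytest.approx(a**2 / 2, rel=0.05)

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 120000)) * 10.0
        lfp = LaminarLFP(data=x, fs=2000.0)
        psd = SP.compute_psd(lfp, f_max=1000.0)
        integral = np.trapezoid(psd.power.to_numpy()[0], psd.freqs)
        assert integral == pytest.approx(x.var(), rel=0.05)

    def test_zeros_in_zeros_out(self):
        lfp = LaminarLFP(data=np.zeros((2, 40000)), fs=2000.0)
        assert np.all(SP.compute_psd(lfp).power.to_numpy() == 0.0)

    def test_segment_longer_than_recording_raises(self):
        lfp = LaminarLFP(data=np.zeros((1, 1000)), fs=2000.0)
        with pytest.raises(ValueError):
            SP.compute_psd(lfp, window_s=2.0)


class TestDedupe:
    def test_duplicates_collapse(self):
        units = [make_unit([0.0, 1.0], unit_id=f"u{i}", max_channel=c)
                 for i, c in enumerate([3, 3, 7])]
        assert SP.dedupe_unit_channels(units) == [3, 7]

    def test_single_channel(self):
        units = [make_unit([0.0, 1.0], unit_id=f"u{i}", max_channel=5)
                 for i in range(4)]
        assert SP.dedupe_unit_channels(units) == [5]

    def test_empty(self):
        assert SP.dedupe_unit_channels([]) == []


@pytest.fixture(scope="module")
def two_groups():
    # 8 control vs 9 injured animals; only the 35-75 Hz component differs
    # (-40% amplitude in the injured group)
    psds, groups = {}, {}
    for s in range(8):
        psds[f"ctrl{s}"] = TestGroupPSD._animal(s, 30.0)
        groups[f"ctrl{s}"] = "control"
    for s in range(9):
        psds[f"inj{s}"] = TestGroupPSD._animal(100 + s, 18.0)
        groups[f"inj{s}"] = "post_mtbi"
    return psds, groups


class TestGroupPSD:
    @staticmethod
    def _animal(seed, gamma_amp):
        cfg = S.SynthConfig(
            duration=60.0, n_channels=4, noise_amplitude_uv=50.0,
            oscillators=(
                S.OscillatorSpec(band=(4.0, 6.0), amplitude_uv=40.0, kind="sine",
                                 depth_center=1, depth_sigma=4),
                S.OscillatorSpec(band=(35.0, 75.0), amplitude_uv=gamma_amp,
                                 kind="noise", depth_center=1, depth_sigma=4),
            ),
            seed=seed,
        )
        return SP.compute_psd(S.generate_lfp(cfg))

    def test_zscore_normalization(self, two_groups):
        psds, groups = two_groups
        res = SP.zscore_group_psd(psds, groups)
        for g, curves_mean in res.group_mean.items():
            # each animal curve is z-scored, so the group mean is bounded
            assert abs(np.mean(curves_mean)) < 0.05

    def test_gamma_reduction_detected(self, two_groups):
        psds, groups = two_groups
        res = SP.zscore_group_psd(psds, groups)
        inside = [
            r for r in res.significant_ranges
            if r["low_hz"] >= 35.0 and r["high_hz"] <= 75.0
            and r["direction"] == "control > post_mtbi"
        ]
        assert inside, f"no significant range inside 35-75 Hz: {res.significant_ranges}"

    def test_identical_groups_not_significant(self):
        psds, groups = {}, {}
        for s in range(4):
            psds[f"a{s}"] = self._animal(s, 30.0)
            groups[f"a{s}"] = "control"
            psds[f"b{s}"] = self._animal(s, 30.0)
            groups[f"b{s}"] = "post_mtbi"
        res = SP.zscore_group_psd(psds, groups)
        assert res.significant_ranges == []

    def test_mains_band_untested(self, two_groups):
        psds, groups = two_groups
        res = SP.zscore_group_psd(psds, groups)
        mains = (res.freqs >= 58.0) & (res.freqs <= 62.0)
        assert np.all(np.isnan(res.p_values[mains]))

    def test_single_animal_group_skips_tests(self):
        psds = {"a": self._animal(0, 30.0), "b": self._animal(1, 30.0),
                "c": self._animal(2, 18.0)}
        groups = {"a": "control", "b": "control", "c": "post_mtbi"}
        res = SP.zscore_group_psd(psds, groups)
        assert not res.tested
        assert set(res.group_mean) == {"control", "post_mtbi"}


class TestDetectors:
    def test_depol_round_trip(self, background_config):
        lfp = S.generate_lfp(background_config(1))
        injected = S.inject_events(
            lfp, [S.DepolShiftEvent(onset_s=40.0, duration_s=1.2,
                                    amplitude_uv=800.0)]
        )
        events = SP.detect_sustained_depolarization(injected)
        assert len(events) == 1
        ev = events[0]
        assert ev.onset_s == pytest.approx(40.0, abs=0.05)
        assert ev.duration_s == pytest.approx(1.2, abs=0.1)
        assert ev.channel_fraction == 1.0

    def test_short_shift_rejected(self, background_config):
        lfp = S.generate_lfp(background_config(1))
        injected = S.inject_events(
            lfp, [S.DepolShiftEvent(onset_s=40.0, duration_s=0.5,
                                    amplitude_uv=800.0)]
        )
        assert SP.detect_sustained_depolarization(injected) == []

    def test_rhythmic_round_trip(self, background_config):
        lfp = S.generate_lfp(background_config(2))
        injected = S.inject_events(
            lfp, [S.RhythmicSpikesEvent(onset_s=60.0, duration_s=3.0)]
        )
        events = SP.detect_paroxysmal_spikes(injected)
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(60.0, abs=0.1)
        assert events[0].band_power_ratio > 5.0

    def test_rhythmic_on_few_channels_rejected(self, background_config):
        lfp = S.generate_lfp(background_config(2))
        injected = S.inject_events(
            lfp, [S.RhythmicSpikesEvent(onset_s=60.0, duration_s=3.0,
                                        channels=(0,))]
        )
        assert SP.detect_paroxysmal_spikes(injected) == []

    def test_short_recording_raises(self):
        lfp = LaminarLFP(data=np.zeros((4, 8000)), fs=2000.0)
        with pytest.raises(ValueError):
            SP.detect_sustained_depolarization(lfp)
        with pytest.raises(ValueError):
            SP.detect_paroxysmal_spikes(lfp)
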