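"""Generator contracts: determinism, spectral content, point-process rates,
and the analytic von Mises locking oracle."""

import numpy as np
import pytest
from scipy.signal import welch

from ca1lamina import metrics as M
from ca1lamina import synth as S


def unit_phases(unit, lfp, band):
    """Ground-truth phase of each spike (linear interp of unwrapped phase)."""
    ph = np.unwrap(lfp.band_phases[band])
    x = np.interp(unit.spike_times * lfp.fs, np.arange(ph.size), ph)
    return np.angle(np.exp(1j * x))


class TestLFP:
    def test_single_oscillator_psd_peak(self):
        cfg = S.SynthConfig(
            duration=30.0, n_channels=2, noise_amplitude_uv=0.0,
            oscillators=(S.OscillatorSpec(band=(5.0, 5.0), amplitude_uv=100.0,
                                          kind="sine", depth_center=0),),
            seed=1,
        )
        lfp = S.generate_lfp(cfg)
        f, p = welch(lfp.data[0], fs=lfp.fs, nperseg=8192)
        assert abs(f[np.argmax(p)] - 5.0) < f[1] - f[0] + 1e-9

    def test_noise_slope(self):
        # log-log PSD slope of pure 1/f background ~ -1 over 1-300 Hz
        cfg = S.SynthConfig(duration=60.0, n_channels=2, noise_exponent=1.0,
                            oscillators=(), seed=3)
        lfp = S.generate_lfp(cfg)
        f, p = welch(lfp.data[0], fs=lfp.fs, nperseg=4096)
        sel = (f >= 1.0) & (f <= 300.0)
        slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_determinism(self):
        cfg = S.control_config(seed=5, duration=10.0)
        a = S.generate_lfp(cfg)
        b = S.generate_lfp(cfg)
        np.testing.assert_array_equal(a.data, b.data)
        ua = S.generate_spike_trains(cfg, a)
        ub = S.generate_spike_trains(cfg, b)
        for x, y in zip(ua, ub):
            np.testing.assert_array_equal(x.spike_times, y.spike_times)
            np.testing.assert_array_equal(x.waveform, y.waveform)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            S.SynthConfig(duration=-1.0)
        with pytest.raises(ValueError):
            S.SynthConfig(sampling_rate=500.0)
        with pytest.raises(ValueError):
            S.SynthConfig(
                interneuron=S.ClassParams(rate_mean_hz=-2.0)
            )

    def test_depth_profile_scales_oscillator(self):
        cfg = S.SynthConfig(
            duration=10.0, n_channels=16, noise_amplitude_uv=0.0,
            oscillators=(S.OscillatorSpec(band=(10.0, 10.0), amplitude_uv=50.0,
                                          kind="sine", depth_center=4.0,
                                          depth_sigma=2.0),),
            seed=2,
        )
        lfp = S.generate_lfp(cfg)
        rms = lfp.data.std(axis=1)
        assert np.argmax(rms) == 4
        assert rms[15] < 0.1 * rms[4]


class TestSpikeTrains:
    def test_rate_recovery_tonic(self):
        # 10 Hz for 600 s: Poisson SE = sqrt(r/T) ~ 0.13 Hz; 5% tolerance
        cfg = S.SynthConfig(
            duration=600.0, n_channels=2, n_pyramidal=0, n_interneuron=1,
            interneuron=S.ClassParams(rate_mean_hz=10.0, rate_cv=0.0),
            oscillators=(), noise_amplitude_uv=0.0, seed=4,
        )
        lfp = S.generate_lfp(cfg)
        (u,) = S.generate_spike_trains(cfg, lfp)
        assert u.n_spikes / 600.0 == pytest.approx(10.0, rel=0.05)

    def test_kappa_zero_gives_chance_mvl(self):
        cfg = S.SynthConfig(
            duration=300.0, n_channels=2, n_pyramidal=0, n_interneuron=1,
            interneuron=S.ClassParams(
                rate_mean_hz=30.0, rate_cv=0.0,
                locking=(S.LockingSpec(band=(5.0, 5.0), kappa=0.0),),
            ),
            oscillators=(S.OscillatorSpec(band=(5.0, 5.0), amplitude_uv=50.0,
                                          kind="sine"),),
            noise_amplitude_uv=0.0, seed=6,
        )
        lfp = S.generate_lfp(cfg)
        (u,) = S.generate_spike_trains(cfg, lfp)
        phases = unit_phases(u, lfp, (5.0, 5.0))
        r = np.abs(np.mean(np.exp(1j * phases)))
        # chance level sqrt(pi/(4n)) plus generous sampling slack
        assert r < 3.0 * np.sqrt(np.pi / (4 * u.n_spikes))

    def test_mvl_matches_bessel_ratio(self):
        # >= 1e5 spikes: empirical MVL within +/-0.003 of I1(k)/I0(k)
        cfg = S.SynthConfig(
            duration=600.0, n_channels=2, n_pyramidal=0, n_interneuron=1,
            interneuron=S.ClassParams(
                rate_mean_hz=200.0, rate_cv=0.0,
                locking=(S.LockingSpec(band=(5.0, 5.0), kappa=2.0),),
            ),
            oscillators=(S.OscillatorSpec(band=(5.0, 5.0), amplitude_uv=100.0,
                                          kind="sine"),),
            noise_amplitude_uv=0.0, seed=7,
        )
        lfp = S.generate_lfp(cfg)
        (u,) = S.generate_spike_trains(cfg, lfp)
        assert u.n_spikes >= 1e5
        phases = unit_phases(u, lfp, (5.0, 5.0))
        r = np.abs(np.mean(np.exp(1j * phases)))
        assert r == pytest.approx(S.expected_mvl(2.0), abs=0.003)

    def test_phase_modulation_preserves_rate(self):
        # I0 normalization: locked and unlocked units share the mean rate
        common = dict(duration=600.0, n_channels=2, n_pyramidal=0,
                      n_interneuron=1, noise_amplitude_uv=0.0,
                      oscillators=(S.OscillatorSpec(band=(5.0, 5.0),
                                                    amplitude_uv=50.0,
                                                    kind="sine"),))
        locked = S.SynthConfig(
            interneuron=S.ClassParams(
                rate_mean_hz=10.0, rate_cv=0.0,
                locking=(S.LockingSpec(band=(5.0, 5.0), kappa=2.0),),
            ),
            seed=8, **common,
        )
        lfp = S.generate_lfp(locked)
        (u,) = S.generate_spike_trains(locked, lfp)
        # 3 sigma of the Poisson rate estimate at 10 Hz / 600 s
        assert u.n_spikes / 600.0 == pytest.approx(10.0, abs=3 * np.sqrt(10 / 600))

    def test_bursty_has_smaller_first_moment(self):
        common = dict(duration=300.0, n_channels=2, oscillators=(),
                      noise_amplitude_uv=0.0)
        cfg = S.SynthConfig(
            n_pyramidal=1, n_interneuron=1,
            pyramidal=S.ClassParams(rate_mean_hz=6.0, rate_cv=0.0,
                                    burst_prob=0.6, intra_burst_isi_ms=4.0),
            interneuron=S.ClassParams(rate_mean_hz=6.0, rate_cv=0.0),
            seed=9, **common,
        )
        lfp = S.generate_lfp(cfg)
        pyr, intn = S.generate_spike_trains(cfg, lfp)
        fm_pyr = M.acg_first_moment(M.autocorrelogram(pyr))
        fm_int = M.acg_first_moment(M.autocorrelogram(intn))
        assert fm_pyr < fm_int

    def test_missing_locking_band_raises(self):
        cfg = S.SynthConfig(
            duration=10.0, n_channels=2, n_pyramidal=0, n_interneuron=1,
            interneuron=S.ClassParams(
                rate_mean_hz=10.0,
                locking=(S.LockingSpec(band=(40.0, 42.0), kappa=1.0),),
            ),
            oscillators=(), seed=1,
        )
        lfp = S.generate_lfp(cfg)
        with pytest.raises(ValueError):
            S.generate_spike_trains(cfg, lfp)

    def test_dentate_units_sit_below_layer(self):
        cfg = S.SynthConfig(duration=10.0, n_channels=12, n_pyramidal=1,
                            n_interneuron=1, n_dentate=2, oscillators=(),
                            seed=2)
        lfp = S.generate_lfp(cfg)
        units = S.generate_spike_trains(cfg, lfp)
        from ca1lamina.types import LAYER_BELOW_PYR
        dg = [u for u in units if u.layer == LAYER_BELOW_PYR]
        assert len(dg) == 2
        assert all(lfp.layers[u.max_channel] == LAYER_BELOW_PYR for u in dg)


class TestEvents:
    def test_empty_specs_identity(self):
        cfg = S.SynthConfig(duration=15.0, n_channels=4, seed=3)
        lfp = S.generate_lfp(cfg)
        out = S.inject_events(lfp, [])
        np.testing.assert_array_equal(out.data, lfp.data)

    def test_event_outside_duration_raises(self):
        cfg = S.SynthConfig(duration=15.0, n_channels=4, seed=3)
        lfp = S.generate_lfp(cfg)
        with pytest.raises(ValueError):
            S.inject_events(lfp, [S.DepolShiftEvent(onset_s=14.5, duration_s=2.0)])

    def test_ground_truth_log(self):
        cfg = S.SynthConfig(duration=20.0, n_channels=4, seed=3)
        lfp = S.generate_lfp(cfg)
        out = S.inject_events(
            lfp,
            [S.DepolShiftEvent(onset_s=5.0, duration_s=1.2, amplitude_uv=500.0),
             S.RhythmicSpikesEvent(onset_s=10.0, duration_s=2.0)],
        )
        kinds = [e["kind"] for e in out.events]
        assert kinds == ["depol_shift", "rhythmic_spikes"]
        assert out.events[0]["onset_s"] == 5.0
        assert out.events[1]["freq_hz"] == 7.0
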