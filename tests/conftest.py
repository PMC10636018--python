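import numpy as np
import pytest

from ca1lamina import metrics as M
from ca1lamina import synth as S


@pytest.fixture(scope="session")
def background_config():
    """Clean multichannel background: 1/f noise + theta sine + broadband
    gamma noise, no events, no units."""

    def make(seed: int, duration: float = 100.0, n_channels: int = 12) -> S.SynthConfig:
        return S.SynthConfig(
            duration=duration,
            n_channels=n_channels,
            noise_amplitude_uv=50.0,
            oscillators=(
                S.OscillatorSpec(band=(4.0, 6.0), amplitude_uv=40.0, kind="sine",
                                 depth_center=3, depth_sigma=6),
                S.OscillatorSpec(band=(35.0, 75.0), amplitude_uv=30.0, kind="noise",
                                 depth_center=3, depth_sigma=6),
            ),
            seed=seed,
        )

    return make


@pytest.fixture(scope="session")
def separated_population():
    """100 units in two classes fully separated across the 7 Hz rate
    boundary (bursty 2 Hz pyramidal-like vs. tonic 12 Hz interneuron-like),
    with their computed metrics and ground-truth classes."""
    cfg = S.SynthConfig(
        duration=60.0,
        n_channels=12,
        n_pyramidal=50,
        n_interneuron=50,
        pyramidal=S.ClassParams(
            rate_mean_hz=2.0, rate_cv=0.3, burst_prob=0.5, intra_burst_isi_ms=4.0,
            waveform_amplitude_uv=300.0, waveform_width_ms=0.35,
        ),
        interneuron=S.ClassParams(
            rate_mean_hz=12.0, rate_cv=0.1,
            waveform_amplitude_uv=200.0, waveform_width_ms=0.25,
        ),
        oscillators=(),
        noise_amplitude_uv=20.0,
        seed=11,
    )
    lfp = S.generate_lfp(cfg)
    units = S.generate_spike_trains(cfg, lfp)
    metrics = [M.compute_unit_metrics(u, cfg.duration) for u in units]
    truth = {u.unit_id: u.meta["true_class"] for u in units}
    return metrics, truth


def make_unit(times, unit_id="u", waveform=None, t_ms=None, **kw):
    """Minimal SpikeUnit with a default synthetic waveform."""
    from ca1lamina.types import SpikeUnit

    if waveform is None:
        t_ms = np.arange(0, 5.0 + 1e-9, 1000.0 / 32000.0)
        waveform = -300.0 * np.exp(-0.5 * ((t_ms - 2.5) / 0.15) ** 2)
    return SpikeUnit(
        unit_id=unit_id,
        spike_times=np.asarray(times, float),
        waveform=waveform,
        waveform_t_ms=t_ms,
        max_channel=kw.pop("max_channel", 0),
        **kw,
    )
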