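"""Core containers shared across the pipeline.

Conventions: time in seconds, LFP potentials in microvolts, waveform time
axes in milliseconds, frequencies in Hz. LFP matrices are channel-major
(``n_channels x n_samples``); channel 0 is the most superficial contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: layer annotations carried per channel / per unit
LAYER_CA1_PYR = "ca1_pyr"
LAYER_BELOW_PYR = "below_pyr"
LAYER_UNKNOWN = "unknown"


@dataclass
class LaminarLFP:
    """Multichannel laminar field-potential recording.

    Parameters
    ----------
    data:
        ``(n_channels, n_samples)`` array of potentials in uV.
    fs:
        Sampling rate in Hz.
    spacing_um:
        Inter-contact spacing along the probe, in micrometres.
    layers:
        Per-channel anatomical annotation (``ca1_pyr`` / ``below_pyr`` /
        ``unknown``).
    band_phases:
        Optional generator ground truth: instantaneous phase (rad) of each
        narrowband oscillator, keyed by ``(low_hz, high_hz)``.
    events:
        Ground-truth log of injected events (dicts with ``kind``, ``onset_s``,
        ``duration_s``, ...).
    """

    data: np.ndarray
    fs: float
    spacing_um: float = 100.0
    layers: list[str] = field(default_factory=list)
    band_phases: dict[tuple[float, float], np.ndarray] = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("LFP data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.layers:
            self.layers = [LAYER_UNKNOWN] * self.n_channels
        if len(self.layers) != self.n_channels:
            raise ValueError("one layer label per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "LaminarLFP":
        return LaminarLFP(
            data=self.data.copy(),
            fs=self.fs,
            spacing_um=self.spacing_um,
            layers=list(self.layers),
            band_phases={k: v.copy() for k, v in self.band_phases.items()},
            events=[dict(e) for e in self.events],
        )


@dataclass
class SpikeUnit:
    """One sorted single unit.

    ``waveform`` is the mean extracellular spike waveform in uV sampled on
    ``waveform_t_ms`` (ms, relative to an arbitrary window start);
    ``max_channel`` is the probe channel of maximal spike amplitude.
    """

    unit_id: str
    spike_times: np.ndarray
    waveform: np.ndarray
    waveform_t_ms: np.ndarray
    max_channel: int
    layer: str = LAYER_UNKNOWN
    animal_id: str = ""
    group: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        self.waveform = np.asarray(self.waveform, dtype=np.float64)
        self.waveform_t_ms = np.asarray(self.waveform_t_ms, dtype=np.float64)
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike times must be sorted")
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValueError("spike times must be non-negative")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class UnitMetrics:
    """Per-unit electrophysiological summary."""

    unit_id: str
    firing_rate: float
    spike_amplitude: float
    spike_width: float
    acg: np.ndarray  # probability per 1-ms lag, lags 1..50 ms
    acg_first_moment: float
    layer: str = LAYER_UNKNOWN
    max_channel: int = -1
    animal_id: str = ""
    group: str = ""
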