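"""Per-unit electrophysiological metrics.

Firing rate, spike autocorrelogram (1-ms bins, lags 1-50 ms, normalized to a
probability distribution) and its first moment, baseline-to-peak spike
amplitude, half-amplitude spike width, and the wavelet high-pass filter used
to condition wideband signals before waveform extraction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt

from .types import SpikeUnit, UnitMetrics

ACG_MAX_LAG_MS = 50

__all__ = [
    "firing_rate",
    "autocorrelogram",
    "acg_first_moment",
    "spike_amplitude",
    "spike_width",
    "wavelet_highpass",
    "compute_unit_metrics",
]


def firing_rate(unit: SpikeUnit, duration: float) -> float:
    """Mean firing rate in Hz: spike count divided by recording duration."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if unit.n_spikes == 0:
        warnings.warn(
            f"unit {unit.unit_id} has no spikes; rate 0 Hz "
            "(such units are excluded from group statistics upstream)",
            stacklevel=2,
        )
        return 0.0
    return unit.n_spikes / duration


def autocorrelogram(unit: SpikeUnit, max_lag_ms: int = ACG_MAX_LAG_MS) -> np.ndarray:
    """Spike-train autocorrelogram as a probability over 1-ms lags.

    Ordered spike-pair time differences are binned at 1 ms for lags
    1..max_lag_ms (bin ``l`` collects differences in ``(l-0.5, l+0.5]`` ms)
    and the counts are normalized by the total count over all lags. Returns
    an all-zero vector when no pair falls within the window.
    """
    if unit.n_spikes < 2:
        raise ValueError("autocorrelogram requires at least 2 spikes")
    t_ms = unit.spike_times * 1000.0
    counts = np.zeros(max_lag_ms, dtype=np.int64)
    hi = max_lag_ms + 0.5
    edges = np.arange(0.5, hi + 1.0, 1.0)  # 0.5, 1.5, ..., max_lag+0.5
    # sliding window over the sorted train: for each spike, later spikes
    # within the lag window
    right = np.searchsorted(t_ms, t_ms + hi, side="right")
    for i in range(t_ms.size - 1):
        j = right[i]
        if j > i + 1:
            d = t_ms[i + 1 : j] - t_ms[i]
            c, _ = np.histogram(d, bins=edges)
            counts += c
    total = counts.sum()
    if total == 0:
        return np.zeros(max_lag_ms, dtype=np.float64)
    return counts / total


def acg_first_moment(acg: np.ndarray) -> float:
    """Probability-weighted mean lag (ms) of a normalized autocorrelogram."""
    acg = np.asarray(acg, dtype=np.float64)
    s = acg.sum()
    if s <= 0:
        raise ValueError("first moment undefined for an all-zero autocorrelogram")
    lags = np.arange(1, acg.size + 1, dtype=np.float64)
    return float(np.dot(lags, acg) / s)


def _baseline(waveform: np.ndarray, frac: float = 0.25) -> float:
    # mean of the leading pre-deflection window
    n = max(1, int(round(frac * waveform.size)))
    return float(np.mean(waveform[:n]))


def spike_amplitude(waveform: np.ndarray, baseline_frac: float = 0.25) -> float:
    """Baseline-to-peak amplitude (uV, unsigned).

    Baseline is the mean of the first ``baseline_frac`` of samples; the peak
    is the sample of maximal absolute deviation from baseline (extracellular
    somatic spikes are trough-dominant, so this is usually the trough).
    """
    waveform = np.asarray(waveform, dtype=np.float64)
    b = _baseline(waveform, baseline_frac)
    dev = waveform - b
    amp = float(np.max(np.abs(dev)))
    if amp == 0:
        raise ValueError("flat waveform: amplitude undefined")
    return amp


def spike_width(
    waveform: np.ndarray,
    t_ms: np.ndarray,
    baseline_frac: float = 0.25,
) -> float:
    """Spike width (ms) at half of the baseline-to-peak amplitude.

    Linear interpolation between samples locates the two half-amplitude
    crossings flanking the extremum.
    """
    waveform = np.asarray(waveform, dtype=np.float64)
    t_ms = np.asarray(t_ms, dtype=np.float64)
    b = _baseline(waveform, baseline_frac)
    dev = waveform - b
    k = int(np.argmax(np.abs(dev)))
    sign = 1.0 if dev[k] >= 0 else -1.0
    x = sign * dev  # peak now positive
    half = x[k] / 2.0

    # left crossing
    i = k
    while i > 0 and x[i - 1] > half:
        i -= 1
    if i == 0 and x[0] > half:
        raise ValueError("half-amplitude level not crossed before the peak")
    t_left = np.interp(half, [x[i - 1], x[i]], [t_ms[i - 1], t_ms[i]])

    # right crossing
    j = k
    n = x.size
    while j < n - 1 and x[j + 1] > half:
        j += 1
    if j == n - 1 and x[-1] > half:
        raise ValueError("half-amplitude level not crossed after the peak")
    t_right = np.interp(half, [x[j + 1], x[j]], [t_ms[j + 1], t_ms[j]])

    width = float(t_right - t_left)
    if width <= 0:
        raise ValueError("malformed waveform: non-positive width")
    return width


def wavelet_highpass(signal: np.ndarray, level: int = 6, wavelet: str = "db4") -> np.ndarray:
    """Wavelet multilevel high-pass (decompose, zero the coarsest
    approximation, reconstruct).

    Removes low-frequency content with minimal waveform-shape distortion:
    at 32 kHz sampling and level 6, the discarded approximation band is
    roughly 0-250 Hz.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size < 2**level:
        raise ValueError(f"signal too short for a level-{level} decomposition")
    coeffs = pywt.wavedec(signal, wavelet, level=level)
    coeffs[0] = np.zeros_like(coeffs[0])
    out = pywt.waverec(coeffs, wavelet)
    return out[: signal.size]


def compute_unit_metrics(unit: SpikeUnit, duration: float) -> UnitMetrics:
    """All per-unit metrics in one pass."""
    acg = autocorrelogram(unit)
    fm = acg_first_moment(acg) if acg.sum() > 0 else np.nan
    return UnitMetrics(
        unit_id=unit.unit_id,
        firing_rate=firing_rate(unit, duration),
        spike_amplitude=spike_amplitude(unit.waveform),
        spike_width=spike_width(unit.waveform, unit.waveform_t_ms),
        acg=acg,
        acg_first_moment=fm,
        layer=unit.layer,
        max_channel=unit.max_channel,
        animal_id=unit.animal_id,
        group=unit.group,
    )
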