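"""Synthetic laminar recordings with known ground truth.

Emulates the statistical structure the downstream analyses assume: a
channels x samples laminar LFP built from per-channel 1/f background noise
plus narrowband oscillators with Gaussian laminar depth profiles; two unit
classes (bursty, slow-firing, large-spike pyramidal cells vs. tonic,
fast-firing interneurons) whose spikes are phase-locked to chosen oscillator
bands through a von Mises intensity modulation; and injectable
hyperexcitability events (sustained negative depolarizing shifts and 6-8 Hz
rhythmic spike trains) with a ground-truth event log.

Spike trains are drawn by point-process thinning of the inhomogeneous
intensity

    lambda(t) = r * exp(kappa * cos(phi(t) - phi0)) / I0(kappa)

so the long-run mean rate is exactly ``r`` (the I0 normalization) and the
expected mean vector length of the spike phases is the analytic von Mises
resultant I1(kappa)/I0(kappa).

Determinism: every random stream is derived from the master seed plus a
stable integer key (stream per unit), so adding units or events does not
perturb existing ones and a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.special import i0, i1

from .types import LAYER_BELOW_PYR, LAYER_CA1_PYR, LAYER_UNKNOWN, LaminarLFP, SpikeUnit

WAVEFORM_FS_HZ = 32_000.0  # waveform templates sampled at acquisition resolution
WAVEFORM_WINDOW_MS = 5.0

__all__ = [
    "OscillatorSpec",
    "LockingSpec",
    "ClassParams",
    "DepolShiftEvent",
    "RhythmicSpikesEvent",
    "SynthConfig",
    "generate_lfp",
    "generate_spike_trains",
    "inject_events",
    "expected_mvl",
    "control_config",
    "post_mtbi_config",
]


def expected_mvl(kappa: float) -> float:
    """Analytic resultant length of a von Mises distribution, I1(k)/I0(k)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return 0.0
    return float(i1(kappa) / i0(kappa))


@dataclass(frozen=True)
class OscillatorSpec:
    """One narrowband LFP component.

    ``band`` is the (low, high) Hz support; ``kind='sine'`` places a pure
    sinusoid at the band centre, ``kind='noise'`` a band-limited Gaussian
    process. ``amplitude_uv`` is the peak-channel sinusoid amplitude (noise
    components use the matching RMS, amplitude/sqrt(2)). The laminar depth
    profile is a Gaussian over channel index.
    """

    band: tuple[float, float]
    amplitude_uv: float
    kind: str = "sine"
    depth_center: float = 5.0
    depth_sigma: float = 6.0


@dataclass(frozen=True)
class LockingSpec:
    """Von Mises locking of a unit class to one oscillator band."""

    band: tuple[float, float]
    kappa: float
    phi0: float = 0.0


@dataclass(frozen=True)
class ClassParams:
    """Firing statistics and waveform template of one unit class."""

    rate_mean_hz: float
    rate_cv: float = 0.25
    burst_prob: float = 0.0  # probability an event is a multi-spike burst
    intra_burst_isi_ms: float = 5.0
    burst_len_mean: float = 3.0  # mean extra length of a burst (>= 2 spikes)
    locking: tuple[LockingSpec, ...] = ()
    waveform_amplitude_uv: float = 300.0
    waveform_width_ms: float = 0.35
    jitter_frac: float = 0.05


@dataclass(frozen=True)
class DepolShiftEvent:
    """Sustained negative LFP deflection (paroxysmal depolarizing shift)."""

    onset_s: float
    duration_s: float
    amplitude_uv: float = 800.0  # magnitude of the negative shift
    channels: tuple[int, ...] | None = None  # None = all channels
    ramp_s: float = 0.08


@dataclass(frozen=True)
class RhythmicSpikesEvent:
    """Synchronized rhythmic spike-wave train in the 6-8 Hz range."""

    onset_s: float
    duration_s: float
    freq_hz: float = 7.0
    amplitude_uv: float = 600.0
    channels: tuple[int, ...] | None = None
    ramp_s: float = 0.1


@dataclass(frozen=True)
class SynthConfig:
    """Full description of one synthetic animal recording."""

    duration: float = 120.0
    sampling_rate: float = 2000.0
    n_channels: int = 32
    channel_spacing_um: float = 100.0
    group: str = "control"
    n_pyramidal: int = 7
    n_interneuron: int = 6
    n_dentate: int = 0  # extra below-layer units (anatomical-gate fixtures)
    pyramidal: ClassParams = field(
        default_factory=lambda: ClassParams(rate_mean_hz=2.27)
    )
    interneuron: ClassParams = field(
        default_factory=lambda: ClassParams(rate_mean_hz=7.46)
    )
    oscillators: tuple[OscillatorSpec, ...] = ()
    noise_exponent: float = 1.0
    noise_amplitude_uv: float = 50.0  # RMS of the 1/f background per channel
    events: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate < 2000.0:
            raise ValueError("sampling rate must be at least 2 kHz")
        for cls in (self.pyramidal, self.interneuron):
            if cls.rate_mean_hz <= 0:
                raise ValueError("class mean rates must be positive")
            for lock in cls.locking:
                if lock.kappa < 0:
                    raise ValueError("locking kappa must be non-negative")

    def layer_labels(self) -> list[str]:
        """Top third of the probe is the CA1 pyramidal layer, bottom third
        lies below it (toward dentate); the middle is unannotated."""
        n = self.n_channels
        top = max(1, n // 3)
        bottom = max(1, n // 3)
        labels = [LAYER_UNKNOWN] * n
        for c in range(top):
            labels[c] = LAYER_CA1_PYR
        for c in range(n - bottom, n):
            labels[c] = LAYER_BELOW_PYR
        return labels


# ---------------------------------------------------------------------------
# LFP generation
# ---------------------------------------------------------------------------


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, exponent: float,
                      rms: float) -> np.ndarray:
    """Gaussian noise with power-law PSD ~ 1/f**exponent, unit-normalized RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n)
    sd = shaped.std()
    if sd > 0:
        shaped *= rms / sd
    return shaped


def _depth_profile(spec: OscillatorSpec, n_channels: int) -> np.ndarray:
    idx = np.arange(n_channels, dtype=np.float64)
    return np.exp(-0.5 * ((idx - spec.depth_center) / spec.depth_sigma) ** 2)


def _oscillator_signal(
    spec: OscillatorSpec, rng: np.random.Generator, n: int, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return (signal at the profile peak, ground-truth phase in (-pi, pi])."""
    lo, hi = spec.band
    t = np.arange(n) / fs
    if spec.kind == "sine":
        f0 = 0.5 * (lo + hi)
        phi_start = rng.uniform(-np.pi, np.pi)
        phase = 2.0 * np.pi * f0 * t + phi_start
        sig = spec.amplitude_uv * np.cos(phase)
        wrapped = np.angle(np.exp(1j * phase))
        return sig, wrapped
    if spec.kind == "noise":
        if hi <= lo:
            raise ValueError("noise oscillator needs a band of positive width")
        white = rng.standard_normal(n)
        spec_f = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        mask = ((f >= lo) & (f <= hi)).astype(float)
        sig = np.fft.irfft(spec_f * mask, n=n)
        sd = sig.std()
        if sd > 0:
            sig *= (spec.amplitude_uv / np.sqrt(2.0)) / sd
        phase = np.angle(hilbert(sig))
        return sig, phase
    raise ValueError(f"unknown oscillator kind {spec.kind!r}")


def generate_lfp(config: SynthConfig) -> LaminarLFP:
    """Laminar LFP = per-channel 1/f noise + depth-profiled oscillators.

    The returned object carries the per-sample ground-truth phase of every
    oscillator band in ``band_phases`` (phase of the component at the depth
    profile's peak channel; the component is synchronous across channels).
    """
    n = int(round(config.duration * config.sampling_rate))
    if n <= 0:
        raise ValueError("empty recording")
    data = np.zeros((config.n_channels, n), dtype=np.float64)

    if config.noise_amplitude_uv > 0:
        for ch in range(config.n_channels):
            rng = np.random.default_rng([config.seed, 10, ch])
            data[ch] += _one_over_f_noise(
                rng, n, config.sampling_rate, config.noise_exponent,
                config.noise_amplitude_uv,
            )

    band_phases: dict[tuple[float, float], np.ndarray] = {}
    for k, osc in enumerate(config.oscillators):
        rng = np.random.default_rng([config.seed, 20, k])
        sig, phase = _oscillator_signal(osc, rng, n, config.sampling_rate)
        profile = _depth_profile(osc, config.n_channels)
        data += profile[:, None] * sig[None, :]
        band_phases[tuple(osc.band)] = phase

    lfp = LaminarLFP(
        data=data,
        fs=config.sampling_rate,
        spacing_um=config.channel_spacing_um,
        layers=config.layer_labels(),
        band_phases=band_phases,
    )
    if config.events:
        lfp = inject_events(lfp, config.events)
    return lfp


# ---------------------------------------------------------------------------
# Spike-train generation
# ---------------------------------------------------------------------------


def _phase_interpolator(phase: np.ndarray, fs: float):
    """Linear interpolation of the unwrapped ground-truth phase."""
    unwrapped = np.unwrap(phase)
    n = unwrapped.size

    def at(t: np.ndarray) -> np.ndarray:
        x = np.clip(t * fs, 0, n - 1)
        return np.interp(x, np.arange(n), unwrapped)

    return at


def _modulation(t: np.ndarray, locks, phase_fns) -> np.ndarray:
    """Product of normalized von Mises factors; time-average 1 per factor."""
    m = np.ones_like(t)
    for lock in locks:
        phi = phase_fns[lock.band](t)
        m *= np.exp(lock.kappa * np.cos(phi - lock.phi0)) / i0(lock.kappa)
    return m


def _thinned_times(
    rng: np.random.Generator, duration: float, rate: float, locks, phase_fns
) -> np.ndarray:
    """Inhomogeneous Poisson times by thinning (exact, no time binning)."""
    lam_max = rate
    for lock in locks:
        lam_max *= np.exp(lock.kappa) / i0(lock.kappa)
    n_cand = rng.poisson(lam_max * duration)
    if n_cand == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    if not locks:
        return cand
    lam = rate * _modulation(cand, locks, phase_fns)
    keep = rng.uniform(0.0, lam_max, n_cand) < lam
    return cand[keep]


def _burst_train(
    rng: np.random.Generator,
    duration: float,
    rate: float,
    params: ClassParams,
    phase_fns,
) -> np.ndarray:
    """Burst-renewal train: phase-modulated Poisson event onsets; each event
    is a single spike or (with ``burst_prob``) a burst of geometric length
    with jittered intra-burst intervals. Onset rate is scaled so the mean
    spike rate equals ``rate``."""
    p_b = params.burst_prob
    # burst length = 2 + Geometric counts; mean burst length:
    mean_burst_len = params.burst_len_mean
    if mean_burst_len < 2:
        raise ValueError("burst_len_mean must be >= 2")
    mean_len = (1.0 - p_b) + p_b * mean_burst_len
    onset_rate = rate / mean_len
    onsets = _thinned_times(rng, duration, onset_rate, params.locking, phase_fns)
    spikes = []
    isi_s = params.intra_burst_isi_ms / 1000.0
    for t0 in onsets:
        spikes.append(t0)
        if p_b > 0 and rng.uniform() < p_b:
            # geometric number of extra spikes, mean (burst_len_mean - 1)
            p_geo = 1.0 / (mean_burst_len - 1.0)
            n_extra = rng.geometric(min(1.0, p_geo))
            t = t0
            for _ in range(n_extra):
                t += rng.gamma(25.0, isi_s / 25.0)  # CV 0.2 around the mean ISI
                if t < duration:
                    spikes.append(t)
    return np.sort(np.asarray(spikes))


def _waveform_template(
    rng: np.random.Generator, amplitude_uv: float, width_ms: float, jitter_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Negative-Gaussian spike template; half-amplitude width is the Gaussian
    FWHM, so amplitude/width ground truth is closed form."""
    amp = amplitude_uv * (1.0 + jitter_frac * rng.standard_normal())
    width = width_ms * (1.0 + jitter_frac * rng.standard_normal())
    amp = max(amp, 0.1 * amplitude_uv)
    width = max(width, 0.1 * width_ms)
    n = int(round(WAVEFORM_WINDOW_MS * WAVEFORM_FS_HZ / 1000.0)) + 1
    t_ms = np.arange(n) * 1000.0 / WAVEFORM_FS_HZ
    center = WAVEFORM_WINDOW_MS / 2.0
    sigma = width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    wf = -amp * np.exp(-0.5 * ((t_ms - center) / sigma) ** 2)
    return wf, t_ms


def generate_spike_trains(config: SynthConfig, lfp: LaminarLFP) -> list[SpikeUnit]:
    """Generate phase-locked spike trains for the configured unit classes.

    Interneurons are tonic inhomogeneous Poisson processes; pyramidal cells
    are burst-renewal processes. Both use the von Mises intensity modulation
    against the ground-truth oscillator phases carried by ``lfp``. Each unit
    gets its class waveform template (with small jitter) and a max-amplitude
    channel inside the annotated pyramidal layer (below it for the optional
    dentate-excluded fixture units).
    """
    for cls in (config.pyramidal, config.interneuron):
        for lock in cls.locking:
            if tuple(lock.band) not in lfp.band_phases:
                raise ValueError(
                    f"locking band {lock.band} has no oscillator in the LFP"
                )
    phase_fns = {
        band: _phase_interpolator(ph, lfp.fs) for band, ph in lfp.band_phases.items()
    }
    pyr_channels = [i for i, l in enumerate(lfp.layers) if l == LAYER_CA1_PYR]
    below_channels = [i for i, l in enumerate(lfp.layers) if l == LAYER_BELOW_PYR]
    if not pyr_channels:
        pyr_channels = [0]
    if not below_channels:
        below_channels = [lfp.n_channels - 1]

    units: list[SpikeUnit] = []
    plan = (
        [("pyr", config.pyramidal, LAYER_CA1_PYR)] * config.n_pyramidal
        + [("int", config.interneuron, LAYER_CA1_PYR)] * config.n_interneuron
        + [("dg", config.pyramidal, LAYER_BELOW_PYR)] * config.n_dentate
    )
    for idx, (tag, params, layer) in enumerate(plan):
        rng = np.random.default_rng([config.seed, 30, idx])
        shape = 1.0 / params.rate_cv**2 if params.rate_cv > 0 else None
        rate = (
            rng.gamma(shape, params.rate_mean_hz / shape)
            if shape is not None
            else params.rate_mean_hz
        )
        rate = max(rate, 0.05)
        if params.burst_prob > 0:
            times = _burst_train(rng, config.duration, rate, params, phase_fns)
        else:
            times = _thinned_times(
                rng, config.duration, rate, params.locking, phase_fns
            )
        wf, t_ms = _waveform_template(
            rng, params.waveform_amplitude_uv, params.waveform_width_ms,
            params.jitter_frac,
        )
        pool = pyr_channels if layer == LAYER_CA1_PYR else below_channels
        max_channel = int(pool[rng.integers(len(pool))])
        units.append(
            SpikeUnit(
                unit_id=f"{config.group}_s{config.seed}_{tag}_{idx:03d}",
                spike_times=times,
                waveform=wf,
                waveform_t_ms=t_ms,
                max_channel=max_channel,
                layer=layer,
                animal_id=f"{config.group}_animal_{config.seed}",
                group=config.group,
                meta={
                    "true_class": "pyramidal" if tag in ("pyr", "dg") else "interneuron",
                    "true_rate_hz": float(rate),
                    "true_amplitude_uv": float(np.max(np.abs(wf))),
                },
            )
        )
    return units


# ---------------------------------------------------------------------------
# Event injection
# ---------------------------------------------------------------------------


def _smooth_envelope(t: np.ndarray, onset: float, duration: float, ramp: float) -> np.ndarray:
    """0 -> 1 -> 0 envelope with raised-cosine ramps inside [onset, onset+dur]."""
    env = np.zeros_like(t)
    end = onset + duration
    ramp = min(ramp, duration / 2.0)
    inside = (t >= onset) & (t <= end)
    env[inside] = 1.0
    if ramp > 0:
        up = (t >= onset) & (t < onset + ramp)
        env[up] = 0.5 * (1.0 - np.cos(np.pi * (t[up] - onset) / ramp))
        down = (t > end - ramp) & (t <= end)
        env[down] = 0.5 * (1.0 - np.cos(np.pi * (end - t[down]) / ramp))
    return env


def inject_events(lfp: LaminarLFP, event_specs) -> LaminarLFP:
    """Add hyperexcitability events to a copy of the LFP.

    Depolarizing shifts are smooth negative DC deflections; rhythmic-spike
    events are synchronized trains of sharp negative transients at the
    event frequency. The ground-truth log is appended to ``events``.
    """
    out = lfp.copy()
    if not event_specs:
        return out
    t = out.times()
    for ev in event_specs:
        if ev.onset_s < 0 or ev.onset_s + ev.duration_s > out.duration + 1e-9:
            raise ValueError("event lies outside the recording")
        chans = (
            list(range(out.n_channels)) if ev.channels is None else list(ev.channels)
        )
        env = _smooth_envelope(t, ev.onset_s, ev.duration_s, ev.ramp_s)
        if isinstance(ev, DepolShiftEvent):
            wave = -ev.amplitude_uv * env
            kind = "depol_shift"
        elif isinstance(ev, RhythmicSpikesEvent):
            # one sharp transient per cycle: narrow negative Gaussian pulses
            period = 1.0 / ev.freq_hz
            phase = np.mod(t - ev.onset_s, period)
            d = np.minimum(phase, period - phase)
            pulse = np.exp(-0.5 * (d / 0.02) ** 2)  # 20 ms wide spikes
            wave = -ev.amplitude_uv * env * pulse
            kind = "rhythmic_spikes"
        else:
            raise TypeError(f"unknown event spec {type(ev).__name__}")
        for ch in chans:
            out.data[ch] += wave
        out.events.append(
            {
                "kind": kind,
                "onset_s": float(ev.onset_s),
                "duration_s": float(ev.duration_s),
                "amplitude_uv": float(ev.amplitude_uv),
                "channel_fraction": len(chans) / out.n_channels,
                **(
                    {"freq_hz": float(ev.freq_hz)}
                    if isinstance(ev, RhythmicSpikesEvent)
                    else {}
                ),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Study-condition presets
# ---------------------------------------------------------------------------

# Oscillator layout shared by both groups: theta, slow-gamma band noise,
# mid-gamma and high-frequency components, all centred on the CA1
# pyramidal layer (upper probe third).
_THETA = (4.0, 6.0)
_GAMMA = (62.0, 82.0)
_GAMMA_WIDE = (35.0, 75.0)
_HFO = (103.0, 117.0)


def _oscillators(gamma_amp: float, hfo_amp: float, theta_amp: float = 40.0):
    return (
        OscillatorSpec(band=_THETA, amplitude_uv=theta_amp, kind="sine",
                       depth_center=5.0, depth_sigma=8.0),
        OscillatorSpec(band=_GAMMA_WIDE, amplitude_uv=gamma_amp, kind="noise",
                       depth_center=5.0, depth_sigma=6.0),
        OscillatorSpec(band=_GAMMA, amplitude_uv=gamma_amp * 0.6, kind="sine",
                       depth_center=5.0, depth_sigma=6.0),
        OscillatorSpec(band=_HFO, amplitude_uv=hfo_amp, kind="sine",
                       depth_center=5.0, depth_sigma=5.0),
    )


def control_config(seed: int = 0, duration: float = 120.0) -> SynthConfig:
    """Control-animal preset: class means set to the measured control-group
    values (pyramidal 2.27 Hz / 0.336 ms / 256 uV; interneuron 7.46 Hz /
    0.373 ms / 367 uV), pyramidal locking to mid-gamma (expected MVL 0.020)
    and high-frequency (0.018) bands, interneuron theta locking (0.013)."""
    return SynthConfig(
        duration=duration,
        group="control",
        seed=seed,
        pyramidal=ClassParams(
            rate_mean_hz=2.27,
            rate_cv=0.5,
            burst_prob=0.35,
            intra_burst_isi_ms=5.0,
            burst_len_mean=3.0,
            locking=(
                LockingSpec(band=_GAMMA, kappa=0.040),
                LockingSpec(band=_HFO, kappa=0.036),
            ),
            waveform_amplitude_uv=256.0,
            waveform_width_ms=0.336,
        ),
        interneuron=ClassParams(
            rate_mean_hz=7.46,
            rate_cv=0.3,
            locking=(LockingSpec(band=_THETA, kappa=0.026),),
            waveform_amplitude_uv=367.0,
            waveform_width_ms=0.373,
        ),
        oscillators=_oscillators(gamma_amp=30.0, hfo_amp=15.0),
        noise_exponent=1.0,
        noise_amplitude_uv=50.0,
    )


def post_mtbi_config(
    seed: int = 0, duration: float = 120.0, velocity: str = "~260"
) -> SynthConfig:
    """Post-concussion preset: interneuron rate/width/amplitude reduced to
    the measured post-injury values, pyramidal gamma entrainment collapsed
    (expected MVL 0.005 / 0.003), interneuron theta entrainment raised
    (0.041), gamma oscillator power reduced 40% and the high-frequency
    component attenuated."""
    int_rate = {"~190": 3.78, "~260": 2.33}.get(velocity, 3.09)
    return SynthConfig(
        duration=duration,
        group="post_mtbi",
        seed=seed,
        pyramidal=ClassParams(
            rate_mean_hz=1.70,
            rate_cv=0.5,
            burst_prob=0.35,
            intra_burst_isi_ms=5.0,
            burst_len_mean=3.0,
            locking=(
                LockingSpec(band=_GAMMA, kappa=0.010),
                LockingSpec(band=_HFO, kappa=0.006),
            ),
            waveform_amplitude_uv=238.0,
            waveform_width_ms=0.280,
        ),
        interneuron=ClassParams(
            rate_mean_hz=int_rate,
            rate_cv=0.3,
            locking=(LockingSpec(band=_THETA, kappa=0.082),),
            waveform_amplitude_uv=170.0,
            waveform_width_ms=0.263,
        ),
        oscillators=_oscillators(gamma_amp=18.0, hfo_amp=7.0),
        noise_exponent=1.0,
        noise_amplitude_uv=50.0,
    )
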