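"""Single-compartment fast-spiking PV+ basket-cell model.

A Hodgkin-Huxley-type point model (leak + transient sodium m^3*h + delayed
rectifier potassium n^4) with Boltzmann-parameterized, shiftable sodium
steady states, used to ask which channel-level change reproduces the jointly
reduced firing rate, spike width and spike amplitude measured in CA1
interneurons after concussion.

    C dV/dt = I_stim - g_L (V - E_L) - g_Na m_inf(V)^3 h (V - E_Na)
              - g_K n^4 (V - E_K)

Sodium activation is instantaneous (m = m_inf, standard for fast-spiking
models); inactivation h and the rectifier gate n relax to their Boltzmann
steady states with voltage-dependent time constants. The inactivation
midpoint is expressed through the ``th_inf`` parameter of the reference
basket-cell parameterization: V_half(h) = th_inf + 14.5 mV, so the baseline
th_inf = -49.5 puts the midpoint at -35 mV and the best-fit th_inf = -59
moves it to -44.5 mV. ``sh`` is a common depolarizing shift of both
activation and inactivation midpoints.

The window current is the overlap of the activation and inactivation curves,
quantified as the integral of min(m_inf, h_inf) over voltage.

Spike features (rate, half-amplitude width, baseline-to-peak amplitude) are
computed with the same operators applied to experimental waveforms
(:mod:`ca1lamina.metrics`), so model/experiment factor ratios share
semantics. The model is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .metrics import spike_amplitude, spike_width

TH_INF_TO_MIDPOINT_MV = 14.5  # V_half(h) = th_inf + this offset

__all__ = [
    "PVModelParams",
    "SimTrace",
    "FactorTriple",
    "steady_states",
    "window_current_area",
    "relative_change",
    "simulate",
    "factor_triple",
    "experimental_factor_triple",
    "parameter_scan",
    "best_fit",
    "TABLE_SCAN_ROWS",
    "EXPERIMENTAL_TRIPLE",
]


@dataclass(frozen=True)
class PVModelParams:
    """Membrane and channel parameters (units: mV, ms, mS/cm^2, uA/cm^2)."""

    c_m: float = 1.0  # uF/cm^2
    g_leak: float = 0.1
    e_leak: float = -65.0
    g_na: float = 35.0
    e_na: float = 55.0
    vm_half: float = -28.0  # activation midpoint at sh = 0
    km: float = 7.0  # activation slope
    th_inf: float = -49.5  # inactivation midpoint parameter (V_half = th_inf + 14.5)
    kh: float = 6.5  # inactivation slope
    sh: float = 0.0  # common depolarizing shift of both midpoints
    g_kdr: float = 9.0  # delayed-rectifier max conductance ("KD fast")
    e_k: float = -90.0
    vn_half: float = -30.0
    kn: float = 10.0
    # gate time-constant parameters: tau(V) = min + amp / (1 + exp((V - vh)/k))
    h_tau_min: float = 0.5
    h_tau_amp: float = 6.0
    h_tau_vhalf: float = -50.0
    h_tau_k: float = 8.0
    n_tau_min: float = 0.2
    n_tau_amp: float = 2.0
    n_tau_vhalf: float = -40.0
    n_tau_k: float = 10.0
    # stimulation protocol
    i_stim: float = 1.6  # uA/cm^2 step amplitude: smallest value on a
    # 0.8-step grid giving repetitive (>= 5 Hz) baseline firing; frozen
    stim_duration_ms: float = 1000.0
    settle_ms: float = 200.0  # pre-stimulus settling
    dt_ms: float = 0.01

    def __post_init__(self) -> None:
        if min(self.g_leak, self.g_na, self.g_kdr) < 0:
            raise ValueError("conductances must be non-negative")
        if 0.0 in (self.km, self.kh, self.kn):
            raise ValueError("Boltzmann slopes must be non-zero")
        if self.e_na <= self.e_leak:
            raise ValueError("sodium reversal must exceed the resting range")


@dataclass
class SimTrace:
    """Simulated membrane trajectory with derived spike features."""

    t_ms: np.ndarray
    v_mv: np.ndarray
    spike_times_ms: np.ndarray
    firing_rate_hz: float
    spike_width_ms: float
    spike_amplitude_mv: float
    mean_waveform: np.ndarray = field(default_factory=lambda: np.empty(0))
    waveform_t_ms: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass(frozen=True)
class FactorTriple:
    """Perturbed/baseline ratios of (rate, width, amplitude)."""

    rate: float
    width: float
    amplitude: float

    def as_array(self) -> np.ndarray:
        return np.array([self.rate, self.width, self.amplitude])


#: perturbed/control ratios of the measured CA1 interneuron group means
#: (rate 3.09/7.46 Hz, width 0.263/0.373 ms, amplitude 170/367 uV)
EXPERIMENTAL_TRIPLE = FactorTriple(
    rate=3.09 / 7.46, width=0.263 / 0.373, amplitude=170.0 / 367.0
)


def experimental_factor_triple(
    post: tuple[float, float, float], control: tuple[float, float, float]
) -> FactorTriple:
    """Factor triple from printed (rate, width, amplitude) group means."""
    if any(c <= 0 for c in control):
        raise ValueError("control means must be positive")
    return FactorTriple(*(p / c for p, c in zip(post, control)))


# ---------------------------------------------------------------------------
# Steady states and window current
# ---------------------------------------------------------------------------


def steady_states(
    params: PVModelParams, v_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Boltzmann steady-state activation (rising) and inactivation (falling)
    curves of the sodium conductance on a voltage grid."""
    v = np.asarray(v_grid, dtype=np.float64)
    if v.min() > -100.0 or v.max() < 20.0:
        raise ValueError("voltage grid must cover at least -100..+20 mV")
    m_inf = 1.0 / (1.0 + np.exp(-(v - (params.vm_half + params.sh)) / params.km))
    vh = params.th_inf + TH_INF_TO_MIDPOINT_MV + params.sh
    h_inf = 1.0 / (1.0 + np.exp((v - vh) / params.kh))
    return m_inf, h_inf


def window_current_area(
    m_inf: np.ndarray, h_inf: np.ndarray, v_grid: np.ndarray
) -> float:
    """Window-current overlap: trapezoidal integral of min(m_inf, h_inf) dV."""
    m_inf, h_inf, v = map(np.asarray, (m_inf, h_inf, v_grid))
    if not (m_inf.shape == h_inf.shape == v.shape):
        raise ValueError("curves and grid must share one shape")
    return float(np.trapezoid(np.minimum(m_inf, h_inf), v))


def relative_change(baseline_area: float, perturbed_area: float) -> float:
    """Fractional decrease of the window area, 1 - perturbed/baseline."""
    if baseline_area <= 0:
        raise ValueError("baseline area must be positive")
    return 1.0 - perturbed_area / baseline_area


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


@njit(cache=False)
def _integrate(
    n_steps, dt, v0, c_m, g_leak, e_leak, g_na, e_na, vm, km, vh, kh,
    g_kdr, e_k, vn, kn, h_tau_min, h_tau_amp, h_tau_vh, h_tau_k,
    n_tau_min, n_tau_amp, n_tau_vh, n_tau_k, stim_on, stim_off, i_stim,
):  # pragma: no cover - exercised through simulate()
    v_out = np.empty(n_steps + 1)
    v = v0
    h = 1.0 / (1.0 + np.exp((v - vh) / kh))
    n = 1.0 / (1.0 + np.exp(-(v - vn) / kn))
    v_out[0] = v
    for step in range(n_steps):
        t = step * dt
        i_app = i_stim if (stim_on <= t < stim_off) else 0.0

        # RK4 on (v, h, n)
        vv, hh, nn = v, h, n
        k1v, k1h, k1n = _deriv(
            vv, hh, nn, i_app, c_m, g_leak, e_leak, g_na, e_na, vm, km, vh, kh,
            g_kdr, e_k, vn, kn, h_tau_min, h_tau_amp, h_tau_vh, h_tau_k,
            n_tau_min, n_tau_amp, n_tau_vh, n_tau_k,
        )
        vv, hh, nn = v + 0.5 * dt * k1v, h + 0.5 * dt * k1h, n + 0.5 * dt * k1n
        k2v, k2h, k2n = _deriv(
            vv, hh, nn, i_app, c_m, g_leak, e_leak, g_na, e_na, vm, km, vh, kh,
            g_kdr, e_k, vn, kn, h_tau_min, h_tau_amp, h_tau_vh, h_tau_k,
            n_tau_min, n_tau_amp, n_tau_vh, n_tau_k,
        )
        vv, hh, nn = v + 0.5 * dt * k2v, h + 0.5 * dt * k2h, n + 0.5 * dt * k2n
        k3v, k3h, k3n = _deriv(
            vv, hh, nn, i_app, c_m, g_leak, e_leak, g_na, e_na, vm, km, vh, kh,
            g_kdr, e_k, vn, kn, h_tau_min, h_tau_amp, h_tau_vh, h_tau_k,
            n_tau_min, n_tau_amp, n_tau_vh, n_tau_k,
        )
        vv, hh, nn = v + dt * k3v, h + dt * k3h, n + dt * k3n
        k4v, k4h, k4n = _deriv(
            vv, hh, nn, i_app, c_m, g_leak, e_leak, g_na, e_na, vm, km, vh, kh,
            g_kdr, e_k, vn, kn, h_tau_min, h_tau_amp, h_tau_vh, h_tau_k,
            n_tau_min, n_tau_amp, n_tau_vh, n_tau_k,
        )
        v = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        h = h + dt / 6.0 * (k1h + 2 * k2h + 2 * k3h + k4h)
        n = n + dt / 6.0 * (k1n + 2 * k2n + 2 * k3n + k4n)
        if h < 0.0:
            h = 0.0
        elif h > 1.0:
            h = 1.0
        if n < 0.0:
            n = 0.0
        elif n > 1.0:
            n = 1.0
        v_out[step + 1] = v
        if v > 200.0 or v < -200.0 or v != v:
            v_out[step + 1 :] = np.nan
            return v_out
    return v_out


@njit(cache=False, inline="always")
def _deriv(
    v, h, n, i_app, c_m, g_leak, e_leak, g_na, e_na, vm, km, vh, kh,
    g_kdr, e_k, vn, kn, h_tau_min, h_tau_amp, h_tau_vh, h_tau_k,
    n_tau_min, n_tau_amp, n_tau_vh, n_tau_k,
):  # pragma: no cover
    m_inf = 1.0 / (1.0 + np.exp(-(v - vm) / km))
    h_inf = 1.0 / (1.0 + np.exp((v - vh) / kh))
    n_inf = 1.0 / (1.0 + np.exp(-(v - vn) / kn))
    tau_h = h_tau_min + h_tau_amp / (1.0 + np.exp((v - h_tau_vh) / h_tau_k))
    tau_n = n_tau_min + n_tau_amp / (1.0 + np.exp((v - n_tau_vh) / n_tau_k))
    i_na = g_na * m_inf**3 * h * (v - e_na)
    i_k = g_kdr * n**4 * (v - e_k)
    i_l = g_leak * (v - e_leak)
    dv = (i_app - i_l - i_na - i_k) / c_m
    dh = (h_inf - h) / tau_h
    dn = (n_inf - n) / tau_n
    return dv, dh, dn


def _detect_spikes(
    v: np.ndarray, t_ms: np.ndarray, threshold_mv: float = 0.0,
    refractory_ms: float = 2.0,
) -> np.ndarray:
    """Upward threshold crossings with a refractory lockout."""
    above = v >= threshold_mv
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return np.empty(0)
    times = [t_ms[crossings[0]]]
    for idx in crossings[1:]:
        if t_ms[idx] - times[-1] >= refractory_ms:
            times.append(t_ms[idx])
    return np.asarray(times)


class IntegrationError(RuntimeError):
    pass


def simulate(params: PVModelParams) -> SimTrace:
    """Integrate the model under a constant current step and derive features.

    The cell settles for ``settle_ms`` before the step. Firing rate counts
    spikes in the second half of the step (excludes the onset transient);
    width and amplitude come from the mean spike waveform (window -2..+3 ms
    around each peak) via the shared waveform operators. A non-spiking trace
    returns NaN features.
    """
    dt = params.dt_ms
    total_ms = params.settle_ms + params.stim_duration_ms
    n_steps = int(round(total_ms / dt))
    vh = params.th_inf + TH_INF_TO_MIDPOINT_MV + params.sh
    v = _integrate(
        n_steps, dt, params.e_leak, params.c_m, params.g_leak, params.e_leak,
        params.g_na, params.e_na, params.vm_half + params.sh, params.km, vh,
        params.kh, params.g_kdr, params.e_k, params.vn_half, params.kn,
        params.h_tau_min, params.h_tau_amp, params.h_tau_vhalf, params.h_tau_k,
        params.n_tau_min, params.n_tau_amp, params.n_tau_vhalf, params.n_tau_k,
        params.settle_ms, total_ms, params.i_stim,
    )
    if np.any(np.isnan(v)):
        raise IntegrationError("membrane potential diverged (|V| > 200 mV)")
    t_ms = np.arange(n_steps + 1) * dt
    spikes = _detect_spikes(v, t_ms)
    spikes = spikes[spikes >= params.settle_ms]

    rate_window_start = params.settle_ms + params.stim_duration_ms / 2.0
    rate_window_s = (total_ms - rate_window_start) / 1000.0
    rate = float(np.sum(spikes >= rate_window_start) / rate_window_s)

    width = amp = np.nan
    mean_wf = np.empty(0)
    wf_t = np.empty(0)
    if spikes.size:
        pre, post = 2.0, 3.0
        n_pre, n_post = int(round(pre / dt)), int(round(post / dt))
        segs = []
        for ts in spikes:
            # align on the voltage peak near the crossing
            i0 = int(round(ts / dt))
            i1 = min(i0 + n_post, v.size - 1)
            ipk = i0 + int(np.argmax(v[i0 : i1 + 1]))
            if ipk - n_pre >= 0 and ipk + n_post < v.size:
                segs.append(v[ipk - n_pre : ipk + n_post + 1])
        if segs:
            mean_wf = np.mean(segs, axis=0)
            wf_t = np.arange(mean_wf.size) * dt
            amp = spike_amplitude(mean_wf)
            width = spike_width(mean_wf, wf_t)
    return SimTrace(
        t_ms=t_ms,
        v_mv=v,
        spike_times_ms=spikes,
        firing_rate_hz=rate,
        spike_width_ms=float(width),
        spike_amplitude_mv=float(amp),
        mean_waveform=mean_wf,
        waveform_t_ms=wf_t,
    )


def factor_triple(perturbed: SimTrace, baseline: SimTrace) -> FactorTriple:
    """Elementwise perturbed/baseline feature ratios."""
    base = (baseline.firing_rate_hz, baseline.spike_width_ms,
            baseline.spike_amplitude_mv)
    pert = (perturbed.firing_rate_hz, perturbed.spike_width_ms,
            perturbed.spike_amplitude_mv)
    if any(not np.isfinite(b) or b == 0 for b in base):
        raise ValueError("baseline trace has undefined or zero features")
    if any(not np.isfinite(p) for p in pert):
        raise ValueError("perturbed trace did not spike")
    return FactorTriple(*(p / b for p, b in zip(pert, base)))


# ---------------------------------------------------------------------------
# Parameter scan / best fit
# ---------------------------------------------------------------------------

#: scan grid mirroring the reference parameter-perturbation table. Rows that
#: perturbed only selected dendritic sections in the multi-compartment source
#: model are applied whole-cell here and flagged non-comparable.
TABLE_SCAN_ROWS: list[dict] = [
    {"name": "th_inf=-59", "deltas": {"th_inf": -59.0}},
    {"name": "th_inf=-60", "deltas": {"th_inf": -60.0}},
    {"name": "th_inf=-59.5, e_na=80", "deltas": {"th_inf": -59.5, "e_na": 80.0}},
    {
        "name": "th_inf=-57, e_na=80, sh=15.5, g_kdr=26",
        "deltas": {"th_inf": -57.0, "e_na": 80.0, "sh": 15.5, "g_kdr": 26.0},
    },
    {
        "name": "th_inf=-57, sh=15.5, g_kdr=26",
        "deltas": {"th_inf": -57.0, "sh": 15.5, "g_kdr": 26.0},
    },
    {
        "name": "th_inf=-58, e_na=70, g_kdr=26",
        "deltas": {"th_inf": -58.0, "e_na": 70.0, "g_kdr": 26.0},
    },
    {"name": "th_inf=-59.3, e_na=80", "deltas": {"th_inf": -59.3, "e_na": 80.0}},
    {
        "name": "dendritic th_inf=-59.3",
        "deltas": {"th_inf": -59.3},
        "non_comparable": True,
    },
    {
        "name": "dendritic th_inf=-59.3, e_na=65",
        "deltas": {"th_inf": -59.3, "e_na": 65.0},
        "non_comparable": True,
    },
    {
        "name": "dendritic e_na=65",
        "deltas": {"e_na": 65.0},
        "non_comparable": True,
    },
    {
        "name": "dendritic th_inf=-59.3, e_na=70",
        "deltas": {"th_inf": -59.3, "e_na": 70.0},
        "non_comparable": True,
    },
    {
        "name": "dendritic th_inf=-59.3, e_na=60",
        "deltas": {"th_inf": -59.3, "e_na": 60.0},
        "non_comparable": True,
    },
    {
        "name": "dendritic th_inf=-59.5, e_na=65",
        "deltas": {"th_inf": -59.5, "e_na": 65.0},
        "non_comparable": True,
    },
]


def parameter_scan(
    rows: list[dict], baseline: PVModelParams | None = None
) -> "pd.DataFrame":
    """Simulate every perturbation row and tabulate its factor triple.

    Each row is ``{"name": str, "deltas": {param: value}}``; parameters not
    named keep their baseline value. Non-spiking rows are reported as failed
    (NaN factors) and excluded from any subsequent fit.
    """
    import pandas as pd

    if not rows:
        raise ValueError("empty scan grid")
    base_params = baseline if baseline is not None else PVModelParams()
    base_trace = simulate(base_params)
    records = []
    for row in rows:
        p = replace(base_params, **row["deltas"])
        rec = {
            "name": row["name"],
            "non_comparable": bool(row.get("non_comparable", False)),
            **{f"param_{k}": v for k, v in row["deltas"].items()},
        }
        try:
            tr = simulate(p)
            ft = factor_triple(tr, base_trace)
            rec.update(
                rate_factor=ft.rate, width_factor=ft.width,
                amplitude_factor=ft.amplitude, failed=False,
            )
        except (ValueError, IntegrationError):
            rec.update(
                rate_factor=np.nan, width_factor=np.nan, amplitude_factor=np.nan,
                failed=True,
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def best_fit(
    scan: "pd.DataFrame",
    target: FactorTriple = EXPERIMENTAL_TRIPLE,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> dict:
    """Pick the scan row minimizing the weighted SSE to the target triple.

    Ties are broken by fewest perturbed parameters, then smallest total
    |delta| from baseline. Failed (non-spiking) rows are excluded.
    """
    ok = scan[~scan["failed"]].copy()
    if ok.empty:
        raise ValueError("no spiking rows in the scan")
    w = np.asarray(weights, dtype=float)
    tgt = target.as_array()
    f = ok[["rate_factor", "width_factor", "amplitude_factor"]].to_numpy()
    ok["loss"] = ((f - tgt) ** 2 * w).sum(axis=1)
    param_cols = [c for c in ok.columns if c.startswith("param_")]
    ok["n_perturbed"] = ok[param_cols].notna().sum(axis=1)
    ok["total_delta"] = ok[param_cols].abs().sum(axis=1)
    ok = ok.sort_values(["loss", "n_perturbed", "total_delta"], kind="stable")
    best = ok.iloc[0]
    return {
        "name": best["name"],
        "loss": float(best["loss"]),
        "factors": FactorTriple(
            float(best["rate_factor"]),
            float(best["width_factor"]),
            float(best["amplitude_factor"]),
        ),
        "non_comparable": bool(best["non_comparable"]),
        "table": ok,
    }
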