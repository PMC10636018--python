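"""On-disk formats for pipeline inputs and outputs.

LFP: raw little-endian float32, channel-major, with a JSON sidecar carrying
sampling rate, channel count, spacing and layer labels. Spike times and
waveforms: long-format CSV. Unit metrics and class labels: CSV, one row per
unit. Ground truth / reports: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import LaminarLFP, SpikeUnit, UnitMetrics

__all__ = [
    "write_lfp", "read_lfp",
    "write_spike_times", "read_spike_times",
    "write_waveforms", "read_waveforms",
    "write_unit_metrics", "read_unit_metrics",
    "write_labels", "read_labels",
]


def write_lfp(lfp: LaminarLFP, path: str | Path) -> None:
    """Write `<path>.f32` (raw float32 channel-major) and `<path>.json`."""
    path = Path(path)
    lfp.data.astype("<f4").tofile(path.with_suffix(".f32"))
    sidecar = {
        "sampling_rate_hz": lfp.fs,
        "n_channels": lfp.n_channels,
        "n_samples": lfp.n_samples,
        "spacing_um": lfp.spacing_um,
        "layers": lfp.layers,
        "dtype": "<f4",
        "order": "channel_major",
        "events": lfp.events,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_lfp(path: str | Path) -> LaminarLFP:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path.with_suffix(".f32"), dtype="<f4").astype(np.float64)
    data = data.reshape(sidecar["n_channels"], sidecar["n_samples"])
    return LaminarLFP(
        data=data,
        fs=sidecar["sampling_rate_hz"],
        spacing_um=sidecar["spacing_um"],
        layers=sidecar["layers"],
        events=sidecar.get("events", []),
    )


def write_spike_times(units: list[SpikeUnit], path: str | Path) -> None:
    rows = [
        {"unit_id": u.unit_id, "time_s": t}
        for u in units
        for t in u.spike_times
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(path, index=False)


def read_spike_times(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {
        uid: np.sort(g["time_s"].to_numpy())
        for uid, g in df.groupby("unit_id", sort=True)
    }


def write_waveforms(units: list[SpikeUnit], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"unit_id": u.unit_id, "sample_ms": u.waveform_t_ms, "uv": u.waveform}
        )
        for u in units
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_waveforms(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    df = pd.read_csv(path)
    return {
        uid: (g["sample_ms"].to_numpy(), g["uv"].to_numpy())
        for uid, g in df.groupby("unit_id", sort=True)
    }


_ACG_COLS = [f"acg_{lag:02d}ms" for lag in range(1, 51)]


def write_unit_metrics(metrics: list[UnitMetrics], path: str | Path) -> None:
    rows = []
    for m in metrics:
        row = {
            "unit_id": m.unit_id,
            "firing_rate_hz": m.firing_rate,
            "spike_amplitude_uv": m.spike_amplitude,
            "spike_width_ms": m.spike_width,
            "acg_first_moment_ms": m.acg_first_moment,
            "layer": m.layer,
            "max_channel": m.max_channel,
            "animal_id": m.animal_id,
            "group": m.group,
        }
        row.update(dict(zip(_ACG_COLS, m.acg)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_unit_metrics(path: str | Path) -> list[UnitMetrics]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            UnitMetrics(
                unit_id=str(r["unit_id"]),
                firing_rate=float(r["firing_rate_hz"]),
                spike_amplitude=float(r["spike_amplitude_uv"]),
                spike_width=float(r["spike_width_ms"]),
                acg=r[_ACG_COLS].to_numpy(dtype=float),
                acg_first_moment=float(r["acg_first_moment_ms"]),
                layer=str(r["layer"]),
                max_channel=int(r["max_channel"]),
                animal_id=str(r["animal_id"]),
                group=str(r["group"]),
            )
        )
    return out


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(labels.items()), columns=["unit_id", "label"]
    ).to_csv(path, index=False)


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["unit_id"].astype(str), df["label"].astype(str)))
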