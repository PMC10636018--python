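#!/usr/bin/env python
"""Per-unit metrics, cell classification, and group statistics.

Computes firing rate, spike amplitude/width and autocorrelogram metrics for
every unit in the cohort; classifies units with the manual rule set and the
k-means cross-check; and compares the two. Group comparisons (Mann-Whitney)
and the rotational-velocity dose ANOVA use the generator's ground-truth
classes, because the post-injury interneuron rate reduction deliberately
pushes those units below the 7 Hz rate boundary the manual rule assumes
(see docs/methods.md).
"""

import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from cohort import animal_configs, velocity_of

from ca1lamina import classify as C
from ca1lamina import io as IO
from ca1lamina import metrics as M
from ca1lamina import reporting as R
from ca1lamina import synth as S

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "tables"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    all_metrics, truth, velocity = [], {}, {}
    for cfg in animal_configs():
        lfp = S.generate_lfp(cfg)
        units = S.generate_spike_trains(cfg, lfp)
        for u in units:
            if u.n_spikes < 2:
                continue
            all_metrics.append(M.compute_unit_metrics(u, cfg.duration))
            truth[u.unit_id] = u.meta["true_class"]
            velocity[u.unit_id] = velocity_of(cfg)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    IO.write_unit_metrics(all_metrics, SCRATCH / "unit_metrics.csv")

    manual = C.classify_manual_table(all_metrics)
    km = C.classify_kmeans(all_metrics, seed=0)
    agreement = C.compare_classifications(manual, km.labels)
    IO.write_labels(manual, RESULTS / "labels_manual.csv")
    IO.write_labels(km.labels, RESULTS / "labels_kmeans.csv")

    # group statistics on ground-truth classes, cell as unit of analysis
    stats = {}
    for cls in ("pyramidal", "interneuron"):
        rows = [m for m in all_metrics if truth[m.unit_id] == cls]
        for attr, name in [
            ("firing_rate", "firing_rate_hz"),
            ("spike_width", "spike_width_ms"),
            ("spike_amplitude", "spike_amplitude_uv"),
        ]:
            vals = {
                g: np.array([getattr(m, attr) for m in rows if m.group == g])
                for g in ("control", "post_mtbi")
            }
            stats[f"{cls}_{name}"] = asdict(
                R.compare_groups(vals, metric=f"{cls} {name}")
            )
    int_rates = {}
    for m in all_metrics:
        if truth[m.unit_id] == "interneuron":
            int_rates.setdefault(velocity[m.unit_id], []).append(m.firing_rate)
    stats["interneuron_rate_velocity_anova"] = asdict(
        R.velocity_anova(
            {g: np.array(v) for g, v in int_rates.items()},
            metric="interneuron firing_rate_hz by rotational velocity",
        )
    )
    summary = {
        "n_units": len(all_metrics),
        "manual_vs_kmeans_percent_agreement": agreement.percent_agreement,
        "kmeans_silhouette": km.silhouette,
        "manual_label_counts": {
            lab: sum(1 for v in manual.values() if v == lab)
            for lab in set(manual.values())
        },
        "group_stats": stats,
    }
    (RESULTS / "unit_group_stats.json").write_text(
        json.dumps(summary, indent=1, default=float)
    )

    ir = stats["interneuron_firing_rate_hz"]["groups"]
    print(f"{len(all_metrics)} units; manual/k-means agreement "
          f"{agreement.percent_agreement:.1f}%")
    print("interneuron rate: control "
          f"{ir['control']['mean']:.2f} +/- {ir['control']['sem']:.2f} Hz vs "
          f"post-mTBI {ir['post_mtbi']['mean']:.2f} +/- "
          f"{ir['post_mtbi']['sem']:.2f} Hz "
          f"(p = {stats['interneuron_firing_rate_hz']['p_value']:.4f})")
    print("velocity ANOVA p = "
          f"{stats['interneuron_rate_velocity_anova']['p_value']:.4f}")


if __name__ == "__main__":
    main()
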