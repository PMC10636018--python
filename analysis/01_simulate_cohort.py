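#!/usr/bin/env python
"""Simulate the synthetic cohort and export the raw artifacts.

Writes a cohort manifest to results/cohort/, and the bulky per-animal
artifacts (spike-time and waveform CSVs, raw LFP binaries) to
scratch/cohort/.
Downstream scripts regenerate LFPs deterministically from the configs, so
the binaries are a convenience export, not a dependency.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from cohort import animal_configs, animal_id, velocity_of

from ca1lamina import io as IO
from ca1lamina import synth as S

RESULTS = Path(__file__).resolve().parents[1] / "results" / "cohort"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "cohort"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    manifest = []
    for cfg in animal_configs():
        lfp = S.generate_lfp(cfg)
        units = S.generate_spike_trains(cfg, lfp)
        aid = animal_id(cfg)
        IO.write_spike_times(units, SCRATCH / f"{aid}_spikes.csv")
        IO.write_waveforms(units, SCRATCH / f"{aid}_waveforms.csv")
        IO.write_lfp(lfp, SCRATCH / aid)
        manifest.append(
            {
                "animal_id": aid,
                "group": cfg.group,
                "velocity": velocity_of(cfg),
                "seed": cfg.seed,
                "duration_s": cfg.duration,
                "n_units": len(units),
                "n_spikes": int(sum(u.n_spikes for u in units)),
            }
        )
        print(f"{aid}: {len(units)} units, "
              f"{sum(u.n_spikes for u in units)} spikes")
    (RESULTS / "manifest.json").write_text(json.dumps(manifest, indent=1))
    n_ctrl = sum(1 for m in manifest if m["group"] == "control")
    print(f"\ncohort: {n_ctrl} control + {len(manifest) - n_ctrl} post-mTBI "
          f"animals -> {RESULTS}")


if __name__ == "__main__":
    main()
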