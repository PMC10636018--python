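"""Shared definition of the synthetic study cohort.

The cohort mirrors the study design: 8 control animals and 9 injured
animals (4 at ~190 rad/s, 5 at ~260 rad/s), each a laminar recording with
the class firing/waveform statistics and entrainment levels set to the
measured group means. Generation is deterministic per (master seed, animal
index), so every script can regenerate any animal instead of passing large
binaries around.
"""

from __future__ import annotations

from ca1lamina import synth as S

MASTER_SEED = 20260301
DURATION_S = 120.0

N_CONTROL = 8
VELOCITY_GROUPS = ["~190"] * 4 + ["~260"] * 5  # 9 injured animals


def animal_configs() -> list[S.SynthConfig]:
    configs = []
    for i in range(N_CONTROL):
        configs.append(S.control_config(seed=MASTER_SEED + i, duration=DURATION_S))
    for j, vel in enumerate(VELOCITY_GROUPS):
        configs.append(
            S.post_mtbi_config(
                seed=MASTER_SEED + 100 + j, duration=DURATION_S, velocity=vel
            )
        )
    return configs


def animal_id(cfg: S.SynthConfig) -> str:
    return f"{cfg.group}_animal_{cfg.seed}"


def velocity_of(cfg: S.SynthConfig) -> str:
    if cfg.group == "control":
        return "control"
    j = cfg.seed - MASTER_SEED - 100
    return VELOCITY_GROUPS[j]
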