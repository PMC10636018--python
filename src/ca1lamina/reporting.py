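"""Group statistics and the end-to-end run report.

Cell-level two-group comparisons use the two-sided Mann-Whitney test (exact
where sample sizes allow); the rotational-velocity dose analysis uses an
ordinary one-way ANOVA across the control / ~190 rad/s / ~260 rad/s
subgroups. Summaries are reported as mean +/- SEM.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.stats import f_oneway, mannwhitneyu

__all__ = ["GroupSummary", "compare_groups", "velocity_anova", "build_report"]


@dataclass
class GroupSummary:
    metric: str
    groups: dict[str, dict]  # per group: n, mean, sem
    test: str
    p_value: float
    statistic: float = np.nan
    flag: str = ""


def _summary(values: np.ndarray) -> dict:
    v = np.asarray(values, dtype=np.float64)
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan,
    }


def compare_groups(
    values: dict[str, np.ndarray], metric: str = ""
) -> GroupSummary:
    """Two-sided Mann-Whitney comparison of one metric between two groups."""
    if len(values) != 2:
        raise ValueError("compare_groups expects exactly two groups")
    (ga, va), (gb, vb) = values.items()
    va, vb = np.asarray(va, float), np.asarray(vb, float)
    if va.size < 2 or vb.size < 2:
        raise ValueError("each group needs at least 2 values")
    stat, p = mannwhitneyu(va, vb, alternative="two-sided")
    return GroupSummary(
        metric=metric,
        groups={ga: _summary(va), gb: _summary(vb)},
        test="mann_whitney_two_sided",
        p_value=float(p),
        statistic=float(stat),
    )


def velocity_anova(
    values: dict[str, np.ndarray], metric: str = ""
) -> GroupSummary:
    """One-way ANOVA across rotational-velocity subgroups
    (e.g. control / ~190 rad/s / ~260 rad/s)."""
    if len(values) < 3:
        raise ValueError("ANOVA across velocity subgroups needs >= 3 subgroups")
    arrays = {g: np.asarray(v, float) for g, v in values.items()}
    if any(v.size < 2 for v in arrays.values()):
        raise ValueError("each subgroup needs at least 2 values")
    flag = ""
    if all(np.ptp(v) == 0 for v in arrays.values()) and len(
        {v[0] for v in arrays.values()}
    ) == 1:
        # all observations identical: zero variance everywhere
        return GroupSummary(
            metric=metric, groups={g: _summary(v) for g, v in arrays.items()},
            test="one_way_anova", p_value=np.nan, statistic=np.nan,
            flag="degenerate: zero variance in every subgroup",
        )
    stat, p = f_oneway(*arrays.values())
    return GroupSummary(
        metric=metric,
        groups={g: _summary(v) for g, v in arrays.items()},
        test="one_way_anova",
        p_value=float(p),
        statistic=float(stat),
        flag=flag,
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

REPORT_SECTIONS = (
    "unit_census",
    "pyramidal_metrics",
    "interneuron_metrics",
    "entrainment",
    "psd",
    "model_scan",
    "events",
)


@dataclass
class RunReport:
    sections: dict = field(default_factory=dict)
    gaps: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return not self.gaps

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "sections": self.sections,
                "gaps": self.gaps,
                "provenance": self.provenance,
            },
            default=_jsonable,
            sort_keys=True,
            **kwargs,
        )

    def to_markdown(self) -> str:
        lines = ["# Laminar CA1 analysis report", ""]
        for name in REPORT_SECTIONS:
            lines.append(f"## {name}")
            if name in self.sections:
                lines.append("```json")
                lines.append(
                    json.dumps(self.sections[name], default=_jsonable, indent=1,
                               sort_keys=True)
                )
                lines.append("```")
            else:
                lines.append("*MISSING STAGE OUTPUT*")
            lines.append("")
        lines.append("## provenance")
        lines.append(json.dumps(self.provenance, default=_jsonable, sort_keys=True))
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def build_report(
    stage_outputs: dict, seeds: dict | None = None, config: dict | None = None
) -> RunReport:
    """Assemble the run report from pipeline stage outputs.

    ``stage_outputs`` maps section names (see ``REPORT_SECTIONS``) to
    JSON-serializable summaries. Missing sections are reported as explicit
    gaps rather than silently dropped; callers treating a complete report as
    mandatory should check ``report.complete``. Provenance embeds the seeds,
    a hash of the generating configuration, and the package version
    (timestamps are deliberately excluded so reruns are byte-identical).
    """
    from . import __version__

    report = RunReport()
    for name in REPORT_SECTIONS:
        if name in stage_outputs and stage_outputs[name] is not None:
            report.sections[name] = stage_outputs[name]
        else:
            report.gaps.append(name)
    cfg_json = json.dumps(config or {}, default=_jsonable, sort_keys=True)
    report.provenance = {
        "seeds": seeds or {},
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "version": __version__,
    }
    return report
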