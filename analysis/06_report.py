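#!/usr/bin/env python
"""Assemble the end-to-end run report from the stage outputs in results/.

Exits non-zero if any stage output is missing, listing the gaps.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort import MASTER_SEED

from ca1lamina import reporting as R

RESULTS = Path(__file__).resolve().parents[1] / "results"


def _load_json(name):
    path = RESULTS / name
    return json.loads(path.read_text()) if path.exists() else None


def _load_csv(name, **kw):
    path = RESULTS / name
    return pd.read_csv(path, **kw).to_dict("records") if path.exists() else None


def main() -> int:
    manifest = _load_json("cohort/manifest.json")
    group_stats = _load_json("unit_group_stats.json")
    stages = {
        "unit_census": manifest,
        "pyramidal_metrics": (
            {k: v for k, v in group_stats["group_stats"].items()
             if k.startswith("pyramidal")} if group_stats else None
        ),
        "interneuron_metrics": (
            {k: v for k, v in group_stats["group_stats"].items()
             if k.startswith("interneuron")} if group_stats else None
        ),
        "entrainment": _load_json("entrainment_ranges.json"),
        "psd": _load_json("psd_ranges.json"),
        "model_scan": _load_json("pv_fit.json"),
        "events": _load_csv("event_log.csv"),
    }
    report = R.build_report(stages, seeds={"master": MASTER_SEED})
    (RESULTS / "report.json").write_text(report.to_json(indent=1))
    (RESULTS / "report.md").write_text(report.to_markdown())
    if not report.complete:
        print(f"INCOMPLETE report; missing stages: {report.gaps}", file=sys.stderr)
        return 1
    print(f"report written to {RESULTS / 'report.md'} "
          f"({len(report.sections)} sections)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
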