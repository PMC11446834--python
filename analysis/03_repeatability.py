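#!/usr/bin/env python
"""Between-day repeatability of EFL and ventilatory parameters.

Reads results/stage_tables.csv (written by 02_analyze_sessions.py),
computes Cohen's kappa for the binary flow-limitation call, the ICC for
its continuous magnitude, and per-parameter ICC/CV at peak exercise and
at matched ventilation, and writes results/repeatability.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from eflkit.config import RunConfig
from eflkit.pipeline import repeatability_from_stage_tables
from eflkit.signal_io import StageRecord

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--stage-tables", type=Path,
                    default=ROOT / "results" / "stage_tables.csv")
    args = ap.parse_args()

    df = pd.read_csv(args.stage_tables)
    field_names = [f for f in StageRecord.__dataclass_fields__]
    tables = {}
    for (pid, visit), g in df.groupby(["participant_id", "visit"]):
        recs = []
        for _, row in g.iterrows():
            kw = {c: row[c] for c in field_names}
            kw["stage_label"] = str(kw["stage_label"])
            kw["EFL_present"] = bool(kw["EFL_present"])
            recs.append(StageRecord(**kw))
        tables[(str(pid), int(visit))] = recs

    report = repeatability_from_stage_tables(tables, RunConfig())
    out = ROOT / "results" / "repeatability.json"
    out.write_text(json.dumps(report, indent=2))

    for sec in ("peak", "matched_ve"):
        r = report[sec]
        print(f"{sec}: kappa={r['kappa']:.3f} ({r['kappa_class']}), "
              f"ICC={r['icc']:.3f} ({r['icc_class']}), "
              f"agreement table {r['agreement_table']}")
    print(f"EFL prevalence (any stage, either visit): "
          f"{report['efl_prevalence_any_stage_pct']:.0f}%")
    print("parameter repeatability at peak (CV%, ICC):")
    for name, p in report["parameters_peak"].items():
        print(f"  {name:12s} CV {p['cv_pct']:5.2f}%  ICC {p['icc']:.2f} "
              f"({p['icc_class']})")
    print(f"report -> {out}")


if __name__ == "__main__":
    main()
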