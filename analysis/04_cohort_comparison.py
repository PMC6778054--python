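#!/usr/bin/env python
"""Grooved-vs-flat cohort comparison through the full pipeline.

Simulates nine elongated, label-rich, periphery-enriched nuclei
("microgrooved substrate") and nine rounder, sparser nuclei ("flat
substrate"), runs every one through alignment, detection, segmentation
and shell statistics, and tests the four planned effects with
two-tailed Mann-Whitney comparisons: lower sphericity, higher nuclear
label count, shorter minimum separation and higher peripheral density
in the grooved group.

Output: results/cohort_metrics.csv, results/cohort_comparisons.json
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from fibgold.pipeline import run_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = run_cohort(seed=0)
    rows = []
    for group in ("grooved", "flat"):
        for i, metrics in enumerate(r[group]):
            rows.append({"group": group, "nucleus": i, **metrics})
    table = pd.DataFrame(rows)
    ROOT.mkdir(exist_ok=True)
    table.to_csv(ROOT / "cohort_metrics.csv", index=False)
    (ROOT / "cohort_comparisons.json").write_text(
        json.dumps(r["comparisons"], indent=2) + "\n"
    )
    print(table.groupby("group").mean(numeric_only=True).to_string(
        float_format=lambda v: f"{v:.2f}"))
    print("\nplanned comparisons (two-tailed Mann-Whitney):")
    for metric, c in r["comparisons"].items():
        direction = "lower" if c["sign_expected"] < 0 else "higher"
        ok = "as planted" if c["sign_observed"] == c["sign_expected"] else "SIGN FLIP"
        print(f"  {metric}: grooved {direction}, p = {c['p_value']:.4g} ({ok})")
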