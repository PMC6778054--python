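#!/usr/bin/env python
"""Score the pipeline's report against the generator's planted truth.

Compares every recovered quantity (volume, densities, invaginations per
section, association percentage, cytosolic share) with the value
planted by the generator, and writes a recovery table.

Output: results/recovery.csv
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    report = json.loads((ROOT / "pipeline" / "report.json").read_text())
    truth = pd.read_csv(ROOT / "phantom" / "particles.csv")

    from fibgold.io import read_stack

    spacing = (90.0, 10.0, 10.0)
    vox_um3 = float(np.prod(spacing)) / 1e9
    nuc = read_stack(ROOT / "phantom" / "nucleus_mask.tif", spacing_override=spacing).data > 0
    per = read_stack(ROOT / "phantom" / "peripheral_mask.tif", spacing_override=spacing).data > 0
    cen = read_stack(ROOT / "phantom" / "central_mask.tif", spacing_override=spacing).data > 0

    nuclear = truth[truth.compartment == "nuclear"]
    rows = [
        ("nuclear_volume_um3", nuc.sum() * vox_um3, report["nuclear_volume_um3"]),
        ("n_labels_nuclear", len(nuclear), report["n_labels_nuclear"]),
        ("pct_cytosolic", 100 * (truth.compartment == "cytosolic").mean(),
         report["pct_cytosolic"]),
        ("peripheral_density_per_um3",
         (truth.region == "peripheral").sum() / (per.sum() * vox_um3),
         report["peripheral_density_per_um3"]),
        ("central_density_per_um3",
         (truth.region == "central").sum() / (cen.sum() * vox_um3),
         report["central_density_per_um3"]),
        ("pct_particles_at_invaginations",
         100 * truth.invagination_id.notna().sum() / len(nuclear),
         report["pct_particles_at_invaginations"]),
    ]
    out = pd.DataFrame(rows, columns=["metric", "planted", "recovered"])
    out["rel_error_pct"] = 100 * (out.recovered - out.planted) / out.planted
    out.to_csv(ROOT / "recovery.csv", index=False)
    print(out.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
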