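"""Bootstrap accuracy and case-drop stability for each group network.

Scaled resampling (200 bootstrap iterations, 50 case-drop replicates per
level, frozen per-target penalties) keeps the driver interactive; the
library defaults are 1000 iterations with full CV refits.
"""

import json
from pathlib import Path

from clpnet import bootstrap_edge_ci, case_drop_cs, load_panel
from clpnet.trajectory import split_by_trajectory

SEED = 7
N_BOOT = 200
CS_REPS = 50

root = Path(__file__).resolve().parents[1]
results = root / "results"

panel = load_panel(root / "scratch" / "cohort.csv")
groups = split_by_trajectory(panel, cutoff=7)

cs_all = {}
for label, g in groups.items():
    boot = bootstrap_edge_ci(g, n_boot=N_BOOT, seed=SEED, covariates=False, fast=True)
    boot.ci_table().to_csv(results / f"bootstrap_ci_{label}.csv", index=False)
    widths = (boot.ci_upper - boot.ci_lower)
    cs_all[label] = {}
    for index in ("in_ei", "out_ei"):
        res = case_drop_cs(g, index=index, reps_per_level=CS_REPS, seed=SEED,
                           covariates=False, fast=True)
        cs_all[label][index] = res.cs_value
    print(f"{label:<11} mean CI width {widths.mean():.3f}  "
          f"CS(in-EI) = {cs_all[label]['in_ei']}  CS(out-EI) = {cs_all[label]['out_ei']}")

(results / "cs_coefficients.json").write_text(json.dumps(cs_all, indent=2))
print("CS at or near the 0.7 grid maximum indicates highly stable "
      "centrality rank order at these sample sizes")
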