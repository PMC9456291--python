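"""Synthetic cohorts: run-down statistics and current-density comparisons.

Generates noisy cohorts for the run-down conditions, applies the run-down
metric per cell, and compares groups with the Shapiro-Wilk-gated test
selection.  Also checks that WT and V185M homomer current densities do not
differ.  Writes results/cohort_rundown.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from kcnq1ca import synth as SY
from kcnq1ca.analysis import current_density, measure_amplitude, rundown_metric
from kcnq1ca.stats import GroupData, compare_groups
from kcnq1ca.synth import ConditionSpec, HIGH_CA_ICS

ROOT = Path(__file__).resolve().parent.parent
N_CELLS = 8
BASE_SEED = 2024

CONDITIONS = {
    "WT standard": ConditionSpec(),
    "WT + CaM": ConditionSpec(cam_overexpressed=True),
    "WT high Ca2+": ConditionSpec(ics_free_ca=HIGH_CA_ICS),
    "V185M standard": ConditionSpec(variant="V185M"),
}


def main():
    rows = []
    groups = {}
    for label, cond in CONDITIONS.items():
        recs = SY.generate_cohort([cond], N_CELLS, "rundown", base_seed=BASE_SEED)
        rel = [100.0 * rundown_metric(r).relative_amplitude_at_window for r in recs]
        groups[label] = np.array(rel)
        rows += [{"condition": label, "cell": i, "relative_4min_pct": round(v, 2)}
                 for i, v in enumerate(rel)]
        print(f"{label}: relative 4-min amplitude {np.mean(rel):.1f} +/- "
              f"{np.std(rel) / np.sqrt(len(rel)):.1f} % (n={len(rel)})")

    res = compare_groups(GroupData({k: groups[k] for k in
                                    ("WT standard", "WT + CaM")}))
    print(f"WT vs WT+CaM run-down: {res.test_name}, p = {res.p_value:.2e} "
          f"{res.stars}")

    dens = {}
    for label, cond in [("WT", ConditionSpec()),
                        ("V185M", ConditionSpec(variant="V185M"))]:
        recs = SY.generate_cohort([cond], N_CELLS, "rundown", base_seed=BASE_SEED + 1)
        dens[label] = np.array([
            current_density(measure_amplitude(r, 1, 450.0, 50.0)[0], r.capacitance_pF)
            for r in recs
        ])
        print(f"{label} homomer density: median {np.median(dens[label]):.0f} pA/pF")
    res = compare_groups(GroupData(dens))
    print(f"WT vs V185M homomer density: {res.test_name}, p = {res.p_value:.3f} "
          f"({'not ' if res.p_value >= 0.05 else ''}significant)")

    (ROOT / "results").mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(ROOT / "results" / "cohort_rundown.csv", index=False)


if __name__ == "__main__":
    main()
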