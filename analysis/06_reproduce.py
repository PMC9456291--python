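"""Reproduce all quantitative anchors and print the pass/fail table.

Thin driver over kcnq1ca.reproduce; writes results/reproduce_report.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from kcnq1ca.reproduce import reproduce

ROOT = Path(__file__).resolve().parent.parent


def main():
    rows = reproduce()
    df = pd.DataFrame(rows)
    print(df[["id", "description", "value", "reference", "abs_error", "pass"]]
          .to_string(index=False))
    n_pass = int(df["pass"].sum())
    print(f"{n_pass}/{len(df)} anchors reproduced within tolerance")
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "reproduce_report.csv", index=False)


if __name__ == "__main__":
    main()
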