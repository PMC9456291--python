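"""Cross-over of the P2 current traces at low intracellular Ca2+.

Simulates the WT model after 5 min of simulated Ca2+ wash-out and maps the
late-P2 amplitude against the P1 potential for the standard protocol and
its controls (saturated Ca2+, short P1, P2 at -40 mV); fits the double
Boltzmann for the HVA component.  Writes results/crossover.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from kcnq1ca import pipelines as P
from kcnq1ca.analysis import extract_gv, fit_boltzmann
from kcnq1ca.gating import build_default_scheme
from kcnq1ca.reproduce import washed_out_ca
from kcnq1ca.synth import HIGH_CA_ICS

ROOT = Path(__file__).resolve().parent.parent


def main():
    wt = build_default_scheme("WT")
    ca_low = washed_out_ca()
    rows = []
    for label, ca, preset in [
        ("low Ca2+, P2 0 mV", ca_low, "iv2s"),
        ("saturated Ca2+", HIGH_CA_ICS, "iv2s"),
        ("low Ca2+, 200 ms P1", ca_low, "iv200ms"),
        ("low Ca2+, P2 -40 mV", ca_low, "iv2s-p2m40"),
    ]:
        prof = P.model_crossover(wt, ca=ca, protocol=preset)
        rows.append({"condition": label, "minimum_mV": prof.minimum_mV})
        where = "none" if prof.minimum_mV is None else f"{prof.minimum_mV:+.0f} mV"
        print(f"{label}: late-P2 minimum at {where}")

    rec = P.model_recording(wt, "iv2s", ca=ca_low)
    fit = fit_boltzmann(extract_gv(rec), 2)
    print(f"low-Ca2+ GV double Boltzmann: LVA V0.5 {fit.components[0].v_half:+.1f} mV "
          f"(k {fit.components[0].k:.1f}); HVA V0.5 {fit.hva.v_half:+.1f} mV "
          f"(k {fit.hva.k:.1f}, amplitude {fit.hva.d:.2f})")
    print("The minimum reflects accumulation in the Ca2+-starved IC* state "
          "during the P1 pulse; it needs long P1 pulses and a P2 potential "
          "that activates the channel to become visible.")

    (ROOT / "results").mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(ROOT / "results" / "crossover.csv", index=False)


if __name__ == "__main__":
    main()
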