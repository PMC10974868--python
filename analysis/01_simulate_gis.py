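#!/usr/bin/env python
"""Simulate the in-vitro transfer-dissolution runs for the three products.

Writes tidy chamber profiles to results/invitro_profiles.csv and prints the
amount of valsartan in solution in each chamber at the end of the 240-min
run.  The rank order (Supra >> Low ~ CoDiovan) mirrors the disintegration
differences between the products: only the Supra product saturates the
gastric medium, the other two dissolve almost exclusively downstream at
pH 6.8.
"""
from pathlib import Path

import pandas as pd

from gispbbm import io, simulate_gis

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    frames = []
    print("Final dissolved amounts after 240 min in the GIS (mg):")
    for scenario in io.packaged_scenarios("in_vitro"):
        sim = simulate_gis(scenario.gis, scenario.formulation)
        tidy = sim.tidy()
        tidy.insert(0, "formulation", scenario.name)
        frames.append(tidy)
        final = (tidy[tidy.time_min == tidy.time_min.max()]
                 .set_index("chamber")["amount_dissolved_mg"])
        print(f"  {scenario.name:20s} stomach {final['stomach']:8.2f}   "
              f"duodenum {final['duodenum']:7.2f}   "
              f"jejunum (cumulative) {final['jejunum']:7.2f}   "
              f"[mass-balance dev {sim.mass_balance_error():.1e}]")
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "invitro_profiles.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
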