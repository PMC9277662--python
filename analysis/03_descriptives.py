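"""First-cycle descriptive statistics by site and layer.

Reads the observation tables written by 02_run_pipeline.py and prints/writes
mean, sd and CoV of apparent strain, stiffness and normalized hysteresis per
site x layer cell, plus the collinearity screen (|rho| > 0.60) of the
numeric covariates.
"""
import argparse
from pathlib import Path

import pandas as pd

from sbmech import stats as st


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    out_rows = []
    for name in ("layer_table", "total_table"):
        table = pd.read_csv(args.results / f"{name}.csv")
        first = table[table.cycle == 1]
        for outcome in ("peak_strain_pct", "stiffness_MPa", "hysteresis_fraction"):
            d = st.descriptives(first, outcome)
            d.insert(0, "outcome", outcome)
            out_rows.append(d)
            print(f"\n== {name}: first-cycle {outcome} ==")
            print(d.to_string(index=False))
    pd.concat(out_rows).to_csv(args.results / "descriptives.csv", index=False)

    total = pd.read_csv(args.results / "total_table.csv")
    spec = total[total.cycle == 1].drop_duplicates("specimen_id")
    numeric = [c for c in ("bvtv", "bmd", "age", "cartilage_thickness_mm",
                           "angle_a", "angle_b", "evenness_a", "evenness_b")
               if c in spec.columns]
    flagged = st.collinearity_screen(spec, numeric)
    print("\n== collinear covariate pairs (|rho| > 0.60) ==")
    for a, b, rho in flagged:
        if a != b:
            print(f"  {a} ~ {b}: rho = {rho:+.3f}")


if __name__ == "__main__":
    main()
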