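"""Mixed-model analysis of stiffness and hysteresis.

Fits Gaussian linear mixed models with horse-level random intercepts on the
observation tables: layer/site/cycle effects on layer stiffness and
hysteresis, site/cycle effects on whole-specimen stiffness, and a backward
selection over morphometric covariates for first-cycle layer stiffness.
Coefficient tables are written as JSON under results/.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from sbmech import stats as st


def fit_and_report(name, spec, table, store):
    fit = st.fit_mixed(spec, table)
    print(f"\n== {name} ({spec.formula()}), n = {fit.n_obs} ==")
    rep = pd.DataFrame(dict(coef=fit.params, lower=fit.conf_int["lower"],
                            upper=fit.conf_int["upper"], p=fit.pvalues))
    print(rep.round(4).to_string())
    store[name] = dict(
        formula=spec.formula(), n=fit.n_obs,
        coefficients={k: float(v) for k, v in fit.params.items()},
        pvalues={k: float(v) for k, v in fit.pvalues.items()},
        group_variance=fit.group_variance, residual_variance=fit.residual_variance,
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    layer = pd.read_csv(args.results / "layer_table.csv")
    total = pd.read_csv(args.results / "total_table.csv")
    store = {}
    fit_and_report("layer_stiffness",
                   st.ModelSpec("stiffness_MPa", ["layer", "site", "C(cycle)"]),
                   layer, store)
    fit_and_report("layer_hysteresis",
                   st.ModelSpec("hysteresis_fraction", ["layer", "site", "C(cycle)"]),
                   layer, store)
    fit_and_report("total_stiffness",
                   st.ModelSpec("stiffness_MPa", ["site", "C(cycle)"]),
                   total, store)

    first = layer[layer.cycle == 1].dropna(subset=["bvtv", "bmd"])
    if len(first) and first.horse_id.nunique() >= 2:
        sel = st.select_model(
            "stiffness_MPa", ["bvtv", "bmd", "dbvf", "age", "cartilage_thickness_mm"],
            first, forced=("layer",))
        print("\n== covariate selection for first-cycle layer stiffness ==")
        print(f"univariable p: { {k: round(v, 3) for k, v in sel.univariable_p.items()} }")
        print(f"entered (p < 0.20): {sel.entered}")
        print(f"retained (p < 0.05): {sel.retained}")
        store["selection"] = dict(entered=sel.entered, retained=sel.retained,
                                  univariable_p=sel.univariable_p)

    (args.results / "mixed_models.json").write_text(json.dumps(store, indent=2))


if __name__ == "__main__":
    main()
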