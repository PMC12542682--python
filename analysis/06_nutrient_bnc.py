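#!/usr/bin/env python
"""Link biodiversity to multi-nutrient cycling (wet season).

Computes the multi-nutrient cycling index from the eight nutrient
variables, regresses it on generalist and specialist β-diversity (LCBD),
ranks OTU predictors with the repeated random forest, and fits the
PLS path model space → environment → assembly → class β-diversity → MNC.
Writes results/bnc_*.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ecospart import diversity as dv
from ecospart import io as eio
from ecospart import nutrients as nt

MASTER_SEED = 20_260_928
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"


def main() -> None:
    table = eio.read_otu_table(DATA / "otu_table.tsv")
    meta = eio.read_metadata(DATA / "metadata.tsv", DATA / "dendritic_km.tsv")
    labels = pd.read_csv(ROOT / "results" / "classification.tsv", sep="\t",
                         index_col=0)["label"]
    season = meta.table.loc[table.sample_ids, "season"]
    wet = [x for x in table.sample_ids if season[x] == "wet"]
    t_wet = table.select_samples(wet).drop_empty_otus()

    mnc = nt.mnc_index(meta.nutrients.loc[wet])
    mnc.standardized.assign(MNC=mnc.index).to_csv(
        ROOT / "results" / "bnc_mnc.tsv", sep="\t")

    beta = {}
    regressions = []
    for cls in ("generalist", "specialist"):
        members = [o for o in t_wet.otu_ids if labels.get(o) == cls]
        sub = t_wet.select_otus(members).drop_empty_otus()
        beta[cls] = nt.beta_scalar(dv.bray_curtis(sub, relative=True))
        regressions.append({"predictor": f"{cls}_beta",
                            **nt.ols_bnc(mnc.index, beta[cls])})
    reg = pd.DataFrame(regressions)
    reg.to_csv(ROOT / "results" / "bnc_regressions.tsv", sep="\t",
               index=False)
    print("OLS of MNC on class β-diversity (wet season):")
    print(reg.round(4).to_string(index=False))

    rf = nt.rf_rank(t_wet, mnc.index, n_iter=100, top_k=30,
                    seed=eio.stage_seed(MASTER_SEED, "rf"))
    imp = rf.importances.sort_values("gini", ascending=False)
    imp["label"] = [labels.get(o, "unknown") for o in imp.index]
    imp.to_csv(ROOT / "results" / "bnc_rf_importance.tsv", sep="\t")
    rf.cv_curve.to_csv(ROOT / "results" / "bnc_rf_cv_curve.tsv", sep="\t",
                       index=False)
    top = imp.head(30)
    print(f"\ntop-30 RF predictors of MNC by class: "
          f"{top.label.value_counts().to_dict()}")

    # PLS path model; the assembly block is the per-sample mean |βNTI|
    bnti_block = pd.read_csv(
        ROOT / "results" / "assembly_mean_abs_bnti.tsv", sep="\t",
        index_col=0).reindex(wet).mean(axis=1)
    position = meta.dendritic_km.loc[wet, wet].iloc[:, 0]
    env = meta.env.loc[wet]
    env_cols = [c for c in env.columns if c.startswith("env")]
    data = pd.DataFrame({
        "position_km": position, "environment": env[env_cols].mean(axis=1),
        "assembly": bnti_block,
        "gen_beta": beta["generalist"].reindex(wet),
        "spec_beta": beta["specialist"].reindex(wet),
        "mnc": mnc.index,
    })
    blocks = {"space": ["position_km"], "environment": ["environment"],
              "assembly": ["assembly"], "generalist_beta": ["gen_beta"],
              "specialist_beta": ["spec_beta"], "mnc": ["mnc"]}
    names = list(blocks)
    pm = pd.DataFrame(False, index=names, columns=names)
    pm.loc["environment", "space"] = True
    pm.loc["assembly", ["space", "environment"]] = True
    pm.loc["generalist_beta", ["space", "environment", "assembly"]] = True
    pm.loc["specialist_beta", ["space", "environment", "assembly"]] = True
    pm.loc["mnc", ["environment", "assembly", "generalist_beta",
                   "specialist_beta"]] = True
    res = nt.plspm(data, blocks, pm, n_boot=500,
                   seed=eio.stage_seed(MASTER_SEED, "plspm"))
    res.paths.to_csv(ROOT / "results" / "bnc_plspm_paths.tsv", sep="\t")
    res.total_effects.to_csv(ROOT / "results" / "bnc_plspm_effects.tsv",
                             sep="\t")
    if res.boot_ci is not None:
        res.boot_ci.to_csv(ROOT / "results" / "bnc_plspm_bootstrap.tsv",
                           sep="\t")
    print(f"\nPLS-PM GOF = {res.gof:.3f}")
    print("direct effects on MNC:",
          res.paths.loc["mnc"][res.paths.loc["mnc"] != 0].round(3).to_dict())
    print("standardized total effects on MNC:",
          res.total_effects.loc["mnc"][["generalist_beta", "specialist_beta"]]
          .round(3).to_dict())


if __name__ == "__main__":
    main()
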