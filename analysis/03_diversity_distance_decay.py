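#!/usr/bin/env python
"""Alpha/beta diversity of generalists vs specialists and distance decay.

Per habitat class: per-sample richness/Chao1/ACE with a Wilcoxon
comparison, PERMANOVA of wet vs dry composition, and distance-decay of
Bray-Curtis similarity against dendritic and environmental distance per
season.  Writes results/diversity_alpha.tsv and results/diversity_stats.tsv.
"""

from pathlib import Path

import pandas as pd

from ecospart import diversity as dv
from ecospart import io as eio

MASTER_SEED = 20_260_928
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"


def class_table(table, labels, cls):
    members = labels.index[labels == cls]
    return table.select_otus(
        [o for o in table.otu_ids if o in set(members)]).drop_empty_otus()


def main() -> None:
    table = eio.read_otu_table(DATA / "otu_table.tsv")
    meta = eio.read_metadata(DATA / "metadata.tsv", DATA / "dendritic_km.tsv")
    labels = pd.read_csv(ROOT / "results" / "classification.tsv", sep="\t",
                         index_col=0)["label"]
    season = meta.table.loc[table.sample_ids, "season"]

    alpha_rows, stats = [], []
    per_class_alpha = {}
    for cls in ("generalist", "specialist"):
        sub = class_table(table, labels, cls)
        alpha = dv.alpha_diversity(sub)
        alpha["habitat_class"] = cls
        alpha_rows.append(alpha)
        per_class_alpha[cls] = alpha

        dm = dv.bray_curtis(sub, relative=True)
        pm = dv.permanova(dm, season.loc[sub.sample_ids], n_perm=999,
                          seed=eio.stage_seed(MASTER_SEED, f"perm-{cls}"))
        stats.append({"test": "permanova_season", "class": cls, **pm})

        for s in ("wet", "dry"):
            ids = [x for x in sub.sample_ids if season[x] == s]
            ssub = sub.select_samples(ids).drop_empty_otus()
            sim = 1 - dv.bray_curtis(ssub, relative=True).data
            dk = meta.dendritic_km.loc[ids, ids].to_numpy()
            dd = dv.distance_decay(sim, dk, n_perm=999,
                                   seed=eio.stage_seed(
                                       MASTER_SEED, f"dd-{cls}-{s}"))
            stats.append({"test": "distance_decay_dendritic", "class": cls,
                          "season": s, **dd})
            env = meta.env.loc[ids]
            ed = dv.env_distance(env[[c for c in env.columns
                                      if c.startswith("env")]])
            dd = dv.distance_decay(sim, ed.data, n_perm=999,
                                   seed=eio.stage_seed(
                                       MASTER_SEED, f"edd-{cls}-{s}"))
            stats.append({"test": "distance_decay_environmental",
                          "class": cls, "season": s, **dd})

    for metric in ("richness", "chao1", "ace"):
        w = dv.wilcoxon_rank_sum(per_class_alpha["generalist"][metric],
                                 per_class_alpha["specialist"][metric])
        stats.append({"test": f"wilcoxon_alpha_{metric}",
                      "class": "generalist_vs_specialist", **w})

    pd.concat(alpha_rows).to_csv(ROOT / "results" / "diversity_alpha.tsv",
                                 sep="\t")
    out = pd.DataFrame(stats)
    out.to_csv(ROOT / "results" / "diversity_stats.tsv", sep="\t",
               index=False)

    a_mean = pd.concat(alpha_rows).groupby("habitat_class")["richness"].mean()
    print("mean per-sample richness:", a_mean.round(1).to_dict())
    dd = out[out.test == "distance_decay_dendritic"]
    print("\ndendritic distance decay (slope, r, p):")
    print(dd[["class", "season", "slope", "r", "p"]].round(4)
          .to_string(index=False))


if __name__ == "__main__":
    main()
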