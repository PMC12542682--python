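#!/usr/bin/env python
"""Co-occurrence networks of generalists vs specialists and their stability.

Builds the four class × season networks (Spearman |rho| > 0.6, BH-FDR
q < 0.05 after the occurrence/abundance filter), compares topology and
cohesion, assigns Zi-Pi roles on the entire (class-union) network, and
runs the removal-robustness experiments: random vs keystone-first and
removal of each habitat class.  Writes results/network_*.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ecospart import io as eio
from ecospart import network as nw
from ecospart.diversity import wilcoxon_rank_sum

MASTER_SEED = 20_260_928
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"


def main() -> None:
    table = eio.read_otu_table(DATA / "otu_table.tsv")
    meta = eio.read_metadata(DATA / "metadata.tsv")
    labels = pd.read_csv(ROOT / "results" / "classification.tsv", sep="\t",
                         index_col=0)["label"]
    season = meta.table.loc[table.sample_ids, "season"]

    topo_rows, cohesion_rows, degree_samples = [], [], {}
    for s in ("wet", "dry"):
        ids = [x for x in table.sample_ids if season[x] == s]
        t_season = table.select_samples(ids).drop_empty_otus()
        for cls in ("generalist", "specialist"):
            members = [o for o in t_season.otu_ids if labels.get(o) == cls]
            sub = t_season.select_otus(members).drop_empty_otus()
            try:
                filt = nw.network_filter(sub)
                g = nw.build_network(filt, labels=labels)
            except ValueError:
                print(f"  {cls}/{s}: nothing passes the network filter")
                continue
            glob, per_node = nw.topology_metrics(g)
            topo_rows.append({"class": cls, "season": s, **glob})
            degree_samples[(cls, s)] = per_node["degree"]
            per_sample, _ = nw.cohesion(filt)
            ratio = (per_sample.C_neg.abs()
                     / per_sample.C_pos.replace(0, np.nan))
            cohesion_rows.append({
                "class": cls, "season": s,
                "C_pos_mean": per_sample.C_pos.mean(),
                "C_neg_mean": per_sample.C_neg.mean(),
                "neg_to_pos_ratio": float(ratio.mean(skipna=True)),
            })

        # entire network for the season: union of the class analyses
        g_all = nw.class_union_network(t_season, labels)
        mods = nw.detect_modules(
            g_all, seed=eio.stage_seed(MASTER_SEED, f"mod-{s}"))
        roles = nw.zi_pi(g_all, mods)
        roles["habitat_class"] = [labels.get(v, "unknown") for v in
                                  roles.index]
        roles.to_csv(ROOT / "results" / f"network_roles_{s}.tsv", sep="\t")
        keystones = roles[roles.keystone]
        print(f"{s}: entire network {g_all.number_of_nodes()} nodes / "
              f"{g_all.number_of_edges()} edges; "
              f"{len(keystones)} keystone(s), of which "
              f"{(keystones.habitat_class == 'specialist').sum()} specialist")

        curves = []
        frac_key = max(0.05, len(keystones) / g_all.number_of_nodes())
        for scheme, kw in [
            ("random", {"max_fraction": frac_key}),
            ("keystone_first", {"roles": roles, "max_fraction": frac_key}),
            ("remove_generalists", {}),
            ("remove_specialists", {}),
            ("remove_opportunists", {}),
        ]:
            try:
                rb = nw.robustness(
                    g_all, scheme, reps=50,
                    seed=eio.stage_seed(MASTER_SEED, f"rb-{s}-{scheme}"),
                    **kw)
            except ValueError:
                continue
            for _, row in rb.points.iterrows():
                curves.append({"season": s, "scheme": scheme,
                               **row.to_dict(), "slope": rb.slope,
                               "nc_before": rb.nc_before,
                               "nc_after": rb.nc_after})
        cdf = pd.DataFrame(curves)
        cdf.to_csv(ROOT / "results" / f"network_robustness_{s}.tsv",
                   sep="\t", index=False)
        slopes = cdf.groupby("scheme")["slope"].first()
        print(f"  robustness slopes: " + ", ".join(
            f"{k}={v:.3f}" for k, v in slopes.items()))

    pd.DataFrame(topo_rows).to_csv(ROOT / "results" / "network_topology.tsv",
                                   sep="\t", index=False)
    pd.DataFrame(cohesion_rows).to_csv(
        ROOT / "results" / "network_cohesion.tsv", sep="\t", index=False)

    print("\nclass network topology:")
    print(pd.DataFrame(topo_rows)[["class", "season", "n_nodes", "n_edges",
                                   "avgK", "density"]]
          .round(3).to_string(index=False))
    for s in ("wet", "dry"):
        pair = degree_samples.get(("generalist", s)), degree_samples.get(
            ("specialist", s))
        if pair[0] is not None and pair[1] is not None and len(pair[0]) > 1:
            w = wilcoxon_rank_sum(pair[0], pair[1])
            print(f"degree generalist vs specialist ({s}): "
                  f"p = {w['p']:.2e}")


if __name__ == "__main__":
    main()
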