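"""Reusable study-scale experiments over the synthetic metacommunity.

These are the computations the analysis scripts narrate and the
acceptance checks re-run: classifier calibration on exchangeable null
tables, planted-label recovery, null-model self-consistency for the
assembly metrics, the generalist/specialist directional battery, and
PLS-PM parameter recovery.  Every experiment takes an explicit seed and
is deterministic given it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assembly as asb
from . import diversity as dv
from . import network as nw
from . import nutrients as nt
from .containers import OtuTable
from .io import stage_seed
from .niche import classify_otus, confusion_scores
from .synthetic import (
    simulate_metacommunity, simulate_null_table, simulate_nutrients,
    simulate_tree,
)


def classifier_null_calibration(seed: int, n_seeds: int = 5,
                                n_samples: int = 60, n_otus: int = 1000,
                                n_perm: int = 1000,
                                alpha: float = 0.05) -> pd.DataFrame:
    """Generalist/specialist call rates on habitat-structure-free tables.

    Cells are exchangeable within samples, so each tail should fire at
    about alpha/2.
    """
    rows = []
    for k in range(n_seeds):
        s = stage_seed(seed, f"null-table-{k}")
        table = simulate_null_table(n_samples, n_otus, depth=20_000, seed=s)
        res = classify_otus(table, threshold=0.0, n_perm=n_perm, alpha=alpha,
                            seed=stage_seed(seed, f"null-classify-{k}"))
        rows.append({
            "seed": s,
            "generalist_rate": float((res.label == "generalist").mean()),
            "specialist_rate": float((res.label == "specialist").mean()),
        })
    return pd.DataFrame(rows)


def classifier_recovery(seed: int, n_seeds: int = 5, n_perm: int = 1000,
                        **sim_kwargs) -> pd.DataFrame:
    """Sensitivity/specificity against planted labels, default conditions."""
    rows = []
    for k in range(n_seeds):
        table, _, _, truth = simulate_metacommunity(
            seed=stage_seed(seed, f"recovery-sim-{k}"), **sim_kwargs)
        res = classify_otus(table, n_perm=n_perm,
                            seed=stage_seed(seed, f"recovery-classify-{k}"))
        scores = confusion_scores(res, truth.classes)
        for cls in ("generalist", "specialist"):
            rows.append({"replicate": k, "class": cls,
                         "sensitivity": scores.loc[cls, "sensitivity"],
                         "specificity": scores.loc[cls, "specificity"]})
    return pd.DataFrame(rows)


def bnti_null_self_consistency(seed: int, n_reps: int = 100,
                               n_null: int = 199, n_taxa: int = 30) -> dict:
    """βNTI on pairs whose composition is random w.r.t. the phylogeny.

    Communities assembled blindly to the tree should land within ±2 in
    ~95% of replicates.
    """
    tree = simulate_tree(n_taxa, seed=stage_seed(seed, "bnti-null-tree"))
    otus = [t.name for t in tree.tips()]
    rng = np.random.default_rng(stage_seed(seed, "bnti-null-pairs"))
    within = 0
    for rep in range(n_reps):
        counts = np.zeros((2, n_taxa), dtype=np.int64)
        for s in range(2):
            k = rng.integers(8, 20)
            chosen = rng.choice(n_taxa, size=k, replace=False)
            counts[s, chosen] = np.maximum(
                1, np.exp(rng.normal(3, 1, size=k)).astype(np.int64))
        table = OtuTable(counts, sample_ids=["a", "b"], otu_ids=otus)
        z = asb.bnti(table, tree, n_null=n_null,
                     seed=int(rng.integers(2**31 - 1)))
        if abs(z.loc["a", "b"]) <= 2:
            within += 1
    return {"fraction_within_2": within / n_reps, "n": n_reps}


def rc_null_self_consistency(seed: int, n_tables: int = 6,
                             n_samples: int = 7, n_taxa: int = 60,
                             n_null: int = 199) -> dict:
    """RC_Bray on tables assembled by the Raup-Crick null itself."""
    rng = np.random.default_rng(stage_seed(seed, "rc-null"))
    within = total = 0
    for rep in range(n_tables):
        regional = rng.dirichlet(np.ones(n_taxa) * 0.4)
        occ = np.clip(regional * n_taxa * 0.5, 0.02, 1.0)
        occ_p = occ / occ.sum()
        counts = np.zeros((n_samples, n_taxa), dtype=np.int64)
        for s in range(n_samples):
            richness = int(rng.integers(18, 28))
            chosen = rng.choice(n_taxa, size=richness, replace=False, p=occ_p)
            counts[s, chosen] = 1
            p = regional[chosen] / regional[chosen].sum()
            counts[s, chosen] += rng.multinomial(2000 - richness, p)
        table = OtuTable(
            counts, sample_ids=[f"s{i}" for i in range(n_samples)],
            otu_ids=[f"o{j}" for j in range(n_taxa)])
        rc = asb.rc_bray(table, n_null=n_null,
                         seed=int(rng.integers(2**31 - 1)))
        iu = np.triu_indices(n_samples, 1)
        vals = rc.to_numpy()[iu]
        within += int((np.abs(vals) <= 0.95).sum())
        total += len(vals)
    return {"fraction_within_095": within / total, "n": total}


def directional_battery(seed: int, n_seeds: int = 50, n_sites: int = 30,
                        n_otus: int = 300, depth: int = 110_394,
                        nst_null: int = 100, coupling: float = 0.8
                        ) -> pd.DataFrame:
    """Generalist-vs-specialist contrasts the survey design should produce.

    Per replicate (wet season, planted labels): group NST, class-network
    average degree, whole-network NC slope when one class is removed,
    and the MNC ~ class β-diversity OLS r².
    """
    rows = []
    for k in range(n_seeds):
        s = stage_seed(seed, f"battery-{k}")
        table, meta, tree, truth = simulate_metacommunity(
            n_sites=n_sites, n_otus=n_otus, depth=depth, seed=s)
        season = meta.table.loc[table.sample_ids, "season"]
        wet = [x for x in table.sample_ids if season[x] == "wet"]
        gen = truth.otus_of("generalist")
        spec = truth.otus_of("specialist")
        t_gen = table.select_samples(wet).select_otus(gen).drop_empty_otus()
        t_spec = table.select_samples(wet).select_otus(spec).drop_empty_otus()
        row = {"replicate": k}

        row["nst_generalist"] = float(asb.nst(
            t_gen, n_null=nst_null, seed=s + 1).NST.iloc[0])
        row["nst_specialist"] = float(asb.nst(
            t_spec, n_null=nst_null, seed=s + 2).NST.iloc[0])

        for label, sub in (("generalist", t_gen), ("specialist", t_spec)):
            try:
                filt = nw.network_filter(sub)
                g = nw.build_network(filt)
                row[f"avgK_{label}"] = 2 * g.number_of_edges() / max(
                    g.number_of_nodes(), 1)
            except ValueError:
                row[f"avgK_{label}"] = 0.0

        t_wet = table.select_samples(wet).drop_empty_otus()
        try:
            g_all = nw.class_union_network(t_wet, truth.classes)
            for scheme in ("remove_specialists", "remove_generalists"):
                rb = nw.robustness(g_all, scheme, reps=10, seed=s + 3)
                row[f"slope_{scheme}"] = rb.slope
        except ValueError:
            row["slope_remove_specialists"] = np.nan
            row["slope_remove_generalists"] = np.nan

        meta_n = simulate_nutrients(table, truth, coupling=coupling,
                                    seed=s + 4)
        mnc = nt.mnc_index(meta_n.nutrients.loc[wet])
        for label, sub in (("generalist", t_gen), ("specialist", t_spec)):
            beta = nt.beta_scalar(dv.bray_curtis(sub, relative=True))
            row[f"bnc_r2_{label}"] = nt.ols_bnc(mnc.index, beta)["r2"]
            row[f"bnc_p_{label}"] = nt.ols_bnc(mnc.index, beta)["p"]
        rows.append(row)
    return pd.DataFrame(rows)


def battery_win_fractions(battery: pd.DataFrame) -> dict:
    """Fraction of replicates in which each qualitative contrast holds."""
    ok = battery.dropna()
    return {
        "nst_specialist_lower": float(
            (ok.nst_specialist < ok.nst_generalist).mean()),
        "avgK_specialist_higher": float(
            (ok.avgK_specialist > ok.avgK_generalist).mean()),
        "specialist_removal_steeper": float(
            (ok.slope_remove_specialists < ok.slope_remove_generalists)
            .mean()),
        "bnc_specialist_stronger": float(
            (ok.bnc_r2_specialist > ok.bnc_r2_generalist).mean()),
        "n": int(len(ok)),
    }


def plspm_chain_recovery(seed: int, n: int = 500, b1: float = 0.8,
                         b2: float = 0.7) -> dict:
    """Recover a standardized X -> M -> Y chain with known coefficients."""
    rng = np.random.default_rng(stage_seed(seed, "pls-chain"))
    x = rng.normal(size=n)
    m = b1 * x + np.sqrt(1 - b1**2) * rng.normal(size=n)
    y = b2 * m + np.sqrt(1 - b2**2) * rng.normal(size=n)
    data = pd.DataFrame({"x": x, "m": m, "y": y})
    pm = pd.DataFrame(False, index=["X", "M", "Y"], columns=["X", "M", "Y"])
    pm.loc["M", "X"] = True
    pm.loc["Y", "M"] = True
    res = nt.plspm(data, {"X": ["x"], "M": ["m"], "Y": ["y"]}, pm,
                   n_boot=0, bootstrap=False)
    gof_hand = float(np.sqrt(res.communalities.mean() * res.r2.mean()))
    return {
        "path_xm": float(res.paths.loc["M", "X"]),
        "path_my": float(res.paths.loc["Y", "M"]),
        "total_effect_xy": float(res.total_effects.loc["Y", "X"]),
        "gof": res.gof,
        "gof_identity_error": abs(res.gof - gof_hand),
        "n": n,
    }


def pipeline_fingerprint(seed: int) -> tuple:
    """A small end-to-end run reduced to hashable numbers (determinism)."""
    table, meta, tree, truth = simulate_metacommunity(
        n_sites=6, n_otus=60, depth=5000, seed=stage_seed(seed, "fp-sim"))
    res = classify_otus(table, n_perm=120, seed=stage_seed(seed, "fp-cls"))
    sub = table.select_samples(table.sample_ids[:6]).drop_empty_otus()
    z = asb.bnti(sub, tree, n_null=30, seed=stage_seed(seed, "fp-bnti"))
    rc = asb.rc_bray(sub, n_null=30, seed=stage_seed(seed, "fp-rc"))
    g = nw.build_network(nw.network_filter(
        table, min_occurrence=0.3, min_mean_abund=1e-5))
    rb = nw.robustness(g, "random", reps=5,
                       seed=stage_seed(seed, "fp-robust"))
    meta_n = simulate_nutrients(table, truth, seed=stage_seed(seed, "fp-nut"))
    mnc = nt.mnc_index(meta_n.nutrients)
    rf = nt.rf_rank(table, mnc.index, n_iter=3, cv_folds=3, cv_repeats=1,
                    top_k=5, seed=stage_seed(seed, "fp-rf"),
                    n_estimators=20, mda_forests=1)
    return (
        tuple(res.label),
        tuple(np.round(z.to_numpy().ravel(), 10)),
        tuple(np.round(rc.to_numpy().ravel(), 10)),
        tuple(sorted(g.edges)),
        tuple(np.round(rb.points.natural_connectivity.to_numpy(), 10)),
        tuple(rf.top_by_gini),
        tuple(np.round(mnc.index.to_numpy(), 12)),
    )
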