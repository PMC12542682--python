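"""Deterministic vs stochastic community assembly inference.

Implements the null-model framework that partitions pairwise community
turnover into five ecological processes:

* ``βMNTD`` — between-community mean nearest taxon distance on the
  phylogeny; ``βNTI`` is its z-score against a tip-label shuffle null.
  |βNTI| > 2 indicates selection (heterogeneous if > 2, homogeneous if
  < −2).
* ``RC_Bray`` — Raup-Crick on Bray-Curtis against a probabilistic
  assembly null (richness and abundance fixed per sample, taxa drawn
  with probability proportional to occupancy, individuals proportional
  to regional relative abundance), scaled to [−1, 1].  For pairs with
  |βNTI| ≤ 2, RC > 0.95 indicates dispersal limitation, RC < −0.95
  homogenizing dispersal, and the rest is undominated.
* ``NST`` — the normalized stochasticity ratio on Bray-Curtis: per-pair
  observed deviation from the null expectation, normalized so 1 means
  turnover indistinguishable from the null (pure stochasticity) and 0
  means maximal deviation (pure determinism); the conventional cutoff
  is 0.5.
* a Mantel correlogram across phylogenetic-distance classes, the
  standard check that niche optima carry phylogenetic signal at short
  distances, which the βNTI framework presupposes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from scipy.spatial.distance import pdist, squareform

from .containers import OtuTable
from .io import check_tree_covers, logger, relative_abundance

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95

PROCESSES = (
    "heterogeneous_selection", "homogeneous_selection",
    "dispersal_limitation", "homogenizing_dispersal", "undominated",
)


# ------------------------------------------------------------- βMNTD

def _patristic(tree: TreeNode, otu_ids: list[str]) -> np.ndarray:
    dm = tree.tip_tip_distances(endpoints=list(otu_ids))
    # reorder to otu_ids
    idx = [dm.ids.index(o) for o in otu_ids]
    return dm.data[np.ix_(idx, idx)]

def _weights(table: OtuTable, weighted: bool) -> np.ndarray:
    rel = relative_abundance(table).to_numpy()
    if weighted:
        return rel
    pres = (rel > 0).astype(float)
    return pres / pres.sum(axis=1, keepdims=True)


def _beta_mntd_from(D: np.ndarray, W: np.ndarray) -> np.ndarray:
    """βMNTD for all sample pairs given patristic D and weight matrix W."""
    n = W.shape[0]
    present = W > 0
    # M[b, i] = distance from taxon i to its nearest taxon present in b
    M = np.empty((n, D.shape[0]))
    for b in range(n):
        M[b] = D[:, present[b]].min(axis=1)
    T = W @ M.T  # T[a, b] = sum_i W[a, i] * M[b, i]
    return 0.5 * (T + T.T)


def beta_mntd(table: OtuTable, tree: TreeNode,
              weighted: bool = True) -> DistanceMatrix:
    """Abundance-weighted (default) βMNTD between all sample pairs."""
    table = table.drop_empty_otus()
    check_tree_covers(tree, table.otu_ids)
    D = _patristic(tree, table.otu_ids)
    W = _weights(table, weighted)
    out = _beta_mntd_from(D, W)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(out, ids=table.sample_ids)


def bnti(table: OtuTable, tree: TreeNode, n_null: int = 999, seed: int = 0,
         weighted: bool = True) -> pd.DataFrame:
    """βNTI: z-score of observed βMNTD against a tip-shuffle null.

    The null shuffles taxa labels among the OTUs present in the analyzed
    table (the conventional "taxa labels" null restricted to the regional
    pool), recomputing βMNTD each time.  Pairs whose null has zero
    standard deviation are reported as NaN with a warning.
    """
    table = table.drop_empty_otus()
    check_tree_covers(tree, table.otu_ids)
    D = _patristic(tree, table.otu_ids)
    W = _weights(table, weighted)
    obs = _beta_mntd_from(D, W)
    rng = np.random.default_rng(seed)
    m = D.shape[0]
    null_sum = np.zeros_like(obs)
    null_sqsum = np.zeros_like(obs)
    for _ in range(n_null):
        p = rng.permutation(m)
        nul = _beta_mntd_from(D[np.ix_(p, p)], W)
        null_sum += nul
        null_sqsum += nul * nul
    mean = null_sum / n_null
    var = null_sqsum / n_null - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    z[sd <= 1e-12] = np.nan
    np.fill_diagonal(z, 0.0)
    if np.isnan(z[np.triu_indices(len(z), 1)]).any():
        logger.warning("bnti: some pairs have zero null sd; reported as NaN")
    return pd.DataFrame(z, index=table.sample_ids, columns=table.sample_ids)


# ----------------------------------------------------------- RC_Bray

def _null_counts(rng, richness, totals, occupancy_p, regional_p, n_taxa):
    """One null community per sample: Stegen's probabilistic assembly."""
    out = np.zeros((len(richness), n_taxa), dtype=np.int64)
    taxa = np.arange(n_taxa)
    for s, (S, N) in enumerate(zip(richness, totals)):
        chosen = rng.choice(taxa, size=S, replace=False, p=occupancy_p)
        out[s, chosen] = 1  # guarantee presence
        if N > S:
            p = regional_p[chosen]
            p = p / p.sum()
            out[s, chosen] += rng.multinomial(N - S, p)
    return out


def rc_bray(table: OtuTable, n_null: int = 999, seed: int = 0) -> pd.DataFrame:
    """Bray-Curtis-based Raup-Crick for all sample pairs, in [−1, 1].

    ``RC = 2 ([#{null BC < obs BC} + 0.5 #{ties}] / n_null − 0.5)``; ties
    counted at half weight.  Null communities fix each sample's richness
    and total abundance, draw taxa with probability proportional to
    occupancy frequency and fill individuals proportionally to regional
    relative abundance.  One null metacommunity is assembled per
    iteration and scored for every pair.
    """
    counts = table.counts
    n, n_taxa = counts.shape
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    occupancy = (counts > 0).sum(axis=0).astype(float)
    regional = counts.sum(axis=0).astype(float)
    occupancy_p = occupancy / occupancy.sum()
    regional_p = regional / regional.sum()

    obs = squareform(pdist(counts.astype(float), metric="braycurtis"))
    rng = np.random.default_rng(seed)
    less = np.zeros((n, n), dtype=float)
    ties = np.zeros((n, n), dtype=float)
    for _ in range(n_null):
        nullc = _null_counts(rng, richness, totals, occupancy_p, regional_p,
                             n_taxa)
        nbc = squareform(pdist(nullc.astype(float), metric="braycurtis"))
        less += (nbc < obs - 1e-12)
        ties += (np.abs(nbc - obs) <= 1e-12)
    rc = 2.0 * ((less + 0.5 * ties) / n_null - 0.5)
    np.fill_diagonal(rc, 0.0)
    return pd.DataFrame(rc, index=table.sample_ids, columns=table.sample_ids)


# -------------------------------------------------- process partition

def partition_processes(bnti_matrix: pd.DataFrame,
                        rc_matrix: pd.DataFrame) -> dict:
    """Five-process fractions from pairwise βNTI and RC_Bray.

    βNTI > 2 → heterogeneous selection; βNTI < −2 → homogeneous
    selection; |βNTI| ≤ 2 and RC > 0.95 → dispersal limitation;
    RC < −0.95 → homogenizing dispersal; else undominated.  Pairs with
    missing βNTI are excluded from the denominator (and logged).
    """
    if list(bnti_matrix.index) != list(rc_matrix.index):
        raise ValueError("βNTI and RC matrices must share sample order")
    iu = np.triu_indices(len(bnti_matrix), k=1)
    b = bnti_matrix.to_numpy()[iu]
    r = rc_matrix.to_numpy()[iu]
    ok = ~np.isnan(b) & ~np.isnan(r)
    if (~ok).any():
        logger.warning("partition_processes: excluding %d pair(s) with "
                       "missing values", int((~ok).sum()))
    b, r = b[ok], r[ok]
    n = len(b)
    if n == 0:
        raise ValueError("no valid pairs to partition")
    het = b > BNTI_THRESHOLD
    hom = b < -BNTI_THRESHOLD
    stoch = ~het & ~hom
    dl = stoch & (r > RC_THRESHOLD)
    hd = stoch & (r < -RC_THRESHOLD)
    und = stoch & ~dl & ~hd
    counts = [het.sum(), hom.sum(), dl.sum(), hd.sum(), und.sum()]
    return {name: float(c) / n for name, c in zip(PROCESSES, counts)}


# ---------------------------------------------------------------- NST

def nst(table: OtuTable, groups=None, n_null: int = 1000,
        seed: int = 0) -> pd.DataFrame:
    """Normalized stochasticity ratio (taxonomic, Bray-Curtis variant).

    For each group of ≥ 3 samples, the null expectation of pairwise
    Bray-Curtis is estimated from ``n_null`` null metacommunities drawn
    by the same assembly engine as :func:`rc_bray` (richness fixed per
    sample, taxa weighted by occupancy within the group).  Per pair,
    letting D be observed dissimilarity, C = 1 − D, and E_D / E_C the
    null expectations:

    * ``D ≥ E_D`` (more divergent than null): NST = E_D (1−D) / (D (1−E_D))
    * ``D <  E_D`` (more similar than null):  NST = E_C (1−C) / (C (1−E_C))

    so NST = 1 when observed turnover equals the null expectation and 0
    at maximal deviation; group NST is the mean over pairs.  Values
    above 0.5 indicate stochasticity-dominated assembly.
    """
    if groups is None:
        groups = pd.Series("all", index=table.sample_ids)
    else:
        groups = pd.Series(list(groups), index=table.sample_ids)
    rows = []
    for gname, members in groups.groupby(groups).groups.items():
        members = list(members)
        if len(members) < 3:
            raise ValueError(f"group {gname!r} has fewer than 3 samples")
        sub = table.select_samples(members).drop_empty_otus()
        counts = sub.counts
        richness = (counts > 0).sum(axis=1)
        totals = counts.sum(axis=1)
        occ = (counts > 0).sum(axis=0).astype(float)
        reg = counts.sum(axis=0).astype(float)
        occ_p, reg_p = occ / occ.sum(), reg / reg.sum()
        obs = squareform(pdist(counts.astype(float), metric="braycurtis"))
        rng = np.random.default_rng(seed)
        acc = np.zeros_like(obs)
        for _ in range(n_null):
            nullc = _null_counts(rng, richness, totals, occ_p, reg_p,
                                 counts.shape[1])
            acc += squareform(pdist(nullc.astype(float), metric="braycurtis"))
        e_d = acc / n_null
        iu = np.triu_indices(len(members), k=1)
        d, ed = obs[iu], e_d[iu]
        c, ec = 1.0 - d, 1.0 - ed
        with np.errstate(divide="ignore", invalid="ignore"):
            nst_div = ed * (1.0 - d) / (d * (1.0 - ed))
            nst_con = ec * (1.0 - c) / (c * (1.0 - ec))
        per_pair = np.where(d >= ed, nst_div, nst_con)
        per_pair = np.clip(np.nan_to_num(per_pair, nan=0.0), 0.0, 1.0)
        rows.append({"group": gname, "NST": float(per_pair.mean()),
                     "n_pairs": len(per_pair),
                     "pairwise": per_pair})
    return pd.DataFrame(rows).set_index("group")


# ------------------------------------------------- Mantel correlogram

def otu_niche_values(table: OtuTable, env: pd.DataFrame) -> pd.DataFrame:
    """Abundance-weighted mean environment per OTU (niche optimum estimate)."""
    rel = relative_abundance(table)
    shares = rel / rel.sum(axis=0)
    return pd.DataFrame(shares.T.to_numpy() @ env.loc[rel.index].to_numpy(),
                        index=table.otu_ids, columns=env.columns)


def mantel_correlogram(niche_values: pd.DataFrame, tree: TreeNode,
                       n_classes: int = 10, n_perm: int = 999,
                       seed: int = 0) -> pd.DataFrame:
    """Mantel correlogram of niche differences across phylo-distance classes.

    For each equal-width patristic-distance class, the Mantel statistic
    between the niche-difference matrix and the class-membership
    indicator is reported with its sign flipped, so positive r means
    OTUs at that phylogenetic distance have more similar niches than
    average.  Permutation p-values (two-sided, OTU-label permutations)
    are Holm-corrected across classes; empty classes are skipped.
    """
    if isinstance(niche_values, pd.Series):
        niche_values = niche_values.to_frame()
    otus = list(niche_values.index)
    D = _patristic(tree, otus)
    nd = squareform(pdist(niche_values.to_numpy(), metric="euclidean"))
    iu = np.triu_indices(len(otus), k=1)
    dvec = D[iu]
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(len(otus)) for _ in range(n_perm)]
    if n_classes == 1:
        # degenerate correlogram: a single class covering every pair is a
        # constant indicator, so report the plain Mantel statistic between
        # niche differences and patristic distance instead
        r_obs = float(np.corrcoef(nd[iu], dvec)[0, 1])
        hits = sum(
            abs(np.corrcoef(nd[np.ix_(p, p)][iu], dvec)[0, 1])
            >= abs(r_obs) - 1e-12
            for p in perms
        )
        return pd.DataFrame([{
            "class": 0, "d_lower": 0.0, "d_upper": float(dvec.max()),
            "n_pairs": int(len(dvec)), "mantel_r": r_obs,
            "p": (1 + hits) / (1 + n_perm), "p_holm": (1 + hits) / (1 + n_perm),
        }])
    edges = np.linspace(0.0, dvec.max() * (1 + 1e-12), n_classes + 1)
    rows = []
    for k in range(n_classes):
        w = (dvec >= edges[k]) & (dvec < edges[k + 1])
        if w.sum() == 0 or w.all():
            logger.warning("mantel_correlogram: class %d empty or "
                           "all-inclusive; skipped", k)
            continue
        wf = w.astype(float)
        r_obs = -np.corrcoef(nd[iu], wf)[0, 1]
        hits = 0
        for p in perms:
            ndp = nd[np.ix_(p, p)][iu]
            rp = -np.corrcoef(ndp, wf)[0, 1]
            if abs(rp) >= abs(r_obs) - 1e-12:
                hits += 1
        rows.append({"class": k, "d_lower": edges[k], "d_upper": edges[k + 1],
                     "n_pairs": int(w.sum()), "mantel_r": float(r_obs),
                     "p": (1 + hits) / (1 + n_perm)})
    out = pd.DataFrame(rows)
    if len(out):
        # Holm step-down correction across classes
        m = len(out)
        order = np.argsort(out["p"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
    return out
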