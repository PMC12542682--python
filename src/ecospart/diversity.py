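"""Alpha/beta diversity, group comparisons, and distance-decay regressions.

Alpha diversity reports richness, bias-corrected Chao1 and ACE (rare
threshold 10) per sample.  Beta diversity is Bray-Curtis dissimilarity.
Group differences are tested with PERMANOVA (Anderson's pseudo-F on the
distance matrix) and Wilcoxon rank-sum tests.  Distance decay regresses
pairwise community similarity (1 − Bray-Curtis) on pairwise dendritic or
environmental distance by OLS; because sample pairs are not independent,
its p-value comes from Mantel-style permutations of sample labels rather
than the naive OLS t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity.alpha import ace, chao1
from skbio.stats.distance import permanova as _skbio_permanova

from .containers import OtuTable
from .io import logger


# ------------------------------------------------------------- alpha

def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample richness, Chao1 (bias-corrected) and ACE.

    Expects integer (rarefied) counts; an empty sample yields zeros with
    a warning.
    """
    rows = {}
    for sid, counts in zip(table.sample_ids, table.counts):
        if counts.sum() == 0:
            logger.warning("alpha_diversity: sample %s is empty", sid)
            rows[sid] = {"richness": 0.0, "chao1": 0.0, "ace": 0.0}
            continue
        rows[sid] = {
            "richness": float((counts > 0).sum()),
            "chao1": float(chao1(counts, bias_corrected=True)),
            "ace": float(ace(counts, rare_threshold=10)),
        }
    out = pd.DataFrame.from_dict(rows, orient="index").loc[table.sample_ids]
    out.index.name = "sample_id"
    return out


# -------------------------------------------------------------- beta

def bray_curtis(table: OtuTable, relative: bool = False) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC(x,y) = Σ|x−y| / Σ(x+y).

    With ``relative=True`` rows are normalized to proportions first —
    the appropriate choice for class subcommunities, whose raw counts
    still carry whole-community sample totals.
    """
    counts = table.counts.astype(float)
    sums = counts.sum(axis=1)
    if (sums == 0).sum() >= 1:
        empty = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise ValueError(f"Bray-Curtis undefined for empty sample(s): {empty}")
    if relative:
        counts = counts / sums[:, None]
    dm = squareform(pdist(counts, metric="braycurtis"))
    return DistanceMatrix(dm, ids=table.sample_ids)


def permanova(dist: DistanceMatrix, groups, n_perm: int = 999,
              seed: int = 0) -> dict:
    """PERMANOVA pseudo-F and permutation p for a grouping factor.

    Follows Anderson's distance-based formulation (sums of squares from
    Gower-centered squared distances); ``p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm)``.
    """
    groups = pd.Series(list(groups), index=dist.ids)
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (sizes < 2).any():
        raise ValueError(
            f"singleton group(s): {sizes[sizes < 2].index.tolist()}"
        )
    res = _skbio_permanova(dist, groups.to_numpy(), permutations=n_perm,
                           seed=seed)
    return {"pseudo_F": float(res["test statistic"]),
            "p": float(res["p-value"]),
            "n_perm": int(res["number of permutations"])}


def wilcoxon_rank_sum(x, y, exact_max_n: int = 25) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison.

    Uses the exact null when both groups have ≤ ``exact_max_n``
    observations and no ties, the tie-corrected normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if (len(x) <= exact_max_n and len(y) <= exact_max_n
                         and len(np.unique(np.r_[x, y])) == len(x) + len(y)) \
        else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method=method)
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "method": method}


# ----------------------------------------------------- distance decay

def env_distance(env: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance on z-scored environmental variables."""
    z = (env - env.mean()) / env.std(ddof=0).replace(0.0, 1.0)
    dm = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return DistanceMatrix(dm, ids=list(env.index))


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def distance_decay(similarity: DistanceMatrix | np.ndarray,
                   distance: DistanceMatrix | np.ndarray,
                   n_perm: int = 999, seed: int = 0) -> dict:
    """OLS of pairwise similarity on pairwise distance, Mantel permutation p.

    Both arguments are symmetric sample × sample matrices over the same
    sample order (a skbio ``DistanceMatrix`` or a plain array); the
    regression runs over the strict upper triangle.  The slope and r are
    the plain OLS point estimates; the two-sided p permutes sample labels
    of the similarity matrix (Mantel scheme) because pairs sharing a
    sample are not independent.
    """
    sim = similarity.data if isinstance(similarity, DistanceMatrix) else np.asarray(similarity)
    dis = distance.data if isinstance(distance, DistanceMatrix) else np.asarray(distance)
    if sim.shape != dis.shape:
        raise ValueError("matrix shapes differ")
    y = _upper(sim)
    x = _upper(dis)
    if np.ptp(x) == 0:
        raise ValueError("distance has zero variance")
    slope, intercept, r, _, _ = scipy.stats.linregress(x, y)
    rng = np.random.default_rng(seed)
    n = sim.shape[0]
    r_obs = abs(r)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = _upper(sim[np.ix_(perm, perm)])
        rp = np.corrcoef(x, yp)[0, 1]
        if abs(rp) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return {"slope": float(slope), "intercept": float(intercept),
            "r": float(r), "p": float(p), "n_pairs": int(len(x))}
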