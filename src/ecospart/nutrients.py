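"""Multi-nutrient cycling index and biodiversity–nutrient-cycling links.

The multi-nutrient cycling (MNC) index is the aquatic analogue of the
terrestrial multifunctionality averaging approach: each of the eight
nutrient variables is min-max standardized to [0, 1] across samples and
the per-sample mean of the standardized values is the index.

The biodiversity–nutrient-cycling (BNC) relationship is quantified three
ways: ordinary least squares of MNC on a per-sample β-diversity scalar
(LCBD by default), random-forest ranking of OTUs predicting MNC, and a
partial least squares path model (PLS-PM, Lohmöller's algorithm, mode A
outer estimation with the centroid inner scheme) linking space,
environment, community assembly and class-specific β-diversity to MNC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import RepeatedKFold

from .containers import NUTRIENT_VARS, OtuTable
from .io import logger, relative_abundance


# ------------------------------------------------------------------ MNC

@dataclass
class MncResult:
    """Per-sample multi-nutrient cycling index and standardized matrix."""

    index: pd.Series                # per-sample MNC in [0, 1]
    standardized: pd.DataFrame      # samples × nutrients, each column in [0, 1]


def mnc_index(nutrients: pd.DataFrame) -> MncResult:
    """Min-max standardize each nutrient column and average per sample.

    ``(X_raw − X_min) / (X_max − X_min)`` per column; constant columns are
    an error (they carry no cycling signal and make the scaling
    undefined).  The result is invariant to positive affine rescaling of
    any nutrient.
    """
    if nutrients.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = nutrients.astype(float)
    rng_ = X.max() - X.min()
    flat = rng_.index[rng_ <= 0].tolist()
    if flat:
        raise ValueError(f"constant nutrient column(s): {flat}")
    std = (X - X.min()) / rng_
    return MncResult(index=std.mean(axis=1).rename("MNC"), standardized=std)


# --------------------------------------------------------- β-diversity

def beta_scalar(dist, method: str = "lcbd") -> pd.Series:
    """Reduce a distance matrix to one β-diversity value per sample.

    ``lcbd`` is the Legendre–De Cáceres local contribution to
    β-diversity: the diagonal of the Gower-centered matrix of squared
    dissimilarities divided by the total sum of squares (sums to 1).
    ``mean_pairwise`` is the row mean of dissimilarities.
    """
    try:
        ids = list(dist.ids)
        d = dist.data
    except AttributeError:
        d = np.asarray(dist, dtype=float)
        ids = list(range(d.shape[0]))
    n = d.shape[0]
    if method == "mean_pairwise":
        return pd.Series(d.sum(axis=1) / (n - 1), index=ids, name="beta")
    if method != "lcbd":
        raise ValueError(f"unknown beta scalar method: {method!r}")
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    ss_total = np.trace(g)
    if ss_total <= 1e-12:
        raise ValueError("LCBD undefined: total sum of squares is zero "
                         "(all samples identical)")
    return pd.Series(np.diag(g) / ss_total, index=ids, name="lcbd")


def ols_bnc(mnc, beta) -> dict:
    """OLS of MNC on a β-diversity scalar with two-sided slope t-test."""
    x = np.asarray(beta, dtype=float)
    y = np.asarray(mnc, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3 samples")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    res = scipy.stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue**2), "p": float(res.pvalue)}


# -------------------------------------------------------- random forest

@dataclass
class RfRanking:
    importances: pd.DataFrame       # per-OTU gini + mda, averaged
    top_by_gini: list
    top_by_mda: list
    cv_curve: pd.DataFrame          # n_features vs repeated-CV MSE


def rf_rank(table: OtuTable, mnc, n_iter: int = 500, cv_folds: int = 10,
            cv_repeats: int = 5, top_k: int = 30, seed: int = 0,
            n_estimators: int = 100, mda_forests: int = 20) -> RfRanking:
    """Rank OTUs by random-forest importance for predicting MNC.

    Gini (impurity) importance is averaged over ``n_iter`` forests with
    distinct sub-seeds; mean decrease accuracy is estimated by
    permutation importance averaged over the first ``mda_forests``
    forests.  The cross-validation error curve refits forests on the top
    1, 2, … features of the Gini ranking under repeated K-fold CV.
    """
    X = relative_abundance(table)
    y = pd.Series(np.asarray(mnc, dtype=float), index=X.index)
    if top_k > X.shape[1]:
        logger.warning("rf_rank: top_k capped at %d OTUs", X.shape[1])
        top_k = X.shape[1]
    rng = np.random.default_rng(seed)
    gini = np.zeros(X.shape[1])
    mda = np.zeros(X.shape[1])
    n_mda = 0
    for it in range(n_iter):
        sub = int(rng.integers(2**31 - 1))
        rf = RandomForestRegressor(n_estimators=n_estimators, random_state=sub,
                                   n_jobs=1)
        rf.fit(X, y)
        gini += rf.feature_importances_
        if it < mda_forests:
            pi = permutation_importance(rf, X, y, n_repeats=1,
                                        random_state=sub, n_jobs=1)
            mda += pi.importances_mean
            n_mda += 1
    gini /= n_iter
    mda /= max(n_mda, 1)
    imp = pd.DataFrame({"gini": gini, "mda": mda}, index=X.columns)
    rank_gini = imp.sort_values("gini", ascending=False)
    rank_mda = imp.sort_values("mda", ascending=False)

    # CV error against nested feature counts on the Gini ranking
    ks = sorted(set(np.unique(np.round(np.geomspace(1, top_k, num=min(top_k, 12)))
                              .astype(int))))
    rkf = RepeatedKFold(n_splits=min(cv_folds, len(y)), n_repeats=cv_repeats,
                        random_state=int(rng.integers(2**31 - 1)))
    curve = []
    for k in ks:
        feats = rank_gini.index[:k]
        errs = []
        for train, test in rkf.split(X):
            rf = RandomForestRegressor(
                n_estimators=max(50, n_estimators // 2),
                random_state=int(rng.integers(2**31 - 1)), n_jobs=1)
            rf.fit(X.iloc[train][feats], y.iloc[train])
            pred = rf.predict(X.iloc[test][feats])
            errs.append(float(np.mean((pred - y.iloc[test]) ** 2)))
        curve.append({"n_features": k, "cv_mse": float(np.mean(errs))})
    return RfRanking(
        importances=imp,
        top_by_gini=rank_gini.index[:top_k].tolist(),
        top_by_mda=rank_mda.index[:top_k].tolist(),
        cv_curve=pd.DataFrame(curve),
    )


# --------------------------------------------------------------- PLS-PM

@dataclass
class PlsPmResult:
    scores: pd.DataFrame            # samples × latent blocks
    outer_weights: dict
    loadings: dict                  # block → Series of indicator loadings
    communalities: pd.Series        # per-block mean squared loading
    paths: pd.DataFrame             # endogenous rows × predecessor columns
    r2: pd.Series                   # per endogenous block
    gof: float
    total_effects: pd.DataFrame     # effect of column block on row block
    boot_ci: pd.DataFrame | None = None


def plspm(data: pd.DataFrame, blocks: dict, path_matrix: pd.DataFrame,
          max_iter: int = 300, tol: float = 1e-6, n_boot: int = 500,
          seed: int = 0, bootstrap: bool = True) -> PlsPmResult:
    """Partial least squares path modeling (Lohmöller, mode A, centroid).

    ``blocks`` maps block names to indicator column lists (non-
    overlapping); ``path_matrix`` is a boolean lower-triangular frame
    (rows = blocks, ``path_matrix.loc[j, k]`` true when block k points
    at block j).  Latent scores are iterated to ``tol``; path
    coefficients are OLS of each endogenous latent on its predecessors;
    GOF = sqrt(mean block communality × mean R² of endogenous blocks);
    total effects sum the products of coefficients along directed paths.
    Bootstrap (percentile, ``n_boot`` resamples) CIs cover the paths.
    """
    names = list(blocks)
    cols = [c for b in names for c in blocks[b]]
    if len(set(cols)) != len(cols):
        raise ValueError("blocks overlap")
    pm = path_matrix.loc[names, names].astype(bool)
    if np.triu(pm.to_numpy()).any():
        raise ValueError("path matrix must be lower-triangular (acyclic)")
    X = data[cols].astype(float)
    Xz = (X - X.mean()) / X.std(ddof=0)
    if Xz.isna().any().any():
        bad = Xz.columns[Xz.isna().any()].tolist()
        raise ValueError(f"constant indicator column(s): {bad}")

    scores, weights = _lohmoeller(Xz, blocks, names, pm, max_iter, tol)

    adj = pm.to_numpy()
    paths = pd.DataFrame(0.0, index=names, columns=names)
    r2 = {}
    for j, bj in enumerate(names):
        preds = [names[k] for k in range(len(names)) if adj[j, k]]
        if not preds:
            continue
        Yp = scores[preds].to_numpy()
        yy = scores[bj].to_numpy()
        gram = Yp.T @ Yp
        if np.linalg.cond(gram) > 1e12:
            raise ValueError(f"singular inner regression for block {bj!r}")
        beta = np.linalg.solve(gram, Yp.T @ yy)
        paths.loc[bj, preds] = beta
        resid = yy - Yp @ beta
        r2[bj] = 1.0 - resid.var() / yy.var()
    r2 = pd.Series(r2, name="r2")

    loadings = {b: pd.Series(
        [float(np.corrcoef(Xz[c], scores[b])[0, 1]) for c in blocks[b]],
        index=blocks[b]) for b in names}
    communalities = pd.Series({b: float((loadings[b] ** 2).mean())
                               for b in names}, name="communality")
    gof = float(np.sqrt(communalities.mean() * r2.mean())) if len(r2) else float("nan")

    # total effects: sum of coefficient products over all directed paths
    B = paths.to_numpy()
    total = np.zeros_like(B)
    power = B.copy()
    for _ in range(len(names)):
        total += power
        power = power @ B
    total_effects = pd.DataFrame(total, index=names, columns=names)

    boot_ci = None
    if bootstrap and n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(Xz)
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Xb = X.iloc[idx].reset_index(drop=True)
            sd = Xb.std(ddof=0)
            if (sd == 0).any():
                continue
            Xbz = (Xb - Xb.mean()) / sd
            try:
                sb, _ = _lohmoeller(Xbz, blocks, names, pm, max_iter, tol)
            except ValueError:
                continue
            row = {}
            for j, bj in enumerate(names):
                preds = [names[k] for k in range(len(names)) if adj[j, k]]
                if not preds:
                    continue
                Yp = sb[preds].to_numpy()
                beta = np.linalg.lstsq(Yp, sb[bj].to_numpy(), rcond=None)[0]
                for p, b_ in zip(preds, beta):
                    row[(bj, p)] = b_
            draws.append(row)
        if draws:
            bdf = pd.DataFrame(draws)
            boot_ci = pd.DataFrame({
                "estimate": [paths.loc[j, k] for j, k in bdf.columns],
                "ci_low": bdf.quantile(0.025).to_numpy(),
                "ci_high": bdf.quantile(0.975).to_numpy(),
            }, index=pd.MultiIndex.from_tuples(bdf.columns,
                                               names=["to", "from"]))
            boot_ci["significant"] = ((boot_ci["ci_low"] > 0)
                                      | (boot_ci["ci_high"] < 0))

    return PlsPmResult(scores=scores, outer_weights=weights,
                       loadings=loadings, communalities=communalities,
                       paths=paths, r2=r2, gof=gof,
                       total_effects=total_effects, boot_ci=boot_ci)


def _lohmoeller(Xz: pd.DataFrame, blocks: dict, names: list,
                pm: pd.DataFrame, max_iter: int, tol: float):
    """Iterate outer (mode A) / inner (centroid) estimation to convergence."""
    n = len(Xz)
    adj = pm.to_numpy()
    neighbor = adj | adj.T
    weights = {b: np.ones(len(blocks[b])) for b in names}

    def make_scores(w):
        sc = {}
        for b in names:
            y = Xz[blocks[b]].to_numpy() @ w[b]
            sd = y.std()
            if sd == 0:
                raise ValueError(f"degenerate latent score for block {b!r}")
            y = y / sd
            # orient the latent with its indicators
            if np.corrcoef(y, Xz[blocks[b]].to_numpy().sum(axis=1))[0, 1] < 0:
                y = -y
            sc[b] = y
        return pd.DataFrame(sc, index=Xz.index)

    scores = make_scores(weights)
    for _ in range(max_iter):
        inner = {}
        for j, b in enumerate(names):
            z = np.zeros(n)
            for k, other in enumerate(names):
                if neighbor[j, k]:
                    sign = np.sign(np.corrcoef(scores[b], scores[other])[0, 1])
                    z += (sign if sign != 0 else 1.0) * scores[other].to_numpy()
            inner[b] = z if np.any(z) else scores[b].to_numpy()
        new_weights = {}
        for b in names:
            xb = Xz[blocks[b]].to_numpy()
            w = xb.T @ inner[b] / n   # mode A: cov(indicator, inner proxy)
            new_weights[b] = w
        new_scores = make_scores(new_weights)
        delta = max(
            float(np.max(np.abs(np.abs(new_weights[b]) - np.abs(weights[b]))))
            for b in names
        )
        weights, scores = new_weights, new_scores
        if delta < tol:
            break
    else:
        raise ValueError(f"PLS-PM did not converge in {max_iter} iterations")
    return scores, weights
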