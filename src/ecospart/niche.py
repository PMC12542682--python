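"""Levins' niche breadth and generalist/specialist classification.

An OTU's niche breadth is the inverse Simpson concentration of its
abundance across samples, ``B_j = 1 / sum_i P_ij^2`` with ``P_ij`` the
share of OTU *j*'s total abundance occurring in sample *i*: ``B = 1``
when the OTU occurs in a single sample, ``B = N`` when it is spread
evenly over all *N* samples.

The observed breadth is tested against a permutation null.  Because
breadth is invariant to reordering an OTU's own values across samples,
shuffling within an OTU column is degenerate; the default null instead
shuffles abundances across OTUs *within each sample* (preserving each
sample's abundance pool while breaking the OTU–sample association).  A
whole-table cell shuffle is available as an alternative.  OTUs whose
observed breadth exceeds the null's upper 95% bound are generalists,
those below the lower bound specialists, and the rest opportunists;
rare OTUs (mean relative abundance below 2e-5) are excluded up front
because detection-limit absences would mimic specialism.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import OtuTable
from .io import relative_abundance

FILTERED = "filtered"
DEFAULT_ABUNDANCE_THRESHOLD = 2e-5


def levins_breadth(rel_abund_column) -> float:
    """Levins' niche breadth of one OTU across N samples; in [1, N]."""
    v = np.asarray(rel_abund_column, dtype=float)
    if (v < 0).any():
        raise ValueError("abundances must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("niche breadth undefined for an all-zero OTU")
    p = v / total
    return float(1.0 / np.sum(p * p))


def _breadth_matrix(values: np.ndarray) -> np.ndarray:
    """Levins breadth for every column of a samples × OTUs matrix."""
    totals = values.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = values / totals
        b = 1.0 / np.sum(p * p, axis=0)
    b[totals <= 0] = np.nan
    return b


def abundance_filter(table: OtuTable,
                     threshold: float = DEFAULT_ABUNDANCE_THRESHOLD) -> list[str]:
    """OTU ids whose mean per-sample relative abundance is >= threshold."""
    rel = relative_abundance(table)
    mean = rel.mean(axis=0)
    return mean.index[mean >= threshold].tolist()


def permutation_null(table: OtuTable, n_perm: int = 1000, seed: int = 0,
                     scheme: str = "within_sample") -> np.ndarray:
    """Per-OTU null breadth distributions (sorted, shape n_perm × n_OTUs).

    ``scheme='within_sample'`` (default) independently permutes each
    sample's abundances across OTUs; ``scheme='whole_table'`` shuffles
    all cells of the table.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    rel = relative_abundance(table).to_numpy()
    null = np.empty((n_perm, rel.shape[1]))
    for k in range(n_perm):
        if scheme == "within_sample":
            perm = rng.permuted(rel, axis=1)
        elif scheme == "whole_table":
            perm = rng.permutation(rel.ravel()).reshape(rel.shape)
        else:
            raise ValueError(f"unknown permutation scheme: {scheme!r}")
        null[k] = _breadth_matrix(perm)
    null.sort(axis=0)
    return null


def classify(b_obs: float, null: np.ndarray, alpha: float = 0.05) -> str:
    """Label one OTU against its null breadth vector.

    Strictly above the upper empirical quantile (type-7) → generalist;
    strictly below the lower → specialist; ties at a bound are left as
    opportunist (conservative).
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    lo = np.quantile(null, alpha / 2)
    hi = np.quantile(null, 1 - alpha / 2)
    if b_obs > hi:
        return "generalist"
    if b_obs < lo:
        return "specialist"
    return "opportunist"


def classify_otus(table: OtuTable, threshold: float = DEFAULT_ABUNDANCE_THRESHOLD,
                  n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
                  scheme: str = "within_sample") -> pd.DataFrame:
    """Full classification: filter, observed breadth, null, labels.

    Returns one row per OTU of the input table with columns ``B_obs``,
    ``mean_rel_abund``, ``null_lower``, ``null_upper`` and ``label``
    (rare OTUs keep their breadth but are labeled ``filtered``).
    Classification pools all samples (both seasons); run on a subset
    table for a per-season classification.
    """
    rel = relative_abundance(table)
    mean_rel = rel.mean(axis=0)
    b_all = pd.Series(_breadth_matrix(rel.to_numpy()), index=rel.columns)

    retained = mean_rel.index[mean_rel >= threshold].tolist()
    sub = table.select_otus(retained)
    null = permutation_null(sub, n_perm=n_perm, seed=seed, scheme=scheme)
    lo = np.quantile(null, alpha / 2, axis=0)
    hi = np.quantile(null, 1 - alpha / 2, axis=0)

    out = pd.DataFrame({
        "B_obs": b_all,
        "mean_rel_abund": mean_rel,
        "null_lower": np.nan,
        "null_upper": np.nan,
        "label": FILTERED,
    })
    out.loc[retained, "null_lower"] = lo
    out.loc[retained, "null_upper"] = hi
    b_ret = b_all.loc[retained].to_numpy()
    labels = np.where(b_ret > hi, "generalist",
                      np.where(b_ret < lo, "specialist", "opportunist"))
    out.loc[retained, "label"] = labels
    out.index.name = "otu_id"
    return out


def confusion_scores(result: pd.DataFrame, true_classes: pd.Series) -> pd.DataFrame:
    """Sensitivity/specificity per habitat class against planted truth.

    Scores are computed over the OTUs the classifier actually labeled:
    OTUs removed by the abundance filter were never candidates for a
    label, mirroring how the rare-OTU exclusion precedes classification
    in practice.
    """
    df = result.join(true_classes.rename("true_class"))
    df = df[df["label"] != FILTERED]
    rows = {}
    for cls in ("generalist", "specialist", "opportunist"):
        is_true = df["true_class"] == cls
        is_pred = df["label"] == cls
        if not is_true.any():
            continue
        rows[cls] = {
            "sensitivity": float((is_true & is_pred).sum() / is_true.sum()),
            "specificity": float((~is_true & ~is_pred).sum() / (~is_true).sum()),
            "n_true": int(is_true.sum()),
        }
    return pd.DataFrame(rows).T
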