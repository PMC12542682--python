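"""Co-occurrence networks and their stability analysis.

Networks are built per season and habitat class: OTUs passing an
occurrence (> 80% of samples) and mean relative abundance (> 0.05%)
filter become nodes; edges connect pairs with |Spearman rho| above 0.6
and Benjamini–Hochberg FDR below 0.05.  On top of the graph the module
computes topology metrics, Louvain modules, Zi–Pi node roles (keystones
= non-peripheral nodes), per-sample cohesion, spectral natural
connectivity, and node-removal robustness curves.

Graphs are plain ``networkx.Graph`` objects; nodes carry
``habitat_class`` and ``mean_rel_abund`` attributes and edges carry
``rho``, ``q`` and ``sign``.  Natural connectivity and topology treat
edges as unweighted (the correlation sign is metadata); shortest-path
metrics are computed on the largest connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .containers import OtuTable
from .io import logger, relative_abundance

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

REMOVAL_SCHEMES = ("random", "keystone_first", "remove_generalists",
                   "remove_specialists", "remove_opportunists")


# ------------------------------------------------------------- filter

def network_filter(table: OtuTable, min_occurrence: float = 0.8,
                   min_mean_abund: float = 5e-4) -> OtuTable:
    """Retain OTUs present in > ``min_occurrence`` of samples with mean
    relative abundance > ``min_mean_abund`` (both strict)."""
    rel = relative_abundance(table)
    occurrence = (table.to_dataframe() > 0).mean(axis=0)
    mean_rel = rel.mean(axis=0)
    keep = occurrence.index[(occurrence > min_occurrence)
                            & (mean_rel > min_mean_abund)].tolist()
    if not keep:
        raise ValueError(
            "no OTU passes the network filter "
            f"(occurrence > {min_occurrence}, mean abundance > "
            f"{min_mean_abund}); relax the thresholds"
        )
    return table.select_otus(keep)


# -------------------------------------------------------- construction

def build_network(table: OtuTable, r_threshold: float = 0.6,
                  q_threshold: float = 0.05,
                  labels: pd.Series | None = None) -> nx.Graph:
    """Spearman co-occurrence network with BH-FDR edge selection.

    All pairwise Spearman correlations (average ranks for ties, t
    approximation for p) are tested; BH correction runs over every
    tested pair; an edge requires |rho| > ``r_threshold`` and adjusted
    p < ``q_threshold``.  Constant OTU columns yield undefined
    correlations and stay isolated (warned).  The construction is fully
    deterministic.
    """
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples to build a network")
    counts = table.counts.astype(float)
    otus = table.otu_ids
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, counts / totals, 0.0)
    mean_rel = pd.Series(rel.mean(axis=0), index=otus)
    if len(otus) < 2:
        g = nx.Graph()
        for o in otus:
            g.add_node(o, mean_rel_abund=float(mean_rel[o]),
                       **({"habitat_class": labels.get(o, "unknown")}
                          if labels is not None else {}))
        return g
    constant = [o for o, col in zip(otus, counts.T) if np.ptp(col) == 0]
    if constant:
        logger.warning("build_network: %d constant OTU(s) left isolated",
                       len(constant))
    rho, pval = scipy.stats.spearmanr(counts, axis=0)
    rho = np.atleast_2d(rho)
    pval = np.atleast_2d(pval)
    iu = np.triu_indices(len(otus), k=1)
    rvec, pvec = rho[iu], pval[iu]
    ok = ~np.isnan(rvec) & ~np.isnan(pvec)
    qvec = np.full_like(pvec, np.nan)
    if ok.any():
        qvec[ok] = multipletests(pvec[ok], method="fdr_bh")[1]

    g = nx.Graph()
    for o in otus:
        attrs = {"mean_rel_abund": float(mean_rel[o])}
        if labels is not None:
            attrs["habitat_class"] = labels.get(o, "unknown")
        g.add_node(o, **attrs)
    for (i, j), r, q in zip(zip(*iu), rvec, qvec):
        if np.isnan(r) or np.isnan(q):
            continue
        if abs(r) > r_threshold and q < q_threshold:
            g.add_edge(otus[i], otus[j], rho=float(r), q=float(q),
                       sign=1 if r > 0 else -1)
    return g


def class_union_network(table: OtuTable, labels: pd.Series,
                        classes=("generalist", "specialist", "opportunist"),
                        min_occurrence: float = 0.8,
                        min_mean_abund: float = 5e-4,
                        r_threshold: float = 0.6,
                        q_threshold: float = 0.05) -> nx.Graph:
    """Entire-community network under the class-specific construction mode.

    The default pipeline runs the correlation analysis independently per
    habitat class (each class filtered and tested on its own relative
    abundances); the entire network is the union of those class
    networks.  Classes whose members all fail the filter contribute no
    nodes.  An induced-from-full-table analysis is available by calling
    :func:`build_network` on the jointly filtered table instead.
    """
    g = nx.Graph()
    for cls in classes:
        members = labels.index[labels == cls]
        members = [o for o in members if o in table.otu_ids]
        if not members:
            continue
        sub = table.select_otus(members).drop_empty_otus()
        if sub.n_otus < 2:
            continue
        try:
            filt = network_filter(sub, min_occurrence, min_mean_abund)
        except ValueError:
            logger.info("class_union_network: no %s passes the filter", cls)
            continue
        gc = build_network(filt, r_threshold, q_threshold, labels=labels)
        g = nx.compose(g, gc)
    if g.number_of_nodes() == 0:
        raise ValueError("no OTU of any class passes the network filter")
    return g


# ------------------------------------------------------------ topology

def topology_metrics(net: nx.Graph) -> tuple[dict, pd.DataFrame]:
    """Whole-network and per-node topology metrics.

    Shortest-path metrics (average path length, diameter) are computed
    on the largest connected component; density = 2E/(N(N−1)); avgK =
    2E/N; betweenness is normalized.  Returns ``(global_metrics,
    per_node_frame)``.
    """
    n, e = net.number_of_nodes(), net.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    comps = sorted(nx.connected_components(net), key=len, reverse=True)
    lcc = net.subgraph(comps[0]) if comps else net
    if lcc.number_of_nodes() >= 2:
        apl = nx.average_shortest_path_length(lcc)
        diam = nx.diameter(lcc)
    else:
        apl, diam = float("nan"), float("nan")
    if lcc.number_of_nodes() < n:
        logger.info("topology_metrics: path metrics on largest component "
                    "(%d of %d nodes)", lcc.number_of_nodes(), n)
    glob = {
        "n_nodes": n, "n_edges": e,
        "density": 2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        "avgK": 2.0 * e / n,
        "avg_path_length": float(apl), "diameter": float(diam),
        "lcc_fraction": lcc.number_of_nodes() / n,
    }
    betw = nx.betweenness_centrality(net, normalized=True)
    per_node = pd.DataFrame({
        "degree": pd.Series(dict(net.degree()), dtype=float),
        "betweenness": pd.Series(betw, dtype=float),
    })
    per_node.index.name = "otu_id"
    return glob, per_node


def detect_modules(net: nx.Graph, seed: int = 0) -> pd.Series:
    """Louvain modules (resolution 1); deterministic for a fixed seed.

    An edgeless graph puts every node in its own module (warned).
    Modules are renumbered by their smallest member id for stability.
    """
    if net.number_of_edges() == 0:
        logger.warning("detect_modules: edgeless graph; singleton modules")
        return pd.Series({node: i for i, node in enumerate(sorted(net))},
                         name="module_id")
    comms = nx.community.louvain_communities(net, seed=seed, resolution=1)
    comms = sorted(comms, key=lambda c: min(map(str, c)))
    out = {}
    for mid, members in enumerate(comms):
        for node in members:
            out[node] = mid
    return pd.Series(out, name="module_id")


def zi_pi(net: nx.Graph, modules: pd.Series) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation (Pi) per node.

    ``Zi = (k_own − mean(k_own | module)) / sd(k_own | module)`` (0 for
    singleton modules or zero sd); ``Pi = 1 − Σ_m (k_m / k)²`` (0 for
    isolated nodes).  Categories: network_hub (Zi > 2.5, Pi > 0.62),
    module_hub (Zi > 2.5), connector (Pi > 0.62), else peripheral.
    Keystones are all non-peripheral nodes.
    """
    missing = [v for v in net.nodes if v not in modules.index]
    if missing:
        raise ValueError(f"nodes without module assignment: {missing[:5]}")
    k_own = {}
    k_by_module = {}
    for v in net.nodes:
        counts: dict = {}
        for u in net.neighbors(v):
            counts[modules[u]] = counts.get(modules[u], 0) + 1
        k_by_module[v] = counts
        k_own[v] = counts.get(modules[v], 0)
    rows = {}
    module_stats = {}
    for mid in modules.unique():
        members = [v for v in net.nodes if modules[v] == mid]
        ks = np.array([k_own[v] for v in members], dtype=float)
        module_stats[mid] = (ks.mean(), ks.std(ddof=0)) if len(ks) else (0, 0)
    for v in net.nodes:
        k = net.degree(v)
        mean, sd = module_stats[modules[v]]
        zi = (k_own[v] - mean) / sd if sd > 0 else 0.0
        pi = 1.0 - sum((km / k) ** 2 for km in k_by_module[v].values()) \
            if k > 0 else 0.0
        if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
            cat = "network_hub"
        elif zi > ZI_THRESHOLD:
            cat = "module_hub"
        elif pi > PI_THRESHOLD:
            cat = "connector"
        else:
            cat = "peripheral"
        rows[v] = {"Zi": zi, "Pi": pi, "category": cat,
                   "module_id": int(modules[v]), "keystone": cat != "peripheral"}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "otu_id"
    return out


# ------------------------------------------------------------ cohesion

def cohesion(table: OtuTable, mode: str = "paper", corr: str = "spearman",
             n_null: int = 100, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample positive/negative cohesion and per-taxon connectedness.

    Connectedness of taxon *i* is the mean of its positive (resp.
    negative) pairwise correlations with the other taxa; cohesion of
    sample *j* is the relative-abundance-weighted sum ``C_j = Σ_i a_ij
    r̄_i``, so ``C_pos ≥ 0`` and ``C_neg ≤ 0``.  ``mode='null_corrected'``
    first subtracts the expectation of each pairwise correlation under
    ``n_null`` within-taxon shuffles.  Returns ``(per_sample,
    per_taxon)`` frames.
    """
    rel = relative_abundance(table)
    n_taxa = table.n_otus
    if n_taxa < 2:
        logger.warning("cohesion: single-taxon table; zero cohesion")
        zero = pd.DataFrame(0.0, index=table.sample_ids,
                            columns=["C_pos", "C_neg"])
        taxa = pd.DataFrame(0.0, index=table.otu_ids,
                            columns=["connectedness_pos", "connectedness_neg"])
        return zero, taxa
    if table.n_samples < 3:
        raise ValueError("cohesion needs at least 3 samples")

    def _corr(values: np.ndarray) -> np.ndarray:
        if corr == "spearman":
            c = scipy.stats.spearmanr(values, axis=0).statistic
        elif corr == "pearson":
            c = np.corrcoef(values, rowvar=False)
        else:
            raise ValueError(f"unknown correlation: {corr!r}")
        return np.nan_to_num(np.atleast_2d(c), nan=0.0)

    values = rel.to_numpy()
    cmat = _corr(values)
    if mode == "null_corrected":
        rng = np.random.default_rng(seed)
        acc = np.zeros_like(cmat)
        for _ in range(n_null):
            shuffled = np.empty_like(values)
            for j in range(n_taxa):
                shuffled[:, j] = rng.permutation(values[:, j])
            acc += _corr(shuffled)
        cmat = cmat - acc / n_null
    elif mode != "paper":
        raise ValueError(f"unknown cohesion mode: {mode!r}")
    np.fill_diagonal(cmat, 0.0)

    pos = np.where(cmat > 0, cmat, np.nan)
    neg = np.where(cmat < 0, cmat, np.nan)
    with np.errstate(invalid="ignore"):
        conn_pos = np.nan_to_num(np.nanmean(pos, axis=1), nan=0.0)
        conn_neg = np.nan_to_num(np.nanmean(neg, axis=1), nan=0.0)
    c_pos = values @ conn_pos
    c_neg = values @ conn_neg
    per_sample = pd.DataFrame({"C_pos": c_pos, "C_neg": c_neg},
                              index=table.sample_ids)
    per_taxon = pd.DataFrame({"connectedness_pos": conn_pos,
                              "connectedness_neg": conn_neg},
                             index=table.otu_ids)
    return per_sample, per_taxon


# ------------------------------------------------- natural connectivity

def natural_connectivity(net) -> float:
    """Spectral robustness: ``ln((1/N) Σ exp(λ_i))`` of the adjacency.

    Accepts a graph or an adjacency matrix; edges are unweighted.  An
    edgeless graph has NC = 0.
    """
    if isinstance(net, nx.Graph):
        if net.number_of_nodes() == 0:
            raise ValueError("natural connectivity undefined on empty graph")
        adj = nx.to_numpy_array(net, weight=None)
    else:
        adj = np.asarray(net, dtype=float)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
    n = adj.shape[0]
    eig = np.linalg.eigvalsh(adj)
    return float(logsumexp(eig) - np.log(n))


# ----------------------------------------------------------- robustness

@dataclass
class RobustnessCurve:
    """Natural-connectivity decline under cumulative node removal."""

    scheme: str
    points: pd.DataFrame   # columns: fraction_removed, natural_connectivity
    slope: float
    nc_before: float
    nc_after: float | None = None  # class schemes: NC after full removal

    def __repr__(self):
        return (f"RobustnessCurve({self.scheme}, {len(self.points)} points, "
                f"slope={self.slope:.3f})")


def _nc_curve(net: nx.Graph, order: list, fractions: np.ndarray,
              n_total: int) -> list[float]:
    out = []
    g = net.copy()
    removed = 0
    for f in fractions:
        target = int(round(f * n_total))
        while removed < target and removed < len(order):
            g.remove_node(order[removed])
            removed += 1
        if g.number_of_nodes() == 0:
            break
        out.append(natural_connectivity(g))
    return out


def keystone_order(net: nx.Graph, roles: pd.DataFrame) -> list:
    """Deterministic keystone removal order: network hubs, module hubs,
    connectors — each by descending degree, ties by id — then the rest."""
    rank = {"network_hub": 0, "module_hub": 1, "connector": 2,
            "peripheral": 3}
    return sorted(
        net.nodes,
        key=lambda v: (rank[roles.loc[v, "category"]], -net.degree(v), str(v)),
    )


def robustness(net: nx.Graph, scheme: str, step: float = 0.05,
               reps: int = 50, seed: int = 0,
               roles: pd.DataFrame | None = None,
               max_fraction: float = 1.0) -> RobustnessCurve:
    """Remove nodes cumulatively and track natural connectivity.

    ``random`` removes in random order (curve averaged over ``reps``
    replicates); ``keystone_first`` removes keystones (network hubs,
    then module hubs, then connectors, by descending degree) before the
    remaining nodes in random order; ``remove_<class>`` removes the
    members of one habitat class in random order (averaged over reps),
    the fraction axis being the fraction of that class removed.  The
    slope is the OLS slope of NC against fraction removed.

    ``max_fraction`` truncates the curve; comparing keystone-first with
    random removal is meaningful over the keystone share of nodes (the
    same proportion removed under both schemes), not over the full
    curve, where the already-collapsed keystone curve flattens.
    """
    if scheme not in REMOVAL_SCHEMES:
        raise ValueError(f"unknown removal scheme: {scheme!r}")
    rng = np.random.default_rng(seed)
    nodes = list(net.nodes)
    nc0 = natural_connectivity(net)
    nc_after = None

    if scheme.startswith("remove_"):
        cls = scheme.removeprefix("remove_").rstrip("s")
        members = [v for v in nodes
                   if net.nodes[v].get("habitat_class") == cls]
        if not members:
            raise ValueError(f"no node carries habitat class {cls!r}")
        pool, n_total = members, len(members)
        remainder = net.copy()
        remainder.remove_nodes_from(members)
        nc_after = (natural_connectivity(remainder)
                    if remainder.number_of_nodes() else float("nan"))
    else:
        pool, n_total = nodes, len(nodes)

    if not 0 < max_fraction <= 1:
        raise ValueError("max_fraction must lie in (0, 1]")
    fractions = np.arange(0.0, max_fraction + 1e-9, step)
    if fractions[-1] < max_fraction - 1e-9:
        fractions = np.append(fractions, max_fraction)
    if scheme == "keystone_first":
        if roles is None:
            roles = zi_pi(net, detect_modules(net, seed=int(rng.integers(2**31 - 1))))
        base = keystone_order(net, roles)
        n_key = sum(roles.loc[v, "category"] != "peripheral" for v in base)
        orders = []
        for _ in range(reps):
            tail = base[n_key:]
            orders.append(base[:n_key] + list(rng.permutation(tail)))
    else:
        orders = [list(rng.permutation(np.array(pool, dtype=object)))
                  for _ in range(reps)]

    curves = [_nc_curve(net, order, fractions, n_total) for order in orders]
    n_pts = min(len(c) for c in curves)
    mat = np.array([c[:n_pts] for c in curves])
    mean_nc = mat.mean(axis=0)
    pts = pd.DataFrame({"fraction_removed": fractions[:n_pts],
                        "natural_connectivity": mean_nc})
    if n_pts >= 2:
        slope = float(scipy.stats.linregress(
            pts["fraction_removed"], pts["natural_connectivity"]).slope)
    else:
        slope = float("nan")
    return RobustnessCurve(scheme=scheme, points=pts, slope=slope,
                           nc_before=nc0, nc_after=nc_after)
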