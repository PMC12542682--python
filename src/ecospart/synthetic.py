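"""Synthetic metacommunities with planted generalist/specialist structure.

The generator emulates a dendritic river survey: ``n_sites`` sites on a
line sampled in two seasons (wet/dry), an environmental gradient running
along the network that shifts between seasons, a Yule phylogeny whose
tips carry Brownian-evolved niche optima (so phylogenetic signal exists
at short phylogenetic distances), and three planted habitat classes:

* **generalists** — flat environmental response, low sampling noise, so
  their abundance profiles are broad and even;
* **specialists** — narrow Gaussian niche response around an inherited
  optimum, concentrating their abundance in the few samples whose
  environment matches it;
* **opportunists** — environment-blind taxa whose abundance in each
  sample is resampled from that sample's pool of generalist/specialist
  abundances.  Their spatiotemporal variation therefore matches the
  community's pooled variation but carries no niche structure, which is
  exactly the situation the classification's permutation null describes,
  so their niche breadth falls inside the null band by construction.

Counts are drawn multinomially per sample at a fixed depth, matching
rarefied data downstream.  All outputs are deterministic under a fixed
seed, and ground-truth labels/parameters are returned for
parameter-recovery tests.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import NUTRIENT_VARS, OtuTable, SampleMetadata

GENERALIST = "generalist"
SPECIALIST = "specialist"
OPPORTUNIST = "opportunist"

#: effective niche width assigned to flat-response generalists
GENERALIST_SIGMA = np.inf


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`simulate_metacommunity`."""

    classes: pd.Series
    niche_optimum: pd.DataFrame      # OTU × environmental axis
    niche_width: pd.Series           # per-OTU sigma (inf for generalists)
    base_log_abundance: pd.Series
    noise_sd: pd.Series              # per-OTU log-normal cell noise sd
    env: pd.DataFrame                # sample × axis environment values
    expected_relative_abundance: pd.DataFrame  # noise-free sample × OTU
    nutrient_weights: pd.DataFrame | None = None
    coupling: float | None = None

    def otus_of(self, label: str) -> list[str]:
        return self.classes.index[self.classes == label].tolist()


# ------------------------------------------------------------------ tree

def simulate_tree(n_tips: int, seed: int, prefix: str = "OTU") -> TreeNode:
    """Simulate a rooted Yule (pure-birth) tree with ``n_tips`` tips.

    Tips are labeled ``{prefix}00001 ...`` in a deterministic order;
    branch lengths are positive and the result is bit-reproducible for a
    fixed seed.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        rng=_random.Random(int(seed)),
    )
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = TreeNode.read([newick])
    width = max(5, len(str(n_tips)))
    for i, tip in enumerate(tree.tips()):
        tip.name = f"{prefix}{i + 1:0{width}d}"
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length <= 0:
            node.length = 1e-8
    tree.length = None
    return tree


def _brownian_tip_values(tree: TreeNode, rng: np.random.Generator) -> pd.Series:
    """Brownian motion along the tree; returns one value per tip."""
    values: dict[int, float] = {id(tree): 0.0}
    out = {}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        step = rng.normal(0.0, np.sqrt(max(node.length, 1e-12)))
        values[id(node)] = parent_val + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    return pd.Series(out)


# --------------------------------------------------------- metacommunity

def simulate_metacommunity(
    n_sites: int = 30,
    n_otus: int = 2000,
    prop_generalist: float = 0.10,
    prop_specialist: float = 0.50,
    env_axes: int = 1,
    depth: int = 110_394,
    seed: int = 0,
    *,
    sigma_specialist: tuple[float, float] = (0.008, 0.022),
    tail_weight: float = 0.004,
    tail_sigma: float = 0.5,
    baseline: float = 0.0001,
    base_log_sd: float = 0.5,
    noise_sd: float = 0.4,
    season_shift: float = 0.25,
    river_length_km: float = 100.0,
) -> tuple[OtuTable, SampleMetadata, TreeNode, SyntheticTruth]:
    """Simulate a two-season dendritic metacommunity with planted classes.

    Returns ``(OtuTable, SampleMetadata, tree, SyntheticTruth)`` with
    ``2 * n_sites`` samples.  Expected abundance of OTU *j* in sample *i*
    is ``exp(base_j) * response_ij`` where the response is flat for
    generalists and, for specialists (per axis, then multiplied),

    ``baseline + exp(-d^2 / (2 sigma_j^2)) + tail_weight * exp(-d^2 / (2 tail_sigma^2))``

    with ``d = E_i - mu_j``: a narrow peak that dominates the niche
    breadth plus a wide, low-amplitude response tail.  The tail mirrors
    how real habitat specialists remain detectable, with abundance
    graded by environmental distance, far from their optimum — it is
    what gives co-occurring specialists rank-correlated profiles and
    hence non-trivial co-occurrence networks.  Opportunists draw each
    cell from the sample's pooled generalist/specialist abundances (see
    module docstring).  Counts are multinomial at ``depth`` after
    per-cell log-normal noise.
    """
    if not (0 <= prop_generalist <= 1 and 0 <= prop_specialist <= 1):
        raise ValueError("class proportions must lie in [0, 1]")
    if prop_generalist + prop_specialist > 1 + 1e-12:
        raise ValueError("prop_generalist + prop_specialist must be <= 1")
    if n_sites < 4:
        raise ValueError("n_sites must be >= 4")

    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_otus, seed=int(rng.integers(2**31 - 1)))
    otu_ids = [t.name for t in tree.tips()]

    # class assignment with exact requested counts
    n_gen = int(round(prop_generalist * n_otus))
    n_spec = int(round(prop_specialist * n_otus))
    n_gen = min(n_gen, n_otus)
    n_spec = min(n_spec, n_otus - n_gen)
    labels = np.array(
        [GENERALIST] * n_gen + [SPECIALIST] * n_spec
        + [OPPORTUNIST] * (n_otus - n_gen - n_spec)
    )
    rng.shuffle(labels)
    classes = pd.Series(labels, index=otu_ids, name="true_class")

    # sites on a line; environment = gradient along the line + season shift
    positions = np.linspace(0.0, 1.0, n_sites)
    site_ids = [f"S{i + 1:02d}" for i in range(n_sites)]
    sample_ids, sample_site, sample_season, sample_pos = [], [], [], []
    for season in ("wet", "dry"):
        for sid, pos in zip(site_ids, positions):
            sample_ids.append(f"{sid}-{season}")
            sample_site.append(sid)
            sample_season.append(season)
            sample_pos.append(pos)
    sample_pos = np.asarray(sample_pos)
    is_dry = np.array([s == "dry" for s in sample_season])

    axis_names = [f"env{a + 1}" for a in range(env_axes)]
    E = np.empty((len(sample_ids), env_axes))
    for a in range(env_axes):
        site_noise = rng.normal(0.0, 0.03, size=n_sites)
        site_vals = positions + site_noise
        vals = np.concatenate([site_vals, site_vals])
        E[:, a] = vals + season_shift * is_dry
    env = pd.DataFrame(E, index=sample_ids, columns=axis_names)

    # niche optima: Brownian on the tree, mapped onto the gradient through
    # ranks -- close relatives keep close optima (phylogenetic signal at
    # short distances) while optima cover the gradient evenly
    mu = pd.DataFrame(index=otu_ids, columns=axis_names, dtype=float)
    lo, hi = E.min() - 0.05, E.max() + 0.05
    for a, name in enumerate(axis_names):
        z = _brownian_tip_values(tree, rng).reindex(otu_ids)
        u = (z.rank(method="first") - 0.5) / len(z)
        mu[name] = lo + u * (hi - lo)

    sigma = pd.Series(np.nan, index=otu_ids, name="niche_width")
    is_spec = (classes == SPECIALIST).to_numpy()
    is_opp = (classes == OPPORTUNIST).to_numpy()
    sigma[classes == GENERALIST] = GENERALIST_SIGMA
    sigma[is_spec] = np.exp(rng.uniform(
        np.log(sigma_specialist[0]), np.log(sigma_specialist[1]), is_spec.sum()
    ))

    base = pd.Series(rng.normal(0.0, base_log_sd, n_otus), index=otu_ids,
                     name="base_log_abundance")
    cell_sd = pd.Series(noise_sd, index=otu_ids, name="noise_sd")

    # expected (noise-free) weights for generalists/specialists
    response = np.ones((len(sample_ids), n_otus))
    sig = sigma.to_numpy()
    gauss = is_spec  # Gaussian niche response applies to specialists
    for a, name in enumerate(axis_names):
        d2 = (E[:, [a]] - mu[name].to_numpy()[None, :]) ** 2
        g = np.exp(-d2 / (2.0 * np.where(gauss, sig, 1.0)[None, :] ** 2))
        tail = tail_weight * np.exp(-d2 / (2.0 * tail_sigma**2))
        resp_a = np.where(gauss[None, :], baseline + g + tail, 1.0)
        response *= resp_a
    weights = np.exp(base.to_numpy())[None, :] * response

    noisy = weights * np.exp(
        rng.normal(0.0, 1.0, size=weights.shape) * cell_sd.to_numpy()[None, :]
    )
    # opportunists: redraw each cell from the sample's generalist/specialist
    # abundance pool -- unstructured variation matching the community's
    core = ~is_opp
    if is_opp.any() and core.any():
        for i in range(noisy.shape[0]):
            pool = noisy[i, core]
            noisy[i, is_opp] = rng.choice(pool, size=int(is_opp.sum()),
                                          replace=True)
            weights[i, is_opp] = pool.mean()
    expected_rel = weights / weights.sum(axis=1, keepdims=True)
    probs = noisy / noisy.sum(axis=1, keepdims=True)
    counts = np.empty_like(probs, dtype=np.int64)
    for i in range(len(sample_ids)):
        counts[i] = rng.multinomial(depth, probs[i])
    table = OtuTable(counts, sample_ids=sample_ids, otu_ids=otu_ids)

    meta_df = pd.DataFrame(
        {"season": sample_season, "site_id": sample_site}, index=sample_ids
    )
    meta_df = pd.concat([meta_df, env], axis=1)
    dk = np.abs(sample_pos[:, None] - sample_pos[None, :]) * river_length_km
    dendritic = pd.DataFrame(dk, index=sample_ids, columns=sample_ids)
    metadata = SampleMetadata(meta_df, dendritic)

    truth = SyntheticTruth(
        classes=classes, niche_optimum=mu, niche_width=sigma,
        base_log_abundance=base, noise_sd=cell_sd, env=env,
        expected_relative_abundance=pd.DataFrame(
            expected_rel, index=sample_ids, columns=otu_ids
        ),
    )
    return table, metadata, tree, truth


def simulate_null_table(n_samples: int = 60, n_otus: int = 1000,
                        depth: int = 20_000, noise_sd: float = 1.0,
                        seed: int = 0) -> OtuTable:
    """A habitat-structure-free table: i.i.d. log-normal cell weights.

    Cells are exchangeable within every sample, which is exactly the
    hypothesis of the within-sample permutation null, so classifier
    calibration can be checked against it.
    """
    rng = np.random.default_rng(seed)
    weights = np.exp(rng.normal(0.0, noise_sd, size=(n_samples, n_otus)))
    probs = weights / weights.sum(axis=1, keepdims=True)
    counts = np.empty_like(probs, dtype=np.int64)
    for i in range(n_samples):
        counts[i] = rng.multinomial(depth, probs[i])
    return OtuTable(
        counts,
        sample_ids=[f"N{i + 1:03d}" for i in range(n_samples)],
        otu_ids=[f"OTU{j + 1:05d}" for j in range(n_otus)],
    )


# ------------------------------------------------------------ nutrients

def simulate_nutrients(
    table: OtuTable,
    truth: SyntheticTruth,
    metadata: SampleMetadata | None = None,
    coupling: float = 0.8,
    noise_sd: float = 1.0,
    n_driver_otus: int | None = None,
    seed: int = 0,
) -> SampleMetadata:
    """Attach the eight nutrient variables, coupled to planted specialists.

    Each nutrient is ``coupling * z(signal) + (1 - coupling) * noise``
    where the signal is a weighted sum of a random subset of planted
    specialists' relative abundances (z-scored so the mixture is on a
    common scale), the noise is ``N(0, noise_sd)``, and the result is
    shifted to be strictly positive.  With ``coupling = 0`` nutrients are
    independent of the community; with ``coupling = 1`` and
    ``noise_sd = 0`` they are a deterministic function of it.

    ``n_driver_otus`` defaults to two-thirds of the planted specialists:
    nutrient cycling is an aggregate of many taxa's activities, so each
    nutrient integrates a broad specialist guild rather than a handful
    of taxa.

    Returns a new :class:`SampleMetadata` with nutrient columns added
    (an empty metadata frame is created when none is supplied) and
    records the driver weights on ``truth``.
    """
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rel = table.to_dataframe().astype(float)
    rel = rel.div(rel.sum(axis=1), axis=0)

    specialists = truth.otus_of(SPECIALIST)
    if not specialists:
        raise ValueError("truth contains no planted specialists to couple to")
    if n_driver_otus is None:
        n_driver_otus = max(1, (2 * len(specialists)) // 3)
    weights = pd.DataFrame(0.0, index=table.otu_ids, columns=list(NUTRIENT_VARS))
    nutrient_cols = {}
    for nut in NUTRIENT_VARS:
        k = min(n_driver_otus, len(specialists))
        drivers = list(rng.choice(specialists, size=k, replace=False))
        w = rng.uniform(0.5, 1.5, size=k)
        weights.loc[drivers, nut] = w
        signal = rel.loc[:, drivers].to_numpy() @ w
        ssd = signal.std()
        z = (signal - signal.mean()) / (ssd if ssd > 0 else 1.0)
        value = coupling * z + (1 - coupling) * rng.normal(
            0.0, noise_sd if noise_sd > 0 else 1e-12, size=len(z)
        )
        span = value.max() - value.min()
        value = value - value.min() + 0.05 * (span if span > 0 else 1.0)
        nutrient_cols[nut] = pd.Series(value, index=rel.index)

    truth.nutrient_weights = weights
    truth.coupling = coupling

    if metadata is None:
        base_df = pd.DataFrame(index=rel.index)
        dendritic = None
    else:
        metadata.validate_against(table)
        base_df = metadata.table.copy()
        dendritic = metadata.dendritic_km
    for nut, col in nutrient_cols.items():
        base_df[nut] = col.reindex(base_df.index)
    return SampleMetadata(base_df, dendritic)
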