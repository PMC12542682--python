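# Methods

This note documents the models and numerical choices behind `ecospart`:
what each statistic is, what the synthetic metacommunity generator does
and does not emulate, and where the design was genuinely open.

## Niche-breadth classification

Levins' breadth `B_j = 1/Σ_i P_ij²` is the inverse Simpson concentration
of OTU *j*'s abundance across the *N* samples, with `P_ij` the share of
the OTU's total abundance in sample *i*; it ranges from 1 (single
sample) to *N* (perfectly even). OTUs with mean relative abundance
below 2×10⁻⁵ are removed before testing (inclusive threshold: exactly
2×10⁻⁵ is retained) because taxa near the detection limit acquire
spuriously narrow breadths.

**Null model.** Breadth is order-free, so permuting one OTU's values
across samples changes nothing — a within-OTU null is degenerate. The
default null therefore shuffles abundances *across OTUs within each
sample*, preserving every sample's abundance pool while breaking the
OTU–sample association; a whole-table cell shuffle is available
(`scheme="whole_table"`). The null is applied per OTU over 1,000
permutations; the 95% band uses empirical type-7 quantiles, and
observations tied with a bound stay opportunist (conservative).
Classification pools all samples; per-season runs are a subset call
away.

A consequence of this null worth knowing: the band's location is set by
the *pooled* cell distribution. Communities containing taxa with
extreme local blooms push the band's lower bound toward 1, which can
mask true specialists. A quasiswap-style null that fixes per-OTU totals
would not share this property; it is not implemented because the
within-sample scheme is this package's documented default.

**Recovery scoring.** Sensitivity/specificity against planted labels
are computed over OTUs the classifier actually labels. The abundance
filter removes rare OTUs *before* classification — they were never
candidates, exactly as the rare-taxon exclusion is applied in practice —
and in synthetic surveys some 2–20% of planted specialists are rare
enough to be filtered.

## Synthetic metacommunity generator

The generator emulates a two-season dendritic river survey and is the
test bed for every downstream method. Defaults: 30 sites on a line
(dendritic distance = position difference × 100 km), wet and dry
seasons (60 samples), 2,000 OTUs (10% generalists, 50% specialists),
110,394 reads per sample drawn multinomially, one environmental axis
running along the network and shifted by +0.25 in the dry season.

* **Phylogeny and optima.** A Yule tree (birth rate 1) with Brownian
  trait evolution; tip values are rank-mapped onto the environmental
  range, so close relatives keep close optima (the short-distance
  phylogenetic signal βNTI requires) while optima cover the gradient
  evenly.
* **Generalists** respond flat; their variation is log-normal cell
  noise (σ = 0.4) plus multinomial sampling.
* **Specialists** respond as `baseline + exp(−d²/2σ_j²) +
  0.004·exp(−d²/0.5)` with σ_j log-uniform in [0.008, 0.022] and
  baseline 10⁻⁴. The narrow peak fixes the niche breadth; the wide,
  low-amplitude tail keeps specialists detectable river-wide with
  abundance graded by environmental distance — that grading is what
  gives co-occurring specialists rank-correlated profiles and hence
  non-trivial co-occurrence networks. Tail amplitude does not affect
  Spearman edges (ranks are scale-free) but does affect breadth, which
  is why it is small.
* **Opportunists** resample each cell from the sample's
  generalist+specialist abundance pool. They are exactly the taxa the
  permutation null describes — community-scale variation with no niche
  structure — so their breadth falls inside the 95% band by
  construction. (A wide-Gaussian opportunist cannot be placed inside
  the band robustly; its breadth would depend on every other generator
  knob.)
* **Nutrients.** Each of the eight variables is
  `coupling·z(signal) + (1−coupling)·noise`, the signal being a
  positively weighted sum of a random specialist guild's relative
  abundances, shifted positive. The guild defaults to two-thirds of
  the planted specialists: nutrient cycling is an aggregate of many
  taxa's activities, and small guilds leave the community-wide
  β-diversity signal too dilute to recover at survey sample sizes.
  `coupling = 0` makes nutrients independent of the community
  (calibration); `coupling = 1, noise = 0` makes them a deterministic
  function of it.

**What the generator does not emulate:** taxonomic structure, true
absences caused by dispersal history, compositional interactions beyond
the shared multinomial denominator, temporal autocorrelation within a
season, and realistic spatial branching (the dendritic network is a
line). Passing tests therefore demonstrate that the *methods* behave
correctly under a known, idealized niche/neutral mixture — not that any
particular real system will show the same effect sizes.

## Community assembly

βMNTD is abundance-weighted by default (`weighted=False` gives presence
weights); the βNTI null shuffles tip labels among the OTUs present in
the analyzed table, 999 (or a documented smaller number of)
randomizations, z-scoring the observed value. Pairs with zero null
standard deviation are reported missing and excluded (with a log
message) from process fractions.

RC_Bray uses the probabilistic assembly null: each sample keeps its
richness and total abundance, taxa are drawn ∝ occupancy frequency,
remaining individuals ∝ regional relative abundance; ties count half;
`RC = 2(F − 0.5) ∈ [−1, 1]`. One null metacommunity is assembled per
iteration and scored for every pair — per-pair marginals are identical
to drawing pair-specific nulls, at a fraction of the cost.

NST follows the taxonomic (Bray-Curtis) variant with the same null
engine: per pair, with observed dissimilarity D, C = 1−D, and null
expectations E_D/E_C, stochasticity is `E_D(1−D)/(D(1−E_D))` when
D ≥ E_D and the symmetric expression in similarities otherwise, so 1
means turnover indistinguishable from null and 0 maximal deviation;
group NST is the pair mean, cutoff 0.5. On dense synthetic tables whose
samples contain nearly the full regional pool (the generalist
subcommunity), the null's presence turnover vanishes and E_D collapses
toward multinomial noise, biasing NST downward for *all* groups; the
generalist-vs-specialist *contrast* is the meaningful readout there,
and it is what the validation battery checks.

The Mantel correlogram uses equal-width patristic distance classes;
the reported r is sign-flipped so positive means "more similar niches
than average at this distance", permutation p-values are two-sided with
Holm correction across classes. With a single class it degenerates to
the plain Mantel statistic between niche differences and patristic
distance.

## Networks

Edges need |Spearman rho| > 0.6 (average ranks, t-approximation
p-values) and BH-FDR q < 0.05 over all tested pairs of one construction
run; nodes are OTUs passing occurrence > 80% and mean relative abundance
> 0.05% (both strict). Correlation analyses run *per habitat class and
season* on the class's own relative abundances (class subtables carry
whole-community sample totals otherwise); the "entire network" is the
union of the class networks. An induced-from-full-table mode
(`build_network` on a jointly filtered table) exists, but at realistic
richness the joint 0.05% filter passes few specialists, so the union is
the default.

Topology treats edges as unweighted; path metrics use the largest
connected component (coverage logged); density = 2E/N(N−1),
avgK = 2E/N. Zi (within-module degree z-score, 0 for singleton or
zero-variance modules) and Pi (participation, 0 for isolated nodes) use
the Louvain partition at resolution 1; categories per the 2.5/0.62
thresholds; keystones are all non-peripheral nodes. Natural
connectivity is `ln(mean exp λ_i)` of the unweighted adjacency
(computed via logsumexp; 0 for an edgeless graph); it is monotone
non-increasing under edge removal.

Cohesion follows the printed abundance-weighted form: connectedness of a
taxon is the mean of its positive (negative) correlations with the
others, cohesion of a sample the relative-abundance-weighted sum. The
`null_corrected` mode subtracts a within-taxon shuffle expectation from
each correlation first; Spearman feeds cohesion by default, for
consistency with the network edges (Pearson available).

Robustness curves remove nodes cumulatively (random curves averaged over
replicates; keystone-first in the deterministic order network hubs →
module hubs → connectors, descending degree, ties by id). The
keystone-vs-random comparison is made over the keystone share of nodes
(`max_fraction`) — over the full curve the already-collapsed keystone
curve flattens and the comparison inverts. Class-removal schemes report
the NC before/after removing the whole class plus a within-class curve.

## Multi-nutrient cycling and BNC

MNC is the per-sample mean of min-max standardized nutrient columns
(constant columns are an error). The per-sample β-diversity scalar
defaults to LCBD (diagonal of the Gower-centered squared-dissimilarity
matrix, sums to 1); `mean_pairwise` is provided. Class β-diversity uses
Bray-Curtis on the class subtable renormalized per sample
(`relative=True`).

Random-forest ranking averages impurity (Gini) importances over many
forests with distinct sub-seeds; mean decrease accuracy is estimated by
permutation importance on a subset of the forests (sklearn exposes no
out-of-bag permutation importance); the cross-validation error curve
refits on nested top-k feature sets under repeated K-fold CV.

PLS-PM is Lohmöller's algorithm: standardized indicators, mode A outer
estimation, centroid inner scheme, convergence 10⁻⁶ (error after 300
iterations), latents oriented positively with their indicators; path
coefficients by OLS of each endogenous latent on its predecessors;
communality = mean squared loading per block (1 for single-indicator
blocks); `GOF = √(mean communality × mean R²)`; total effects sum
coefficient products over directed paths; percentile bootstrap
(500 resamples) gives path CIs.

## Problem sizes and determinism

The validation experiments run at documented scales chosen for
desk-scale feasibility: classifier calibration/recovery at the full
default conditions (60 samples × 2,000 OTUs × 1,000 permutations, five
replicates), βNTI/RC self-consistency with 199 randomizations, and the
50-replicate contrast battery at 30 sites × 300 OTUs × 110,394 reads.
The worked analysis in `analysis/` uses 30 sites × 600 OTUs. Every
randomized stage takes an explicit seed; pipeline-level master seeds
derive per-stage seeds via `stage_seed` (CRC32 of the stage name folded
into a SeedSequence), and the whole pipeline is bit-reproducible for a
fixed master seed.

## Known limitations

* The within-sample permutation null's 95% band depends on the pooled
  abundance distribution (see above); strongly bloom-dominated
  communities compress it.
* NST values on dense low-turnover tables are biased toward determinism
  for all groups; interpret contrasts, not absolute values, there.
* Spearman co-occurrence on compositional data inherits the usual
  compositionality caveats; SparCC-style corrections are out of scope.
* PLS-PM block composition for real surveys (which indicators enter
  "space" or "environment") is a modelling choice; the analysis scripts
  document one defensible default.
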