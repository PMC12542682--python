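# ecospart

Generalist/specialist partitioning of microbial metacommunities: who are
the habitat generalists and specialists in a survey, how differently are
their communities assembled, what do they contribute to co-occurrence
network stability, and which group sustains multi-nutrient cycling?

The package targets river (and comparable) microbiome surveys — an OTU
count table over sites × seasons, sample metadata with environmental and
nutrient measurements plus pairwise along-network ("dendritic")
distances, and a phylogeny of the OTUs — and implements the full
analysis chain:

1. **Niche-breadth classification** (`ecospart.niche`). Levins' breadth
   for OTU *j* over *N* samples, `B_j = 1 / Σ_i P_ij²`, where `P_ij` is
   the share of OTU *j*'s abundance in sample *i* (`B = 1`: confined to
   one sample; `B = N`: perfectly even). Each observed breadth is
   compared with the 95% band of a permutation null (1,000 within-sample
   shuffles of the relative-abundance table): above → **generalist**,
   below → **specialist**, inside → **opportunist**. OTUs with mean
   relative abundance < 2×10⁻⁵ are excluded first, because
   detection-limit absences mimic specialism.
2. **Diversity and distance decay** (`ecospart.diversity`). Richness,
   Chao1, ACE; Bray-Curtis β-diversity; PERMANOVA; Wilcoxon rank-sum
   comparisons; OLS of community similarity against dendritic or
   environmental distance with Mantel-permutation p-values.
3. **Community assembly** (`ecospart.assembly`). βMNTD/βNTI against a
   tip-shuffle null, Bray-Curtis Raup-Crick (RC) against a probabilistic
   assembly null, the five-process partition (heterogeneous/homogeneous
   selection, dispersal limitation, homogenizing dispersal, undominated;
   thresholds |βNTI| = 2 and |RC| = 0.95), the normalized stochasticity
   ratio (NST, cutoff 0.5), and a Mantel correlogram for phylogenetic
   signal in niche optima.
4. **Network stability** (`ecospart.network`). Per class and season:
   Spearman co-occurrence networks (|rho| > 0.6, BH-FDR q < 0.05, after
   an occurrence > 80% / mean abundance > 0.05% filter), topology
   metrics, Louvain modules, Zi-Pi node roles (keystones = non-peripheral
   nodes), per-sample cohesion, spectral natural connectivity
   `ln(mean exp λ_i)`, and node-removal robustness curves.
5. **Multi-nutrient cycling** (`ecospart.nutrients`). The MNC index
   (min-max standardize eight nutrient variables, average per sample),
   OLS of MNC on per-sample β-diversity (LCBD), repeated random-forest
   predictor ranking, and PLS path modeling (Lohmöller, mode A, centroid
   scheme) with goodness of fit `GOF = √(mean communality × mean R²)`.

Because raw survey data require external sequence processing, the
package ships a fully tested synthetic metacommunity generator
(`ecospart.synthetic`) that plants ground-truth generalists, specialists
and opportunists along a seasonal dendritic gradient — every analysis is
exercised end-to-end against known truth (see `docs/methods.md`).

## Worked example

`analysis/` contains the numbered pipeline over one simulated survey
(30 sites × 2 seasons, 600 OTUs, 110,394 reads/sample):

```bash
python analysis/01_simulate_survey.py
python analysis/02_classify_niche_breadth.py
...
python analysis/06_nutrient_bnc.py
```

Step 02 prints the classification and its recovery of the planted truth:

```
classification (60 samples pooled, 1000 permutations):
opportunist    292
specialist     222
generalist      75
filtered        11

recovery of planted labels (classified OTUs):
             sensitivity  specificity  n_true
generalist         1.000        0.972    60.0
specialist         0.737        0.970   289.0
```

i.e. every planted generalist is recovered, and the specialists the
classifier does call are almost never wrong (specificity 0.97).
Step 04 contrasts assembly processes — specialists are far more
deterministic (NST 0.06 vs 0.21–0.27 for generalists; both groups sit
below the 0.5 stochasticity cutoff in this synthetic design, see the
methods note) — and step 06 links biodiversity to nutrient cycling:

```
OLS of MNC on class β-diversity (wet season):
      predictor   slope  intercept     r2      p
generalist_beta -6.1688     0.6146 0.0626 0.1823
specialist_beta 34.4412    -0.7390 0.3070 0.0015

PLS-PM GOF = 0.544
direct effects on MNC: {'environment': 0.159, 'assembly': 0.189,
 'generalist_beta': -0.198, 'specialist_beta': 0.569}
```

The specialist β-diversity → MNC association is strong and significant;
the generalist one is not — the planted coupling is recovered.

A thin CLI mirrors the library: `ecospart simulate | classify |
diversity | assembly | network | bnc` (see `ecospart --help`); every
subcommand takes `--seed` and an optional YAML `--config`.

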