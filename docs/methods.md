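# Methods

`phyllonet` links three layers of a host–microbiome system: the
population-genetic structure of a host plant sampled from island and
mainland regions, the composition of its phyllosphere (leaf-associated)
fungal community, and the topology of the fungal co-occurrence network.
This note records the models, the estimators, the numerical
conventions, and the choices made where the design was genuinely open.

## Study design assumed throughout

Two regions (a "mainland" and an "island" group), three populations per
region, ten plants per population (60 plants), genotyped at 11
polymorphic microsatellite loci; per plant an ITS-style OTU count table
rarefied to a common depth of 5415 reads, on the order of 700–800 OTUs
after filtering. All thresholds that drive decisions are pipeline
defaults: OTUs with fewer than 10 total reads are discarded;
best-hit taxonomy is rejected outright above e-value 1e-50 and
truncated by identity (≥90 % genus, ≥85 % family, ≥80 % order, ≥75 %
class, below that kingdom only); network OTUs need ≥0.01 % overall
relative abundance; edges need |Spearman rho| > 0.6 with
Benjamini–Hochberg-adjusted p < 0.05; indicator OTUs need a
logarithmic effect score ≥ 3.0; keystone roles use Zi = 2.5 and
Pi = 0.62.

## Host population genetics

**Observed heterozygosity (Ho)** is the per-locus fraction of
heterozygous individuals among non-missing calls, averaged unweighted
over loci. A locus with no data in a group is dropped from that group's
mean (the allele-frequency accessor, by contrast, treats an empty
group × locus cell as an error, because downstream distances cannot be
formed from it).

**Nei's standard genetic distance** (1972) averages the gene identities
Jx, Jy, Jxy arithmetically across loci before forming
`D = −ln(Jxy/√(Jx·Jy))`; the small-sample-corrected 1978 estimator is
available by flag. Populations sharing no alleles have infinite D; the
matrix carries the infinity explicitly and ordination refuses it with a
clear error unless the caller caps it.

**AMOVA** decomposes squared inter-individual distances — the number of
allele differences per locus (0, 1 or 2, the multiset-intersection
complement), summed over pairwise-complete loci — into among-region,
among-population-within-region, and within-population components by the
standard method of moments with unequal-size coefficients. Fixation
indices are ratios of components; a totally monomorphic dataset reports
F_CT = 0 by convention. Significance of F_CT permutes whole populations
among regions. With six populations in two groups of three there are
exactly 20 distinct assignments, so the implementation **enumerates
them exactly** (p has resolution 1/20 and minimum 0.1, attained when the
observed split maximizes F_CT together with its mirror image); a sampled
permutation null is used above eight populations, and an
individual-level permutation scheme (`permute="individuals"`) is
available when finer resolution is wanted. End-to-end checks therefore
call an AMOVA "significant" at p ≤ 0.1 under the population scheme —
the exact test's floor — rather than at a nominal 0.05 it cannot reach.

**PGE (plant genetic eigenvectors)** are PCoA axes of an
individual-level genetic distance. Nei's formula degenerates for
single-individual "populations", so the individual distance is the
allele-sharing distance `1 − shared/2` averaged over
pairwise-complete loci; this is documented and swappable.

**Isolation by distance** is a Mantel test of population Nei distance
against great-circle geographic distance (haversine, Earth radius
6371.0 km).

## Ordination, clustering, permutation machinery

**PCoA** Gower-centres −½D² and keeps only positive-eigenvalue axes
(no Lingoes/Cailliez correction; a strict mode errors on non-Euclidean
input instead). Axis *i* is scaled to norm √λᵢ, and its sign is fixed
so the largest-magnitude loading (first such index on ties) is
positive. Eigenvalues below `max(|λ|)·1e-10` are treated as zero.

**UPGMA** agglomerates by average linkage with node height equal to
half the between-cluster average distance, so cophenetic distances
reproduce an ultrametric input exactly. Ties merge the pair whose
lexicographically smallest member labels sort first, making dendrograms
deterministic. Newick output uses height differences as branch lengths.

**PCNM** spatial eigenvectors truncate the geographic distance matrix
at the longest minimum-spanning-tree edge, replace larger entries by
four times the threshold, and take the positive-eigenvalue PCoA axes.
All positive axes are retained (no Moran's-I screening). Because plants
share site coordinates, axis values are constant within site.

**Permutation convention.** Every permutation p-value is
`(1 + b)/(1 + n_perm)` — never zero. Strata restrict permutations to
within-stratum shuffles (used for PERMANOVA's "population as a random
effect" reading). The Mantel test is one-sided (greater) by default,
the ecological convention; CADM permutes every matrix except the first
(reference) and uses tie-corrected Kendall W. 999 permutations is the
default everywhere; calibration tests use fewer (19–99) to keep
Monte-Carlo blocks fast, which only coarsens the p-value grid.

**Seeding discipline.** Data-generation seeds and permutation-test
seeds must come from different streams: `default_rng(k)` reproduces the
same bit stream wherever the same small integer `k` is reused, which
can correlate the first null permutations with the data (observed as a
few extra percent of null rejections before the pipeline adopted
hashed per-stage substreams). The pipeline derives each stage's seed as
a hash of `(global seed, stage name)`; rarefaction uses a per-sample
stream keyed by `(seed, crc32(sample id))` so results are independent
of sample order.

## Community composition

Rarefaction subsamples without replacement (multivariate
hypergeometric) to exactly the target depth; the analytic rarefaction
curve uses `E[S_m] = Σᵢ [1 − C(N−Nᵢ, m)/C(N, m)]` in log-gamma
arithmetic. Hellinger-transformed counts feed Bray–Curtis
dissimilarities.

**ANOSIM** uses the rank-based statistic `R = (r̄_between − r̄_within)/(M/2)`.
**PERMANOVA** performs a sequential (Type I) decomposition of the
Gower-centred matrix over ordered predictor blocks via projection
traces (`SS = tr(HG)`); each term's pseudo-F uses the full-model
residual; permutations shuffle sample identities of G within strata.
Term order follows the convention host-genetic block, geographic block,
MAP, MAT, elevation. Rank-deficient terms are skipped with a warning.

**Forward selection** of PGE/PCNM axes is greedy on sum-of-squares
gain. The admission test compares the observed best gain against the
permutation null of the **maximum** gain over all remaining candidates;
testing the best of k candidates against a per-candidate null would
admit noise axes at roughly k·α, whereas the max-null keeps the
familywise admission rate at α (all-noise inputs stay empty ~95 % of
the time at α = 0.05).

**Wilcoxon rank-sum**: exact enumeration of all label arrangements when
the pooled sample size is ≤ 12 (ties get half credit in U, so tied
small samples are also exact); the normal approximation with tie and
continuity corrections above that.

**Indicator OTUs** (two classes): counts are normalized to one million
per sample; a Kruskal–Wallis screen at α = 0.05 is followed by an
effect size — the mean over 30 bootstrap rounds (two-thirds
subsampling per class, without replacement) of log10 |difference of
class means|, clamped below at zero — thresholded at 3.0 and signed by
the enriched class. This is a deliberate two-class simplification of
the published LEfSe procedure (no subclass logic, a mean-difference
effect in place of the multivariate LDA axis); output columns mirror
LEfSe's (feature, class, effect, p).

## Co-occurrence networks

Edges come from all-pairs Spearman correlations (midranks; t-approx
p-values; a constant OTU gets rho 0 / p 1 and can never form an edge)
computed on rarefied counts — equal depths make counts and relative
abundances rank-identical up to ties, and a flag switches to relative
abundance. Upper-triangle p-values are BH-adjusted jointly; the edge
rule is |rho| > 0.6 **and adjusted** p < 0.05 (raw-p mode is available
and labelled). Isolated nodes are dropped by default.

Modules are Louvain partitions of the unweighted graph, best of 10
seeded restarts by Newman–Girvan modularity, first-found on ties;
an edgeless graph gets singleton modules with Q = 0. Per-plant
subnetworks are node-induced subgraphs on the OTUs present in that
plant and inherit the parent partition (no re-detection), keeping node
role identities comparable across plants; re-detection is a flag.

Topology metrics: nodes, edges, average degree 2E/N, Freeman degree
centralization `Σ(dmax−dᵢ)/((n−1)(n−2))`, closeness centralization with
closeness computed inside each connected component and normalized by
`(n−1)(n−2)/(2n−3)` on the full n (a repository convention — published
tools differ on disconnected graphs), and modularity. Centralizations
are defined as 0 for n < 3. Erdős–Rényi G(n, m) baselines match
observed node and edge counts exactly.

Zi (within-module degree z-score, population SD, 0 when the SD is 0)
and Pi (participation coefficient, 0 for isolated nodes) classify
roles with strict inequalities: module hub Zi > 2.5, connector
Pi > 0.62, network hub both, peripheral otherwise — a node exactly at
a threshold is peripheral-by-complement. Keystones are all
non-peripheral nodes. Note that a node whose links split over only two
modules has Pi ≤ 0.5 and can never be a connector at the 0.62
threshold.

## Driver attribution

**Random forest**: regression forests (mtry = p/3) per network metric;
importance is the permutation increase in MSE of the fitted forest
evaluated on the full sample (scikit-learn exposes no public
out-of-bag permutation importance; the full-sample variant ranks
predictors the same way). Significance refits the forest on
response-permuted data: p = (1 + #{null importance ≥ observed})/(n_perm + 1).

**Multispecies GLM**: per OTU a negative-binomial (NB2, log link)
regression with ML dispersion (statsmodels; Poisson fallback on
optimizer failure); the community statistic TS for a term is the sum
over OTUs of the likelihood-ratio statistics between sequential designs
with and without the term, floored at zero against optimizer noise.
p-values permute response rows jointly (unrestricted row permutation in
place of PIT-trap resampling — adequate at these scales and exact under
row exchangeability). The intercept-only log-likelihood is cached
across permutations (it depends only on the count multiset). The
pipeline runs the GLM on the most abundant OTUs (default 40) because
fitting two NB models per OTU per permutation is the most expensive
step of the whole pipeline.

## The synthetic generator

The generator is the package's test bed: it emits genotype, geography,
climate and OTU-table files in exactly the dialects the analysis
modules read, plus a ground-truth JSON that analysis code never reads.

*Genotypes* follow a hierarchical Balding–Nichols model: ancestral
allele frequencies per locus are symmetric-Dirichlet over 8 alleles;
regional frequencies are Dirichlet draws with concentration
`p(1−F)/F` at F = 0.10 between regions, and population frequencies
diverge at F = 0.05 within regions; diploids draw two alleles
independently. These defaults reproduce the magnitude of regional
differentiation the design assumes (estimated F_CT ≈ 0.10–0.14; the
allele-difference AMOVA estimator runs slightly above the nominal F,
which the ±0.05 recovery band absorbs).

*Geography/climate*: two coastal-subtropical coordinate clusters
~100 km apart; plants inherit site coordinates; MAT/MAP carry regional
offsets (+1 °C, +250 mm on the mainland) with site noise; mainland
sites sit higher (200–400 m vs 40–160 m).

*OTU table*: a latent Gaussian factor model mapped through `exp` to
relative abundances and sampled multinomially at the raw per-sample
depth (5415 + margin, so depth 5415 survives the count filter). A
Gaussian copula was chosen because Spearman correlations are invariant
to the monotone `exp`, giving a tunable rank-correlation target.
Components:

- **Modules**: 6 blocks of 15 OTUs, each loading √0.75 on its own
  latent factor (within-block correlation 0.75 — comfortably above the
  0.6 edge rule, which is what makes the planted blocks recoverable as
  network modules at n = 60).
- **Hub**: one abundant OTU whose latent variable enters the five
  non-region module factors with loading 0.84. Member–hub correlation
  is then 0.84·√0.75 ≈ 0.73 (above the edge rule after count-noise
  attenuation), while member–member correlation across coupled modules
  is 0.84²·0.75 ≈ 0.53 (safely below it, so the modules stay separate).
  Coupling fewer modules makes the hub's participation coefficient
  hover around the 0.62 connector threshold; spanning five makes its
  keystone classification a robust consequence of the construction.
- **Host effect**: 40 OTUs shift along the first PCoA axis of the
  allele-sharing genetic distances with coefficient β = 1.0. The axis
  sign (arbitrary in PCoA) is oriented toward the mainland so the
  planted associations are positive, matching the overwhelmingly
  positive association pattern of real phyllosphere networks (the
  generator's networks are ≥ 99 % positive edges).
- **Region module**: the sixth module is mainland-enriched by 4 log
  units, so its members are abundant on the mainland and mostly absent
  from island plants. This one block produces both the regional
  composition shift (ANOSIM/PERMANOVA/indicator signal) and the denser
  mainland per-plant subnetworks (more present module nodes → more
  edges and higher degree), without inflating between-module
  correlations elsewhere.
- **Noise**: the remaining ~640 OTUs are independent, with log-normal
  baselines `N(1.0, 1.2)` chosen so that unstructured OTUs carry most
  of the read mass; if the correlated blocks dominated the multinomial
  denominator, compositional closure would attenuate the very
  correlations the blocks plant (this was measurable as ~0.1 lost
  Spearman before the noise floor was raised).
- **Rare tail**: 40 extra OTUs with 1–9 total reads, destined for the
  count filter.

What the generator does **not** emulate: phylogenetic structure among
OTUs, overdispersion beyond the log-normal latent (a knob exists but
the default is plain multinomial, consistent with operating
post-rarefaction), PCR/chimera artefacts, distance decay within
regions, and any negative planted associations. Passing tests
therefore show the estimators recover planted structure of this kind
at this scale — not that real phyllosphere data satisfy the model.

## Test-suite problem sizes

Calibration blocks use 100–400 replicates at reduced permutation
counts (19–99) and small designs (n = 14–25); recovery and end-to-end
checks use 20 seeds of the full default design (60 plants, 772 + 40
OTUs, depth 5415). The acceptance script runs one full pipeline pass
(999 permutations for the distance-based tests, 49/99 for forest/GLM)
plus a five-seed recovery summary.

## Known limitations

- The AMOVA F_CT population-permutation test is exact but has
  resolution 1/20 in the 6-population design; claims of significance
  at that level mean "the observed split is extremal among all
  assignments".
- Nei distances are undefined (infinite) between populations sharing
  no alleles; the pipeline caps them at 10 for ordination and the cap
  is configurable.
- The NB dispersion ML estimate is unstable for very sparse OTUs; the
  Poisson fallback under-states the likelihood there, which is
  conservative for the permutation TS test but can cost power.
- Closeness centralization on disconnected graphs follows the
  within-component convention described above and will differ from
  tools that use other conventions.
- The indicator screen is not LEfSe: no subclass consistency checks,
  and the effect size is a bootstrap mean-difference score, not an LDA
  projection.
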