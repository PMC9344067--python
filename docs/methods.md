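# Methods

This note records the statistical definitions, conventions and design
choices `micronet` implements, in the order the pipeline applies them.

## Input model

The root input is an OTU × sample matrix of non-negative integer read
counts with a taxonomy table (kingdom ∈ {Bacteria, Fungi}, then
phylum…genus, gaps marked `unclassified`) and per-sample metadata: eight
soil variables — pH, EC (mS/cm), OM (mg/g), TN (mg/kg), NH4_N (mg/kg),
NO3_N (mg/kg), TP (mg/g), AK (mg/kg) — plus a habitat-group label.
Relative abundances close each sample to 1. "Detected" always means raw
count > 0; the prevalence rule for network inference keeps OTUs detected in
strictly more than `prevalence_min_samples` samples (default 8, i.e. ≥ 9 of
15). The filter is applied to the pooled two-kingdom matrix before
screening; abundance classification defaults to the full table
(configurable), since rarity judgements should not depend on a
network-motivated filter.

## Diversity

Shannon entropy is reported in nats (a log-base flag gives bits); Chao1
uses the bias-corrected estimator S_obs + F₁(F₁−1)/(2(F₂+1)), with the
classic F₁²/(2F₂) form behind a flag. Rarefaction subsamples without
replacement (multivariate hypergeometric draws) and averages observed
richness over replicates. Group comparisons use one-way ANOVA with Tukey
HSD at α = 0.05 and a greedy compact-letter display: groups are processed
in order of descending mean and share a letter whenever all pairwise
comparisons within the letter set are non-significant.

## Ordination and community–environment tests

Bray–Curtis d(u,v) = 1 − 2Σmin(uᵢ,vᵢ)/(Σu+Σv) on sample profiles. PCoA is
classical scaling; negative eigenvalues (Bray–Curtis is non-Euclidean) are
zeroed and excluded from the explained-variance denominator, the common
default. PERMANOVA follows Anderson's partition of squared distances;
R² = SS_between/SS_total is computed from that partition directly, while
pseudo-F and the permutation p-value p = (1 + #{F* ≥ F})/(1 + n_perm) come
from scikit-bio's seeded implementation (the two routes are cross-checked
in the tests). Procrustes is symmetric — both configurations centred and
scaled to unit sum of squares before the optimal rotation — so M² ∈ [0, 1];
the PROTEST p permutes rows of the second configuration. The environment
side of the comparison is a PCA of standardised soil variables with
min(#variables, n−1) axes, a choice left open by convention and fixed here
for symmetry with the community PCoA. CCA regresses the chi-square
transformed community matrix on standardised environment variables; the
constrained fraction is the constrained share of total inertia, with the
number of constrained axes set by the rank of the environment matrix
(rank deficiency is reported, constant variables dropped with a warning).
CCA operates on relative abundances; permutation counts default to 999.

## Six-class abundance scheme

With m and M the minimum and maximum per-sample relative abundance of an
OTU, and thresholds a = 1% and r = 0.01%: AAT iff m > a; ART iff M < r;
CRAT iff m < r and M > a; CAT iff M > a and m ≥ r; CRT iff M ≤ a and
m < r; MT otherwise. Boundary values (exactly a or r) are resolved by the
≥/≤ conventions so the six classes partition every profile — the verbal
definitions use open inequalities that leave boundaries undefined.
Abundant = {AAT, CAT, CRAT}; rare = {ART, CRT}; MT is neither. (A common
statement of this scheme lists CAT among the rare classes in one clause;
that is inconsistent with CAT's own definition and is treated here as a
slip for CRT.)

## Network inference

Spearman ρ with average ranks over all unordered OTU pairs of the
prevalence-filtered relative-abundance table; two-sided p by the t
approximation with n−2 df (standard at n = 15); BH-FDR over all pairs
tested, with the number of tests logged. An edge requires |ρ| > 0.8 and
q < 0.05. Two deliberate readings: the correlation threshold acts on |ρ|
(a positive-only rule could never produce the minority of negative edges
such networks report), and significance acts on the FDR-adjusted value
(a raw-p mode exists for comparability). Correlations are computed on
relative abundances; a config switch allows counts. OTUs constant across
samples are excluded and logged. Isolated OTUs never enter the graph.

## Topology and null model

APL is the mean shortest-path length over all reachable ordered pairs
(self-pairs excluded), which stays defined for disconnected graphs; the
diameter is confined to the largest connected component; ACC is the mean
local clustering with degree < 2 contributing 0. Modularity and Louvain
module detection are unweighted and sign-blind (one modularity value is
reported for a signed network, so a signed variant would be a different
statistic), deterministic given the seed. The degree power law is fitted by
least squares on (ln k, ln count(k)) over degrees with positive counts —
the "R² of the power law" convention — requiring at least three distinct
degrees. The null model is G(n, m) with exactly the observed edge count, m
edges drawn uniformly from the pair universe via the package RNG; 100
realizations by default. Because the convention behind a published "±" on
null-ensemble rows is typically unstated, both the ensemble sd and the se
of the mean are reported. python-igraph supplies the C-speed path and
clustering kernels; the test suite proves those kernels equal brute-force
BFS/triangle-counting oracles under exactly the conventions above on 100
random graphs.

## Node roles and keystones

For node i in module s: Zi = (k_is − mean_s)/sd_s with the population sd
over module members (sd_s = 0 ⇒ Zi = 0), and Pi = 1 − Σ_t (k_it/k_i)².
Roles at Zi* = 2.5, Pi* = 0.62: peripheral / connector / module hub /
network hub; boundary equality goes to the peripheral side since the
defining inequalities are strict. Generalists (non-peripherals) are the
keystone candidates, summarised by kingdom and abundant/rare dichotomy.
Edge signs are ignored for connectivity, consistent with the topology
stage.

## Subnetworks and environment

Each sample induces a subgraph on the network nodes with count > 0 in that
sample (a relative-abundance floor is configurable); modularity is
recomputed per subgraph with a fixed seed. Every (soil variable, topology
property) pair gets a Spearman ρ and two-sided p (Pearson by flag);
significance flags use raw p at α = 0.05 with BH q reported alongside,
since such heatmaps are conventionally unadjusted.

## Synthetic generator

The generator emulates the *output* of an amplicon survey, not sequencing
itself: default 15 samples in five habitat groups, 2000 bacterial and 300
fungal OTUs, log-normal baseline abundances (σ = 2 on the log scale, giving
the heavy tail and sparsity of real tables), mean depth 30 000 reads.
Planted structure lives on a latent Gaussian scale: module members share a
factor with weight w = 2 sin(πρ_s/6) so the latent Pearson correlation
corresponds to the target Spearman ρ_s (default 0.9); negative edges come
from sign-flipped loadings, with per-module flip counts chosen to
approximate the target negative-edge fraction (default 5%), and kingdom
mixing chosen the same way to approximate the inter-kingdom edge fraction.
Environment coupling adds β · (standardised variable) to the latent scale
of selected taxa. Counts are Poisson draws around log-normal-perturbed
expected values (dispersion = 0 short-circuits to rounded expectations, a
noise-free limit used by limit-case tests). What this does *not* emulate:
compositional log-ratio effects beyond closure, sequencing error, phylogenetic
correlation, or spatial autocorrelation among samples — so green tests show
the chain recovers planted monotone structure from realistic count noise,
not that real soil communities satisfy the model.

## Problem sizes and determinism

Tests and examples run the generator at tens-to-hundreds of OTUs and the
null ensembles at the reference network scale (745 nodes, 1800 edges, 100
realizations), sizes chosen so the full suite completes in well under a
minute while Monte-Carlo errors stay far below the tolerances asserted.
Every stochastic stage (generator, permutation tests, Louvain, ensembles,
rarefaction) takes an explicit seed; the pipeline derives stage seeds from
one master seed and records them in the run manifest, so identical configs
give byte-identical outputs.

## Known limitations

Spearman screening on relative abundances is blind to compositional
artefacts (no SparCC/SPIEC-EASI-style correction); the power-law R² is a
descriptive regression, not a maximum-likelihood tail test; Louvain is a
heuristic whose partition (not its determinism) can vary across seeds;
PERMANOVA assumes exchangeability within groups; and the greedy letter
display can, for pathological significance patterns, use more letters than
the minimal clique cover.
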