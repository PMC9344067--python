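# micronet

Inter-kingdom microbial co-occurrence network analysis for OTU tables.

`micronet` is a Python library for the downstream community analysis of
paired bacterial (16S) and fungal (ITS) OTU count tables from environmental
surveys — soils, sediments, rhizospheres — where the questions are: how
diverse is each sample, does composition track habitat and soil chemistry,
which taxa co-occur across samples, and which taxa hold the co-occurrence
network together?

It is aimed at microbial ecologists who already have OTU tables (from
QIIME/Uparse-style upstream processing) plus a table of soil variables, and
want a scripted, reproducible version of the standard analysis chain
instead of a pile of one-off R snippets.

## What it computes

* **Alpha diversity** — observed richness, Shannon H = −Σ pᵢ ln pᵢ,
  bias-corrected Chao1 = S_obs + F₁(F₁−1)/(2(F₂+1)), rarefaction curves,
  and one-way ANOVA across habitat groups with Tukey-HSD letter displays.
* **Beta diversity / ordination** — Bray–Curtis distances, PCoA, PERMANOVA
  (pseudo-F, R², permutation p), symmetric Procrustes M² with PROTEST
  permutation test against a PCA of the soil variables, and CCA with the
  constrained fraction of inertia.
* **Six-class abundance scheme** — each OTU is classed from the min/max of
  its per-sample relative abundance against 1% and 0.01% thresholds
  (AAT/CAT/ART/CRT/MT/CRAT), with the derived abundant/rare dichotomy.
* **Network inference** — Spearman ρ over all OTU pairs present in more
  than eight samples, BH-FDR correction, signed edges where |ρ| > 0.8 and
  q < 0.05.
* **Topology** — density, average clustering coefficient (ACC), average
  path length over reachable pairs (APL), diameter, Louvain modularity,
  log–log degree power-law R², edge-sign fractions; all compared against
  Erdős–Rényi G(n, m) null ensembles for the small-world diagnosis.
* **Keystones** — within-module connectivity Zi and among-module
  connectivity Pi per node, the four-quadrant role rule at (2.5, 0.62),
  and generalist summaries by kingdom and abundance class.
* **Link partitions** — bacteria–bacteria / bacteria–fungi / fungi–fungi
  edge counts and the phylum-pair matrix behind chord diagrams.
* **Subnetworks vs environment** — per-sample induced subgraphs, their
  topologies, and Spearman correlations with each soil variable.
* **Synthetic data** — a generator that plants known correlation modules,
  signs, and environment couplings in realistic two-kingdom count tables,
  so the whole chain can be validated against ground truth.

## Worked example

`examples/` contains one narrative script per capability. For instance,
comparing a network-scale Erdős–Rényi null ensemble with a clustered graph
(`examples/04_random_null_and_small_world.py`) prints:

```
ER null ensemble, 100 x G(745, 1800):
  mean APL = 4.36 +/- 0.02 (sd), se 0.002
  mean ACC = 0.0063 +/- 0.0018 (sd)

Watts-Strogatz comparison graph (1490 edges): ACC=0.370, APL=8.53
  ACC ratio vs null = 82.2 (z = 200.1), APL ratio = 1.75
```

A random graph of 745 nodes and 1800 edges has short paths (≈4.4 steps) and
essentially no clustering (ACC ≈ 0.006, i.e. the edge density); a clustered
network of the same size shows an ACC tens of times the null mean — the
small-world signature.

Running the full pipeline on a synthetic community with planted structure
(`examples/01_simulate_and_run_pipeline.py`) prints:

```
OTUs in / filtered:    380 / 380
OTU pairs screened:    72010
network nodes, edges:  55, 87
modularity Q:          0.837
planted-edge recovery: precision=0.90, recall=0.70, sign agreement=1.00
```

meaning 90% of inferred edges were genuinely planted, 70% of planted
correlations survived the conservative |ρ| > 0.8 screen at n = 15, and every
recovered edge got the correct sign.

The same chain is available from the shell:

```bash
micronet run --synthetic --outdir out --seed 1
micronet simulate --outdir data --seed 1
```

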