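"""Synthetic two-kingdom OTU tables with planted correlation structure.

The generator emulates the *output* of an amplicon workflow on a soil
survey: ~15 samples in a few habitat groups, thousands of bacterial and
hundreds of fungal OTUs, heavy-tailed abundances, sparsity, and eight soil
variables (pH, EC, OM, TN, NH4_N, NO3_N, TP, AK) coupled to a subset of
taxa.

Correlation structure is planted on a latent Gaussian scale: members of a
module share a per-sample factor, z_i = s_i * sqrt(w) * F_m + sqrt(1-w) *
eps_i, where the loading weight w = 2 sin(pi * rho_s / 6) converts the
target Spearman rho_s into the latent Pearson correlation of a bivariate
normal.  Negative planted edges arise by sign-flipping s_i for some module
members.  Counts are realised through exp(mu_i + z_i) closed per sample,
scaled to the sequencing depth and drawn as overdispersed (log-normal-
Poisson) counts; the pipeline only ever sees those counts, so recovery is
judged on sample Spearman correlations, not latent values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import ENV_VARS, RANKS, AbundanceTable, SampleMetadata, TaxonomyMap

# value ranges used for habitat-group means of each soil variable,
# matching magnitudes typical of deltaic saline-alkali topsoil
_ENV_RANGES = {
    "pH": (7.6, 8.1),
    "EC": (1.2, 5.4),
    "OM": (17.0, 59.0),
    "TN": (70.0, 170.0),
    "NH4_N": (3.0, 3.9),
    "NO3_N": (1.1, 5.5),
    "TP": (1.0, 1.4),
    "AK": (80.0, 300.0),
}

_BACTERIAL_PHYLA = (
    "Proteobacteria", "Chloroflexi", "Bacteroidetes", "Acidobacteria",
    "Gemmatimonadetes", "Actinobacteria", "Firmicutes", "Verrucomicrobia",
)
_BACTERIAL_WEIGHTS = (0.40, 0.15, 0.12, 0.10, 0.08, 0.07, 0.05, 0.03)
_FUNGAL_PHYLA = (
    "Ascomycota", "Basidiomycota", "Mortierellomycota", "Glomeromycota",
    "unclassified",
)
_FUNGAL_WEIGHTS = (0.55, 0.25, 0.08, 0.05, 0.07)


@dataclass
class SyntheticConfig:
    """Study-design parameters of a synthetic dataset.

    Defaults mirror the emulated survey: 15 samples in five habitat groups,
    a bacteria-dominated two-kingdom community, and a modest number of
    planted correlation modules.
    """

    n_samples: int = 15
    n_bacteria: int = 2000
    n_fungi: int = 300
    n_modules: int = 8
    module_size_range: tuple[int, int] = (6, 12)
    within_module_rho: float = 0.9
    frac_negative_edges: float = 0.05
    inter_kingdom_frac: float = 0.1
    sequencing_depth: float = 30000.0
    dispersion: float = 0.3
    abundance_sigma: float = 2.0   # sd of log baseline abundance (heavy tail)
    env_coupled_taxa: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be at least 4")
        for name in ("frac_negative_edges", "inter_kingdom_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.within_module_rho <= 1:
            raise ValueError("within_module_rho must lie in (0, 1]")
        lo, hi = self.module_size_range
        if not 2 <= lo <= hi:
            raise ValueError("module sizes must be at least 2 and ordered")
        if self.n_modules * hi > self.n_bacteria + self.n_fungi:
            raise ValueError("module sizes may exceed the number of OTUs")


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic dataset: planted edges with signs, the
    module membership, and the environment couplings."""

    planted_edges: pd.DataFrame          # otu_a, otu_b, sign (+1/-1), module
    module_assignment: dict              # otu_id -> module index
    env_loadings: pd.DataFrame           # otu_id, env_var, beta

    def edge_set(self) -> set[frozenset]:
        return {
            frozenset((a, b))
            for a, b in zip(self.planted_edges["otu_a"], self.planted_edges["otu_b"])
        }

    def to_tsv(self, path: str | Path) -> None:
        self.planted_edges.to_csv(path, sep="\t", index=False)


def _split_count(size: int, target_frac: float, cap: int) -> int:
    """Number of 'marked' members of a module of ``size`` whose mixed pairs
    best approximate ``target_frac`` of all pairs."""
    if size < 2:
        return 0
    pairs = size * (size - 1) / 2
    best, best_err = 0, float("inf")
    for f in range(0, min(size, cap) + 1):
        err = abs(f * (size - f) / pairs - target_frac)
        if err < best_err:
            best, best_err = f, err
    return best


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[AbundanceTable, TaxonomyMap, SampleMetadata, PlantedTruth]:
    """Generate counts, taxonomy, metadata and ground truth from a config.

    Fixed seed implies bit-identical output.  With ``dispersion = 0`` the
    counts are the rounded expected values (a noise-free sequencing limit
    used by limit-case tests); otherwise they are log-normal-Poisson draws.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_b, n_f = cfg.n_bacteria, cfg.n_fungi
    n = n_b + n_f
    otu_ids = [f"B{i+1:05d}" for i in range(n_b)] + [f"F{i+1:05d}" for i in range(n_f)]
    kingdoms = np.array(["Bacteria"] * n_b + ["Fungi"] * n_f)

    # --- taxonomy ------------------------------------------------------
    phyla = np.empty(n, dtype=object)
    phyla[:n_b] = rng.choice(_BACTERIAL_PHYLA, size=n_b, p=_BACTERIAL_WEIGHTS)
    phyla[n_b:] = rng.choice(_FUNGAL_PHYLA, size=n_f, p=_FUNGAL_WEIGHTS)
    tax_rows = {}
    for i, otu in enumerate(otu_ids):
        lineage = {"kingdom": kingdoms[i], "phylum": phyla[i]}
        for rank in RANKS[2:]:
            if rng.random() < 0.15:
                lineage[rank] = "unclassified"
            else:
                lineage[rank] = f"{phyla[i]}_{rank[0]}{rng.integers(1, 6)}"
        tax_rows[otu] = lineage
    taxonomy = TaxonomyMap(
        pd.DataFrame.from_dict(tax_rows, orient="index").rename_axis("otu_id")
    )

    # --- samples, habitat groups, environment --------------------------
    sample_ids = [f"S{i+1:02d}" for i in range(cfg.n_samples)]
    n_groups = min(5, max(2, cfg.n_samples // 3))
    group_of = np.array([f"H{(i % n_groups) + 1}" for i in range(cfg.n_samples)])
    env = {}
    for var in ENV_VARS:
        lo, hi = _ENV_RANGES[var]
        span = hi - lo
        means = {g: rng.uniform(lo, hi) for g in np.unique(group_of)}
        vals = np.array([
            means[g] + 0.08 * span * rng.standard_normal() for g in group_of
        ])
        env[var] = np.clip(vals, lo - 0.5 * span, hi + 0.5 * span)
    meta = SampleMetadata(pd.DataFrame(
        {**env, "habitat_group": group_of},
        index=pd.Index(sample_ids, name="sample_id"),
    ))

    # --- planted modules ------------------------------------------------
    lo, hi = cfg.module_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_modules)
    if sizes.sum() > n:
        raise ValueError("module sizes exceed the number of OTUs")
    unassigned_b = list(rng.permutation(n_b))
    unassigned_f = list(rng.permutation(np.arange(n_b, n)))
    module_of: dict[int, int] = {}
    sign = np.ones(n)
    edges = []
    for m, size in enumerate(sizes):
        n_fungal = min(_split_count(int(size), cfg.inter_kingdom_frac, len(unassigned_f)),
                       len(unassigned_f))
        members = [unassigned_f.pop() for _ in range(n_fungal)]
        # fill from the bacterial pool, falling back to fungi if exhausted
        for _ in range(int(size) - n_fungal):
            if unassigned_b:
                members.append(unassigned_b.pop())
            elif unassigned_f:
                members.append(unassigned_f.pop())
            else:
                raise ValueError("module sizes exceed the number of OTUs")
        n_neg = _split_count(len(members), cfg.frac_negative_edges, len(members))
        flipped = rng.choice(len(members), size=n_neg, replace=False)
        for j in flipped:
            sign[members[j]] = -1.0
        for i in members:
            module_of[i] = m
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                a, b = sorted((members[a_idx], members[b_idx]))
                edges.append({
                    "otu_a": otu_ids[a], "otu_b": otu_ids[b],
                    "sign": int(sign[a] * sign[b]), "module": m,
                })
    planted = pd.DataFrame(edges, columns=["otu_a", "otu_b", "sign", "module"])

    # --- latent correlation structure ----------------------------------
    w = 2.0 * np.sin(np.pi * cfg.within_module_rho / 6.0)
    factors = rng.standard_normal((cfg.n_modules, cfg.n_samples))
    z = rng.standard_normal((n, cfg.n_samples))
    for i, m in module_of.items():
        z[i] = sign[i] * (np.sqrt(w) * factors[m]) + np.sqrt(1.0 - w) * z[i]

    # --- environment coupling ------------------------------------------
    module_members = set(module_of)
    free = [i for i in range(n) if i not in module_members]
    pool = free if len(free) >= cfg.env_coupled_taxa else list(range(n))
    coupled = rng.choice(pool, size=min(cfg.env_coupled_taxa, len(pool)),
                         replace=False)
    env_rows = []
    for i in coupled:
        var = ENV_VARS[rng.integers(len(ENV_VARS))]
        beta = rng.uniform(0.8, 1.5) * rng.choice([-1.0, 1.0])
        x = np.asarray(env[var], dtype=float)
        xs = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        z[int(i)] = z[int(i)] + beta * xs
        env_rows.append({"otu_id": otu_ids[int(i)], "env_var": var, "beta": beta})
    env_loadings = pd.DataFrame(env_rows, columns=["otu_id", "env_var", "beta"])

    # --- counts ---------------------------------------------------------
    mu = rng.normal(0.0, cfg.abundance_sigma, size=n)
    intensity = np.exp(mu[:, None] + z)
    proportions = intensity / intensity.sum(axis=0)
    lam = cfg.sequencing_depth * proportions
    if cfg.dispersion > 0:
        noisy = lam * rng.lognormal(
            -0.5 * cfg.dispersion ** 2, cfg.dispersion, size=lam.shape
        )
        counts = rng.poisson(noisy)
    else:
        counts = np.rint(lam).astype(np.int64)
    table = AbundanceTable(pd.DataFrame(
        counts, index=pd.Index(otu_ids, name="otu_id"), columns=sample_ids
    ))
    truth = PlantedTruth(
        planted_edges=planted,
        module_assignment={otu_ids[i]: m for i, m in module_of.items()},
        env_loadings=env_loadings,
    )
    return table, taxonomy, meta, truth


def write_dataset(
    outdir: str | Path,
    table: AbundanceTable,
    taxonomy: TaxonomyMap,
    meta: SampleMetadata,
    truth: PlantedTruth | None = None,
) -> None:
    """Write the generated dataset in the TSV formats the readers consume,
    plus a ``truth.tsv`` sidecar of planted edges."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_tsv(outdir / "abundance.tsv")
    taxonomy.to_tsv(outdir / "taxonomy.tsv")
    meta.to_tsv(outdir / "metadata.tsv")
    if truth is not None:
        truth.to_tsv(outdir / "truth.tsv")


def truth_recovery_report(truth: PlantedTruth, g: nx.Graph) -> dict:
    """Precision/recall of the inferred network against the planted edges.

    Precision is NA (None) when nothing was detected; sign agreement is the
    fraction of true-positive edges whose inferred sign matches the planted
    one (NA when there are no true positives).
    """
    detected = {frozenset((u, v)) for u, v in g.edges}
    planted_signs = {
        frozenset((a, b)): s
        for a, b, s in zip(truth.planted_edges["otu_a"],
                           truth.planted_edges["otu_b"],
                           truth.planted_edges["sign"])
    }
    planted = set(planted_signs)
    tp = detected & planted
    agree = sum(
        1 for e in tp
        if g.edges[tuple(e)]["sign"] == planted_signs[e]
    )
    return {
        "n_planted": len(planted),
        "n_detected": len(detected),
        "n_true_positive": len(tp),
        "precision": len(tp) / len(detected) if detected else None,
        "recall": len(tp) / len(planted) if planted else None,
        "sign_agreement": agree / len(tp) if tp else None,
    }
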