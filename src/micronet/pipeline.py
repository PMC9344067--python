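"""End-to-end orchestration: tables in, every analysis TSV out.

``run_pipeline`` executes the full chain — I/O and validation; per-kingdom
alpha diversity with group ANOVA; Bray-Curtis / PCoA / PERMANOVA /
Procrustes / CCA; six-class taxa classification; prevalence filtering and
Spearman-BH screening of the pooled two-kingdom table; network construction
and topology with an Erdős–Rényi null ensemble; Zi-Pi roles and keystones;
kingdom/phylum link partitions; per-sample subnetwork-environment
correlations — and writes a JSON manifest (versions, seeds, thresholds and
stage counts) that fully determines the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha import alpha_diversity, group_anova
from .beta import bray_curtis, cca, env_pca, pcoa, permanova, procrustes_test
from .io import (
    AbundanceTable, SampleMetadata, TaxonomyMap,
    prevalence_filter, read_abundance_table, read_metadata,
    to_relative_abundance, write_network,
)
from .links import partition_links, phylum_link_matrix, phylum_links_long
from .network import build_network, correlation_screen
from .roles import keystone_table, zi_pi
from .subnet import env_topology_correlation, subnet_topology_table
from .synthetic import (
    PlantedTruth, SyntheticConfig, generate_dataset, truth_recovery_report,
    write_dataset,
)
from .taxa import classify_abundance
from .topology import (
    louvain_modules, random_ensemble, small_world_report, topology_summary,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Either ``synthetic`` is true (a dataset is generated from
    ``synthetic_config``) or the three input paths must point to TSV files.
    The master ``seed`` drives every stochastic stage through fixed offsets.
    """

    outdir: str = "micronet_out"
    synthetic: bool = True
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)
    abundance_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None

    prevalence_min_samples: int = 8      # strictly-more-than rule
    r_min: float = 0.8
    q_max: float = 0.05
    use_raw_p: bool = False
    abundant_thr: float = 0.01
    rare_thr: float = 0.0001
    classify_filtered: bool = False      # classify on the full table by default
    n_permutations: int = 999
    ensemble_size: int = 100
    anova_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic_config", None)
        cfg = cls(**raw)
        if syn is not None:
            if "module_size_range" in syn:
                syn["module_size_range"] = tuple(syn["module_size_range"])
            cfg.synthetic_config = SyntheticConfig(**syn)
        return cfg

    def validate(self) -> None:
        if not 0 < self.rare_thr < self.abundant_thr < 1:
            raise ValueError("need 0 < rare_thr < abundant_thr < 1")
        if not 0 < self.r_min < 1:
            raise ValueError("r_min must lie in (0, 1)")
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must lie in (0, 1]")
        if not self.synthetic:
            missing = [
                p for p in ("abundance_path", "taxonomy_path", "metadata_path")
                if getattr(self, p) is None
            ]
            if missing:
                raise ValueError(f"non-synthetic run lacks paths: {missing}")


def _split_by_kingdom(
    table: AbundanceTable, tax: TaxonomyMap
) -> dict[str, AbundanceTable]:
    out = {}
    for kingdom in ("Bacteria", "Fungi"):
        otus = [o for o in table.otu_ids if tax.kingdom(o) == kingdom]
        if otus:
            sub = table.data.loc[otus]
            if (sub.sum(axis=0) > 0).all():
                out[kingdom] = AbundanceTable(sub)
    return out


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and return the output directory."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.seed)
    manifest: dict = {
        "micronet_version": __version__,
        "numpy_version": np.__version__,
        "networkx_version": nx.__version__,
        "config": _config_dict(cfg),
        "counts": {},
    }
    counts = manifest["counts"]

    # stage 1: inputs ----------------------------------------------------
    truth: PlantedTruth | None = None
    if cfg.synthetic:
        logger.info("stage input: generating synthetic dataset")
        table, tax, meta, truth = generate_dataset(cfg.synthetic_config)
        write_dataset(outdir / "input", table, tax, meta, truth)
    else:
        logger.info("stage input: reading %s", cfg.abundance_path)
        table, tax = read_abundance_table(cfg.abundance_path, cfg.taxonomy_path)
        meta = read_metadata(cfg.metadata_path)
    meta.covers(table)
    counts["otus_in"] = table.shape[0]
    counts["samples"] = table.shape[1]

    # stage 2: alpha diversity -------------------------------------------
    by_kingdom = _split_by_kingdom(table, tax)
    alpha_frames = []
    anova_rows = []
    for kingdom, sub in by_kingdom.items():
        adf = alpha_diversity(sub)
        adf.insert(0, "kingdom", kingdom)
        alpha_frames.append(adf)
        for metric in ("observed", "shannon", "chao1"):
            gc = group_anova(adf[metric], meta, alpha=cfg.anova_alpha,
                             metric=metric)
            anova_rows.append({
                "kingdom": kingdom, "metric": metric,
                "F": gc.f_statistic, "p": gc.p_value,
                "letters": ";".join(
                    f"{g}={row.letters}" for g, row in gc.table.iterrows()
                ),
            })
    pd.concat(alpha_frames).to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    pd.DataFrame(anova_rows).to_csv(outdir / "alpha_anova.tsv", sep="\t",
                                    index=False)

    # stage 3: ordination --------------------------------------------------
    beta_rows = []
    env_ord = env_pca(meta)
    for kingdom, sub in by_kingdom.items():
        d = bray_curtis(sub)
        ord_res = pcoa(d)
        ord_res.coordinates.to_csv(outdir / f"pcoa_{kingdom.lower()}.tsv",
                                   sep="\t")
        perm = permanova(d, meta.habitat_group, n_perm=cfg.n_permutations,
                         seed=seed + 11)
        proc = procrustes_test(ord_res, env_ord, n_perm=cfg.n_permutations,
                               seed=seed + 12)
        cca_res = cca(to_relative_abundance(sub), meta)
        beta_rows.append({
            "kingdom": kingdom,
            "permanova_r2": perm.r2, "permanova_f": perm.pseudo_f,
            "permanova_p": perm.p_value,
            "procrustes_m2": proc.m2, "procrustes_p": proc.p_value,
            "cca_constrained_fraction": cca_res.constrained_fraction,
            "pcoa_axis1": ord_res.proportion_explained[0],
            "pcoa_axis2": (ord_res.proportion_explained[1]
                           if len(ord_res.proportion_explained) > 1 else 0.0),
        })
    pd.DataFrame(beta_rows).to_csv(outdir / "beta_summary.tsv", sep="\t",
                                   index=False)

    # stage 4: abundance classes ------------------------------------------
    class_basis = (
        prevalence_filter(table, cfg.prevalence_min_samples)
        if cfg.classify_filtered else table
    )
    classes = classify_abundance(
        to_relative_abundance(class_basis), cfg.abundant_thr, cfg.rare_thr
    )
    classes.to_csv(outdir / "taxa_classes.tsv", sep="\t")
    counts["class_counts"] = classes["class"].value_counts().to_dict()

    # stage 5: network inference ------------------------------------------
    filtered = prevalence_filter(table, cfg.prevalence_min_samples)
    counts["otus_after_prevalence"] = filtered.shape[0]
    records = correlation_screen(to_relative_abundance(filtered))
    counts["pairs_tested"] = int(len(records))
    records.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    g = build_network(records, tax, r_min=cfg.r_min, q_max=cfg.q_max,
                      classes=classes, use_raw_p=cfg.use_raw_p)
    counts["network_nodes"] = g.number_of_nodes()
    counts["network_edges"] = g.number_of_edges()

    if g.number_of_edges() == 0:
        logger.warning("empty network: skipping topology, roles, links and "
                       "subnetwork stages")
        write_network(g, outdir / "network.graphml")
    else:
        modules, q_mod = louvain_modules(g, seed=seed + 21)
        nx.set_node_attributes(g, modules, "module")
        write_network(g, outdir / "network.graphml")

        # stage 6: topology + null ensemble
        topo = topology_summary(g, seed=seed + 21)
        ens = random_ensemble(topo.nodes, topo.edges,
                              n_realizations=cfg.ensemble_size,
                              seed=seed + 22)
        sw = small_world_report(topo, ens)
        topo_df = pd.DataFrame([{**topo.as_dict(),
                                 "aplr_mean": ens.aplr_mean,
                                 "aplr_sd": ens.aplr_sd,
                                 "aplr_se": ens.aplr_se,
                                 "accr_mean": ens.accr_mean,
                                 "accr_sd": ens.accr_sd,
                                 "accr_se": ens.accr_se,
                                 **sw}])
        topo_df.to_csv(outdir / "topology.tsv", sep="\t", index=False)
        counts["modularity"] = q_mod

        # stage 7: node roles
        roles = zi_pi(g, modules)
        keystones = keystone_table(roles, classes, tax)
        keystones["nodes"].to_csv(outdir / "node_roles.tsv", sep="\t")
        summary = {k: v for k, v in keystones.items() if k != "nodes"}
        (outdir / "keystone_summary.json").write_text(
            json.dumps(summary, indent=2)
        )
        counts["generalists"] = keystones["n_generalists"]

        # stage 8: kingdom / phylum links
        part = partition_links(g, tax)
        pd.DataFrame([{
            "bb": part.bb, "bf": part.bf, "ff": part.ff,
            **{f"{k}_frac": v for k, v in part.fractions.items()},
            "bacteria_involved": part.bacteria_involved,
            "bacteria_involved_frac": part.bacteria_involved_fraction,
        }]).to_csv(outdir / "link_partition.tsv", sep="\t", index=False)
        mat, involvement = phylum_link_matrix(g, tax)
        mat.to_csv(outdir / "phylum_link_matrix.tsv", sep="\t")
        phylum_links_long(mat).to_csv(outdir / "phylum_links_long.tsv",
                                      sep="\t", index=False)
        involvement.to_csv(outdir / "phylum_involvement.tsv", sep="\t")

        # stage 9: per-sample subnetworks vs environment
        st = subnet_topology_table(g, table, seed=seed + 23)
        st.to_csv(outdir / "subnet_topology.tsv", sep="\t")
        env_corr = env_topology_correlation(st, meta)
        env_corr.to_csv(outdir / "env_topology_correlation.tsv", sep="\t",
                        index=False)

    # stage 10: truth recovery (synthetic runs only)
    if truth is not None:
        report = truth_recovery_report(truth, g)
        (outdir / "truth_recovery.json").write_text(json.dumps(report, indent=2))
        counts["truth_recovery"] = report

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    logger.info("pipeline complete: %s", outdir)
    return outdir


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["synthetic_config"]["module_size_range"] = list(
        d["synthetic_config"]["module_size_range"]
    )
    return d
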