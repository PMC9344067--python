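"""Per-sample subnetworks and their correlation with soil variables.

Each sample induces a subgraph of the full co-occurrence network on the
OTUs it actually contains (count > 0, configurable to a relative-abundance
floor).  The topology of these subnetworks, one row per sample, is then
correlated (Spearman by default) with each environmental variable to ask
which soil property tracks network architecture across samples.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable, SampleMetadata, ENV_VARS
from .topology import topology_summary

logger = logging.getLogger(__name__)

#: subnetwork statistics correlated against the environment
SUBNET_PROPERTIES = (
    "nodes", "edges", "density", "acc", "apl", "diameter", "modularity",
)


def sample_subgraph(
    g: nx.Graph,
    table: AbundanceTable,
    sample: str,
    min_relative_abundance: float = 0.0,
) -> nx.Graph:
    """Induced subgraph on the network nodes present in one sample.

    Presence means count > 0, or relative abundance above
    ``min_relative_abundance`` when a floor is given.  All full-network
    edges between retained nodes are kept.
    """
    if sample not in table.sample_ids:
        raise KeyError(f"unknown sample id {sample!r}")
    col = table.data[sample]
    if min_relative_abundance > 0:
        present = set(col.index[col / col.sum() > min_relative_abundance])
    else:
        present = set(col.index[col > 0])
    keep = [n for n in g.nodes if n in present]
    return g.subgraph(keep).copy()


def subnet_topology_table(
    g: nx.Graph,
    table: AbundanceTable,
    seed: int = 0,
    min_relative_abundance: float = 0.0,
) -> pd.DataFrame:
    """One topology-summary row per sample (same metric definitions as the
    full network)."""
    rows = {}
    for sample in table.sample_ids:
        sub = sample_subgraph(g, table, sample, min_relative_abundance)
        rows[sample] = topology_summary(sub, seed=seed).as_dict()
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def env_topology_correlation(
    subnet_table: pd.DataFrame,
    meta: SampleMetadata,
    alpha: float = 0.05,
    method: str = "spearman",
    properties=SUBNET_PROPERTIES,
) -> pd.DataFrame:
    """Correlate each environmental variable with each subnetwork property.

    Returns a long DataFrame (env_var, property, rho, p, q, significant);
    the significance flag uses the raw p-value at ``alpha`` while the BH-
    adjusted q across the whole grid is reported alongside.  Constant
    variables or properties yield NA and are logged.
    """
    if len(subnet_table) < 5:
        raise ValueError("need at least five samples for correlations")
    corr = {"spearman": stats.spearmanr, "pearson": stats.pearsonr}[method]
    env = meta.env_matrix().loc[subnet_table.index]
    rows = []
    for var in ENV_VARS:
        x = env[var].to_numpy(dtype=float)
        for prop in properties:
            y = subnet_table[prop].to_numpy(dtype=float)
            def _constant(v: np.ndarray) -> bool:
                return np.std(v) <= 1e-12 * max(1.0, np.abs(v).max())

            if _constant(x) or _constant(y) or not np.all(np.isfinite(y)):
                logger.warning("constant or undefined pair (%s, %s): NA", var, prop)
                rows.append({"env_var": var, "property": prop,
                             "rho": np.nan, "p": np.nan})
                continue
            rho, p = corr(x, y)
            rows.append({"env_var": var, "property": prop,
                         "rho": float(rho), "p": float(p)})
    df = pd.DataFrame(rows)
    valid = df["p"].notna()
    q = np.full(len(df), np.nan)
    if valid.any():
        q[valid.to_numpy()] = multipletests(df.loc[valid, "p"], method="fdr_bh")[1]
    df["q"] = q
    df["significant"] = df["p"] < alpha
    return df
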