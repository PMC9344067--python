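"""Co-occurrence network inference by Spearman screening with BH-FDR.

All unordered OTU pairs of a (prevalence-filtered) relative-abundance table
are scored by Spearman's rho with average ranks for ties; two-sided p-values
use the t approximation (standard at n = 15); Benjamini-Hochberg adjustment
runs over every pair tested.  An edge enters the network iff |rho| exceeds
the correlation threshold and the adjusted p-value (q) falls below the
significance threshold — the absolute-value rule is required for the signed
network to contain its minority of negative edges.
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable, RelativeAbundanceTable, TaxonomyMap

logger = logging.getLogger(__name__)


def correlation_screen(
    rel: RelativeAbundanceTable | AbundanceTable,
) -> pd.DataFrame:
    """Spearman rho, raw p and BH-adjusted q for all unordered OTU pairs.

    OTUs constant across samples are excluded (their correlation is
    undefined) and logged.  Returns a DataFrame with columns
    ``otu_a, otu_b, rho, p, q``.
    """
    values = rel.data.to_numpy(dtype=float)
    n_samples = values.shape[1]
    if n_samples < 5:
        raise ValueError("correlation screening needs at least five samples")
    variable = values.std(axis=1) > 0
    if not variable.all():
        dropped = [o for o, v in zip(rel.otu_ids, variable) if not v]
        logger.warning(
            "excluding %d OTUs constant across samples from screening: %s",
            len(dropped), dropped[:10],
        )
    ids = [o for o, v in zip(rel.otu_ids, variable) if v]
    sub = values[variable]
    if len(ids) < 2:
        return pd.DataFrame(columns=["otu_a", "otu_b", "rho", "p", "q"])
    ranks = stats.rankdata(sub, axis=1)
    rho = np.corrcoef(ranks)
    iu, ju = np.triu_indices(len(ids), 1)
    r = np.clip(rho[iu, ju], -1.0, 1.0)
    # two-sided p by the t approximation with n-2 degrees of freedom
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n_samples - 2) / np.maximum(1e-300, 1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n_samples - 2)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    logger.info("screened %d OTU pairs (%d OTUs)", len(r), len(ids))
    id_arr = np.asarray(ids)
    return pd.DataFrame(
        {"otu_a": id_arr[iu], "otu_b": id_arr[ju], "rho": r, "p": p, "q": q}
    )


def build_network(
    records: pd.DataFrame,
    tax: TaxonomyMap,
    r_min: float = 0.8,
    q_max: float = 0.05,
    classes: pd.DataFrame | None = None,
    use_raw_p: bool = False,
) -> nx.Graph:
    """Build the signed co-occurrence graph from screened pairs.

    An edge is kept iff |rho| > ``r_min`` and the operative significance
    value (BH-adjusted ``q`` by default, raw ``p`` with ``use_raw_p``) is
    below ``q_max``.  Isolated OTUs never appear.  Node attributes carry
    kingdom, phylum and, when ``classes`` is given, the six-class abundance
    label; edges carry rho and sign.
    """
    sig_col = "p" if use_raw_p else "q"
    kept = records[
        (records["rho"].abs() > r_min) & (records[sig_col] < q_max)
    ]
    g = nx.Graph()
    if kept.empty:
        logger.warning("no OTU pair survived screening: returning empty network")
        return g
    for row in kept.itertuples(index=False):
        g.add_edge(
            row.otu_a,
            row.otu_b,
            rho=float(row.rho),
            sign=1 if row.rho > 0 else -1,
            weight=abs(float(row.rho)),
        )
    for node in g.nodes:
        g.nodes[node]["kingdom"] = str(tax.kingdom(node))
        g.nodes[node]["phylum"] = str(tax.phylum(node))
        if classes is not None and node in classes.index:
            g.nodes[node]["abundance_class"] = str(classes.at[node, "class"])
            g.nodes[node]["dichotomy"] = str(classes.at[node, "dichotomy"])
    logger.info(
        "network: %d nodes, %d edges (|rho| > %g, %s < %g)",
        g.number_of_nodes(), g.number_of_edges(), r_min, sig_col, q_max,
    )
    return g
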