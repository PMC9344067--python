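"""Zi-Pi node roles and keystone identification.

Within-module connectivity Zi standardises a node's edge count into its own
module over that module's members (population standard deviation, following
the original participation-coefficient formulation); among-module
connectivity Pi = 1 - sum_t (k_it / k_i)^2 measures how evenly a node's
edges spread over modules.  Nodes are split into four roles at the classic
thresholds Zi* = 2.5 and Pi* = 0.62:

    peripheral   Zi < 2.5, Pi < 0.62
    connector    Zi < 2.5, Pi > 0.62
    module hub   Zi > 2.5, Pi < 0.62
    network hub  Zi > 2.5, Pi > 0.62

Boundary equality goes to the peripheral side.  Connectors, module hubs and
network hubs together are the generalists — the operational keystone taxa.
"""

from __future__ import annotations

import logging
from collections import Counter

import networkx as nx
import numpy as np
import pandas as pd

from .io import TaxonomyMap

logger = logging.getLogger(__name__)

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

ROLES = ("peripheral", "connector", "module hub", "network hub")


def classify_role(zi: float, pi: float) -> str:
    hub = zi > ZI_THRESHOLD
    connector = pi > PI_THRESHOLD
    if hub and connector:
        return "network hub"
    if hub:
        return "module hub"
    if connector:
        return "connector"
    return "peripheral"


def zi_pi(g: nx.Graph, modules: dict) -> pd.DataFrame:
    """Per-node Zi, Pi and role for a graph with a full module assignment.

    Returns a DataFrame indexed by node id with columns ``module, degree,
    zi, pi, role, generalist``.  Edge signs are ignored.  Nodes of degree
    zero are rejected (they cannot occur in a screened co-occurrence
    network, and Pi is undefined for them).
    """
    missing = [n for n in g.nodes if n not in modules]
    if missing:
        raise ValueError(f"nodes without module assignment: {missing[:10]}")
    zero = [n for n, d in g.degree() if d == 0]
    if zero:
        raise ValueError(f"nodes of degree zero have undefined Pi: {zero[:10]}")

    # per-node edge counts into each module
    k_into: dict = {n: Counter() for n in g.nodes}
    for u, v in g.edges:
        k_into[u][modules[v]] += 1
        k_into[v][modules[u]] += 1

    # within-module degree statistics per module (population sd)
    members: dict = {}
    for n in g.nodes:
        members.setdefault(modules[n], []).append(n)
    stats = {}
    for mod, nodes in members.items():
        within = np.array([k_into[n][mod] for n in nodes], dtype=float)
        stats[mod] = (within.mean(), within.std())

    rows = {}
    for n in g.nodes:
        mod = modules[n]
        k_i = g.degree(n)
        mean_s, sd_s = stats[mod]
        zi = (k_into[n][mod] - mean_s) / sd_s if sd_s > 0 else 0.0
        pi = 1.0 - sum((k_t / k_i) ** 2 for k_t in k_into[n].values())
        role = classify_role(zi, pi)
        rows[n] = {
            "module": mod,
            "degree": k_i,
            "zi": float(zi),
            "pi": float(pi),
            "role": role,
            "generalist": role != "peripheral",
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "otu_id"
    return df


def keystone_table(
    roles: pd.DataFrame,
    classes: pd.DataFrame,
    tax: TaxonomyMap,
) -> dict:
    """Summarise generalists (keystones) by kingdom and abundant/rare status.

    Returns a dict with the per-node listing (``nodes``), generalist counts
    by kingdom and by dichotomy, and the keystone fraction of the network.
    OTUs absent from the classification are listed as ``unclassified`` with
    a warning.
    """
    listing = roles.copy()
    listing["kingdom"] = [tax.kingdom(o) for o in listing.index]
    listing["phylum"] = [tax.phylum(o) for o in listing.index]
    dichotomy = []
    missing = []
    for o in listing.index:
        if o in classes.index:
            dichotomy.append(classes.at[o, "dichotomy"])
        else:
            dichotomy.append("unclassified")
            missing.append(o)
    if missing:
        logger.warning("OTUs missing from abundance classes: %s", missing[:10])
    listing["dichotomy"] = dichotomy
    listing["abundance_class"] = [
        classes.at[o, "class"] if o in classes.index else "unclassified"
        for o in listing.index
    ]
    generalists = listing[listing["generalist"]]
    return {
        "nodes": listing,
        "n_nodes": int(len(listing)),
        "n_generalists": int(len(generalists)),
        "keystone_fraction": float(len(generalists) / len(listing)) if len(listing) else 0.0,
        "generalists_by_kingdom": generalists["kingdom"].value_counts().to_dict(),
        "generalists_by_dichotomy": generalists["dichotomy"].value_counts().to_dict(),
        "generalists_by_role": generalists["role"].value_counts().to_dict(),
    }
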