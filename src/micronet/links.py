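"""Edge partitioning by kingdom and by phylum pair.

``bacteria_involved`` counts every edge with at least one bacterial endpoint
(BB + BF); it is reported alongside the three-way partition because the two
summaries answer different questions and do not sum to 100% together.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .io import TaxonomyMap


@dataclass
class LinkPartition:
    bb: int
    bf: int
    ff: int

    @property
    def total(self) -> int:
        return self.bb + self.bf + self.ff

    @property
    def fractions(self) -> dict:
        t = self.total
        if t == 0:
            return {"bb": 0.0, "bf": 0.0, "ff": 0.0}
        return {"bb": self.bb / t, "bf": self.bf / t, "ff": self.ff / t}

    @property
    def bacteria_involved(self) -> int:
        return self.bb + self.bf

    @property
    def bacteria_involved_fraction(self) -> float:
        return self.bacteria_involved / self.total if self.total else 0.0


def partition_links(g: nx.Graph, tax: TaxonomyMap) -> LinkPartition:
    """Assign every edge to bacteria-bacteria, bacteria-fungi or fungi-fungi
    by its endpoint kingdoms."""
    counts = {"bb": 0, "bf": 0, "ff": 0}
    for u, v in g.edges:
        kingdoms = {tax.kingdom(u), tax.kingdom(v)}
        if kingdoms == {"Bacteria"}:
            counts["bb"] += 1
        elif kingdoms == {"Fungi"}:
            counts["ff"] += 1
        else:
            counts["bf"] += 1
    return LinkPartition(**counts)


def phylum_link_matrix(
    g: nx.Graph, tax: TaxonomyMap
) -> tuple[pd.DataFrame, pd.Series]:
    """Symmetric matrix of edge counts per unordered (kingdom-qualified)
    phylum pair, plus each phylum's involvement fraction (edges touching the
    phylum / total edges).  Intra-phylum edges sit on the diagonal and count
    once."""
    def label(node: str) -> str:
        return f"{tax.kingdom(node)}:{tax.phylum(node)}"

    phyla = sorted({label(n) for n in g.nodes})
    mat = pd.DataFrame(0, index=phyla, columns=phyla, dtype=int)
    for u, v in g.edges:
        a, b = sorted((label(u), label(v)))
        mat.at[a, b] += 1
        if a != b:
            mat.at[b, a] += 1
    total = g.number_of_edges()
    involvement = {}
    for p in phyla:
        touching = int(mat.loc[p].sum())  # off-diagonal counts + intra-phylum edges
        involvement[p] = touching / total if total else 0.0
    return mat, pd.Series(involvement, name="involvement_fraction")


def phylum_links_long(mat: pd.DataFrame) -> pd.DataFrame:
    """Long-format (phylum_a, phylum_b, count) table for chord-diagram
    tools; upper triangle plus diagonal only."""
    rows = []
    for i, a in enumerate(mat.index):
        for b in mat.columns[i:]:
            count = int(mat.at[a, b])
            if count:
                rows.append({"phylum_a": a, "phylum_b": b, "count": count})
    return pd.DataFrame(rows, columns=["phylum_a", "phylum_b", "count"])
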