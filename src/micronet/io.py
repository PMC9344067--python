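"""Tabular input/output and basic table transformations.

All tables are plain UTF-8 TSV files:

* abundance table — rows are OTUs, columns are samples, integer read counts;
* taxonomy table  — ``otu_id`` plus the six ranks kingdom..genus, with the
  literal token ``unclassified`` for annotation gaps;
* sample metadata — ``sample_id``, the eight soil variables (pH, EC, OM, TN,
  NH4_N, NO3_N, TP, AK) and a ``habitat_group`` label.

Networks are exported as GraphML/GEXF (readable by Gephi and friends) or as a
long edge TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: taxonomy ranks stored for every OTU, in order
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: the soil physicochemical variables carried in sample metadata
ENV_VARS = ("pH", "EC", "OM", "TN", "NH4_N", "NO3_N", "TP", "AK")

#: token used for missing taxonomy annotations (kingdom may never carry it)
UNCLASSIFIED = "unclassified"

KINGDOMS = ("Bacteria", "Fungi")


class ValidationError(ValueError):
    """An input table violates one of its structural invariants."""


def _check_unique(values, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class AbundanceTable:
    """OTU x sample matrix of non-negative integer read counts.

    ``data`` is indexed by OTU id with one column per sample.  Every sample
    column must sum to a positive total (an all-zero sample carries no
    information and breaks relative-abundance closure).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "OTU ids")
        _check_unique(df.columns, "sample ids")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("abundance table contains non-numeric entries")
        if np.any(values != np.floor(values)):
            r, c = np.argwhere(values != np.floor(values))[0]
            raise ValidationError(
                f"non-integer count at OTU {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at OTU {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        colsums = values.sum(axis=0)
        if np.any(colsums <= 0):
            bad = df.columns[np.asarray(colsums <= 0)].tolist()
            raise ValidationError(f"samples with zero total counts: {bad}")
        self.data = df.astype(np.int64)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="otu_id")


@dataclass
class RelativeAbundanceTable:
    """Same axes as :class:`AbundanceTable`; per-sample proportions in [0, 1]."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "OTU ids")
        _check_unique(self.data.columns, "sample ids")
        colsums = self.data.to_numpy().sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValidationError("relative abundance columns must sum to 1")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="otu_id")


@dataclass
class TaxonomyMap:
    """OTU id -> ranked lineage (kingdom..genus).

    The kingdom must be a real kingdom label (``Bacteria`` or ``Fungi``);
    every other rank may be the literal token ``unclassified``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise ValidationError(f"taxonomy table lacks rank columns: {missing}")
        _check_unique(self.data.index, "OTU ids in taxonomy")
        bad = self.data.index[~self.data["kingdom"].isin(KINGDOMS)].tolist()
        if bad:
            raise ValidationError(
                f"OTUs with kingdom outside {KINGDOMS} (kingdom may not be "
                f"'{UNCLASSIFIED}'): {bad[:10]}"
            )

    def kingdom(self, otu_id: str) -> str:
        return self.data.at[otu_id, "kingdom"]

    def phylum(self, otu_id: str) -> str:
        return self.data.at[otu_id, "phylum"]

    def covers(self, table: AbundanceTable) -> None:
        """Raise listing offenders if any table OTU lacks a taxonomy entry."""
        missing = [o for o in table.otu_ids if o not in self.data.index]
        if missing:
            raise ValidationError(
                f"{len(missing)} OTUs missing from taxonomy: {missing[:20]}"
            )

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="otu_id")


@dataclass
class SampleMetadata:
    """Per-sample environmental vector plus habitat group label."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in (*ENV_VARS, "habitat_group") if c not in self.data.columns]
        if missing:
            raise ValidationError(f"metadata lacks columns: {missing}")
        _check_unique(self.data.index, "sample ids in metadata")
        env = self.data.loc[:, list(ENV_VARS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(env)):
            raise ValidationError("metadata contains non-finite environmental values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def habitat_group(self) -> pd.Series:
        return self.data["habitat_group"]

    def env_matrix(self, variables=ENV_VARS) -> pd.DataFrame:
        return self.data.loc[:, list(variables)].astype(float)

    def covers(self, table: AbundanceTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_abundance_table(
    path: str | Path, taxonomy_path: str | Path
) -> tuple[AbundanceTable, TaxonomyMap]:
    """Read and cross-validate an abundance TSV and its taxonomy TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found")
    table = AbundanceTable(df)
    tax = read_taxonomy(taxonomy_path)
    tax.covers(table)
    return table, tax


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    return TaxonomyMap(pd.read_csv(path, sep="\t", index_col=0, dtype=str))


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", index_col=0))


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def to_relative_abundance(table: AbundanceTable) -> RelativeAbundanceTable:
    """Close each sample to proportions: value(i,j) = count(i,j) / colsum(j)."""
    counts = table.data.to_numpy(dtype=float)
    colsums = counts.sum(axis=0)
    if np.any(colsums <= 0):
        bad = table.data.columns[colsums <= 0].tolist()
        raise ValidationError(f"cannot normalise zero-sum samples: {bad}")
    rel = pd.DataFrame(
        counts / colsums, index=table.data.index, columns=table.data.columns
    )
    return RelativeAbundanceTable(rel)


def prevalence_filter(
    table: AbundanceTable, min_samples_exclusive: int
) -> AbundanceTable:
    """Keep OTUs detected (count > 0) in strictly more than the given number
    of samples.

    The default pipeline threshold is 8 of 15 samples, i.e. an OTU must be
    present in at least nine samples to enter correlation screening.
    """
    n_samples = table.shape[1]
    if not 0 <= min_samples_exclusive < n_samples:
        raise ValueError(
            f"min_samples_exclusive must be in [0, {n_samples}); "
            f"got {min_samples_exclusive}"
        )
    prevalence = (table.data.to_numpy() > 0).sum(axis=1)
    keep = prevalence > min_samples_exclusive
    if not keep.any():
        raise ValidationError(
            "prevalence filter removed every OTU; lower min_samples_exclusive"
        )
    return AbundanceTable(table.data.loc[keep])


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

_NETWORK_FORMATS = ("graphml", "gexf", "edge-tsv")


def write_network(g: nx.Graph, path: str | Path, format: str | None = None) -> None:
    """Write a co-occurrence network with its node and edge attributes.

    ``format`` is one of ``graphml``, ``gexf`` or ``edge-tsv``; when omitted
    it is inferred from the file suffix.
    """
    path = Path(path)
    fmt = format or {".graphml": "graphml", ".gexf": "gexf", ".tsv": "edge-tsv"}.get(
        path.suffix, None
    )
    if fmt not in _NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; use one of {_NETWORK_FORMATS}")
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gexf":
        nx.write_gexf(g, path)
    else:
        rows = [
            {"source": u, "target": v, **attrs} for u, v, attrs in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "rho", "sign"]).to_csv(
            path, sep="\t", index=False
        )


def read_network(path: str | Path) -> nx.Graph:
    """Read a GraphML network written by :func:`write_network`."""
    return nx.read_graphml(path)
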