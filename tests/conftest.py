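import numpy as np
import pandas as pd
import pytest

from micronet import AbundanceTable, RelativeAbundanceTable, SampleMetadata, TaxonomyMap
from micronet.io import ENV_VARS, RANKS


def make_table(counts, otu_ids=None, sample_ids=None) -> AbundanceTable:
    counts = np.asarray(counts)
    otu_ids = otu_ids or [f"OTU{i+1}" for i in range(counts.shape[0])]
    sample_ids = sample_ids or [f"S{j+1}" for j in range(counts.shape[1])]
    return AbundanceTable(pd.DataFrame(counts, index=otu_ids, columns=sample_ids))


def make_taxonomy(kingdoms: dict, phyla: dict | None = None) -> TaxonomyMap:
    """kingdoms: otu_id -> 'Bacteria'/'Fungi'; phyla optional per OTU."""
    rows = {}
    for otu, k in kingdoms.items():
        row = {"kingdom": k}
        row["phylum"] = (phyla or {}).get(otu, "PhylumX")
        for rank in RANKS[2:]:
            row[rank] = "unclassified"
        rows[otu] = row
    return TaxonomyMap(pd.DataFrame.from_dict(rows, orient="index").rename_axis("otu_id"))


def make_metadata(sample_ids, habitat_groups, env=None, seed=0) -> SampleMetadata:
    rng = np.random.default_rng(seed)
    data = {var: rng.uniform(1, 10, len(sample_ids)) for var in ENV_VARS}
    if env:
        data.update(env)
    data["habitat_group"] = habitat_groups
    return SampleMetadata(pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id")))


def make_relative(values, otu_ids=None, sample_ids=None) -> RelativeAbundanceTable:
    values = np.asarray(values, dtype=float)
    otu_ids = otu_ids or [f"OTU{i+1}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j+1}" for j in range(values.shape[1])]
    return RelativeAbundanceTable(
        pd.DataFrame(values, index=otu_ids, columns=sample_ids)
    )


@pytest.fixture
def counts_3x2():
    return make_table([[4, 0], [6, 5], [0, 5]])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
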