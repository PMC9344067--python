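"""Six-class abundance classification of OTUs.

Each OTU is classified from the minimum ``m`` and maximum ``M`` of its
per-sample relative abundance against two thresholds, by default 1%
(abundant) and 0.01% (rare):

==== =========================================== =================
code name                                        rule (m, M)
==== =========================================== =================
AAT  always abundant taxa                        m > 1%
CAT  conditionally abundant taxa                 M > 1%, m >= 0.01% (not AAT)
ART  always rare taxa                            M < 0.01%
CRT  conditionally rare taxa                     M <= 1%, m < 0.01% (not ART)
MT   moderate taxa                               0.01% <= m <= M <= 1%
CRAT conditionally rare and abundant taxa        m < 0.01%, M > 1%
==== =========================================== =================

Boundary values (exactly 1% or exactly 0.01%) are resolved by the >=/<=
conventions above so that the six classes partition all OTUs.  The derived
dichotomy is abundant = {AAT, CAT, CRAT}, rare = {ART, CRT}; moderate taxa
are neither.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import RelativeAbundanceTable

ABUNDANT_CLASSES = frozenset({"AAT", "CAT", "CRAT"})
RARE_CLASSES = frozenset({"ART", "CRT"})


def _classify_one(m: float, M: float, abundant_thr: float, rare_thr: float) -> str:
    if m > abundant_thr:
        return "AAT"
    if M < rare_thr:
        return "ART"
    if M > abundant_thr:           # not always abundant, sometimes abundant
        return "CRAT" if m < rare_thr else "CAT"
    if m < rare_thr:               # never abundant, sometimes rare
        return "CRT"
    return "MT"


def dichotomy_of(cls: str) -> str:
    if cls in ABUNDANT_CLASSES:
        return "abundant"
    if cls in RARE_CLASSES:
        return "rare"
    return "neither"


def classify_abundance(
    rel: RelativeAbundanceTable,
    abundant_thr: float = 0.01,
    rare_thr: float = 0.0001,
) -> pd.DataFrame:
    """Classify every OTU of a relative-abundance table.

    Returns a DataFrame indexed by OTU id with columns ``class``,
    ``dichotomy``, ``min_rel`` and ``max_rel``.
    """
    if not 0 < rare_thr < abundant_thr < 1:
        raise ValueError(
            f"need 0 < rare_thr < abundant_thr < 1; got {rare_thr}, {abundant_thr}"
        )
    values = rel.data.to_numpy(dtype=float)
    mins = values.min(axis=1)
    maxs = values.max(axis=1)
    classes = [
        _classify_one(m, M, abundant_thr, rare_thr) for m, M in zip(mins, maxs)
    ]
    return pd.DataFrame(
        {
            "class": classes,
            "dichotomy": [dichotomy_of(c) for c in classes],
            "min_rel": mins,
            "max_rel": maxs,
        },
        index=pd.Index(rel.otu_ids, name="otu_id"),
    )
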