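"""Alpha diversity: observed richness, Shannon, Chao1, rarefaction, group ANOVA.

Shannon entropy is reported in nats by default; Chao1 uses the bias-corrected
estimator S_obs + F1(F1-1) / (2(F2+1)) where F1 and F2 are singleton and
doubleton counts (the classic F1^2/(2 F2) form is available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import AbundanceTable, SampleMetadata


def _shannon(counts: np.ndarray, base: float | None) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def _chao1(counts: np.ndarray, bias_corrected: bool) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2
    return s_obs + f1 * f1 / (2 * f2)


def alpha_diversity(
    table: AbundanceTable,
    base: float | None = None,
    bias_corrected: bool = True,
) -> pd.DataFrame:
    """Per-sample observed richness, Shannon (nats unless ``base`` given) and
    Chao1.  Returns a DataFrame indexed by sample id."""
    rows = {}
    for sample in table.sample_ids:
        counts = table.data[sample].to_numpy()
        rows[sample] = {
            "observed": int((counts > 0).sum()),
            "shannon": _shannon(counts, base),
            "chao1": _chao1(counts, bias_corrected),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def rarefaction_curve(
    table: AbundanceTable,
    depths: list[int],
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected observed richness per sample at each subsampling depth.

    Subsampling is without replacement (multivariate hypergeometric draws),
    averaged over ``reps`` replicates.  Depths exceeding a sample's library
    size raise an error.
    """
    rng = np.random.default_rng(seed)
    depths = sorted(int(d) for d in depths)
    if any(d < 1 for d in depths):
        raise ValueError("depths must be positive")
    out = {}
    for sample in table.sample_ids:
        counts = table.data[sample].to_numpy()
        library = int(counts.sum())
        row = {}
        for depth in depths:
            if depth > library:
                raise ValueError(
                    f"depth {depth} exceeds library size {library} of {sample}"
                )
            richness = [
                int((rng.multivariate_hypergeometric(counts, depth) > 0).sum())
                for _ in range(reps)
            ]
            row[depth] = float(np.mean(richness))
        out[sample] = row
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "sample_id"
    return df


@dataclass
class GroupComparison:
    """One-way ANOVA of a per-sample metric across habitat groups, with a
    Tukey-HSD compact letter display (groups sharing a letter do not differ
    at the chosen alpha)."""

    metric: str
    table: pd.DataFrame  # per group: n, mean, sd, letters
    f_statistic: float
    p_value: float
    alpha: float


def _letter_display(groups: list[str], nsd: set[frozenset]) -> dict[str, str]:
    """Greedy compact letter display from the not-significantly-different
    pair set.  Groups are assumed ordered (by descending mean)."""
    letter_sets: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, h)) in nsd for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # drop sets fully contained in another
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def group_anova(
    values: pd.Series,
    meta: SampleMetadata,
    alpha: float = 0.05,
    metric: str = "",
) -> GroupComparison:
    """One-way ANOVA of ``values`` (indexed by sample id) across habitat
    groups, with Tukey HSD letters at ``alpha``."""
    groups = meta.habitat_group.loc[values.index]
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two habitat groups for ANOVA")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than two samples: {small}")
    arrays = [values[groups == g].to_numpy(dtype=float) for g in counts.index]
    f_stat, p = stats.f_oneway(*arrays)
    tukey = pairwise_tukeyhsd(values.to_numpy(dtype=float), groups.to_numpy(), alpha=alpha)
    nsd: set[frozenset] = set()
    res = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    for _, row in res.iterrows():
        if not row["reject"]:
            nsd.add(frozenset((row["group1"], row["group2"])))
    order = (
        values.groupby(groups).mean().sort_values(ascending=False).index.tolist()
    )
    letters = _letter_display(order, nsd)
    summary = pd.DataFrame(
        {
            "n": [int((groups == g).sum()) for g in order],
            "mean": [values[groups == g].mean() for g in order],
            "sd": [values[groups == g].std(ddof=1) for g in order],
            "letters": [letters[g] for g in order],
        },
        index=pd.Index(order, name="habitat_group"),
    )
    return GroupComparison(metric, summary, float(f_stat), float(p), alpha)
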