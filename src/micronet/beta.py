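"""Beta diversity and ordination: Bray-Curtis, PCoA, PERMANOVA, Procrustes,
CCA.

Community dissimilarity uses Bray-Curtis, d(u, v) = 1 - 2 sum_i min(u_i, v_i)
/ (sum u + sum v).  Ordination is classical PCoA (double-centred Gram matrix
eigendecomposition; negative eigenvalues are zeroed and excluded from the
explained-variance denominator).  Group separation is tested by Anderson's
PERMANOVA with permutation p-values; community-environment concordance by
symmetric Procrustes with a PROTEST row-permutation test; and constrained
ordination by canonical correspondence analysis (CCA).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import cca as _skbio_cca
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io import ENV_VARS, AbundanceTable, RelativeAbundanceTable, SampleMetadata

logger = logging.getLogger(__name__)


def bray_curtis(table: AbundanceTable | RelativeAbundanceTable) -> DistanceMatrix:
    """Bray-Curtis distance matrix over samples (columns) of a table."""
    data = table.data.to_numpy(dtype=float).T  # samples x OTUs
    if data.shape[0] < 2:
        raise ValueError("need at least two samples for a distance matrix")
    if np.any(data.sum(axis=1) <= 0):
        raise ValueError("zero-sum sample in distance computation")
    return DistanceMatrix(squareform(pdist(data, metric="braycurtis")),
                          ids=table.sample_ids)


@dataclass
class OrdinationResult:
    """Sample coordinates plus per-axis proportion of variation explained."""

    coordinates: pd.DataFrame          # samples x axes
    proportion_explained: np.ndarray   # nonincreasing, in [0, 1]
    degenerate: bool = False           # all-zero distances collapse to a point

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix."""
    if np.allclose(d.data, 0.0):
        coords = pd.DataFrame(
            np.zeros((len(d.ids), 1)), index=list(d.ids), columns=["PC1"]
        )
        logger.warning("all distances zero: degenerate single-point ordination")
        return OrdinationResult(coords, np.array([0.0]), degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative-eigenvalue advisory
        res = _skbio_pcoa(d)
    prop = res.proportion_explained.to_numpy()
    n_axes = max(1, int((prop > 1e-12).sum()))
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.index = list(d.ids)
    return OrdinationResult(coords, prop[:n_axes])


@dataclass
class PermanovaResult:
    r2: float
    pseudo_f: float
    p_value: float
    n_perm: int


def permanova(
    d: DistanceMatrix,
    groups: pd.Series | list,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Anderson's PERMANOVA on a distance matrix.

    R^2 = SS_between / SS_total from the distance partition; pseudo-F and the
    permutation p-value, p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), come
    from scikit-bio's seeded implementation.
    """
    if isinstance(groups, pd.Series):
        groups = groups.loc[list(d.ids)]
        labels = groups.to_numpy()
    else:
        labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        raise ValueError(
            f"groups of size one are not testable: {uniq[counts < 2].tolist()}"
        )
    sq = d.data ** 2
    n = len(labels)
    ss_total = sq[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = sq[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(uniq)
    pseudo_f = (ss_between / (a - 1)) / (ss_within / (n - a))
    res = _skbio_permanova(d, labels, permutations=n_perm, seed=seed)
    return PermanovaResult(
        r2=float(ss_between / ss_total),
        pseudo_f=float(pseudo_f),
        p_value=float(res["p-value"]),
        n_perm=n_perm,
    )


@dataclass
class ProcrustesResult:
    m2: float
    p_value: float
    n_perm: int


def _pad_columns(a: np.ndarray, k: int) -> np.ndarray:
    if a.shape[1] >= k:
        return a
    return np.hstack([a, np.zeros((a.shape[0], k - a.shape[1]))])


def procrustes_test(
    x: OrdinationResult | np.ndarray | pd.DataFrame,
    y: OrdinationResult | np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> ProcrustesResult:
    """Symmetric Procrustes M^2 between two sample configurations with a
    PROTEST permutation p-value.

    Both configurations are centred and scaled to unit sum of squares before
    the optimal rotation, so M^2 lies in [0, 1] and equals 0 iff the shapes
    agree up to translation, rotation and scaling.  The p-value permutes the
    rows of ``y``: p = (1 + #{M^2_perm <= M^2_obs}) / (1 + n_perm).
    """
    xa = x.coordinates.to_numpy() if isinstance(x, OrdinationResult) else np.asarray(
        x, dtype=float
    )
    ya = y.coordinates.to_numpy() if isinstance(y, OrdinationResult) else np.asarray(
        y, dtype=float
    )
    if isinstance(x, pd.DataFrame):
        xa = x.to_numpy(dtype=float)
    if isinstance(y, pd.DataFrame):
        ya = y.to_numpy(dtype=float)
    if xa.shape[0] != ya.shape[0]:
        raise ValueError("configurations must cover the same samples")
    if xa.shape[0] < 3:
        raise ValueError("Procrustes needs at least three samples")
    k = max(xa.shape[1], ya.shape[1])
    xa, ya = _pad_columns(xa, k), _pad_columns(ya, k)
    _, _, m2 = _scipy_procrustes(xa, ya)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, _, m2_perm = _scipy_procrustes(xa, ya[rng.permutation(len(ya))])
        if m2_perm <= m2:
            hits += 1
    return ProcrustesResult(float(m2), (1 + hits) / (1 + n_perm), n_perm)


def env_pca(meta: SampleMetadata, variables=ENV_VARS) -> OrdinationResult:
    """PCA of standardised environmental variables, for the environment side
    of a Procrustes comparison.  Axes: min(#variables, n-1)."""
    env = meta.env_matrix(variables)
    sd = env.std(ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping constant env variables: %s",
                       sd.index[~keep].tolist())
    env = env.loc[:, keep]
    if env.shape[1] == 0:
        raise ValueError("no environmental variable with positive variance")
    z = (env - env.mean()) / env.std(ddof=1)
    u, s, _ = np.linalg.svd(z.to_numpy(), full_matrices=False)
    k = min(env.shape[1], env.shape[0] - 1)
    scores = u[:, :k] * s[:k]
    var = s ** 2
    coords = pd.DataFrame(
        scores, index=env.index, columns=[f"PC{i+1}" for i in range(k)]
    )
    return OrdinationResult(coords, var[:k] / var.sum())


@dataclass
class CcaResult:
    """Constrained fraction of inertia plus sample scores of the constrained
    axes."""

    constrained_fraction: float
    sample_scores: pd.DataFrame
    n_constrained_axes: int
    rank_deficient: bool


def cca(
    rel: RelativeAbundanceTable,
    meta: SampleMetadata,
    variables=ENV_VARS,
) -> CcaResult:
    """Canonical correspondence analysis of a community table on standardised
    environmental variables.

    ``constrained_fraction`` is the share of total chi-square inertia carried
    by the constrained axes — the proportion of community variation the
    measured environment explains.
    """
    env = meta.env_matrix(variables).loc[rel.sample_ids]
    sd = env.std(ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("CCA: dropping constant env variables: %s",
                       sd.index[~keep].tolist())
    env = env.loc[:, keep]
    if env.shape[1] < 1:
        raise ValueError("CCA needs at least one varying environmental variable")
    z = (env - env.mean()) / env.std(ddof=1)
    rank = int(np.linalg.matrix_rank(z.to_numpy() - z.to_numpy().mean(axis=0)))
    rank_deficient = rank < env.shape[1]
    if rank_deficient:
        logger.warning("CCA: environment matrix is rank deficient (rank %d of %d)",
                       rank, env.shape[1])
    # drop OTUs never observed (zero column in the species matrix)
    y = rel.data.T  # samples x OTUs
    y = y.loc[:, y.sum(axis=0) > 0]
    res = _skbio_cca(y, z)
    prop = res.proportion_explained.to_numpy()
    q = min(rank, y.shape[1])
    scores = res.samples.iloc[:, :q]
    scores.index = list(y.index)
    return CcaResult(
        constrained_fraction=float(prop[:q].sum()),
        sample_scores=scores,
        n_constrained_axes=q,
        rank_deficient=rank_deficient,
    )
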