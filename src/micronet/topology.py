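"""Global network topology, degree power-law fit, Louvain modules, and
Erdős–Rényi null ensembles.

Conventions (fixed across the package):

* average path length (APL) is the mean shortest-path length over all
  reachable ordered node pairs, self-pairs excluded — well defined for
  disconnected graphs;
* average clustering coefficient (ACC) is the mean of local clustering over
  all nodes, with nodes of degree < 2 contributing 0;
* the diameter is the longest shortest path within the largest connected
  component;
* modularity and module detection are sign-blind and unweighted.

python-igraph provides the C-speed path/clustering kernels (its conventions
match the above; verified against brute-force oracles in the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import igraph as ig
import networkx as nx
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class TopologySummary:
    """The headline statistics of one co-occurrence graph."""

    nodes: int
    edges: int
    density: float
    r2_powerlaw: float  # NaN when the degree distribution cannot be fitted
    acc: float
    apl: float
    diameter: int
    modularity: float
    pos_frac: float
    neg_frac: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PowerLawFit:
    exponent: float
    r2: float


@dataclass
class RandomEnsembleSummary:
    """APL/ACC of an Erdős–Rényi G(n, m) ensemble; the spread is reported
    both as the ensemble standard deviation and as the standard error of the
    mean."""

    n_realizations: int
    aplr_mean: float
    aplr_sd: float
    aplr_se: float
    accr_mean: float
    accr_sd: float
    accr_se: float


def _to_igraph(g: nx.Graph) -> ig.Graph:
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    return ig.Graph(len(nodes), edges)


def _apl_acc(h: ig.Graph) -> tuple[float, float]:
    if h.ecount() == 0:
        return 0.0, 0.0
    apl = h.average_path_length(directed=False, unconn=True)
    acc = h.transitivity_avglocal_undirected(mode="zero")
    return float(apl), float(acc)


def louvain_modules(
    g: nx.Graph, seed: int = 0, resolution: float = 1.0
) -> tuple[dict, float]:
    """Louvain community detection (unweighted, sign-blind) and its
    Newman-Girvan modularity Q.  Deterministic given the seed."""
    if g.number_of_edges() == 0:
        raise ValueError("module detection requires at least one edge")
    communities = nx.community.louvain_communities(
        g, weight=None, resolution=resolution, seed=seed
    )
    q = nx.community.modularity(g, communities, weight=None, resolution=resolution)
    assignment = {n: i for i, c in enumerate(communities) for n in c}
    return assignment, float(q)


def power_law_fit(g: nx.Graph) -> PowerLawFit:
    """Least-squares fit of ln count(k) on ln k over the degree histogram.

    Requires at least three distinct positive degrees with nonzero counts.
    """
    degrees = np.array([d for _, d in g.degree() if d > 0])
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        raise ValueError(
            f"power-law fit undefined: only {len(ks)} distinct degrees"
        )
    fit = stats.linregress(np.log(ks), np.log(counts))
    return PowerLawFit(exponent=-float(fit.slope), r2=float(fit.rvalue ** 2))


def topology_summary(g: nx.Graph, seed: int = 0) -> TopologySummary:
    """Compute the full statistics record of one graph.

    An empty graph yields an all-zero summary with a warning; a graph whose
    degree distribution is too degenerate for the power-law regression
    reports NaN for that entry.
    """
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        logger.warning("topology_summary of an empty graph")
        return TopologySummary(0, 0, 0.0, float("nan"), 0.0, 0.0, 0, 0.0, 0.0, 0.0)
    density = 2 * m / (n * (n - 1)) if n > 1 else 0.0
    apl, acc = _apl_acc(_to_igraph(g))
    if m > 0:
        giant = max(nx.connected_components(g), key=len)
        diameter = nx.diameter(g.subgraph(giant)) if len(giant) > 1 else 0
        _, modularity = louvain_modules(g, seed=seed)
        signs = np.array([attrs.get("sign", 1) for *_, attrs in g.edges(data=True)])
        pos_frac = float((signs > 0).mean())
        neg_frac = float((signs < 0).mean())
    else:
        diameter, modularity, pos_frac, neg_frac = 0, 0.0, 0.0, 0.0
    try:
        r2 = power_law_fit(g).r2
    except ValueError:
        r2 = float("nan")
    return TopologySummary(
        nodes=n, edges=m, density=float(density), r2_powerlaw=r2,
        acc=acc, apl=apl, diameter=int(diameter), modularity=modularity,
        pos_frac=pos_frac, neg_frac=neg_frac,
    )


def _gnm_edges(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """m distinct edges drawn uniformly from the C(n, 2) pair universe."""
    total = n * (n - 1) // 2
    idx = rng.choice(total, size=m, replace=False)
    # invert the row-major upper-triangle linearisation t = i(2n-i-1)/2 + j-i-1
    i = (n - 2 - np.floor(
        np.sqrt(-8.0 * idx + 4.0 * n * (n - 1) - 7) / 2.0 - 0.5
    )).astype(np.int64)
    j = idx - i * (2 * n - i - 1) // 2 + i + 1
    return np.column_stack([i, j.astype(np.int64)])


def random_ensemble(
    n_nodes: int,
    n_edges: int,
    n_realizations: int = 100,
    seed: int = 0,
) -> RandomEnsembleSummary:
    """APL/ACC statistics of ``n_realizations`` Erdős–Rényi G(n, m) graphs
    with exactly ``n_edges`` uniformly placed edges."""
    total = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= total:
        raise ValueError(f"impossible edge count {n_edges} for {n_nodes} nodes")
    rng = np.random.default_rng(seed)
    apls, accs = [], []
    for _ in range(n_realizations):
        edges = _gnm_edges(n_nodes, n_edges, rng)
        h = ig.Graph(n_nodes, [tuple(e) for e in edges])
        apl, acc = _apl_acc(h)
        apls.append(apl)
        accs.append(acc)
    apls, accs = np.asarray(apls), np.asarray(accs)
    sqrt_n = np.sqrt(n_realizations)
    return RandomEnsembleSummary(
        n_realizations=n_realizations,
        aplr_mean=float(apls.mean()),
        aplr_sd=float(apls.std(ddof=1)) if n_realizations > 1 else 0.0,
        aplr_se=float(apls.std(ddof=1) / sqrt_n) if n_realizations > 1 else 0.0,
        accr_mean=float(accs.mean()),
        accr_sd=float(accs.std(ddof=1)) if n_realizations > 1 else 0.0,
        accr_se=float(accs.std(ddof=1) / sqrt_n) if n_realizations > 1 else 0.0,
    )


def small_world_report(
    obs: TopologySummary, null: RandomEnsembleSummary
) -> dict:
    """Observed-vs-random ratios and z-scores for ACC and APL.

    A clustering coefficient far above the matched random expectation at a
    comparable path length is the operational signature of a small-world
    network.  Z-scores are None when the ensemble spread is zero.
    """
    def ratio(a: float, b: float) -> float:
        return float(a / b) if b != 0 else float("inf")

    def z(a: float, mean: float, sd: float):
        return float((a - mean) / sd) if sd > 0 else None

    return {
        "acc_ratio": ratio(obs.acc, null.accr_mean),
        "apl_ratio": ratio(obs.apl, null.aplr_mean),
        "acc_z": z(obs.acc, null.accr_mean, null.accr_sd),
        "apl_z": z(obs.apl, null.aplr_mean, null.aplr_sd),
    }
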