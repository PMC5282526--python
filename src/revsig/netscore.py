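"""Degree-weighted network efficacy.

Differential genes are mapped onto an undirected interaction network, the
largest directly-connected cluster is isolated, and each member gene's
log2 ratio is weighted by its node degree — a proxy for positional
importance — and summed::

    W = sum_{g in cluster} d_g * r_g

Significance is a two-sided permutation test drawing random gene sets of
cluster size from the measured network genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import LogRatioMatrix
from .stats import add_one_p

logger = logging.getLogger(__name__)

__all__ = [
    "largest_cluster",
    "weighted_ratio",
    "weighted_ratio_significance",
    "weighted_term_correlation",
    "WeightedRatioResult",
]


def largest_cluster(genes, network: nx.Graph) -> nx.Graph:
    """Largest connected component of the subgraph induced on ``genes``.

    Ties by size are broken toward the component containing the
    lexicographically smallest gene id (deterministic).  An empty
    intersection returns an empty graph with a warning.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    present = set(genes) & set(network.nodes)
    if not present:
        logger.warning("no query gene present in the network")
        return nx.Graph()
    sub = network.subgraph(present)
    components = sorted(nx.connected_components(sub),
                        key=lambda c: (-len(c), min(c)))
    top = components[0]
    if len(top) == 1:
        logger.warning("largest cluster is a single isolated node")
    return nx.Graph(sub.subgraph(top))


def _degrees(cluster: nx.Graph, network: nx.Graph, degree_source: str) -> dict[str, int]:
    if degree_source == "network":
        return {g: network.degree[g] for g in cluster.nodes}
    if degree_source == "cluster":
        return {g: cluster.degree[g] for g in cluster.nodes}
    raise ValueError("degree_source must be 'network' or 'cluster'")


def weighted_ratio(cluster: nx.Graph, lrm: LogRatioMatrix, condition: str,
                   network: nx.Graph | None = None,
                   degree_source: str = "network",
                   normalize: bool = False) -> float:
    """W = sum of degree * log2 ratio over the cluster for one condition.

    Degrees come from the full network by default (``degree_source=
    "cluster"`` recomputes within the cluster).  Cluster genes missing from
    the ratio matrix contribute 0 (logged).  ``normalize=True`` divides by
    cluster size for cross-study comparison.
    """
    if degree_source == "network" and network is None:
        raise ValueError("full-network degrees requested but no network given")
    deg = _degrees(cluster, network if network is not None else cluster, degree_source)
    r = lrm.values[condition]
    missing = [g for g in cluster.nodes if g not in r.index]
    if missing:
        logger.info("weighted ratio: %d cluster genes unmeasured, contribute 0", len(missing))
    # sorted order: the float sum must not depend on graph insertion order
    w = float(sum(deg[g] * r[g] for g in sorted(cluster.nodes) if g in r.index))
    return w / cluster.number_of_nodes() if normalize else w


@dataclass
class WeightedRatioResult:
    cluster_nodes: frozenset[str]
    w: dict[str, float]  # condition -> W
    p: dict[str, float]  # condition -> two-sided permutation p
    n_permutations: int
    seed: int | None


def weighted_ratio_significance(cluster: nx.Graph, lrm: LogRatioMatrix,
                                network: nx.Graph, conditions=None,
                                n_permutations: int = 1000, seed: int | None = None,
                                degree_source: str = "network") -> WeightedRatioResult:
    """Two-sided permutation p for W in each condition.

    The null draws random gene sets of cluster size from the measured
    network genes; each drawn gene carries its own network degree.
    """
    conditions = list(lrm.conditions) if conditions is None else list(conditions)
    # degree-0 genes cannot contribute to any W; drawing the null from the
    # connected, measured genes also keeps the pool identical whether the
    # network came from memory or from an edge list (which has no isolates)
    pool = sorted(g for g in set(network.nodes) & set(lrm.genes)
                  if network.degree[g] > 0)
    size = cluster.number_of_nodes()
    if len(pool) < size:
        raise ValueError("measured network universe smaller than the cluster")
    pool_deg = np.array([network.degree[g] for g in pool], dtype=float)
    values = lrm.values.loc[pool].to_numpy(dtype=float)
    cond_idx = {c: list(lrm.conditions).index(c) for c in conditions}

    w_obs = {c: weighted_ratio(cluster, lrm, c, network=network,
                               degree_source=degree_source) for c in conditions}
    rng = np.random.default_rng(seed)
    exceed = {c: 0 for c in conditions}
    for _ in range(n_permutations):
        pick = rng.choice(len(pool), size=size, replace=False)
        picked = pool_deg[pick][:, None] * values[pick]
        totals = picked.sum(axis=0)
        for c in conditions:
            if abs(totals[cond_idx[c]]) >= abs(w_obs[c]):
                exceed[c] += 1
    p = {c: add_one_p(exceed[c], n_permutations) for c in conditions}
    return WeightedRatioResult(cluster_nodes=frozenset(cluster.nodes), w=w_obs, p=p,
                               n_permutations=n_permutations, seed=seed)


def weighted_term_correlation(cluster: nx.Graph, lrm: LogRatioMatrix,
                              condition_a: str, condition_b: str,
                              network: nx.Graph | None = None,
                              degree_source: str = "network",
                              n_permutations: int = 1000,
                              seed: int | None = None) -> tuple[float, float, pd.DataFrame]:
    """Correlate per-gene weighted terms d_g * r_g between two conditions.

    Returns (Pearson r, permutation p, the per-gene term table).  The
    permutation p shuffles one condition's terms across genes and compares
    |r*| with |r| (add-one estimator).
    """
    if degree_source == "network" and network is None:
        raise ValueError("full-network degrees requested but no network given")
    deg = _degrees(cluster, network if network is not None else cluster, degree_source)
    genes = sorted(g for g in cluster.nodes if g in lrm.genes)
    if len(genes) < 3:
        raise ValueError("need at least 3 measured cluster genes")
    d = np.array([deg[g] for g in genes], dtype=float)
    ta = d * lrm.values.loc[genes, condition_a].to_numpy(dtype=float)
    tb = d * lrm.values.loc[genes, condition_b].to_numpy(dtype=float)
    r = float(sps.pearsonr(ta, tb)[0])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        rb = tb[rng.permutation(len(tb))]
        if abs(float(sps.pearsonr(ta, rb)[0])) >= abs(r):
            exceed += 1
    p = add_one_p(exceed, n_permutations)
    table = pd.DataFrame({"degree": d, condition_a: ta, condition_b: tb},
                         index=pd.Index(genes, name="gene"))
    return r, p, table
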