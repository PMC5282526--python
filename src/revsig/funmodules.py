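"""Functional-module detection and module/term overlap statistics.

A functional graph links genes whose log-ratio trajectories correlate at
or above a Pearson threshold (0.8 by default, signed), optionally
restricted to a backbone interaction network.  Modules are found with the
classic Markov Cluster Algorithm (MCL): alternate expansion (matrix
power) and inflation (entrywise power + column renormalization) of the
column-stochastic transition matrix until it converges to an attractor
structure, whose connected components are the clusters.  Cross-dataset
module overlap and shared enriched functions are scored with the
hypergeometric tail; term-term similarity edges use the overlap
coefficient OC(A,B) = |A n B| / min(|A|, |B|).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import LogRatioMatrix
from .pathways import term_enrichment
from .stats import hypergeom_sf

logger = logging.getLogger(__name__)

__all__ = [
    "build_functional_graph",
    "mcl_cluster",
    "ModuleSet",
    "module_overlap_significance",
    "overlap_coefficient",
    "enrichment_map_edges",
    "shared_function_count",
]


def build_functional_graph(lrm: LogRatioMatrix, backbone: nx.Graph | None = None,
                           r_threshold: float = 0.8, genes=None,
                           absolute: bool = False) -> nx.Graph:
    """Correlation-filtered functional graph over gene trajectories.

    An edge (g, h) is kept iff Pearson(r_g, r_h) >= ``r_threshold``
    (signed by default; ``absolute=True`` thresholds |r| instead) and, when
    a backbone network is given, (g, h) is a backbone edge.  Zero-variance
    genes are excluded with a logged count.
    """
    if lrm.values.shape[1] < 3:
        raise ValueError("correlation needs at least 3 conditions")
    sub = lrm.values if genes is None else lrm.values.loc[
        [g for g in genes if g in lrm.values.index]]
    data = sub.to_numpy(dtype=float)
    variable = np.ptp(data, axis=1) > 0
    dropped = int((~variable).sum())
    if dropped:
        logger.info("functional graph: excluded %d zero-variance genes", dropped)
    names = list(sub.index[variable])
    data = data[variable]

    G = nx.Graph()
    G.add_nodes_from(names)
    if len(names) < 2:
        return G

    if backbone is not None:
        pos = {g: i for i, g in enumerate(names)}
        centered = data - data.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        for a, b in backbone.edges:
            if a in pos and b in pos and a != b:
                i, j = pos[a], pos[b]
                r = float(centered[i] @ centered[j] / (norms[i] * norms[j]))
                if (abs(r) if absolute else r) >= r_threshold:
                    G.add_edge(a, b, weight=r)
        return G

    corr = np.corrcoef(data)
    crit = np.abs(corr) if absolute else corr
    ii, jj = np.where(np.triu(crit >= r_threshold, k=1))
    for i, j in zip(ii, jj):
        G.add_edge(names[i], names[j], weight=float(corr[i, j]))
    return G


@dataclass
class ModuleSet:
    modules: list[frozenset[str]]
    labels: dict[str, int] = field(default_factory=dict)
    singletons_discarded: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = {g: i for i, mod in enumerate(self.modules) for g in mod}


def mcl_cluster(graph: nx.Graph, inflation: float = 2.0, expansion: int = 2,
                prune_threshold: float = 1e-5, max_iter: int = 100,
                min_module_size: int = 3, tol: float = 1e-8) -> ModuleSet:
    """Markov clustering of a non-negatively weighted graph.

    Self-loops of weight 1 are added (standard MCL regularization), the
    adjacency is column-normalized, and expansion/inflation alternate until
    the maximum entry change drops below ``tol``.  Clusters are the
    connected components of the non-zero structure of the limit matrix; a
    node attracted to several systems goes to the lowest-labeled module.
    Modules below ``min_module_size`` are discarded and counted.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty graph")
    n = len(nodes)
    pos = {g: i for i, g in enumerate(nodes)}
    M = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = abs(float(data.get("weight", 1.0)))
        M[pos[a], pos[b]] = w
        M[pos[b], pos[a]] = w
    np.fill_diagonal(M, 1.0)
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        last = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune_threshold] = 0.0
        M /= M.sum(axis=0, keepdims=True)
        if np.max(np.abs(M - last)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iter)

    # clusters: connected components of the symmetrized support of the limit
    support = nx.Graph()
    support.add_nodes_from(range(n))
    ii, jj = np.nonzero(M)
    support.add_edges_from((int(i), int(j)) for i, j in zip(ii, jj) if i != j)
    raw = [frozenset(nodes[i] for i in comp)
           for comp in nx.connected_components(support)]
    raw.sort(key=lambda mod: (-len(mod), min(mod)))

    modules, labels, discarded = [], {}, 0
    for mod in raw:
        if len(mod) >= min_module_size:
            label = len(modules)
            modules.append(mod)
            for g in mod:
                if g not in labels:  # disjointness: lowest label wins
                    labels[g] = label
        else:
            discarded += len(mod)
    return ModuleSet(modules=modules, labels=labels,
                     singletons_discarded=discarded, converged=converged)


def module_overlap_significance(module_a, module_b, universe) -> float:
    """Hypergeometric P(X >= |A n B|) for the overlap of two modules."""
    universe = set(universe)
    a = set(module_a) & universe
    b = set(module_b) & universe
    k = len(a & b)
    return hypergeom_sf(k, len(universe), len(a), len(b))


def overlap_coefficient(set_a, set_b) -> float:
    """OC(A, B) = |A n B| / min(|A|, |B|)."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def enrichment_map_edges(term_sets: dict, similarity_cutoff: float = 0.5,
                         external_gene_list=None, universe=None,
                         edge_p_cutoff: float = 0.01) -> pd.DataFrame:
    """Term-term similarity edges by overlap coefficient (inclusive cutoff).

    When an external gene list (and universe) is supplied, each edge also
    carries the hypergeometric p of the two terms' union against that list
    — the post-analysis edge weight — and edges are annotated with whether
    it clears ``edge_p_cutoff``.
    """
    ids = sorted(term_sets)
    rows = []
    for i, ta in enumerate(ids):
        for tb in ids[i + 1:]:
            oc = overlap_coefficient(term_sets[ta], term_sets[tb])
            if oc >= similarity_cutoff:
                row = {"term_a": ta, "term_b": tb, "overlap_coefficient": oc}
                if external_gene_list is not None:
                    if universe is None:
                        raise ValueError("external gene list requires a universe")
                    union = set(term_sets[ta]) | set(term_sets[tb])
                    uni = set(universe)
                    k = len(union & set(external_gene_list) & uni)
                    p = hypergeom_sf(k, len(uni), len(union & uni),
                                     len(set(external_gene_list) & uni))
                    row["edge_p"] = p
                    row["significant"] = p <= edge_p_cutoff
                rows.append(row)
    cols = ["term_a", "term_b", "overlap_coefficient"]
    if external_gene_list is not None:
        cols += ["edge_p", "significant"]
    return pd.DataFrame(rows, columns=cols)


def shared_function_count(modules_a: ModuleSet, modules_b: ModuleSet,
                          terms: dict, universe, q_cutoff: float = 0.01
                          ) -> tuple[frozenset[str], float]:
    """Terms enriched in both datasets' modules, with overlap significance.

    A term counts for a dataset when it is enriched (BH q < ``q_cutoff``)
    in at least one of its modules.  The intersection's size is scored by
    a hypergeometric test over the term universe.
    """

    def enriched_terms(modules: ModuleSet) -> set[str]:
        hits: set[str] = set()
        for mod in modules.modules:
            query = set(mod) & set(universe)
            if not query:
                continue
            for row in term_enrichment(query, terms, universe):
                if row.q < q_cutoff:
                    hits.add(row.term_id)
        return hits

    ea, eb = enriched_terms(modules_a), enriched_terms(modules_b)
    common = frozenset(ea & eb)
    if not ea or not eb:
        return common, 1.0
    p = hypergeom_sf(len(common), len(terms), len(ea), len(eb))
    return common, p
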