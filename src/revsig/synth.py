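"""Synthetic inputs with planted truth for every stage of the pipeline.

The generators emulate the structure of a disease-versus-control microarray
study with a dose (or time) series that progressively restores a planted
disease signature, a reference library of drug instances in which some drugs
mimic and some invert that signature, a pathway database with activator /
repressor roles, an interaction network with planted dense modules, and a
literature count matrix with one planted enriched item set.

Intensity model: ``intensity = 2**(baseline + effect + noise)`` with the
per-gene baseline drawn once, so intensities are strictly positive and
planted fold-changes are exact when ``noise_sd == 0``.

Each generator draws from its own RNG stream derived from the master seed by
a fixed offset, so stages are reproducible when re-run in isolation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    ExpressionStudy,
    Pathway,
    PathwayDB,
    PlantedTruth,
    ReferenceLibrary,
)

__all__ = [
    "SynthConfig",
    "generate_expression_study",
    "generate_reference_library",
    "generate_pathway_db",
    "generate_interaction_network",
    "generate_literature_counts",
    "generate_all",
]

# fixed per-stage RNG stream offsets (stage reproducibility in isolation)
_STREAM = {
    "expression": 11,
    "library": 23,
    "pathways": 37,
    "network": 53,
    "literature": 71,
}


@dataclass
class SynthConfig:
    """Configuration of the planted synthetic world.

    Defaults describe a desk-scale analogue of the study design this
    pipeline targets: a few thousand genes, a disease contrast with a large
    planted two-fold signature, a three-step restoring dose series, and a
    reference library of 50 drugs x 2 instances of which a handful mimic
    and a handful invert the disease signature.
    """

    n_genes: int = 2000
    n_drugs: int = 50
    instances_per_drug: int = 2
    frac_disease_up: float = 0.15
    frac_disease_down: float | None = None  # defaults to frac_disease_up
    effect_log2: float = 1.5
    noise_sd: float = 0.2
    reversal_drugs: tuple[str, ...] = ("drug00", "drug01", "drug02", "drug03", "drug04")
    mimic_drugs: tuple[str, ...] = ("drug05", "drug06", "drug07", "drug08", "drug09")
    doses_or_times: tuple[str, ...] = ("dose:10", "dose:50", "dose:100")
    restore_fraction_per_step: float = 0.5
    seed: int = 0

    # ranking noise: number of random adjacent transpositions applied to a
    # planted instance ranking, as a multiple of n_genes
    rank_noise: float = 2.0

    # interaction-network plant
    n_modules: int = 4
    module_size: int = 8
    p_within: float = 0.9
    p_between: float = 0.02
    background_edge_prob: float = 0.002

    # pathway plant
    n_pathways: int = 20
    pathway_size: int = 20

    # literature plant
    n_keywords: int = 10
    lit_enriched_prob: float = 0.9
    lit_background_prob: float = 0.1

    # expression plumbing
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.5
    frac_unexpressed: float = 0.05  # genes planted below the background filter
    background_level: float = 100.0

    def __post_init__(self) -> None:
        if self.frac_disease_down is None:
            self.frac_disease_down = self.frac_disease_up
        errors = []
        for name in ("n_genes", "n_drugs", "instances_per_drug"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        for name in ("frac_disease_up", "frac_disease_down", "restore_fraction_per_step",
                     "lit_enriched_prob", "lit_background_prob", "frac_unexpressed"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                errors.append(f"{name} must lie in [0, 1]")
        if self.frac_disease_up + self.frac_disease_down > 1.0:
            errors.append("planted up+down fractions exceed 1")
        if self.noise_sd < 0:
            errors.append("noise_sd must be non-negative")
        if set(self.reversal_drugs) & set(self.mimic_drugs):
            errors.append("reversal and mimic drug lists must be disjoint")
        if errors:
            raise ValueError("invalid SynthConfig: " + "; ".join(errors))

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes - 1)))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def drug_ids(self) -> list[str]:
        return [f"drug{i:02d}" for i in range(self.n_drugs)]

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self.seed * 1000 + _STREAM[stage])


def _plant_gene_sets(config: SynthConfig) -> tuple[list[str], list[str], list[str]]:
    """Deterministically split the gene universe into up / down / null genes.

    The planted sets occupy the front of the id-ordered universe; randomness
    is unnecessary because all downstream statistics are invariant to which
    ids are planted.
    """
    genes = config.gene_ids()
    n_up = int(round(config.frac_disease_up * config.n_genes))
    n_down = int(round(config.frac_disease_down * config.n_genes))
    return genes[:n_up], genes[n_up:n_up + n_down], genes[n_up + n_down:]


def make_truth(config: SynthConfig) -> PlantedTruth:
    """The planted truth implied by a config (gene sets only; generators fill the rest)."""
    up, down, _ = _plant_gene_sets(config)
    return PlantedTruth(up_genes=frozenset(up), down_genes=frozenset(down))


def generate_expression_study(config: SynthConfig) -> tuple[ExpressionStudy, PlantedTruth]:
    """Simulate the control / disease / dose-series intensity matrix.

    Planted up (down) genes are shifted by +effect_log2 (-effect_log2) on
    the log2 scale in the disease sample; each dose step removes
    ``restore_fraction_per_step`` of the remaining effect.  A small planted
    fraction of null genes is "unexpressed" (below the background filter).
    """
    rng = config.rng("expression")
    genes = config.gene_ids()
    up, down, null = _plant_gene_sets(config)
    truth = PlantedTruth(up_genes=frozenset(up), down_genes=frozenset(down))

    samples = ["control", "disease"] + [f"treated_{i}" for i in range(len(config.doses_or_times))]
    roles = {"control": "control", "disease": "disease"}
    for i, label in enumerate(config.doses_or_times):
        roles[f"treated_{i}"] = label

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    # unexpressed genes sit just below factor*background on the intensity scale
    n_unexpr = int(round(config.frac_unexpressed * config.n_genes))
    unexpressed = null[:n_unexpr]
    idx = {g: i for i, g in enumerate(genes)}
    low = np.log2(config.background_level) - 1.0  # intensity = background/2 < 1.4*background
    for g in unexpressed:
        baseline[idx[g]] = low

    sign = np.zeros(config.n_genes)
    sign[[idx[g] for g in up]] = 1.0
    sign[[idx[g] for g in down]] = -1.0

    # residual effect multiplier per sample
    keep = {"control": 0.0, "disease": 1.0}
    residual = 1.0
    for i in range(len(config.doses_or_times)):
        residual *= (1.0 - config.restore_fraction_per_step)
        keep[f"treated_{i}"] = residual

    log2x = np.empty((config.n_genes, len(samples)))
    for j, s in enumerate(samples):
        log2x[:, j] = baseline + keep[s] * config.effect_log2 * sign
    if config.noise_sd > 0:
        log2x += rng.normal(0.0, config.noise_sd, log2x.shape)

    intensities = pd.DataFrame(np.exp2(log2x), index=pd.Index(genes, name="gene"),
                               columns=samples)
    background = pd.DataFrame(config.background_level, index=intensities.index,
                              columns=intensities.columns)
    study = ExpressionStudy(intensities=intensities, roles=roles, background=background)
    return study, truth


def _noisy_permutation(order: np.ndarray, n_swaps: int, rng: np.random.Generator) -> np.ndarray:
    """Apply random adjacent transpositions to an ordering (vectorised sweeps)."""
    order = order.copy()
    n = len(order)
    if n < 2 or n_swaps <= 0:
        return order
    positions = rng.integers(0, n - 1, size=n_swaps)
    for p in positions:
        order[p], order[p + 1] = order[p + 1], order[p]
    return order


def generate_reference_library(config: SynthConfig, truth: PlantedTruth) -> ReferenceLibrary:
    """Simulate the drug-instance rank library.

    Mimic drugs place the planted up genes at the top ranks and the planted
    down genes at the bottom; reversal drugs do the opposite; neutral drugs
    are uniform random permutations.  Ranking noise is a fixed number of
    random adjacent transpositions (``rank_noise * n_genes``).
    """
    genes = config.gene_ids()
    n = len(genes)
    if n == 0:
        raise ValueError("empty gene universe")
    universe = set(genes)
    if not (truth.up_genes <= universe and truth.down_genes <= universe):
        raise ValueError("planted truth references genes outside the universe")

    rng = config.rng("library")
    idx = {g: i for i, g in enumerate(genes)}
    up_idx = np.array(sorted(idx[g] for g in truth.up_genes), dtype=int)
    down_idx = np.array(sorted(idx[g] for g in truth.down_genes), dtype=int)
    other_idx = np.array([i for i in range(n)
                          if genes[i] not in truth.up_genes and genes[i] not in truth.down_genes],
                         dtype=int)
    n_swaps = int(round(config.rank_noise * n))

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for drug in config.drug_ids():
        for k in range(config.instances_per_drug):
            inst = f"{drug}_i{k}"
            if drug in config.mimic_drugs or drug in config.reversal_drugs:
                mid = other_idx.copy()
                rng.shuffle(mid)
                top, bottom = (up_idx, down_idx) if drug in config.mimic_drugs else (down_idx, up_idx)
                order = np.concatenate([top, mid, bottom])  # order[r-1] = gene at rank r
                order = _noisy_permutation(order, n_swaps, rng)
            else:
                order = rng.permutation(n)
            ranks = np.empty(n, dtype=int)
            ranks[order] = np.arange(1, n + 1)
            columns[inst] = ranks
            meta_rows.append((inst, drug))

    ranks = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    meta = pd.DataFrame(meta_rows, columns=["instance_id", "drug"]).set_index("instance_id")
    return ReferenceLibrary(ranks=ranks, meta=meta)


def generate_pathway_db(config: SynthConfig, truth: PlantedTruth) -> tuple[PathwayDB, PlantedTruth]:
    """Simulate pathway gene sets with activator/repressor roles.

    Half of the planted pathways are "up" pathways built from planted up
    genes (all activators, direction +1), half are "down" pathways from
    planted down genes (direction -1); the remainder are random gene sets
    (direction 0).  The first up pathway is duplicated with every role
    flipped to repressor, giving an exactly negated activity.
    """
    if config.pathway_size < 2:
        raise ValueError("pathway size must be at least 2")
    rng = config.rng("pathways")
    genes = config.gene_ids()
    up = sorted(truth.up_genes)
    down = sorted(truth.down_genes)

    n_planted_up = min(3, len(up) // config.pathway_size)
    n_planted_down = min(3, len(down) // config.pathway_size)
    pathways: list[Pathway] = []
    direction: dict[str, int] = {}

    def take(pool: list[str], k: int) -> list[str]:
        picked = list(rng.choice(pool, size=k, replace=False))
        return picked

    for i in range(n_planted_up):
        pid = f"path_up{i:02d}"
        members = take(up, config.pathway_size)
        pathways.append(Pathway(pid, f"planted up pathway {i}", frozenset(members)))
        direction[pid] = 1
    for i in range(n_planted_down):
        pid = f"path_dn{i:02d}"
        members = take(down, config.pathway_size)
        pathways.append(Pathway(pid, f"planted down pathway {i}", frozenset(members)))
        direction[pid] = -1
    while len(pathways) < config.n_pathways - 1:
        pid = f"path_rand{len(pathways):02d}"
        members = take(genes, config.pathway_size)
        pathways.append(Pathway(pid, f"random pathway {len(pathways)}", frozenset(members)))
        direction[pid] = 0

    if n_planted_up > 0:
        flipped = pathways[0].role_flipped()
        pathways.append(flipped)
        direction[flipped.id] = -direction[pathways[0].id]

    new_truth = PlantedTruth(
        up_genes=truth.up_genes,
        down_genes=truth.down_genes,
        pathway_direction=direction,
        module_partition=truth.module_partition,
        enriched_literature_items=truth.enriched_literature_items,
    )
    return PathwayDB(pathways), new_truth


def generate_interaction_network(config: SynthConfig, truth: PlantedTruth
                                 ) -> tuple[nx.Graph, PlantedTruth]:
    """Simulate an undirected interaction network with planted dense modules.

    Modules are near-cliques (edge probability ``p_within``) drawn from the
    planted differential genes, joined by sparse inter-module edges
    (``p_between``); the rest of the universe gets sparse background edges.
    """
    rng = config.rng("network")
    genes = config.gene_ids()
    diff = sorted(truth.up_genes) + sorted(truth.down_genes)
    needed = config.n_modules * config.module_size
    if needed > len(diff):
        raise ValueError("not enough planted differential genes for the requested modules")

    partition: dict[str, int] = {}
    modules: list[list[str]] = []
    for m in range(config.n_modules):
        members = diff[m * config.module_size:(m + 1) * config.module_size]
        modules.append(members)
        for g in members:
            partition[g] = m

    G: nx.Graph = nx.Graph()
    G.add_nodes_from(genes)
    for members in modules:
        for a, b in itertools.combinations(members, 2):
            if rng.random() < config.p_within:
                G.add_edge(a, b)
    for ma, mb in itertools.combinations(modules, 2):
        for a in ma:
            for b in mb:
                if rng.random() < config.p_between:
                    G.add_edge(a, b)
    in_module = set(partition)
    rest = [g for g in genes if g not in in_module]
    if config.background_edge_prob > 0 and len(rest) > 1:
        # sparse Erdos-Renyi background among non-module genes
        m_edges = rng.binomial(len(rest) * (len(rest) - 1) // 2, config.background_edge_prob)
        a = rng.integers(0, len(rest), size=2 * m_edges)
        b = rng.integers(0, len(rest), size=2 * m_edges)
        added = 0
        for i, j in zip(a, b):
            if added >= m_edges:
                break
            if i != j:
                G.add_edge(rest[i], rest[j])
                added += 1

    new_truth = PlantedTruth(
        up_genes=truth.up_genes,
        down_genes=truth.down_genes,
        pathway_direction=truth.pathway_direction,
        module_partition=partition,
        enriched_literature_items=truth.enriched_literature_items,
    )
    return G, new_truth


def generate_literature_counts(config: SynthConfig, truth: PlantedTruth
                               ) -> tuple[pd.DataFrame, PlantedTruth]:
    """Simulate the item x keyword literature count matrix.

    Planted enriched items (the reversal and mimic drugs) have probability
    ``lit_enriched_prob`` of a non-zero count per keyword; all other items
    ``lit_background_prob``.  Non-zero counts are 1 + Poisson(2), so a few
    items are "heavily referred" — the bias the binarization step removes.
    """
    rng = config.rng("literature")
    items = config.drug_ids()
    keywords = [f"kw{i:02d}" for i in range(config.n_keywords)]
    enriched = frozenset(config.reversal_drugs) | frozenset(config.mimic_drugs)

    probs = np.array([config.lit_enriched_prob if it in enriched else config.lit_background_prob
                      for it in items])
    nonzero = rng.random((len(items), len(keywords))) < probs[:, None]
    counts = np.where(nonzero, 1 + rng.poisson(2.0, nonzero.shape), 0)
    matrix = pd.DataFrame(counts, index=pd.Index(items, name="item"),
                          columns=keywords)

    new_truth = PlantedTruth(
        up_genes=truth.up_genes,
        down_genes=truth.down_genes,
        pathway_direction=truth.pathway_direction,
        module_partition=truth.module_partition,
        enriched_literature_items=enriched,
    )
    return matrix, new_truth


def generate_all(config: SynthConfig) -> dict:
    """Run every generator and return the complete synthetic world."""
    study, truth = generate_expression_study(config)
    library = generate_reference_library(config, truth)
    pathway_db, truth = generate_pathway_db(config, truth)
    network, truth = generate_interaction_network(config, truth)
    literature, truth = generate_literature_counts(config, truth)
    return {
        "config": config,
        "study": study,
        "library": library,
        "pathways": pathway_db,
        "network": network,
        "literature": literature,
        "truth": truth,
    }
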