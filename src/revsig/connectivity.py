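"""Connectivity-map style signature matching.

A query signature (up and down tag lists) is scored against each reference
instance (a full gene ranking, rank 1 = most up-regulated by the
treatment) with a Kolmogorov-Smirnov-type enrichment statistic; instance
scores are aggregated to drug level by the same statistic over the ordered
instance list, with a permutation p-value; and two queries' drug-score
profiles are compared by Pearson correlation — the inverse-relationship
statistic at the heart of signature-reversal drug repurposing.

With V(1) < ... < V(t) the sorted ranks of the t tag genes in a universe
of n::

    a  = max_j [ j/t - V(j)/n ]
    b  = max_j [ V(j)/n - (j-1)/t ]
    ES = a if a >= b else -b

ES is +1-bounded concentration at the top of the ranking, -1-bounded at
the bottom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import RankedInstance, ReferenceLibrary, Signature
from .stats import add_one_p

logger = logging.getLogger(__name__)

__all__ = [
    "ks_enrichment",
    "ks_enrichment_from_ranks",
    "instance_connectivity",
    "scale_scores",
    "drug_enrichment",
    "profile_correlation",
    "ConnectivityResult",
]


def ks_enrichment_from_ranks(tag_ranks, n: int) -> float:
    """KS enrichment score from tag positions (subset of 1..n)."""
    v = np.sort(np.asarray(tag_ranks, dtype=float))
    t = len(v)
    if t == 0:
        raise ValueError("empty tag set")
    if t > n or v[0] < 1 or v[-1] > n or len(np.unique(v)) != t:
        raise ValueError("tag ranks must be a subset of 1..n")
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a >= b else -b


def ks_enrichment(tags, instance: RankedInstance, missing: str = "drop") -> float:
    """KS enrichment of a tag set in one instance's ranking.

    Tags absent from the instance's universe are dropped with a logged
    count (``missing="drop"``, the default) or raise (``missing="error"``).
    """
    tags = set(tags)
    if not tags:
        raise ValueError("empty tag set")
    present = [g for g in tags if g in instance.rank_of]
    n_missing = len(tags) - len(present)
    if n_missing:
        if missing == "error":
            raise KeyError(f"{n_missing} tags missing from instance {instance.instance_id}")
        logger.debug("instance %s: dropped %d missing tags", instance.instance_id, n_missing)
    if not present:
        raise ValueError("no tag present in the instance universe")
    return ks_enrichment_from_ranks([instance.rank_of[g] for g in present], instance.n)


def instance_connectivity(sig: Signature, instance: RankedInstance,
                          missing: str = "drop") -> tuple[float | None, float | None, float]:
    """(ES_up, ES_down, combined score c) for one instance.

    c = 0 when the two enrichment scores share a sign (discordant tags),
    otherwise c = ES_up - ES_down.  With a single tag list, c is the ES of
    that list (down tags contribute with flipped sign).
    """
    es_up = ks_enrichment(sig.up_tags, instance, missing) if sig.up_tags else None
    es_down = ks_enrichment(sig.down_tags, instance, missing) if sig.down_tags else None
    if es_up is None:
        return None, es_down, -es_down
    if es_down is None:
        return es_up, None, es_up
    c = 0.0 if np.sign(es_up) == np.sign(es_down) else es_up - es_down
    return es_up, es_down, c


def scale_scores(c_values) -> np.ndarray:
    """Scale combined scores into [-1, 1].

    Positive scores are divided by the maximum positive score, negative by
    the magnitude of the minimum negative score; zeros stay zero.
    """
    c = np.asarray(c_values, dtype=float)
    out = np.zeros_like(c)
    pos, neg = c > 0, c < 0
    if pos.any():
        out[pos] = c[pos] / c[pos].max()
    if neg.any():
        out[neg] = c[neg] / abs(c[neg].min())
    return out


@dataclass
class ConnectivityResult:
    """Per-instance and per-drug connectivity scores with permutation provenance."""

    label: str
    per_instance: pd.DataFrame  # instance_id(index), drug, es_up, es_down, c, scaled
    per_drug: pd.DataFrame  # drug(index), es, p, n_instances
    n_permutations: int
    seed: int | None


def _max_positive_es(k: int, n: int) -> float:
    """Largest attainable ES for k tags in a universe of n (tags at ranks 1..k)."""
    j = np.arange(1, k + 1, dtype=float)
    return float(np.max(j / k - j / n))


def drug_enrichment(sig: Signature, library: ReferenceLibrary,
                    n_permutations: int = 1000, seed: int | None = None,
                    missing: str = "drop") -> ConnectivityResult:
    """Score a signature against a library and aggregate to drug level.

    Instances are ordered by descending combined score c (ties broken by
    instance id); each drug's ES is the same KS statistic over its
    instances' positions in that ordering, and its p-value compares |ES|
    with |ES*| over random position sets of the same size (add-one
    estimator).
    """
    genes = library.genes
    gene_pos = pd.Index(genes)
    rank_mat = library.ranks.to_numpy()
    n_genes = len(genes)

    def tag_ranks(tags) -> tuple[np.ndarray, int]:
        present = gene_pos.get_indexer([g for g in tags if g in gene_pos])
        dropped = len(tags) - len(present)
        return present, dropped

    rows = []
    up_idx, up_dropped = tag_ranks(sig.up_tags) if sig.up_tags else (None, 0)
    down_idx, down_dropped = tag_ranks(sig.down_tags) if sig.down_tags else (None, 0)
    if up_dropped or down_dropped:
        if missing == "error":
            raise KeyError(f"{up_dropped + down_dropped} query tags missing from library universe")
        logger.info("query %s: dropped %d tags missing from library", sig.label,
                    up_dropped + down_dropped)
    if (up_idx is not None and len(up_idx) == 0) and (down_idx is not None and len(down_idx) == 0):
        raise ValueError("no query tag present in the library universe")

    for col_i, inst in enumerate(library.ranks.columns):
        col = rank_mat[:, col_i]
        es_up = (ks_enrichment_from_ranks(col[up_idx], n_genes)
                 if up_idx is not None and len(up_idx) else None)
        es_down = (ks_enrichment_from_ranks(col[down_idx], n_genes)
                   if down_idx is not None and len(down_idx) else None)
        if es_up is None:
            c = -es_down
        elif es_down is None:
            c = es_up
        else:
            c = 0.0 if np.sign(es_up) == np.sign(es_down) else es_up - es_down
        rows.append((inst, str(library.meta.loc[inst, "drug"]), es_up, es_down, c))

    per_instance = pd.DataFrame(rows, columns=["instance_id", "drug", "es_up", "es_down", "c"]
                                ).set_index("instance_id")
    per_instance["scaled"] = scale_scores(per_instance["c"].to_numpy())

    # order instances by descending c; ties (e.g. the c = 0 mass under a
    # null query) are broken by a seeded random key, not by instance id —
    # ids cluster same-drug instances, which would bias the drug ES
    rng = np.random.default_rng(seed)
    jitter = dict(zip(per_instance.index, rng.random(len(per_instance))))
    order = per_instance.loc[
        sorted(per_instance.index,
               key=lambda i: (-per_instance.at[i, "c"], jitter[i], i))]
    n_inst = len(order)
    position = pd.Series(np.arange(1, n_inst + 1), index=order.index)
    drug_rows = []
    for drug in library.drugs:
        inst_ids = library.meta.index[library.meta["drug"] == drug]
        k = len(inst_ids)
        if k > n_inst:
            raise ValueError("drug has more instances than the library")
        es = ks_enrichment_from_ranks(position[inst_ids].to_numpy(), n_inst)
        null = np.empty(n_permutations)
        for b in range(n_permutations):
            null[b] = ks_enrichment_from_ranks(
                rng.choice(n_inst, size=k, replace=False) + 1, n_inst)
        p = add_one_p(int((np.abs(null) >= abs(es)).sum()), n_permutations)
        drug_rows.append((drug, es, p, k))
    per_drug = pd.DataFrame(drug_rows, columns=["drug", "es", "p", "n_instances"]
                            ).set_index("drug")
    return ConnectivityResult(label=sig.label, per_instance=per_instance,
                              per_drug=per_drug, n_permutations=n_permutations, seed=seed)


def profile_correlation(result_a: ConnectivityResult, result_b: ConnectivityResult,
                        p_threshold: float = 0.05,
                        rule: str = "either") -> tuple[float, float, list[str]]:
    """Pearson correlation between two queries' drug enrichment profiles.

    Drugs present in both results are filtered to those with permutation
    p < ``p_threshold`` in either query (``rule="either"``, default) or in
    both (``rule="both"``).  Returns (r, two-sided p, drugs used).
    """
    if rule not in ("either", "both"):
        raise ValueError("rule must be 'either' or 'both'")
    common = result_a.per_drug.index.intersection(result_b.per_drug.index)
    pa = result_a.per_drug.loc[common, "p"]
    pb = result_b.per_drug.loc[common, "p"]
    mask = (pa < p_threshold) | (pb < p_threshold) if rule == "either" \
        else (pa < p_threshold) & (pb < p_threshold)
    drugs = list(common[mask])
    if len(drugs) < 3:
        raise ValueError(f"only {len(drugs)} drugs pass the filter; need at least 3")
    r, p = sps.pearsonr(result_a.per_drug.loc[drugs, "es"],
                        result_b.per_drug.loc[drugs, "es"])
    return float(r), float(p), drugs
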