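"""Repressor-weighted pathway activity and term over-representation.

Pathway activity for a condition is the size-normalized weighted sum of
member log2 ratios, with repressor genes weighted -1::

    A_P = (1 / |P|) * sum_{g in P, measured} w_g * r_g

Significance comes from a two-sided permutation null that redraws gene
sets of the same size from the measured universe and randomly reassigns
the pathway's role-weight multiset.  Term enrichment is the one-sided
Fisher exact test (hypergeometric tail) with Benjamini-Hochberg
adjustment; the EASE variant (k-1 in the table) is available behind a
flag for comparison but is not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import LogRatioMatrix, Pathway, PathwayDB
from .stats import add_one_p, bh_adjust, hypergeom_sf

logger = logging.getLogger(__name__)

__all__ = [
    "pathway_activity",
    "activity_significance",
    "activities_table",
    "term_enrichment",
    "PathwayActivity",
    "EnrichmentRow",
]


def pathway_activity(lrm: LogRatioMatrix, pathway: Pathway, condition: str,
                     divisor: str = "membership") -> float:
    """Weighted mean log2 ratio over the pathway for one condition.

    Missing members contribute 0; the divisor is the full membership size
    by default (``divisor="measured"`` uses the measured count instead).
    """
    r = lrm.values[condition]
    # sorted order makes the float sum independent of set iteration order
    measured = [g for g in sorted(pathway.members) if g in r.index]
    if not measured:
        raise ValueError(f"no member of pathway {pathway.id} is measured")
    total = float(sum(pathway.role_weight[g] * r[g] for g in measured))
    denom = len(pathway.members) if divisor == "membership" else len(measured)
    return total / denom


@dataclass
class PathwayActivity:
    pathway_id: str
    activity: float
    p: float
    q: float | None
    n_genes_used: int
    n_permutations: int
    seed: int | None


def activity_significance(lrm: LogRatioMatrix, pathway: Pathway, condition: str,
                          n_permutations: int = 1000, seed: int | None = None,
                          divisor: str = "membership") -> PathwayActivity:
    """Two-sided permutation p for one pathway's activity.

    The null redraws random gene sets of pathway size from the measured
    genes, with the pathway's role-weight multiset randomly reassigned, and
    compares |A*| with |A| (add-one estimator).
    """
    r = lrm.values[condition]
    size = len(pathway.members)
    if len(r) < size:
        raise ValueError("measured gene universe smaller than the pathway")
    a = pathway_activity(lrm, pathway, condition, divisor=divisor)
    measured = [g for g in pathway.members if g in r.index]

    weights = np.array([pathway.role_weight[g] for g in sorted(pathway.members)], dtype=float)
    values = r.to_numpy(dtype=float)
    denom = size if divisor == "membership" else len(measured)
    rng = np.random.default_rng(seed)
    # vectorised null: one row of gene draws + one row of weight shuffles per round
    exceed = 0
    for _ in range(n_permutations):
        pick = rng.choice(len(values), size=size, replace=False)
        w = rng.permutation(weights)
        a_null = float(values[pick] @ w) / denom
        if abs(a_null) >= abs(a):
            exceed += 1
    p = add_one_p(exceed, n_permutations)
    return PathwayActivity(pathway_id=pathway.id, activity=a, p=p, q=None,
                           n_genes_used=len(measured), n_permutations=n_permutations,
                           seed=seed)


def activities_table(lrm: LogRatioMatrix, db: PathwayDB, condition: str,
                     n_permutations: int = 1000, seed: int | None = None,
                     divisor: str = "membership") -> pd.DataFrame:
    """Activity, permutation p and BH q for every pathway in a database."""
    rows = []
    for i, pw in enumerate(db):
        pw_seed = None if seed is None else seed + i
        res = activity_significance(lrm, pw, condition, n_permutations=n_permutations,
                                    seed=pw_seed, divisor=divisor)
        rows.append((pw.id, res.activity, res.p, res.n_genes_used))
    table = pd.DataFrame(rows, columns=["pathway_id", "activity", "p", "n_genes_used"]
                         ).set_index("pathway_id")
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float


def term_enrichment(query, terms: dict, universe,
                    ease: bool = False) -> list[EnrichmentRow]:
    """One-sided Fisher over-representation test per term, BH-adjusted.

    ``terms`` maps term_id -> gene set (or -> (name, gene set)).  Query and
    terms are intersected with the universe before testing.  ``ease=True``
    subtracts one hit (the DAVID EASE convention), a deliberately
    conservative variant.
    """
    universe = set(universe)
    query = set(query) & universe
    if not query:
        raise ValueError("empty query gene set")
    N, n = len(universe), len(query)
    rows = []
    for term_id, value in terms.items():
        if isinstance(value, tuple):
            name, members = value
        else:
            name, members = term_id, value
        members = set(members) & universe
        K = len(members)
        k = len(query & members)
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeom_sf(k_eff, N, K, n) if K else 1.0
        rows.append(EnrichmentRow(term_id=term_id, term_name=str(name),
                                  k=k, K=K, n=n, N=N, p=p, q=1.0))
    q = bh_adjust([row.p for row in rows])
    for row, qv in zip(rows, q):
        row.q = float(qv)
    rows.sort(key=lambda row: (row.p, row.term_id))
    return rows
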