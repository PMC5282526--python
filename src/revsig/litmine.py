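"""Keyword literature-association statistics (offline).

The input is an item x keyword matrix of publication counts (e.g. drug
names against disease keywords).  Counts are binarized to presence /
absence — removing the bias a few heavily-cited items would otherwise
introduce — and a query item set is scored by comparing its total against
same-sized random item sets (the randomized-test p-value, add-one
convention).  The incremental curve repeats the test on growing prefixes
of the items ranked by total citation count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import add_one_p

__all__ = [
    "binarize",
    "set_association_test",
    "incremental_curve",
    "SetAssociationResult",
]


def binarize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Map every positive count to 1; idempotent."""
    if (matrix.values < 0).any():
        raise ValueError("literature counts must be non-negative")
    return (matrix > 0).astype(int)


@dataclass
class SetAssociationResult:
    observed_sum: int
    null_mean: float
    null_sd: float
    p: float
    n_random: int
    seed: int | None


def set_association_test(query_items, matrix: pd.DataFrame, n_random: int = 1000,
                         seed: int | None = None) -> SetAssociationResult:
    """Randomized-set test of a query's binarized citation total.

    Null sets are drawn uniformly without replacement from all items, same
    size as the query; p = (1 + #{null >= observed}) / (1 + n_random).
    """
    query = sorted(set(query_items))
    items = list(matrix.index)
    missing = set(query) - set(items)
    if missing:
        raise KeyError(f"query items absent from the matrix: {sorted(missing)[:5]}")
    if len(query) > len(items):
        raise ValueError("query larger than the item universe")
    if n_random < 1:
        raise ValueError("n_random must be at least 1")

    row_sums = binarize(matrix).sum(axis=1)
    observed = int(row_sums.loc[query].sum())
    # sample over the id-sorted universe so p is invariant to file row order
    totals = row_sums.loc[sorted(items)].to_numpy()
    rng = np.random.default_rng(seed)
    k = len(query)
    null = np.empty(n_random)
    for b in range(n_random):
        null[b] = totals[rng.choice(len(totals), size=k, replace=False)].sum()
    p = add_one_p(int((null >= observed).sum()), n_random)
    return SetAssociationResult(observed_sum=observed, null_mean=float(null.mean()),
                                null_sd=float(null.std()), p=p, n_random=n_random,
                                seed=seed)


def rank_by_citations(matrix: pd.DataFrame, items=None) -> list[str]:
    """Items ordered by total (raw) citation count descending, ties lexical."""
    pool = list(matrix.index) if items is None else [i for i in items if i in matrix.index]
    totals = matrix.loc[pool].sum(axis=1)
    return sorted(pool, key=lambda it: (-totals[it], it))


def incremental_curve(ranked_items, matrix: pd.DataFrame, n_random: int = 1000,
                      seed: int | None = None) -> pd.DataFrame:
    """Randomized-set p for every prefix of a ranked item list.

    Each prefix gets its own derived seed so that prefix k's p equals a
    standalone test of the same set with seed ``seed + k``.
    """
    ranked = list(ranked_items)
    rows = []
    for k in range(1, len(ranked) + 1):
        sub_seed = None if seed is None else seed + k
        res = set_association_test(ranked[:k], matrix, n_random=n_random, seed=sub_seed)
        rows.append((k, res.observed_sum, res.p))
    return pd.DataFrame(rows, columns=["prefix_size", "observed_sum", "p"])
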