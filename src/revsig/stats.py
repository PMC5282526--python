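"""Small shared statistical helpers.

Benjamini-Hochberg is delegated to statsmodels; the hypergeometric
upper-tail is scipy's survival function.  The add-one permutation p
estimator is centralized here so every permutation test in the package
shares one convention (p is never exactly 0).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "hypergeom_sf", "add_one_p"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); the over-representation tail."""
    if k <= max(0, K + n - N):
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def add_one_p(n_exceed: int, n_permutations: int) -> float:
    """Add-one permutation p-value: (1 + #exceed) / (1 + #permutations)."""
    return (1.0 + n_exceed) / (1.0 + n_permutations)
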