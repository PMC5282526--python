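"""Filtering, normalization and gene-signature selection.

The chain mirrors a standard two-color-array workflow: keep probes above
local background, quantile-normalize intensities, form log2 ratios against
the control condition, then select signature genes either by a plain
fold-change rule, by assignment to model temporal/dose profiles (a
simplified short-time-series miner), or by a regularized two-class
d-statistic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionStudy, LogRatioMatrix, Signature
from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "filter_above_background",
    "quantile_normalize",
    "log_ratio",
    "select_fold_change",
    "FoldChangeSelection",
    "assign_model_profiles",
    "ProfileAssignment",
    "two_class_statistic",
    "TwoClassSelection",
    "apply_gene_mapping",
]


def filter_above_background(study: ExpressionStudy, factor: float = 1.4,
                            scope: str = "any") -> ExpressionStudy:
    """Keep genes whose intensity clears ``factor x local background``.

    scope="any" (default) retains a gene expressed in at least one sample;
    scope="all" requires every sample to clear the threshold.
    """
    if study.background is None:
        raise ValueError("study has no local-background matrix; skip this stage")
    if scope not in ("any", "all"):
        raise ValueError("scope must be 'any' or 'all'")
    above = study.intensities.values >= factor * study.background.values
    keep = above.any(axis=1) if scope == "any" else above.all(axis=1)
    logger.info("background filter (factor=%.2f, scope=%s): kept %d of %d genes",
                factor, scope, int(keep.sum()), len(keep))
    return ExpressionStudy(
        intensities=study.intensities.loc[keep],
        roles=dict(study.roles),
        background=study.background.loc[keep],
    )


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization: force every column onto the mean distribution.

    After normalization every column's sorted value vector equals the
    row-wise mean of the sorted input columns.  Ties within a column
    receive the mean of the reference values at their tied ranks, so the
    procedure is idempotent.
    """
    if matrix.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        # average rank (1-based); ties -> mean of reference at the tied positions
        ranks = pd.Series(values[:, j]).rank(method="average").to_numpy()
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log_ratio(study: ExpressionStudy, reference_role: str = "control",
              pseudocount: float = 1.0, include_reference: bool = False) -> LogRatioMatrix:
    """log2((x + eps) / (x_ref + eps)) per gene against the reference condition.

    Multiple reference samples are averaged first.  The default pseudocount
    of 1.0 (intensity scale) guards near-zero intensities.
    """
    ref_samples = study.samples_with_role(reference_role)
    if not ref_samples:
        raise ValueError(f"no sample with role {reference_role!r}")
    ref = study.intensities[ref_samples].mean(axis=1).to_numpy() + pseudocount
    if (ref <= 0).any():
        raise ValueError("zero reference intensity; use a positive pseudocount")
    cols = [s for s in study.samples if s not in ref_samples or include_reference]
    values = {}
    for s in cols:
        x = study.intensities[s].to_numpy() + pseudocount
        if (x <= 0).any():
            raise ValueError(f"non-positive intensity in sample {s}; "
                             "use a positive pseudocount")
        values[s] = np.log2(x / ref)
    return LogRatioMatrix(pd.DataFrame(values, index=study.genes))


@dataclass
class FoldChangeSelection:
    """A fold-change signature plus the genes excluded for direction conflicts."""

    signature: Signature
    conflicting: frozenset[str]
    fold: float


def select_fold_change(lrm: LogRatioMatrix, fold: float = 2.0, scope: str = "any",
                       conditions: list[str] | None = None,
                       label: str = "") -> FoldChangeSelection:
    """Select up/down tags by the |log2 ratio| >= log2(fold) rule (inclusive).

    A gene qualifying up in one condition and down in another has no single
    direction to query and is excluded from both tag sets, reported in
    ``conflicting``.
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    if scope not in ("any", "all"):
        raise ValueError("scope must be 'any' or 'all'")
    values = lrm.values if conditions is None else lrm.values[list(conditions)]
    cut = np.log2(fold)
    agg = np.any if scope == "any" else np.all
    up_mask = agg(values.to_numpy() >= cut, axis=1)
    down_mask = agg(values.to_numpy() <= -cut, axis=1)
    both = up_mask & down_mask
    if both.any():
        logger.info("fold-change selection: %d genes conflict across conditions",
                    int(both.sum()))
    up = frozenset(values.index[up_mask & ~both])
    down = frozenset(values.index[down_mask & ~both])
    sig = Signature(up_tags=up, down_tags=down, label=label or f"fold>={fold:g}")
    return FoldChangeSelection(signature=sig, conflicting=frozenset(values.index[both]),
                               fold=fold)


# ---------------------------------------------------------------------------
# model-profile assignment (simplified short-time-series miner)

@dataclass
class ProfileAssignment:
    model_profiles: pd.DataFrame  # profiles x conditions (unit-change templates)
    gene_to_profile: dict[str, int]
    profile_counts: dict[int, int]
    profile_p: dict[int, float]
    profile_fdr: dict[int, float]
    unassigned: frozenset[str] = frozenset()  # zero-variance genes
    n_permutations: int = 0
    seed: int | None = None


def _candidate_profiles(n_steps: int, step: float) -> np.ndarray:
    """All cumulative trajectories of per-step changes in {-1, 0, +1} x step."""
    deltas = np.array(list(itertools.product((-1, 0, 1), repeat=n_steps)), dtype=float)
    profiles = np.concatenate([np.zeros((len(deltas), 1)), np.cumsum(deltas, axis=1)],
                              axis=1) * step
    # drop the flat profile (undefined correlation) and duplicates
    keep = [i for i in range(len(profiles)) if np.ptp(profiles[i]) > 0]
    profiles = profiles[keep]
    _, uniq = np.unique(profiles, axis=0, return_index=True)
    return profiles[np.sort(uniq)]


def _cap_by_distance(profiles: np.ndarray, cap: int) -> np.ndarray:
    """Greedy farthest-point selection of at most ``cap`` profiles (deterministic)."""
    if len(profiles) <= cap:
        return profiles
    dist = np.linalg.norm(profiles[:, None, :] - profiles[None, :, :], axis=2)
    chosen = [0]
    while len(chosen) < cap:
        mind = dist[:, chosen].min(axis=1)
        mind[chosen] = -1.0
        chosen.append(int(np.argmax(mind)))  # argmax tie -> lowest index
    return profiles[sorted(chosen)]


def _row_corr(data: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Pearson correlation of every data row with every template row."""
    d = data - data.mean(axis=1, keepdims=True)
    t = templates - templates.mean(axis=1, keepdims=True)
    dn = np.linalg.norm(d, axis=1, keepdims=True)
    tn = np.linalg.norm(t, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (d @ t.T) / (dn * tn.T)


def assign_model_profiles(lrm: LogRatioMatrix, n_profiles: int = 16,
                          n_permutations: int = 1000,
                          seed: int | None = None) -> ProfileAssignment:
    """Assign each gene to its best-correlated unit-change model profile.

    Candidate profiles are all per-step changes in {-1,0,+1} over the
    ordered conditions, scaled to the data's median absolute step,
    deduplicated and capped at ``n_profiles`` by greedy farthest-point
    selection.  Profile over-occupancy is scored by permuting each gene's
    condition labels (``n_permutations`` rounds) and BH-adjusting the
    per-profile tail probabilities.
    """
    values = lrm.values
    n_cond = values.shape[1]
    if n_cond < 3:
        raise ValueError("model-profile assignment needs at least 3 ordered conditions")
    data = values.to_numpy(dtype=float)
    steps = np.abs(np.diff(data, axis=1))
    step = float(np.median(steps[steps > 0])) if (steps > 0).any() else 1.0

    profiles = _cap_by_distance(_candidate_profiles(n_cond - 1, step), n_profiles)

    variable = np.ptp(data, axis=1) > 0
    unassigned = frozenset(values.index[~variable])
    if unassigned:
        logger.info("profile assignment: %d zero-variance genes unassigned", len(unassigned))
    sub = data[variable]

    corr = _row_corr(sub, profiles)
    best = np.argmax(corr, axis=1)  # argmax breaks ties toward the lower index
    gene_to_profile = dict(zip(values.index[variable], best.astype(int)))
    counts = {p: int((best == p).sum()) for p in range(len(profiles))}

    rng = np.random.default_rng(seed)
    n_genes = sub.shape[0]
    exceed = np.zeros(len(profiles), dtype=int)
    observed = np.array([counts[p] for p in range(len(profiles))])
    for _ in range(n_permutations):
        keys = rng.random((n_genes, n_cond))
        perm_idx = np.argsort(keys, axis=1)
        permuted = np.take_along_axis(sub, perm_idx, axis=1)
        pc = _row_corr(permuted, profiles)
        pb = np.argmax(pc, axis=1)
        null_counts = np.bincount(pb, minlength=len(profiles))
        exceed += null_counts >= observed
    p = (1.0 + exceed) / (1.0 + n_permutations)
    q = bh_adjust(p)
    return ProfileAssignment(
        model_profiles=pd.DataFrame(profiles, columns=values.columns),
        gene_to_profile=gene_to_profile,
        profile_counts=counts,
        profile_p={i: float(p[i]) for i in range(len(profiles))},
        profile_fdr={i: float(q[i]) for i in range(len(profiles))},
        unassigned=unassigned,
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# two-class d-statistic (regularized mean difference)

@dataclass
class TwoClassSelection:
    d_scores: pd.Series
    s0: float
    threshold: float
    selected_up: frozenset[str]
    selected_down: frozenset[str]


def two_class_statistic(matrix: pd.DataFrame, group_labels: list,
                        threshold: float = 2.0,
                        s0_quantile: float = 0.5,
                        s0: float | None = None) -> TwoClassSelection:
    """Regularized two-class d-statistic with fudge factor s0.

    d_g = (mean2 - mean1) / (s_g + s0), where s_g is the pooled standard
    error of the mean difference and s0 a chosen quantile (default median)
    of the {s_g}, or a fixed value when given.  Genes with |d| >= threshold
    are selected.
    """
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    idx1 = labels == groups[0]
    idx2 = labels == groups[1]
    n1, n2 = int(idx1.sum()), int(idx2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    x1 = matrix.loc[:, idx1].to_numpy(dtype=float)
    x2 = matrix.loc[:, idx2].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    s0 = float(np.quantile(s, s0_quantile)) if s0 is None else float(s0)
    d = (m2 - m1) / (s + s0)
    d_series = pd.Series(d, index=matrix.index, name="d")
    up = frozenset(matrix.index[d >= threshold])
    down = frozenset(matrix.index[d <= -threshold])
    return TwoClassSelection(d_scores=d_series, s0=s0, threshold=threshold,
                             selected_up=up, selected_down=down)


def apply_gene_mapping(signature: Signature, mapping: pd.DataFrame) -> Signature:
    """Translate tag ids through a two-column (from_id, to_id) table.

    Unmapped genes are dropped with a logged count; the first mapping wins
    when a source id maps to several targets.
    """
    table = mapping.drop_duplicates(subset=mapping.columns[0], keep="first")
    lut = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
    up = frozenset(lut[g] for g in signature.up_tags if g in lut)
    down = frozenset(lut[g] for g in signature.down_tags if g in lut)
    dropped = (len(signature.up_tags) - len([g for g in signature.up_tags if g in lut])
               + len(signature.down_tags) - len([g for g in signature.down_tags if g in lut]))
    if dropped:
        logger.info("gene mapping: dropped %d unmapped tags", dropped)
    # a collision can map an up and a down tag onto one target; drop those too
    clash = up & down
    if clash:
        logger.info("gene mapping: %d targets received both directions; dropped", len(clash))
    return Signature(up - clash, down - clash, label=signature.label)
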