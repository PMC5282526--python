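"""Shared in-memory containers for the analysis chain.

Expression data lives in pandas DataFrames (genes x samples), interaction
networks in :class:`networkx.Graph`, and the remaining domain objects are
small dataclasses.  Everything here is deliberately dumb: validation on
construction, no behaviour beyond trivial derived views.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionStudy",
    "LogRatioMatrix",
    "Signature",
    "RankedInstance",
    "ReferenceLibrary",
    "Pathway",
    "PathwayDB",
    "PlantedTruth",
]

#: sample-role vocabulary: ``control``, ``disease``, ``dose:<level>``, ``time:<point>``
REFERENCE_ROLE = "control"


@dataclass
class ExpressionStudy:
    """An intensity matrix with per-sample condition roles.

    Parameters
    ----------
    intensities
        Non-negative gene x sample intensity matrix; index = gene ids,
        columns = sample ids.
    roles
        Map sample id -> role label.  Exactly one role is the designated
        reference condition (``control``).
    background
        Optional local-background matrix, same shape as ``intensities``.
    """

    intensities: pd.DataFrame
    roles: dict[str, str]
    background: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.intensities.values < 0).any():
            raise ValueError("intensities must be non-negative")
        missing = set(self.intensities.columns) - set(self.roles)
        if missing:
            raise ValueError(f"samples without a role: {sorted(missing)}")
        if REFERENCE_ROLE not in self.roles.values():
            raise ValueError("no sample carries the reference role 'control'")
        if self.background is not None and self.background.shape != self.intensities.shape:
            raise ValueError("background shape must match intensities")

    @property
    def genes(self) -> pd.Index:
        return self.intensities.index

    @property
    def samples(self) -> pd.Index:
        return self.intensities.columns

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.intensities.columns if self.roles[s] == role]


@dataclass
class LogRatioMatrix:
    """log2(condition / reference) per gene, one column per non-reference condition."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise ValueError("log-ratio matrix contains non-finite values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> pd.Index:
        return self.values.columns


@dataclass
class Signature:
    """Up/down tag lists queried against a reference library.

    At least one of the two tag sets must be non-empty, they must be
    disjoint, and each is capped (cmap convention: 1000 tags per direction).
    """

    up_tags: frozenset[str]
    down_tags: frozenset[str]
    label: str = ""
    TAG_CAP = 1000

    def __post_init__(self) -> None:
        self.up_tags = frozenset(self.up_tags)
        self.down_tags = frozenset(self.down_tags)
        if not self.up_tags and not self.down_tags:
            raise ValueError("signature needs at least one non-empty tag set")
        if self.up_tags & self.down_tags:
            raise ValueError("up and down tags must be disjoint")
        if len(self.up_tags) > self.TAG_CAP or len(self.down_tags) > self.TAG_CAP:
            raise ValueError(f"tag sets exceed the cap of {self.TAG_CAP}")

    def reversed(self) -> "Signature":
        """The same signature with directions swapped (a 'reversed-disease' query)."""
        return Signature(self.down_tags, self.up_tags, label=f"{self.label}:reversed")


@dataclass
class RankedInstance:
    """One treatment instance: a full gene ranking, rank 1 = most up-regulated."""

    instance_id: str
    drug: str
    rank_of: dict[str, int]

    def __post_init__(self) -> None:
        n = len(self.rank_of)
        if sorted(self.rank_of.values()) != list(range(1, n + 1)):
            raise ValueError(f"ranks of instance {self.instance_id} are not a permutation of 1..{n}")

    @property
    def n(self) -> int:
        return len(self.rank_of)


@dataclass
class ReferenceLibrary:
    """A rank matrix (genes x instances) plus instance -> drug metadata."""

    ranks: pd.DataFrame  # integer ranks, each column a permutation of 1..n_genes
    meta: pd.DataFrame  # index = instance ids, column 'drug' (extra columns allowed)

    def __post_init__(self) -> None:
        if list(self.ranks.columns) != list(self.meta.index):
            raise ValueError("rank-matrix columns must match metadata instance ids")
        if "drug" not in self.meta.columns:
            raise ValueError("metadata needs a 'drug' column")
        n = len(self.ranks.index)
        expect = np.arange(1, n + 1)
        for col in self.ranks.columns:
            if not np.array_equal(np.sort(self.ranks[col].to_numpy()), expect):
                raise ValueError(f"instance {col} is not a permutation of 1..{n}")

    @property
    def genes(self) -> pd.Index:
        return self.ranks.index

    @property
    def drugs(self) -> list[str]:
        return sorted(self.meta["drug"].unique())

    def instances(self) -> Iterator[RankedInstance]:
        for col in self.ranks.columns:
            yield RankedInstance(
                instance_id=col,
                drug=str(self.meta.loc[col, "drug"]),
                rank_of=dict(zip(self.ranks.index, self.ranks[col].astype(int))),
            )


@dataclass
class Pathway:
    """A gene set with per-gene role weights (+1 activator, -1 repressor)."""

    id: str
    name: str
    members: frozenset[str]
    role_weight: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if len(self.members) < 2:
            raise ValueError(f"pathway {self.id} has fewer than 2 members")
        if not self.role_weight:
            self.role_weight = {g: 1 for g in self.members}
        if set(self.role_weight) != set(self.members):
            raise ValueError(f"pathway {self.id}: role weights must cover exactly the members")
        if any(w not in (1, -1) for w in self.role_weight.values()):
            raise ValueError(f"pathway {self.id}: role weights must be +1 or -1")

    def role_flipped(self) -> "Pathway":
        return Pathway(
            id=f"{self.id}_flipped",
            name=f"{self.name} (roles flipped)",
            members=self.members,
            role_weight={g: -w for g, w in self.role_weight.items()},
        )


@dataclass
class PathwayDB:
    pathways: list[Pathway]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate pathway ids")

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def get(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.id == pathway_id:
                return p
        raise KeyError(pathway_id)


@dataclass
class PlantedTruth:
    """Ground truth planted by the synthetic generators."""

    up_genes: frozenset[str]
    down_genes: frozenset[str]
    pathway_direction: dict[str, int] = field(default_factory=dict)
    module_partition: dict[str, int] = field(default_factory=dict)
    enriched_literature_items: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.up_genes = frozenset(self.up_genes)
        self.down_genes = frozenset(self.down_genes)
        if self.up_genes & self.down_genes:
            raise ValueError("planted up and down gene sets must be disjoint")
        self.enriched_literature_items = frozenset(self.enriched_literature_items)
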