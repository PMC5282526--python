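"""Plain-text readers and writers for every pipeline input and output.

All formats are tab-separated text: expression matrices (genes x samples,
with a sample-role sidecar), rank matrices with an instance-metadata
sidecar, GMT gene sets with a role-weight sidecar, two-column undirected
edge lists, item x keyword literature counts, one-id-per-line ``.grp``
tag lists, and a truth/provenance JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import (
    ExpressionStudy,
    Pathway,
    PathwayDB,
    PlantedTruth,
    ReferenceLibrary,
    Signature,
)

logger = logging.getLogger(__name__)

RANK_HEADER = "# rank direction: 1 = most up-regulated by treatment"


# -- expression -------------------------------------------------------------

def write_expression_study(study: ExpressionStudy, prefix: Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips float64 exactly; pandas' default formatting does not
    study.intensities.to_csv(f"{prefix}.expr.tsv", sep="\t", float_format="%.17g")
    pd.Series(study.roles, name="role").rename_axis("sample").to_csv(
        f"{prefix}.samples.tsv", sep="\t")
    if study.background is not None:
        study.background.to_csv(f"{prefix}.bg.tsv", sep="\t", float_format="%.17g")


def read_expression_study(prefix: Path) -> ExpressionStudy:
    prefix = Path(prefix)
    # round_trip parsing: the default float parser loses the last ulp
    intensities = pd.read_csv(f"{prefix}.expr.tsv", sep="\t", index_col=0,
                              float_precision="round_trip").astype(float)
    roles = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", index_col=0)["role"].to_dict()
    bg_path = Path(f"{prefix}.bg.tsv")
    background = (pd.read_csv(bg_path, sep="\t", index_col=0,
                              float_precision="round_trip").astype(float)
                  if bg_path.exists() else None)
    return ExpressionStudy(intensities=intensities, roles=roles, background=background)


# -- rank library -----------------------------------------------------------

def write_reference_library(library: ReferenceLibrary, prefix: Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.ranks.tsv", "w") as fh:
        fh.write(RANK_HEADER + "\n")
        library.ranks.to_csv(fh, sep="\t")
    library.meta.to_csv(f"{prefix}.meta.tsv", sep="\t")


def read_reference_library(prefix: Path) -> ReferenceLibrary:
    prefix = Path(prefix)
    with open(f"{prefix}.ranks.tsv") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("rank matrix must declare its rank direction in a header line")
        ranks = pd.read_csv(fh, sep="\t", index_col=0)
    meta = pd.read_csv(f"{prefix}.meta.tsv", sep="\t", index_col=0)
    # deterministic tie-break: re-rank each column, ties by gene id
    for col in ranks.columns:
        values = ranks[col]
        if values.duplicated().any():
            logger.warning("instance %s has tied ranks; breaking ties by gene id", col)
            order = sorted(ranks.index, key=lambda g: (values[g], g))
            ranks[col] = pd.Series(range(1, len(order) + 1), index=order)
    return ReferenceLibrary(ranks=ranks.astype(int), meta=meta)


# -- signatures -------------------------------------------------------------

def write_signature(sig: Signature, prefix: Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for name, tags in (("up", sig.up_tags), ("down", sig.down_tags)):
        with open(f"{prefix}.{name}.grp", "w") as fh:
            fh.writelines(f"{g}\n" for g in sorted(tags))


def read_signature(prefix: Path, label: str = "") -> Signature:
    prefix = Path(prefix)

    def read_grp(path: Path) -> frozenset[str]:
        if not path.exists():
            return frozenset()
        return frozenset(line.strip() for line in path.read_text().splitlines()
                         if line.strip())

    return Signature(read_grp(Path(f"{prefix}.up.grp")),
                     read_grp(Path(f"{prefix}.down.grp")), label=label)


# -- pathways (GMT + role sidecar) ------------------------------------------

def write_pathway_db(db: PathwayDB, prefix: Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.gmt", "w") as fh:
        for pw in db:
            fh.write("\t".join([pw.id, pw.name] + sorted(pw.members)) + "\n")
    rows = [(pw.id, g, pw.role_weight[g]) for pw in db for g in sorted(pw.members)]
    pd.DataFrame(rows, columns=["pathway_id", "gene_id", "weight"]).to_csv(
        f"{prefix}.roles.tsv", sep="\t", index=False)


def read_pathway_db(prefix: Path) -> PathwayDB:
    prefix = Path(prefix)
    roles_path = Path(f"{prefix}.roles.tsv")
    roles: dict[str, dict[str, int]] = {}
    if roles_path.exists():
        table = pd.read_csv(roles_path, sep="\t")
        for pid, sub in table.groupby("pathway_id"):
            roles[str(pid)] = dict(zip(sub["gene_id"], sub["weight"].astype(int)))
    pathways = []
    for line in Path(f"{prefix}.gmt").read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        pid, name, members = parts[0], parts[1], parts[2:]
        weight = roles.get(pid, {g: 1 for g in members})
        pathways.append(Pathway(id=pid, name=name, members=frozenset(members),
                                role_weight=weight))
    return PathwayDB(pathways)


# -- networks ---------------------------------------------------------------

def write_edge_list(network: nx.Graph, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    edges = sorted(tuple(sorted(e)) for e in network.edges)
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        fh.writelines(f"{a}\t{b}\n" for a, b in edges)


def read_edge_list(path: Path) -> nx.Graph:
    table = pd.read_csv(path, sep="\t")
    G = nx.Graph()
    for a, b in zip(table.iloc[:, 0], table.iloc[:, 1]):
        if a != b:
            G.add_edge(str(a), str(b))
    return G


# -- literature -------------------------------------------------------------

def write_literature_matrix(matrix: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t")


def read_literature_matrix(path: Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if (matrix.values < 0).any():
        raise ValueError("literature counts must be non-negative")
    return matrix


# -- truth ------------------------------------------------------------------

def write_truth(truth: PlantedTruth, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "up_genes": sorted(truth.up_genes),
        "down_genes": sorted(truth.down_genes),
        "pathway_direction": dict(sorted(truth.pathway_direction.items())),
        "module_partition": dict(sorted(truth.module_partition.items())),
        "enriched_literature_items": sorted(truth.enriched_literature_items),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path: Path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    return PlantedTruth(
        up_genes=frozenset(payload["up_genes"]),
        down_genes=frozenset(payload["down_genes"]),
        pathway_direction={k: int(v) for k, v in payload["pathway_direction"].items()},
        module_partition={k: int(v) for k, v in payload["module_partition"].items()},
        enriched_literature_items=frozenset(payload["enriched_literature_items"]),
    )
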