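"""End-to-end orchestration: simulate (or load) inputs, preprocess, score.

The pipeline runs the full analysis chain from one declarative config:
background filter -> quantile normalization -> log ratios -> fold-change
signature -> connectivity scoring of the disease query and its reversed
(treatment-analogue) query -> profile correlation -> pathway activities ->
degree-weighted network efficacy -> functional modules -> literature
association.  Every stochastic stage draws its seed from the master seed
by a fixed offset, so a rerun with the same config is bit-identical.

Stage runtimes are logged to a separate ``runlog.json`` that is excluded
from determinism checks; every result file carries the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .connectivity import ConnectivityResult, drug_enrichment, profile_correlation
from .containers import Signature
from .funmodules import build_functional_graph, mcl_cluster, shared_function_count
from .litmine import incremental_curve, rank_by_citations, set_association_test
from .netscore import largest_cluster, weighted_ratio_significance
from .pathways import activities_table
from .preprocess import (
    filter_above_background,
    log_ratio,
    quantile_normalize,
    select_fold_change,
)
from .synth import SynthConfig, generate_all

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ResultBundle", "run_pipeline", "compare_three_way"]

_SEED_OFFSET = {
    "connectivity_disease": 101,
    "connectivity_reversed": 103,
    "pathways": 107,
    "netscore": 109,
    "litmine": 113,
}


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    synth: SynthConfig | None = None
    input_prefix: str | None = None  # load synth-format files from this prefix instead
    background_factor: float = 1.4
    fold_threshold: float = 2.0
    r_threshold: float = 0.8
    p_cutoff: float = 0.05
    q_cutoff: float = 0.01
    n_permutations: int = 1000
    seed: int = 0
    outdir: str = "results/run"

    def validate(self) -> None:
        errors = []
        if self.synth is None and self.input_prefix is None:
            errors.append("either a synth block or an input prefix is required")
        if self.input_prefix is not None:
            for suffix in (".expr.tsv", ".samples.tsv", ".ranks.tsv", ".meta.tsv",
                           ".gmt", ".edges.tsv", ".lit.tsv"):
                if not Path(self.input_prefix + suffix).exists():
                    errors.append(f"missing input file: {self.input_prefix}{suffix}")
        if not self.background_factor >= 0:
            errors.append("background_factor must be non-negative")
        if not self.fold_threshold > 1:
            errors.append("fold_threshold must exceed 1")
        if not -1.0 <= self.r_threshold <= 1.0:
            errors.append("r_threshold must lie in [-1, 1]")
        for name in ("p_cutoff", "q_cutoff"):
            if not 0.0 < getattr(self, name) <= 1.0:
                errors.append(f"{name} must lie in (0, 1]")
        if self.n_permutations < 1:
            errors.append("n_permutations must be at least 1")
        if errors:
            raise ValueError("invalid run config: " + "; ".join(errors))

    def hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        synth = payload.pop("synth", None)
        if synth is not None:
            synth = SynthConfig(**synth)
        return cls(synth=synth, **payload)


@dataclass
class ResultBundle:
    config_hash: str
    seed: int
    signature: Signature
    connectivity_disease: ConnectivityResult
    connectivity_reversed: ConnectivityResult
    profile_r: float
    profile_p: float
    profile_drugs: list[str]
    pathway_activities: pd.DataFrame
    network_w: dict[str, float]
    network_p: dict[str, float]
    cluster_size: int
    modules: list[frozenset[str]]
    literature_p: float
    literature_curve: pd.DataFrame
    stage_log: dict[str, float] = field(default_factory=dict)


def run_pipeline(config: RunConfig, write: bool = True) -> ResultBundle:
    """Run the full analysis chain; see the module docstring for the stages."""
    config.validate()
    seed = config.seed
    stage_log: dict[str, float] = {}

    def timed(name: str):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, *exc):
                stage_log[name] = time.perf_counter() - self_inner.t0

        return _T()

    try:
        with timed("inputs"):
            if config.synth is not None:
                world = generate_all(config.synth)
            else:
                prefix = config.input_prefix
                world = {
                    "study": rio.read_expression_study(prefix),
                    "library": rio.read_reference_library(prefix),
                    "pathways": rio.read_pathway_db(prefix),
                    "network": rio.read_edge_list(prefix + ".edges.tsv"),
                    "literature": rio.read_literature_matrix(prefix + ".lit.tsv"),
                    "truth": None,
                }
            study, library = world["study"], world["library"]
            pathway_db, network = world["pathways"], world["network"]
            literature = world["literature"]

        with timed("preprocess"):
            if study.background is not None:
                study = filter_above_background(study, factor=config.background_factor)
            normalized = quantile_normalize(study.intensities)
            study = dataclasses.replace(study, intensities=normalized)
            lrm = log_ratio(study)

        with timed("signature"):
            disease_cond = study.samples_with_role("disease")
            selection = select_fold_change(lrm, fold=config.fold_threshold,
                                           conditions=disease_cond, label="disease")
            sig = selection.signature
            sig_rev = sig.reversed()

        with timed("connectivity"):
            res_dis = drug_enrichment(sig, library, n_permutations=config.n_permutations,
                                      seed=seed + _SEED_OFFSET["connectivity_disease"])
            res_rev = drug_enrichment(sig_rev, library, n_permutations=config.n_permutations,
                                      seed=seed + _SEED_OFFSET["connectivity_reversed"])
            r, p_r, drugs_used = profile_correlation(res_dis, res_rev,
                                                     p_threshold=config.p_cutoff)

        with timed("pathways"):
            act = activities_table(lrm, pathway_db, disease_cond[0],
                                   n_permutations=config.n_permutations,
                                   seed=seed + _SEED_OFFSET["pathways"])

        with timed("netscore"):
            de_genes = sig.up_tags | sig.down_tags
            cluster = largest_cluster(de_genes, network)
            if cluster.number_of_nodes() >= 2:
                net = weighted_ratio_significance(
                    cluster, lrm, network, n_permutations=config.n_permutations,
                    seed=seed + _SEED_OFFSET["netscore"])
                network_w, network_p = net.w, net.p
            else:
                network_w, network_p = {}, {}

        with timed("modules"):
            graph = build_functional_graph(lrm, r_threshold=config.r_threshold,
                                           genes=sorted(de_genes))
            module_set = mcl_cluster(graph)

        with timed("literature"):
            top_drugs = [d for d in res_dis.per_drug.index
                         if res_dis.per_drug.at[d, "p"] < config.p_cutoff
                         and d in literature.index]
            lit_seed = seed + _SEED_OFFSET["litmine"]
            if top_drugs:
                lit = set_association_test(top_drugs, literature,
                                           n_random=config.n_permutations, seed=lit_seed)
                curve = incremental_curve(rank_by_citations(literature, top_drugs),
                                          literature, n_random=config.n_permutations,
                                          seed=lit_seed)
                lit_p = lit.p
            else:
                lit_p, curve = 1.0, pd.DataFrame(
                    columns=["prefix_size", "observed_sum", "p"])
    except Exception as exc:
        failing = next(iter(reversed(stage_log)), "inputs")
        raise RuntimeError(f"pipeline failed after stage {failing!r}: {exc}") from exc

    bundle = ResultBundle(
        config_hash=config.hash(), seed=seed, signature=sig,
        connectivity_disease=res_dis, connectivity_reversed=res_rev,
        profile_r=r, profile_p=p_r, profile_drugs=drugs_used,
        pathway_activities=act, network_w=network_w, network_p=network_p,
        cluster_size=cluster.number_of_nodes(), modules=module_set.modules,
        literature_p=lit_p, literature_curve=curve, stage_log=stage_log,
    )
    if write:
        write_bundle(bundle, Path(config.outdir))
    return bundle


def write_bundle(bundle: ResultBundle, outdir: Path) -> None:
    """Write the bundle as TSV/JSON files plus a human-readable summary.

    ``runlog.json`` (stage runtimes) is the only non-deterministic file;
    everything else is reproducible bit-for-bit from config + seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# config={bundle.config_hash} seed={bundle.seed}\n"

    def tsv(frame: pd.DataFrame, name: str, index: bool = True) -> None:
        with open(outdir / name, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", index=index)

    rio.write_signature(bundle.signature, outdir / "signature")
    tsv(bundle.connectivity_disease.per_drug, "connectivity_disease.tsv")
    tsv(bundle.connectivity_reversed.per_drug, "connectivity_reversed.tsv")
    tsv(bundle.connectivity_disease.per_instance, "instances_disease.tsv")
    tsv(bundle.pathway_activities, "pathway_activities.tsv")
    tsv(bundle.literature_curve, "literature_curve.tsv", index=False)
    modules_rows = [(g, i) for i, mod in enumerate(bundle.modules) for g in sorted(mod)]
    tsv(pd.DataFrame(modules_rows, columns=["gene", "module"]), "modules.tsv", index=False)

    summary = {
        "config_hash": bundle.config_hash,
        "seed": bundle.seed,
        "n_up_tags": len(bundle.signature.up_tags),
        "n_down_tags": len(bundle.signature.down_tags),
        "profile_correlation": bundle.profile_r,
        "profile_correlation_p": bundle.profile_p,
        "n_drugs_in_profile": len(bundle.profile_drugs),
        "network_w": bundle.network_w,
        "network_p": bundle.network_p,
        "cluster_size": bundle.cluster_size,
        "n_modules": len(bundle.modules),
        "literature_p": bundle.literature_p,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (outdir / "runlog.json").write_text(
        json.dumps(bundle.stage_log, indent=2, sort_keys=True) + "\n")


def compare_three_way(bundle_a: ResultBundle, bundle_b: ResultBundle,
                      bundle_c: ResultBundle, terms: dict | None = None,
                      universe=None, p_threshold: float = 0.05) -> pd.DataFrame:
    """Pairwise profile correlations among three queries' drug profiles.

    Pairs without enough shared significant drugs are skipped with an
    explicit message in the table.  When term annotations are given, the
    shared enriched-function intersections are appended per pair.
    """
    bundles = {"A": bundle_a, "B": bundle_b, "C": bundle_c}
    rows = []
    for x, y in (("A", "B"), ("A", "C"), ("B", "C")):
        try:
            r, p, drugs = profile_correlation(
                bundles[x].connectivity_disease, bundles[y].connectivity_disease,
                p_threshold=p_threshold)
            row = {"pair": f"{x}-{y}", "r": r, "p": p, "n_drugs": len(drugs),
                   "note": ""}
        except ValueError as exc:
            row = {"pair": f"{x}-{y}", "r": np.nan, "p": np.nan, "n_drugs": 0,
                   "note": f"skipped: {exc}"}
        if terms is not None:
            common, cp = shared_function_count(
                _as_moduleset(bundles[x]), _as_moduleset(bundles[y]), terms, universe)
            row["n_shared_functions"] = len(common)
            row["shared_function_p"] = cp
        rows.append(row)
    return pd.DataFrame(rows)


def _as_moduleset(bundle: ResultBundle):
    from .funmodules import ModuleSet

    return ModuleSet(modules=bundle.modules)
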