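import numpy as np
import pandas as pd
import pytest

from revsig.containers import ExpressionStudy, ReferenceLibrary, Signature
from revsig.synth import SynthConfig


@pytest.fixture
def small_config() -> SynthConfig:
    """A small planted world: 200 genes, 10 drugs, mild noise."""
    return SynthConfig(
        n_genes=200,
        n_drugs=10,
        instances_per_drug=2,
        frac_disease_up=0.2,
        frac_disease_down=0.2,
        effect_log2=1.5,
        noise_sd=0.1,
        reversal_drugs=("drug00", "drug01"),
        mimic_drugs=("drug02", "drug03"),
        n_modules=2,
        module_size=8,
        n_pathways=8,
        pathway_size=10,
        seed=7,
    )


@pytest.fixture
def noise_free_config(small_config) -> SynthConfig:
    import dataclasses

    return dataclasses.replace(small_config, noise_sd=0.0, rank_noise=0.0,
                               p_within=1.0, p_between=0.0,
                               background_edge_prob=0.0)


def make_study(values: dict, roles: dict, background: float | None = None
               ) -> ExpressionStudy:
    """Convenience constructor for tiny hand-built studies."""
    frame = pd.DataFrame(values)
    bg = None if background is None else pd.DataFrame(
        background, index=frame.index, columns=frame.columns)
    return ExpressionStudy(intensities=frame, roles=roles, background=bg)


def make_library(rng: np.random.Generator, n_genes: int = 80, n_drugs: int = 12,
                 instances_per_drug: int = 4) -> ReferenceLibrary:
    """A fully null reference library of uniform random rankings."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    cols, meta = {}, []
    for d in range(n_drugs):
        for i in range(instances_per_drug):
            inst = f"d{d:02d}_i{i}"
            cols[inst] = rng.permutation(n_genes) + 1
            meta.append((inst, f"d{d:02d}"))
    return ReferenceLibrary(
        ranks=pd.DataFrame(cols, index=pd.Index(genes, name="gene")),
        meta=pd.DataFrame(meta, columns=["instance_id", "drug"]).set_index("instance_id"),
    )


def random_signature(rng: np.random.Generator, genes, n_up: int = 5,
                     n_down: int = 5) -> Signature:
    tags = rng.choice(list(genes), size=n_up + n_down, replace=False)
    return Signature(frozenset(tags[:n_up]), frozenset(tags[n_up:]), label="random")
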