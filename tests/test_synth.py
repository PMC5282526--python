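"""Generators: planted effects are exact in noise-free mode, outputs are
deterministic per seed, and every planted object is realized as stated."""

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from revsig.synth import (
    SynthConfig,
    generate_expression_study,
    generate_interaction_network,
    generate_literature_counts,
    generate_pathway_db,
    generate_reference_library,
)


class TestExpressionStudy:
    def test_noise_free_fold_change_is_exact(self, noise_free_config):
        config = dataclasses.replace(noise_free_config, effect_log2=1.0)
        study, truth = generate_expression_study(config)
        gene = sorted(truth.up_genes)[0]
        ratio = study.intensities.at[gene, "disease"] / study.intensities.at[gene, "control"]
        assert ratio == pytest.approx(2.0, abs=1e-12)

    def test_restore_fraction_residual_effect(self, noise_free_config):
        # two dose steps at restore 0.5 leave 0.25 of the planted effect
        config = dataclasses.replace(noise_free_config, effect_log2=1.0,
                                     doses_or_times=("dose:a", "dose:b"),
                                     restore_fraction_per_step=0.5)
        study, truth = generate_expression_study(config)
        gene = sorted(truth.up_genes)[0]
        residual = np.log2(study.intensities.at[gene, "treated_1"]
                           / study.intensities.at[gene, "control"])
        assert residual == pytest.approx(0.25, abs=1e-12)

    def test_same_seed_reproduces_identical_matrices(self, small_config):
        a, _ = generate_expression_study(small_config)
        b, _ = generate_expression_study(small_config)
        pd.testing.assert_frame_equal(a.intensities, b.intensities)

    def test_intensities_strictly_positive(self, small_config):
        study, _ = generate_expression_study(small_config)
        assert (study.intensities.values > 0).all()

    def test_mean_planted_effect_converges(self):
        # with noise, the empirical mean log2 effect approaches the planted one
        config = SynthConfig(n_genes=2000, seed=3)
        study, truth = generate_expression_study(config)
        up = sorted(truth.up_genes)
        effect = np.log2(study.intensities.loc[up, "disease"]
                         / study.intensities.loc[up, "control"])
        assert effect.mean() == pytest.approx(config.effect_log2, abs=0.05)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            SynthConfig(n_genes=0)

    def test_overlapping_drug_lists_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SynthConfig(reversal_drugs=("drug00",), mimic_drugs=("drug00",))


class TestReferenceLibrary:
    def test_noise_free_mimic_places_up_genes_on_top(self, noise_free_config):
        study, truth = generate_expression_study(noise_free_config)
        library = generate_reference_library(noise_free_config, truth)
        inst = "drug02_i0"  # a mimic drug
        ranks = library.ranks[inst]
        up = sorted(truth.up_genes)
        assert set(ranks.loc[up]) == set(range(1, len(up) + 1))
        down = sorted(truth.down_genes)
        n = noise_free_config.n_genes
        assert set(ranks.loc[down]) == set(range(n - len(down) + 1, n + 1))

    def test_noise_free_reversal_places_up_genes_on_bottom(self, noise_free_config):
        _, truth = generate_expression_study(noise_free_config)
        library = generate_reference_library(noise_free_config, truth)
        ranks = library.ranks["drug00_i0"]  # a reversal drug
        up = sorted(truth.up_genes)
        n = noise_free_config.n_genes
        assert set(ranks.loc[up]) == set(range(n - len(up) + 1, n + 1))

    def test_every_instance_is_a_permutation(self, small_config):
        _, truth = generate_expression_study(small_config)
        library = generate_reference_library(small_config, truth)
        # permutation property enforced by the container's validator
        assert library.ranks.shape == (small_config.n_genes,
                                       small_config.n_drugs * small_config.instances_per_drug)

    def test_neutral_drug_mean_rank_is_central(self):
        # uniform permutations: mean rank of any fixed gene ~ (n+1)/2
        config = SynthConfig(n_genes=50, n_drugs=1, instances_per_drug=1000,
                             reversal_drugs=(), mimic_drugs=(),
                             n_modules=0, module_size=0, seed=5)
        _, truth = generate_expression_study(config)
        library = generate_reference_library(config, truth)
        ranks = library.ranks.loc["g0000"].to_numpy(dtype=float)
        se = np.sqrt((config.n_genes ** 2 - 1) / 12 / len(ranks))
        assert abs(ranks.mean() - (config.n_genes + 1) / 2) < 3 * se

    def test_seed_determinism(self, small_config):
        _, truth = generate_expression_study(small_config)
        a = generate_reference_library(small_config, truth)
        b = generate_reference_library(small_config, truth)
        pd.testing.assert_frame_equal(a.ranks, b.ranks)


class TestPathwayDB:
    def test_flipped_duplicate_negates_every_role(self, small_config):
        _, truth = generate_expression_study(small_config)
        db, truth = generate_pathway_db(small_config, truth)
        original = db.get("path_up00")
        flipped = db.get("path_up00_flipped")
        assert flipped.members == original.members
        for g in original.members:
            assert flipped.role_weight[g] == -original.role_weight[g]

    def test_members_within_universe_and_direction_recorded(self, small_config):
        _, truth = generate_expression_study(small_config)
        db, truth = generate_pathway_db(small_config, truth)
        universe = set(small_config.gene_ids())
        for pw in db:
            assert pw.members <= universe
        assert truth.pathway_direction["path_up00"] == 1
        assert truth.pathway_direction["path_dn00"] == -1
        assert truth.pathway_direction["path_up00_flipped"] == -1

    def test_undersized_pathways_rejected(self, small_config):
        config = dataclasses.replace(small_config, pathway_size=1)
        _, truth = generate_expression_study(config)
        with pytest.raises(ValueError, match="at least 2"):
            generate_pathway_db(config, truth)


class TestInteractionNetwork:
    def test_isolated_cliques_form_components(self, noise_free_config):
        _, truth = generate_expression_study(noise_free_config)
        network, truth = generate_interaction_network(noise_free_config, truth)
        module_nodes = set(truth.module_partition)
        sub = network.subgraph(module_nodes)
        comps = list(nx.connected_components(sub))
        assert len(comps) == noise_free_config.n_modules
        for comp in comps:
            assert len(comp) == noise_free_config.module_size
            for g in comp:
                assert sub.degree[g] == noise_free_config.module_size - 1

    def test_no_self_loops(self, small_config):
        _, truth = generate_expression_study(small_config)
        network, _ = generate_interaction_network(small_config, truth)
        assert nx.number_of_selfloops(network) == 0

    def test_edge_list_roundtrip(self, small_config, tmp_path):
        from revsig.io import read_edge_list, write_edge_list

        _, truth = generate_expression_study(small_config)
        network, _ = generate_interaction_network(small_config, truth)
        path = tmp_path / "net.edges.tsv"
        write_edge_list(network, path)
        back = read_edge_list(path)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, network.edges))


class TestLiteratureCounts:
    def test_pure_plant_binarizes_to_indicator(self, small_config):
        config = dataclasses.replace(small_config, lit_enriched_prob=1.0,
                                     lit_background_prob=0.0)
        _, truth = generate_expression_study(config)
        matrix, truth = generate_literature_counts(config, truth)
        binary_rows = (matrix > 0).sum(axis=1)
        for item in matrix.index:
            expected = config.n_keywords if item in truth.enriched_literature_items else 0
            assert binary_rows[item] == expected

    def test_counts_non_negative_and_deterministic(self, small_config):
        _, truth = generate_expression_study(small_config)
        a, _ = generate_literature_counts(small_config, truth)
        b, _ = generate_literature_counts(small_config, truth)
        assert (a.values >= 0).all()
        pd.testing.assert_frame_equal(a, b)


def test_truth_references_only_universe_genes(small_config):
    """Every planted object cites genes/items present in the generated world."""
    study, truth = generate_expression_study(small_config)
    library = generate_reference_library(small_config, truth)
    db, truth = generate_pathway_db(small_config, truth)
    network, truth = generate_interaction_network(small_config, truth)
    matrix, truth = generate_literature_counts(small_config, truth)
    universe = set(study.genes)
    assert truth.up_genes <= universe and truth.down_genes <= universe
    assert set(truth.module_partition) <= universe
    assert truth.enriched_literature_items <= set(matrix.index)
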