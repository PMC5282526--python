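"""Background filtering, quantile normalization, ratio transforms and the
three signature-selection routes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revsig.containers import LogRatioMatrix
from revsig.preprocess import (
    assign_model_profiles,
    filter_above_background,
    log_ratio,
    quantile_normalize,
    select_fold_change,
    two_class_statistic,
)

from conftest import make_study

ROLES2 = {"s1": "control", "s2": "disease"}


class TestBackgroundFilter:
    def test_threshold_boundary(self):
        # 150/100 = 1.5 >= 1.4 kept; 130/100 dropped
        study = make_study({"s1": [150.0, 130.0], "s2": [150.0, 130.0]},
                           ROLES2, background=100.0)
        kept = filter_above_background(study, factor=1.4)
        assert list(kept.genes) == [0]

    def test_factor_zero_keeps_everything(self):
        study = make_study({"s1": [1.0, 2.0], "s2": [3.0, 4.0]}, ROLES2,
                           background=100.0)
        assert len(filter_above_background(study, factor=0.0).genes) == 2

    def test_any_versus_all_scope(self):
        study = make_study({"s1": [150.0], "s2": [50.0]}, ROLES2, background=100.0)
        assert len(filter_above_background(study, scope="any").genes) == 1
        assert len(filter_above_background(study, scope="all").genes) == 0

    def test_missing_background_raises(self):
        study = make_study({"s1": [1.0], "s2": [1.0]}, ROLES2)
        with pytest.raises(ValueError, match="skip"):
            filter_above_background(study)


class TestQuantileNormalize:
    def test_two_column_example(self):
        matrix = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = quantile_normalize(matrix)
        expected = pd.DataFrame({"a": [1.5, 3.5], "b": [1.5, 3.5]})
        pd.testing.assert_frame_equal(out, expected)

    def test_identical_columns_are_a_fixed_point(self):
        matrix = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        pd.testing.assert_frame_equal(quantile_normalize(matrix), matrix)

    def test_rank_order_preserved_within_columns(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(rng.random((30, 3)), columns=list("abc"))
        out = quantile_normalize(matrix)
        for col in matrix:
            assert (np.argsort(out[col].to_numpy())
                    == np.argsort(matrix[col].to_numpy())).all()

    def test_ties_get_mean_of_tied_rank_values(self):
        matrix = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 4.0]})
        out = quantile_normalize(matrix)
        # reference distribution (1.5, 2.5); tied column gets the midpoint twice
        assert out["a"].tolist() == [2.0, 2.0]
        assert out["b"].tolist() == [1.5, 2.5]

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, np.nan]}))


class TestLogRatio:
    def test_hand_values(self):
        study = make_study({"s1": [100.0, 100.0, 100.0],
                            "s2": [200.0, 100.0, 50.0]}, ROLES2)
        lrm = log_ratio(study, pseudocount=0.0)
        assert lrm.values["s2"].tolist() == pytest.approx([1.0, 0.0, -1.0])

    def test_reference_column_excluded_by_default(self):
        study = make_study({"s1": [100.0], "s2": [200.0]}, ROLES2)
        assert list(log_ratio(study).conditions) == ["s2"]

    def test_zero_reference_without_pseudocount_raises(self):
        study = make_study({"s1": [0.0], "s2": [1.0]}, ROLES2)
        with pytest.raises(ValueError):
            log_ratio(study, pseudocount=0.0)


class TestFoldChangeSelection:
    def lrm(self, rows: dict) -> LogRatioMatrix:
        return LogRatioMatrix(pd.DataFrame(rows).T.rename(
            columns=lambda i: f"c{i}"))

    def test_inclusive_boundary(self):
        lrm = self.lrm({"g1": [1.0], "g2": [0.9], "g3": [-1.0]})
        sel = select_fold_change(lrm, fold=2.0)
        assert sel.signature.up_tags == {"g1"}
        assert sel.signature.down_tags == {"g3"}

    def test_conflicting_gene_excluded_and_reported(self):
        lrm = self.lrm({"g1": [1.2, -1.2], "g2": [1.5, 0.0]})
        sel = select_fold_change(lrm, fold=2.0)
        assert "g1" in sel.conflicting
        assert sel.signature.up_tags == {"g2"}
        assert "g1" not in sel.signature.down_tags

    def test_fold_at_most_one_rejected(self):
        lrm = self.lrm({"g1": [1.0], "g2": [2.0]})
        with pytest.raises(ValueError):
            select_fold_change(lrm, fold=1.0)

    def test_raising_fold_never_adds_tags(self):
        # single condition: no cross-condition conflicts, so selection is
        # monotone in the fold threshold
        rng = np.random.default_rng(1)
        lrm = LogRatioMatrix(pd.DataFrame(
            rng.normal(0, 1.5, (50, 1)), columns=["c0"],
            index=[f"g{i}" for i in range(50)]))
        loose = select_fold_change(lrm, fold=2.0).signature
        tight = select_fold_change(lrm, fold=3.0).signature
        assert tight.up_tags <= loose.up_tags
        assert tight.down_tags <= loose.down_tags


class TestModelProfiles:
    def trajectories(self) -> LogRatioMatrix:
        rng = np.random.default_rng(4)
        monotone = np.outer(np.ones(40), [0.0, 0.5, 1.0, 1.5])
        noise = rng.normal(0, 1.0, (40, 4))
        frame = pd.DataFrame(np.vstack([monotone, noise]),
                             columns=["c0", "c1", "c2", "c3"],
                             index=[f"g{i}" for i in range(80)])
        return LogRatioMatrix(frame)

    def test_exact_template_match_assigned(self):
        lrm = self.trajectories()
        result = assign_model_profiles(lrm, n_profiles=30, n_permutations=50, seed=0)
        profiles = result.model_profiles.to_numpy()
        # the monotone-up unit template is among the candidates
        steps = np.diff(profiles, axis=1)
        monotone_idx = [i for i in range(len(profiles)) if (steps[i] > 0).all()]
        assert result.gene_to_profile["g0"] in monotone_idx

    def test_flat_gene_unassigned(self):
        frame = pd.DataFrame({"c0": [0.0, 1.0], "c1": [0.0, 2.0], "c2": [0.0, 3.0]},
                             index=["flat", "rising"])
        result = assign_model_profiles(LogRatioMatrix(frame), n_permutations=10, seed=0)
        assert "flat" in result.unassigned
        assert "flat" not in result.gene_to_profile

    def test_planted_monotone_block_is_significant(self):
        # 8 capped profiles: the BH floor 8/1001 still clears the 0.01 bar
        lrm = self.trajectories()
        result = assign_model_profiles(lrm, n_profiles=8, n_permutations=1000, seed=1)
        profile = result.gene_to_profile["g0"]
        # all 40 planted genes land on one profile and it is over-occupied
        assert all(result.gene_to_profile[f"g{i}"] == profile for i in range(40))
        assert result.profile_fdr[profile] < 0.01

    def test_null_input_yields_no_significant_profile(self):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame(rng.normal(0, 1, (60, 4)),
                             columns=["c0", "c1", "c2", "c3"],
                             index=[f"g{i}" for i in range(60)])
        result = assign_model_profiles(LogRatioMatrix(frame),
                                       n_permutations=200, seed=2)
        assert all(q >= 0.01 for q in result.profile_fdr.values())

    def test_too_few_conditions_rejected(self):
        frame = pd.DataFrame({"c0": [0.0], "c1": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            assign_model_profiles(LogRatioMatrix(frame))


class TestTwoClassStatistic:
    def test_hand_value_with_fixed_s0(self):
        matrix = pd.DataFrame([[1.0, 1.0, 3.0, 3.0]], index=["g"])
        sel = two_class_statistic(matrix, ["a", "a", "b", "b"], s0=1.0)
        assert sel.d_scores["g"] == pytest.approx(2.0)

    def test_identical_groups_give_zero(self):
        matrix = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]], index=["g"])
        sel = two_class_statistic(matrix, ["a", "a", "b", "b"], s0=1.0)
        assert sel.d_scores["g"] == 0.0

    def test_negation_antisymmetry_and_label_swap(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(rng.normal(0, 1, (20, 6)),
                              index=[f"g{i}" for i in range(20)])
        labels = ["a", "a", "a", "b", "b", "b"]
        d = two_class_statistic(matrix, labels, s0=0.5).d_scores
        d_neg = two_class_statistic(-matrix, labels, s0=0.5).d_scores
        d_swap = two_class_statistic(matrix, ["b"] * 3 + ["a"] * 3, s0=0.5).d_scores
        assert np.allclose(d_neg, -d)
        assert np.allclose(np.abs(d_swap), np.abs(d))

    def test_small_group_rejected(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        with pytest.raises(ValueError):
            two_class_statistic(matrix, ["a", "b", "b"])


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_quantile_normalize_equalizes_column_distributions(seed):
    """All columns share one sorted value vector after normalization."""
    rng = np.random.default_rng(seed)
    matrix = pd.DataFrame(rng.random((20, 3)), columns=list("abc"))
    out = quantile_normalize(matrix).to_numpy()
    ref = np.sort(out[:, 0])
    for j in (1, 2):
        assert np.array_equal(np.sort(out[:, j]), ref)
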