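import numpy as np
import pandas as pd
import pytest

from qnbench import (
    DataError,
    STRATEGY_NAMES,
    normalize,
    normalize_all,
    normalize_class_specific,
    normalize_discrete,
    qsmooth_normalize,
    qsmooth_weights,
    quantile_normalize,
    ratio_transform,
    reference_distribution,
)
from conftest import make_dataset
from oracles import qsmooth_weights_oracle


class TestDispatch:
    def test_adjust_is_identity(self, two_class_dataset):
        out = normalize(two_class_dataset, "adjust")
        assert out.equals(two_class_dataset)
        assert out is not two_class_dataset

    def test_unknown_strategy_rejected(self, two_class_dataset):
        with pytest.raises(ValueError, match="unknown strategy"):
            normalize(two_class_dataset, "combat")

    def test_all_equals_core_qn(self, two_class_dataset):
        out = normalize(two_class_dataset, "all")
        assert np.array_equal(
            out.values.to_numpy(), quantile_normalize(two_class_dataset.values.to_numpy())
        )

    @pytest.mark.parametrize("strategy", [s for s in STRATEGY_NAMES if s != "ratio"])
    def test_shape_order_and_labels_preserved(self, two_class_dataset, strategy):
        out = normalize(two_class_dataset, strategy)
        assert out.sample_ids == two_class_dataset.sample_ids
        assert out.feature_ids == two_class_dataset.feature_ids
        assert list(out.classes) == list(two_class_dataset.classes)
        assert list(out.batches) == list(two_class_dataset.batches)


class TestNestingLimits:
    def test_single_class_class_specific_equals_all(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.uniform(1, 9, (15, 6)), "AAAAAA", ["b1", "b2"] * 3)
        assert normalize_class_specific(ds).equals(normalize_all(ds))

    def test_single_batch_discrete_equals_class_specific(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.uniform(1, 9, (15, 6)), "AAABBB", ["b1"] * 6)
        assert normalize_discrete(ds).equals(normalize_class_specific(ds))

    def test_one_sample_per_cell_is_identity(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.uniform(1, 9, (10, 4)), "AABB", ["b1", "b2"] * 2)
        assert normalize_discrete(ds).equals(ds)


class TestClassSpecific:
    def test_scaled_class_keeps_scaled_reference(self):
        """If class B is class A scaled x2, the post-normalization class-B
        reference is exactly twice the class-A reference."""
        rng = np.random.default_rng(5)
        a = rng.uniform(1, 9, (12, 3))
        b = 2.0 * a[:, [1, 2, 0]]
        ds = make_dataset(np.hstack([a, b]), "AAABBB", ["b1"] * 6)
        out = normalize_class_specific(ds)
        ref_a = reference_distribution(out.values.iloc[:, :3])
        ref_b = reference_distribution(out.values.iloc[:, 3:])
        assert np.allclose(ref_b, 2.0 * ref_a)

    def test_within_class_distributions_shared_across_classes_not(self):
        rng = np.random.default_rng(6)
        ds = make_dataset(
            np.hstack([rng.uniform(1, 9, (20, 4)), rng.uniform(10, 90, (20, 4))]),
            "AAAABBBB",
            ["b1"] * 8,
        )
        out = normalize_class_specific(ds)
        arr = out.values.to_numpy()
        for cols in (range(4), range(4, 8)):
            sorted_cols = np.sort(arr[:, cols], axis=0)
            assert np.allclose(sorted_cols, sorted_cols[:, [0]])
        assert not np.allclose(np.sort(arr[:, 0]), np.sort(arr[:, 4]))


class TestDiscrete:
    def test_each_cell_shares_a_distribution(self):
        rng = np.random.default_rng(7)
        ds = make_dataset(
            rng.uniform(1, 9, (20, 8)), "AAAABBBB", ["b1", "b1", "b2", "b2"] * 2
        )
        out = normalize_discrete(ds)
        for cls, batch in {("A", "b1"), ("A", "b2"), ("B", "b1"), ("B", "b2")}:
            cols = [
                s
                for s in ds.sample_ids
                if ds.classes[s] == cls and ds.batches[s] == batch
            ]
            sorted_cols = np.sort(out.values[cols].to_numpy(), axis=0)
            assert np.allclose(sorted_cols, sorted_cols[:, [0]])


class TestRatio:
    def test_within_batch_pairing_formula(self):
        ds = make_dataset([[2.0, 5.0], [4.0, 4.0]], "AB", ["b1", "b1"])
        rds = ratio_transform(ds)
        assert np.array_equal(rds.values.to_numpy()[:, 0], [2.5, 1.0])
        assert list(rds.values.columns) == ["S2/S1"]
        assert list(rds.batches) == ["b1"]

    def test_identical_classes_give_all_ones(self):
        a = np.array([[3.0], [7.0]])
        ds = make_dataset(np.hstack([a, a]), "AB", ["b1", "b1"])
        assert np.array_equal(ratio_transform(ds).values.to_numpy(), np.ones((2, 1)))

    def test_unbalanced_batch_rejected(self):
        ds = make_dataset(np.ones((2, 5)), "AAABB", ["b1"] * 5)
        with pytest.raises(DataError, match="unbalanced pairing"):
            ratio_transform(ds)

    def test_pairs_only_within_batches_and_column_count(self, two_class_dataset):
        rds = ratio_transform(two_class_dataset)
        assert rds.n_pairs == 4  # 2 pairs per batch x 2 batches
        assert (rds.values.to_numpy() > 0).all()
        for name, batch in rds.batches.items():
            num, den = name.split("/")
            assert two_class_dataset.batches[num] == batch
            assert two_class_dataset.batches[den] == batch

    def test_random_pairing_is_seeded(self, two_class_dataset):
        r1 = ratio_transform(
            two_class_dataset, pairing="random", rng=np.random.default_rng(9)
        )
        r2 = ratio_transform(
            two_class_dataset, pairing="random", rng=np.random.default_rng(9)
        )
        assert list(r1.values.columns) == list(r2.values.columns)


class TestQsmoothWeights:
    def test_identical_group_quantiles_give_weight_one(self):
        base = np.sort(np.random.default_rng(0).uniform(size=(30, 2)), axis=0)
        sorted_m = np.tile(base, (1, 2))  # both groups hold the same two columns
        w = qsmooth_weights(sorted_m, ["A", "A", "B", "B"])
        assert np.allclose(w, 1.0)

    def test_fully_separated_groups_give_weight_near_zero(self):
        base = np.sort(np.random.default_rng(1).uniform(size=(30, 2)), axis=0)
        sorted_m = np.hstack([base, base + 100.0])
        w = qsmooth_weights(sorted_m, ["A", "A", "B", "B"])
        assert np.all(w < 1e-4)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        sorted_m = np.sort(rng.lognormal(0, 1, size=(20, 6)), axis=0)
        labels = ["A", "A", "A", "B", "B", "B"]
        assert np.allclose(
            qsmooth_weights(sorted_m, labels),
            qsmooth_weights_oracle(sorted_m, labels),
        )

    @pytest.mark.parametrize("n_features", [20, 57, 200])
    def test_oracle_agreement_across_window_parities(self, n_features):
        rng = np.random.default_rng(n_features)
        sorted_m = np.sort(rng.lognormal(0, 1, size=(n_features, 4)), axis=0)
        labels = ["A", "A", "B", "B"]
        assert np.allclose(
            qsmooth_weights(sorted_m, labels),
            qsmooth_weights_oracle(sorted_m, labels),
        )

    def test_small_class_rejected(self):
        with pytest.raises(DataError, match="fewer than 2"):
            qsmooth_weights(np.sort(np.ones((5, 3)), axis=0), ["A", "A", "B"])


class TestQsmoothNormalize:
    def test_weight_one_limit_equals_all(self, two_class_dataset):
        out = qsmooth_normalize(two_class_dataset, weights=np.ones(20))
        assert np.allclose(
            out.values.to_numpy(), normalize_all(two_class_dataset).values.to_numpy()
        )

    def test_weight_zero_limit_equals_class_specific(self, two_class_dataset):
        out = qsmooth_normalize(two_class_dataset, weights=np.zeros(20))
        assert np.allclose(
            out.values.to_numpy(),
            normalize_class_specific(two_class_dataset).values.to_numpy(),
        )

    def test_identical_class_distributions_reduce_to_all(self):
        rng = np.random.default_rng(13)
        a = rng.uniform(1, 9, (25, 3))
        b = a[rng.permutation(25)][:, [2, 0, 1]]  # same values, reshuffled
        ds = make_dataset(np.hstack([a, b]), "AAABBB", ["b1"] * 6)
        out = qsmooth_normalize(ds)
        assert np.allclose(
            out.values.to_numpy(), normalize_all(ds).values.to_numpy(), atol=1e-9
        )

    def test_output_is_convex_combination_rankwise(self, two_class_dataset):
        out, fit = qsmooth_normalize(two_class_dataset, return_fit=True)
        all_out = normalize_all(two_class_dataset).values.to_numpy()
        cs_out = normalize_class_specific(two_class_dataset).values.to_numpy()
        lo = np.minimum(np.sort(all_out, 0), np.sort(cs_out, 0)) - 1e-9
        hi = np.maximum(np.sort(all_out, 0), np.sort(cs_out, 0)) + 1e-9
        sorted_out = np.sort(out.values.to_numpy(), 0)
        assert np.all(sorted_out >= lo) and np.all(sorted_out <= hi)

    def test_fit_invariants(self, two_class_dataset):
        _, fit = qsmooth_normalize(two_class_dataset, return_fit=True)
        assert np.all((fit.weights >= 0) & (fit.weights <= 1))
        assert np.allclose(
            fit.qref, reference_distribution(two_class_dataset.values)
        )
        assert list(fit.qhat.columns) == ["A", "B"]

    def test_single_class_rejected(self, tiny_dataset):
        with pytest.raises(DataError, match="2 classes"):
            qsmooth_normalize(tiny_dataset)
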