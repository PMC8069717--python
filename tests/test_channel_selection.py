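import numpy as np
import pytest

from eegfatigue import (
    ChannelWeightTable,
    build_channel_weight_table,
    common_weights_accuracy,
    common_weights_addition,
    make_toy_feature_table,
    select_common_channels,
    single_channel_accuracy,
)


def _table(weights, accs=None, n_feats=None):
    weights = np.asarray(weights, float)
    s, c, f = weights.shape
    accs = np.ones_like(weights) if accs is None else np.asarray(accs, float)
    return ChannelWeightTable(
        weights=weights,
        accuracies=accs,
        channel_labels=[f"ch{i}" for i in range(c)],
        subject_ids=[f"S{i+1}" for i in range(s)],
        feature_names=[f"f{i}" for i in range(f)],
    )


class TestSingleChannelAccuracy:
    def test_perfectly_separated_column(self):
        X = make_toy_feature_table(n_samples=60, n_features=2, n_informative=1,
                                   class_sep=50.0, seed=0, n_channels=2)
        ch, feat = X.column_index[0]
        assert single_channel_accuracy(X, ch, feat) == 1.0

    def test_column_equal_to_label(self):
        X = make_toy_feature_table(n_samples=40, n_features=2, n_informative=0,
                                   class_sep=0.0, seed=1, n_channels=2)
        X.values[:, 0] = X.labels.astype(float)
        ch, feat = X.column_index[0]
        for folds in (3, 5):
            assert single_channel_accuracy(X, ch, feat, cv_folds=folds) == 1.0

    def test_uninformative_column_near_chance(self):
        accs = []
        for seed in range(50):
            X = make_toy_feature_table(n_samples=80, n_features=2, n_informative=0,
                                       class_sep=0.0, seed=seed, n_channels=2)
            ch, feat = X.column_index[1]
            accs.append(single_channel_accuracy(X, ch, feat, seed=seed))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    def test_missing_column_rejected(self):
        X = make_toy_feature_table(n_samples=30, n_features=2, n_informative=1,
                                   n_channels=2)
        with pytest.raises(KeyError):
            single_channel_accuracy(X, "nope", "f0")


class TestWeightAddition:
    def test_elementwise_sum_of_normalized_weights(self):
        # two subjects whose normalized channel weights are [0.5, 1] and [1, 0]
        w = np.array([[[0.25], [0.5]], [[0.9], [0.1]]])
        t = _table(w)
        # subject 1: min-max of [0.25, 0.5] -> [0, 1]; subject 2: [1, 0]
        np.testing.assert_allclose(common_weights_addition(t), [1.0, 1.0])

    def test_single_subject_preserves_ranking(self):
        w = np.array([[[0.1, 0.3], [0.6, 0.2], [0.9, 0.5]]])
        t = _table(w)
        per_channel = w[0].mean(axis=1)
        order = np.argsort(-common_weights_addition(t))
        np.testing.assert_array_equal(order, np.argsort(-per_channel))

    def test_matches_normalize_then_sum_oracle(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal((3, 16, 5))
        t = _table(w)
        expected = np.zeros(16)
        for s in range(3):
            v = w[s].mean(axis=1)
            expected += (v - v.min()) / (v.max() - v.min())
        np.testing.assert_allclose(common_weights_addition(t), expected, atol=1e-12)

    def test_degenerate_subject_contributes_half_with_warning(self):
        w = np.array([[[0.4], [0.4]], [[0.2], [0.8]]])
        t = _table(w)
        with pytest.warns(UserWarning, match="all channel weights equal"):
            out = common_weights_addition(t)
        np.testing.assert_allclose(out, [0.5, 1.5])

    def test_sum_normalization_option(self):
        w = np.array([[[1.0], [3.0]]])
        t = _table(w)
        np.testing.assert_allclose(
            common_weights_addition(t, normalize="sum"), [0.25, 0.75]
        )


class TestAccuracyWeighting:
    def test_unit_accuracies_reduce_to_weight_sum(self):
        rng = np.random.default_rng(1)
        w = rng.random((2, 4, 3))
        t = _table(w)
        np.testing.assert_allclose(
            common_weights_accuracy(t), w.sum(axis=(0, 2)), atol=1e-12
        )

    def test_products_single_subject_single_feature(self):
        w = np.array([[[0.2], [0.4]]])
        a = np.array([[[0.5], [1.0]]])
        t = _table(w, a)
        np.testing.assert_allclose(common_weights_accuracy(t), [0.1, 0.4])

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        w = rng.standard_normal((4, 6, 5))
        a = rng.random((4, 6, 5))
        t = _table(w, a)
        expected = np.zeros(6)
        for s in range(4):
            for c in range(6):
                for f in range(5):
                    expected[c] += w[s, c, f] * a[s, c, f]
        np.testing.assert_allclose(common_weights_accuracy(t), expected, atol=1e-12)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(3)
        w = rng.standard_normal((3, 4, 2))
        a = rng.random((3, 4, 2))
        t1 = _table(w, a)
        t2 = _table(w[::-1], a[::-1])
        np.testing.assert_allclose(
            common_weights_accuracy(t1), common_weights_accuracy(t2), atol=1e-12
        )
        np.testing.assert_allclose(
            common_weights_addition(t1), common_weights_addition(t2), atol=1e-12
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            ChannelWeightTable(
                weights=np.zeros((1, 2, 3)),
                accuracies=np.zeros((1, 2, 2)),
                channel_labels=["a", "b"],
                subject_ids=["S1"],
                feature_names=["f1", "f2", "f3"],
            )

    def test_accuracy_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            _table(np.zeros((1, 2, 1)), np.full((1, 2, 1), 1.5))


class TestSelect:
    def test_sixteen_channels_keep_eight_by_default(self):
        labels = [f"ch{i}" for i in range(16)]
        sel = select_common_channels(np.arange(16.0), labels)
        assert len(sel) == 8

    def test_increasing_weights_select_highest_indices(self):
        labels = ["a", "b", "c", "d"]
        sel = select_common_channels(np.array([1.0, 2.0, 3.0, 4.0]), labels)
        assert sel == ["d", "c"]

    def test_tie_at_cut_goes_to_lower_original_index(self):
        labels = ["a", "b", "c", "d"]
        sel = select_common_channels(np.array([1.0, 5.0, 3.0, 3.0]), labels, n_keep=2)
        assert sel == ["b", "c"]

    def test_n_keep_exceeding_channels_rejected(self):
        with pytest.raises(ValueError):
            select_common_channels(np.zeros(3), ["a", "b", "c"], n_keep=4)


class TestEndToEndTable:
    def test_build_table_shapes_and_ranges(self, small_features):
        X, _ = small_features
        table = build_channel_weight_table(X, seed=0)
        assert table.weights.shape == (2, 8, 5)
        assert np.all((table.accuracies >= 0) & (table.accuracies <= 1))
        assert table.subject_ids == ["S1", "S2"]

    def test_planted_channels_recovered(self, small_features):
        X, truth = small_features
        table = build_channel_weight_table(X, seed=0)
        sel = select_common_channels(
            common_weights_accuracy(table), table.channel_labels
        )
        recovered = set(sel) & set(truth["informative_labels"])
        assert len(recovered) >= 2
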