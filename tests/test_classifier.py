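import numpy as np
import pandas as pd
import pytest

from dhikit.classifier import (
    LABEL_COLUMN,
    TrainConfig,
    _BatchNorm,
    _Dense,
    predict,
    smote_balance,
    split_dataset,
    table_checksum,
    train,
)


def toy_table(n_per_class=100, n_classes=2, n_features=4, spread=6.0, seed=0):
    """Well-separated Gaussian blobs, one per class."""
    rng = np.random.default_rng(seed)
    frames = []
    for c in range(n_classes):
        x = rng.normal(c * spread, 1.0, (n_per_class, n_features))
        f = pd.DataFrame(x, columns=[f"f{i}" for i in range(n_features)])
        f[LABEL_COLUMN] = c
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def small_config(**kw):
    base = dict(features=("f0", "f1", "f2", "f3"), hidden_layers=3,
                hidden_width=32, max_epochs=50, batch_size=64,
                n_classes=2, seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestSplit:
    def test_partition_sizes_by_rounding(self):
        table = toy_table(5)  # N = 10
        tr, va, te = split_dataset(table, seed=0)
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_disjoint_and_exhaustive(self):
        table = toy_table(60)
        tr, va, te = split_dataset(table, seed=1)
        all_idx = np.concatenate([tr.index, va.index, te.index])
        assert sorted(all_idx) == sorted(table.index)
        assert len(set(tr.index) & set(va.index)) == 0
        assert len(set(tr.index) & set(te.index)) == 0

    def test_reproducible_per_seed(self):
        table = toy_table(30)
        a = split_dataset(table, seed=5)
        b = split_dataset(table, seed=5)
        for x, y in zip(a, b):
            assert list(x.index) == list(y.index)

    def test_stratified_keeps_class_balance(self):
        table = toy_table(200, n_classes=2)
        _, _, te = split_dataset(table, seed=2, stratified=True)
        counts = te[LABEL_COLUMN].value_counts()
        assert counts[0] == counts[1] == 20

    def test_stratified_rejects_tiny_class(self):
        table = toy_table(10)
        table = pd.concat([table, table.iloc[:1].assign(**{LABEL_COLUMN: 5})],
                          ignore_index=True)
        with pytest.raises(ValueError):
            split_dataset(table, seed=0, stratified=True)

    def test_invalid_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(toy_table(10), ratios=(0.8, 0.2, 0.0))


class TestSmote:
    def test_exact_balancing_counts(self):
        table = pd.concat([toy_table(100, 1), toy_table(40, 1, seed=1).assign(
            **{LABEL_COLUMN: 1})], ignore_index=True)
        out = smote_balance(table, seed=0)
        counts = out[LABEL_COLUMN].value_counts()
        assert counts[0] == counts[1] == 100

    def test_synthetic_rows_on_neighbor_segments(self):
        table = pd.concat([toy_table(60, 1), toy_table(25, 1, seed=1).assign(
            **{LABEL_COLUMN: 1})], ignore_index=True)
        out = smote_balance(table, seed=3)
        cols = [f"f{i}" for i in range(4)]
        orig = table.loc[table[LABEL_COLUMN] == 1, cols].to_numpy()
        synth = out.iloc[len(table):][cols].to_numpy()
        assert len(synth) == 35
        for row in synth:
            on_some_segment = False
            for i in range(len(orig)):
                d = orig - orig[i]
                num = row - orig[i]
                with np.errstate(invalid="ignore", divide="ignore"):
                    u = np.where(d != 0, num / d, np.nan)
                for j in range(len(orig)):
                    if j == i:
                        continue
                    uj = u[j][~np.isnan(u[j])]
                    if uj.size and np.allclose(uj, uj[0], atol=1e-8) \
                            and -1e-9 <= uj[0] <= 1 + 1e-9:
                        on_some_segment = True
                        break
                if on_some_segment:
                    break
            assert on_some_segment

    def test_originals_retained_unchanged(self):
        table = pd.concat([toy_table(50, 1), toy_table(20, 1, seed=1).assign(
            **{LABEL_COLUMN: 1})], ignore_index=True)
        out = smote_balance(table, seed=0)
        pd.testing.assert_frame_equal(out.iloc[:len(table)], table)

    def test_balanced_input_returned_unchanged(self):
        table = toy_table(50)
        out = smote_balance(table, seed=0)
        pd.testing.assert_frame_equal(out, table)

    def test_k_clamped_with_warning(self):
        table = pd.concat([toy_table(50, 1), toy_table(3, 1, seed=1).assign(
            **{LABEL_COLUMN: 1})], ignore_index=True)
        with pytest.warns(UserWarning, match="clamped"):
            out = smote_balance(table, k_neighbors=5, seed=0)
        assert out[LABEL_COLUMN].value_counts()[1] == 50

    def test_singleton_class_duplicated_with_warning(self):
        table = pd.concat([toy_table(10, 1), toy_table(1, 1, seed=1).assign(
            **{LABEL_COLUMN: 1})], ignore_index=True)
        with pytest.warns(UserWarning, match="single"):
            out = smote_balance(table, seed=0)
        assert out[LABEL_COLUMN].value_counts()[1] == 10


class TestTrainPredict:
    def test_separable_classes_learned(self):
        table = toy_table(550, n_classes=2)
        tr, va, _ = split_dataset(table, seed=0)
        model = train(tr, va, small_config())
        assert 1.0 - min(model.history["val_error"]) >= 0.98
        proba, labels = predict(model, va)
        acc = (labels == va[LABEL_COLUMN].to_numpy()).mean()
        assert acc >= 0.98

    def test_architecture_matches_config(self):
        table = toy_table(30)
        tr, va, _ = split_dataset(table, seed=0)
        cfg = small_config(hidden_layers=10, hidden_width=16, max_epochs=2,
                           n_classes=6)
        model = train(tr, va, cfg)
        dense = [l for l in model.layers if isinstance(l, _Dense)]
        bn = [l for l in model.layers if isinstance(l, _BatchNorm)]
        assert len(dense) == 11 and len(bn) == 10  # 10 hidden + softmax head
        assert dense[-1].w.shape[1] == 6

    def test_training_deterministic(self):
        table = toy_table(80)
        tr, va, _ = split_dataset(table, seed=0)
        m1 = train(tr, va, small_config(max_epochs=5))
        m2 = train(tr, va, small_config(max_epochs=5))
        assert m1.history["val_loss"] == m2.history["val_loss"]

    def test_loss_decreases_on_separable_data(self):
        table = toy_table(200)
        tr, va, _ = split_dataset(table, seed=0)
        model = train(tr, va, small_config(max_epochs=8))
        losses = model.history["train_loss"]
        assert losses[-1] < losses[0]

    def test_probabilities_sum_to_one(self):
        table = toy_table(60)
        tr, va, _ = split_dataset(table, seed=0)
        model = train(tr, va, small_config(max_epochs=3))
        proba, _ = predict(model, va)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(np.isfinite(proba))

    def test_no_leakage_into_validation(self):
        table = toy_table(100)
        tr, va, te = split_dataset(table, seed=0)
        sums = (table_checksum(va), table_checksum(te))
        balanced = smote_balance(tr, seed=0)
        train(balanced, va, small_config(max_epochs=3))
        assert (table_checksum(va), table_checksum(te)) == sums

    def test_feature_mismatch_rejected(self):
        table = toy_table(60)
        tr, va, _ = split_dataset(table, seed=0)
        model = train(tr, va, small_config(max_epochs=2))
        with pytest.raises(ValueError):
            predict(model, np.ones((3, 7)))

    def test_empty_validation_rejected(self):
        table = toy_table(30)
        with pytest.raises(ValueError):
            train(table, table.iloc[:0], small_config())
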