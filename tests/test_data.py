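"""Loaders, segmentation, and split protocols."""

import numpy as np
import pytest

from tcngru import (SplitSpec, SynthConfig, WindowedDataset, generate,
                    kfold_subject_dependent, load_uci_har, load_unimib_windows,
                    make_validation_split, segment_sliding,
                    split_subject_independent, write_uci_layout)
from tcngru.data import DataError, load_uci_split


@pytest.fixture(scope="module")
def uci_tree(tmp_path_factory):
    cfg = SynthConfig(num_subjects=5, windows_per_subject_per_class=2,
                      window_length=16, channels=9, seed=4)
    ds = generate(cfg)
    root = tmp_path_factory.mktemp("uci")
    write_uci_layout(ds, root, train_subjects=[1, 2, 3], test_subjects=[4, 5])
    return cfg, ds, root


class TestUciLayout:
    def test_round_trip_is_bit_identical(self, uci_tree):
        cfg, ds, root = uci_tree
        train, test = load_uci_har(root)
        assert train.X.shape == (3 * 6 * 2, 16, 9)
        assert test.X.shape == (2 * 6 * 2, 16, 9)
        joined = np.concatenate([train.X, test.X])
        # writer sorts by subject membership; order within splits is preserved
        mask_train = np.isin(ds.subject, [1, 2, 3])
        expect = np.concatenate([ds.X[mask_train], ds.X[~mask_train]])
        assert np.array_equal(joined, expect)
        assert np.array_equal(train.y, ds.y[mask_train])
        assert np.array_equal(test.subject, ds.subject[~mask_train])

    def test_missing_channel_file_is_named(self, uci_tree, tmp_path):
        _, ds, root = uci_tree
        import shutil
        broken = tmp_path / "broken"
        shutil.copytree(root, broken)
        victim = broken / "train" / "Inertial Signals" / "body_acc_x_train.txt"
        victim.unlink()
        with pytest.raises((FileNotFoundError, DataError)):
            load_uci_split(broken, "train")

    def test_short_row_reports_file_and_row(self, uci_tree, tmp_path):
        import shutil
        _, _, root = uci_tree
        broken = tmp_path / "shortrow"
        shutil.copytree(root, broken)
        victim = broken / "train" / "Inertial Signals" / "body_gyro_z_train.txt"
        lines = victim.read_text().splitlines()
        lines[2] = " ".join(lines[2].split()[:-3])
        victim.write_text("\n".join(lines) + "\n")
        with pytest.raises(DataError, match="row 3"):
            load_uci_split(broken, "train")

    def test_overlapping_subject_sets_rejected(self, uci_tree):
        _, ds, _ = uci_tree
        with pytest.raises(DataError):
            write_uci_layout(ds, "/tmp/never", [1, 2], [2, 3])


class TestUnimib:
    def test_toy_arrays(self, rng):
        X = rng.normal(size=(10, 151, 3))
        ds = load_unimib_windows(X, rng.integers(1, 18, 10), np.arange(10))
        assert ds.X.shape == (10, 151, 3)
        assert ds.num_classes == 17 and ds.label_names[0] == "StandingUpFS"

    def test_flat_channel_major_round_trip(self, rng):
        windows = rng.normal(size=(2, 151, 3))
        flat = windows.transpose(0, 2, 1).reshape(2, 453)  # ax | ay | az blocks
        ds = load_unimib_windows(flat, [1, 5], [1, 2], order="channel")
        assert np.array_equal(ds.X, windows)

    def test_label_out_of_range(self, rng):
        with pytest.raises(DataError):
            load_unimib_windows(rng.normal(size=(2, 151, 3)), [1, 18], [1, 2])

    def test_subset_of_labels_accepted(self, rng):
        ds = load_unimib_windows(rng.normal(size=(16, 151, 3)),
                                 np.arange(1, 17), np.arange(16))
        assert ds.num_classes == 17  # names preserved even if a class is absent


class TestSegmentation:
    def test_half_overlap(self):
        sig = np.arange(256, dtype=float)[:, None]
        w = segment_sliding(sig, 128, 0.5)
        assert w.shape == (3, 128, 1)
        assert [int(w[i, 0, 0]) for i in range(3)] == [0, 64, 128]

    def test_zero_overlap(self):
        sig = np.zeros((300, 2))
        assert segment_sliding(sig, 100, 0.0).shape == (3, 100, 2)

    def test_exact_fit_single_window(self):
        assert segment_sliding(np.zeros((128, 1)), 128, 0.5).shape == (1, 128, 1)

    def test_window_longer_than_signal(self):
        with pytest.raises(DataError):
            segment_sliding(np.zeros((100, 1)), 128, 0.5)


class TestSplits:
    def test_subject_independent_routing(self, small_synth):
        _, ds = small_synth
        spec = SplitSpec(train_subjects=(1, 2, 3, 4), test_subjects=(5, 6))
        train, test = split_subject_independent(ds, spec)
        assert set(np.unique(test.subject)) == {5, 6}
        assert not set(np.unique(train.subject)) & set(np.unique(test.subject))
        assert len(train) + len(test) == len(ds)

    def test_overlap_and_empty_test_rejected(self, small_synth):
        _, ds = small_synth
        with pytest.raises(DataError):
            SplitSpec(train_subjects=(1, 2), test_subjects=(2, 3))
        with pytest.raises(DataError):
            split_subject_independent(
                ds, SplitSpec(train_subjects=(1,), test_subjects=()))

    def test_kfold_sizes_and_determinism(self, small_synth):
        _, ds = small_synth
        folds = kfold_subject_dependent(ds, k=5, seed=3)
        sizes = sorted(len(f) for f in folds)
        assert sum(sizes) == len(ds)
        assert max(sizes) - min(sizes) <= 1
        again = kfold_subject_dependent(ds, k=5, seed=3)
        assert all(np.array_equal(a, b) for a, b in zip(folds, again))
        # folds partition the indices exactly
        union = np.sort(np.concatenate(folds))
        assert np.array_equal(union, np.arange(len(ds)))

    def test_kfold_uneven_sizes(self):
        ds = WindowedDataset(np.zeros((101, 4, 1)), np.zeros(101, dtype=int),
                             np.zeros(101, dtype=int), ("a",))
        sizes = sorted(len(f) for f in kfold_subject_dependent(ds, k=5, seed=0))
        assert sizes == [20, 20, 20, 20, 21]

    def test_kfold_bounds(self, small_synth):
        _, ds = small_synth
        with pytest.raises(DataError):
            kfold_subject_dependent(ds, k=1)
        with pytest.raises(DataError):
            kfold_subject_dependent(ds, k=len(ds) + 1)

    def test_validation_split_stratified(self, small_synth):
        _, ds = small_synth
        fit, val = make_validation_split(ds, fraction=0.10, seed=0)
        assert len(fit) + len(val) == len(ds)
        assert abs(len(val) - 0.10 * len(ds)) < 1.0
        expected_per_class = len(val) / ds.num_classes
        for c in range(ds.num_classes):
            assert abs((val.y == c).sum() - expected_per_class) <= 1
        fit2, val2 = make_validation_split(ds, fraction=0.10, seed=0)
        assert np.array_equal(val.X, val2.X)

    def test_validation_split_empty_rejected(self):
        ds = WindowedDataset(np.zeros((3, 4, 1)), [0, 0, 0], [1, 1, 1], ("a",))
        with pytest.raises(DataError):
            make_validation_split(ds, fraction=0.01)


def test_dataset_validation():
    with pytest.raises(DataError):
        WindowedDataset(np.zeros((2, 4, 1)), [0, 1], [1], ("a", "b"))
    with pytest.raises(DataError):
        WindowedDataset(np.zeros((2, 4, 1)), [0, 5], [1, 1], ("a", "b"))


def test_dataset_cache_round_trip(small_synth, tmp_path):
    _, ds = small_synth
    path = tmp_path / "cache.npz"
    ds.save(path)
    back = WindowedDataset.load(path)
    assert np.array_equal(back.X, ds.X)
    assert np.array_equal(back.y, ds.y)
    assert back.label_names == ds.label_names
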