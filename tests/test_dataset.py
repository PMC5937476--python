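import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enzyvox.dataset import (
    ClassWeights,
    DatasetSplit,
    LabeledSample,
    class_counts,
    compute_class_weights,
    draw_flip_code,
    load_labels,
    one_hot,
    persist_split,
    split_dataset,
    training_stream,
)
from enzyvox.synthetic_fixtures import FixtureSpec, generate_trace
from enzyvox.voxelizer import FlipCode, VoxelizerConfig, voxelize

from oracles import class_weights_oracle

# training class counts of the full-scale PDB snapshot (largest class: EC3)
PDB_TRAIN_COUNTS = (7096, 12081, 15290, 2875, 1703, 1632)


def _dummy_samples(n, n_classes=6):
    return [LabeledSample(f"s{i:04d}", i % n_classes + 1,
                          generate_trace(FixtureSpec("helix", n_residues=10,
                                                     seed=i)))
            for i in range(n)]


class TestSplitDataset:
    def test_exact_sizes_for_100(self):
        split = split_dataset(_dummy_samples(100), seed=0)
        assert split.sizes == (64, 16, 20)

    def test_deterministic(self):
        samples = _dummy_samples(50)
        s1 = split_dataset(samples, seed=42)
        s2 = split_dataset(samples, seed=42)
        for a, b in zip((s1.train, s1.validation, s1.test),
                        (s2.train, s2.validation, s2.test)):
            assert [x.structure_id for x in a] == [x.structure_id for x in b]

    def test_partition_no_duplicates(self):
        samples = _dummy_samples(37)
        split = split_dataset(samples, seed=3)
        ids = [s.structure_id for part in (split.train, split.validation,
                                           split.test) for s in part]
        assert sorted(ids) == sorted(s.structure_id for s in samples)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            split_dataset(_dummy_samples(4), seed=0)

    def test_persisted_id_lists(self, tmp_path):
        split = split_dataset(_dummy_samples(20), seed=1)
        persist_split(split, tmp_path)
        train_ids = (tmp_path / "train_ids.txt").read_text().split()
        assert train_ids == [s.structure_id for s in split.train]


class TestClassWeights:
    def test_largest_class_has_weight_one(self):
        w = compute_class_weights(PDB_TRAIN_COUNTS).w
        assert w[2] == 1.0

    def test_ratio_values(self):
        w = compute_class_weights(PDB_TRAIN_COUNTS).w
        assert w[0] == pytest.approx(15290 / 7096, rel=1e-12)
        assert w[5] == pytest.approx(15290 / 1632, rel=1e-12)
        assert np.allclose(w, class_weights_oracle(PDB_TRAIN_COUNTS), rtol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(counts=st.lists(st.integers(1, 10_000), min_size=6, max_size=6),
           scale=st.integers(1, 50))
    def test_scale_invariance(self, counts, scale):
        w1 = compute_class_weights(counts).w
        w2 = compute_class_weights([c * scale for c in counts]).w
        assert np.allclose(w1, w2, rtol=1e-12)

    def test_uniform_counts_give_unit_weights(self):
        assert np.array_equal(compute_class_weights([7] * 6).w, np.ones(6))

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights([1, 2, 3, 0, 5, 6])

    def test_weights_invariants_enforced(self):
        with pytest.raises(ValueError):
            ClassWeights(np.array([0.5, 1, 1, 1, 1, 1]))


class TestLabels:
    def test_load_labels_roundtrip(self, tmp_path):
        pd.DataFrame({"structure_id": ["a", "b"], "ec_class": [1, 6]}).to_csv(
            tmp_path / "labels.csv", index=False)
        samples = load_labels(tmp_path / "labels.csv", tmp_path)
        assert [(s.structure_id, s.ec_class) for s in samples] == [("a", 1),
                                                                   ("b", 6)]

    def test_multi_label_rejected_with_warning(self, tmp_path):
        pd.DataFrame({"structure_id": ["a", "a", "b"],
                      "ec_class": [1, 2, 3]}).to_csv(tmp_path / "labels.csv",
                                                     index=False)
        with pytest.warns(UserWarning, match="multi-label"):
            samples = load_labels(tmp_path / "labels.csv", tmp_path)
        assert [s.structure_id for s in samples] == ["b"]

    def test_out_of_range_class_rejected(self):
        with pytest.raises(ValueError):
            LabeledSample("x", 7, None)


class TestTrainingStream:
    def _split(self, n=6):
        samples = _dummy_samples(n)
        return DatasetSplit(train=samples, validation=[], test=[])

    def test_p_flip_zero_matches_unflipped_voxelization(self, vox_cfg):
        split = self._split()
        stream = training_stream(split, vox_cfg, p_flip=0.0, seed=0)
        got = {g.source_id: g.values for g, _ in stream}
        for s in split.train:
            assert np.array_equal(got[s.structure_id],
                                  voxelize(s.source, vox_cfg).values)

    def test_p_flip_one_matches_full_flip(self, vox_cfg):
        split = self._split()
        stream = training_stream(split, vox_cfg, p_flip=1.0, seed=0)
        got = {g.source_id: g.values for g, _ in stream}
        for s in split.train:
            expected = voxelize(s.source, vox_cfg, FlipCode(1, 1, 1)).values
            assert np.array_equal(got[s.structure_id], expected)

    def test_reproducible_and_reshuffled_across_passes(self, vox_cfg):
        split = self._split()
        order = [
            [g.source_id for g, _ in training_stream(split, vox_cfg, 0.2,
                                                     seed=5, n_passes=2)]
            for _ in range(2)
        ]
        assert order[0] == order[1]  # same seed, same stream
        assert sorted(order[0][:6]) == sorted(order[0][6:])  # each pass is a permutation

    def test_labels_are_one_hot(self, vox_cfg):
        split = self._split()
        for _, y in training_stream(split, vox_cfg, 0.2, seed=1):
            assert y.sum() == 1.0
            assert set(np.unique(y)) <= {0.0, 1.0}

    def test_invalid_p_flip(self, vox_cfg):
        with pytest.raises(ValueError):
            next(training_stream(self._split(), vox_cfg, p_flip=1.5, seed=0))


def test_draw_flip_code_extremes():
    rng = np.random.default_rng(0)
    assert all(draw_flip_code(rng, 0.0) == FlipCode(0, 0, 0) for _ in range(20))
    assert all(draw_flip_code(rng, 1.0) == FlipCode(1, 1, 1) for _ in range(20))


def test_one_hot_and_class_counts():
    assert np.array_equal(one_hot(3), [0, 0, 1, 0, 0, 0])
    with pytest.raises(ValueError):
        one_hot(0)
    counts = class_counts(_dummy_samples(14))
    assert counts.sum() == 14
    assert np.array_equal(counts, [3, 3, 2, 2, 2, 2])
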