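"""Dataset container, stratified splits, manifests and table I/O."""

import numpy as np
import pytest
from PIL import Image

from erj.data_model import (
    LabeledDataset,
    SplitSpec,
    base_pool_split,
    load_embeddings,
    load_image_folder,
    load_manifest,
    save_embeddings,
    save_manifest,
    stratified_split,
)


class TestLabeledDataset:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            LabeledDataset(["a"], np.zeros((2, 3)), np.zeros(2, dtype=int), ["c"])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            LabeledDataset(
                ["a", "a"], np.zeros((2, 3)), np.zeros(2, dtype=int), ["c"]
            )

    def test_label_outside_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            LabeledDataset(["a"], np.zeros((1, 3)), np.array([2]), ["c0", "c1"])

    def test_subset_preserves_order_and_payload(self, random_feature_dataset):
        ds = random_feature_dataset(2, 5)
        sub = ds.subset(["s00003", "s00001"])
        assert sub.sample_ids == ["s00003", "s00001"]
        np.testing.assert_array_equal(sub.payload[0], ds.payload[3])


class TestStratifiedSplit:
    def test_full_scale_counts(self, random_feature_dataset):
        """6 classes x 1000 at 8:2 gives 800 train / 200 test per class."""
        ds = random_feature_dataset(6, 1000)
        train, test = stratified_split(ds, SplitSpec(seed=3))
        assert set(train.class_counts().values()) == {800}
        assert set(test.class_counts().values()) == {200}

    def test_floor_rounding_remainder_to_test(self, random_feature_dataset):
        ds = random_feature_dataset(1, 5)
        train, test = stratified_split(ds, SplitSpec(train_fraction=0.8))
        assert len(train) == 4 and len(test) == 1
        assert set(train.sample_ids) | set(test.sample_ids) == set(ds.sample_ids)
        assert not set(train.sample_ids) & set(test.sample_ids)

    def test_counts_stable_across_seeds(self, random_feature_dataset):
        ds = random_feature_dataset(1, 10)
        for seed in (0, 99):
            train, test = stratified_split(
                ds, SplitSpec(train_fraction=0.8, seed=seed)
            )
            assert (len(train), len(test)) == (8, 2)

    def test_membership_deterministic_given_seed(self, random_feature_dataset):
        ds = random_feature_dataset(3, 20)
        spec = SplitSpec(seed=42)
        t1, _ = stratified_split(ds, spec)
        t2, _ = stratified_split(ds, spec)
        assert t1.sample_ids == t2.sample_ids

    def test_partition_property_across_seeds_and_fractions(
        self, random_feature_dataset
    ):
        ds = random_feature_dataset(3, 17)
        for seed in range(5):
            for frac in (0.3, 0.5, 0.8):
                train, test = stratified_split(
                    ds, SplitSpec(train_fraction=frac, seed=seed)
                )
                assert len(train) + len(test) == len(ds)
                assert not set(train.sample_ids) & set(test.sample_ids)
                for cls, total in ds.class_counts().items():
                    got = train.class_counts()[cls]
                    assert abs(got - frac * total) < 1

    def test_tiny_class_rejected_by_name(self, random_feature_dataset):
        ds = random_feature_dataset(1, 1)
        with pytest.raises(ValueError, match="c0"):
            stratified_split(ds, SplitSpec())


class TestBasePoolSplit:
    def test_full_scale_counts(self, random_feature_dataset):
        """800 train per class at 1:9 gives 80 base / 720 pool."""
        ds = random_feature_dataset(6, 800)
        base, pool = base_pool_split(ds, SplitSpec(seed=1))
        assert set(base.class_counts().values()) == {80}
        assert set(pool.class_counts().values()) == {720}

    def test_smallest_valid_split(self, random_feature_dataset):
        ds = random_feature_dataset(1, 2)
        base, pool = base_pool_split(ds, SplitSpec(base_fraction_of_train=0.5))
        assert len(base) == 1 and len(pool) == 1

    def test_zero_base_fraction_for_class_rejected(self, random_feature_dataset):
        ds = random_feature_dataset(1, 5)
        with pytest.raises(ValueError, match="zero"):
            base_pool_split(ds, SplitSpec(base_fraction_of_train=0.1))

    def test_repeat_call_identical_membership(self, random_feature_dataset):
        ds = random_feature_dataset(2, 30)
        spec = SplitSpec(base_fraction_of_train=0.2, seed=9)
        b1, p1 = base_pool_split(ds, spec)
        b2, p2 = base_pool_split(ds, spec)
        assert b1.sample_ids == b2.sample_ids
        assert p1.sample_ids == p2.sample_ids


class TestImageFolder:
    @pytest.fixture
    def folder(self, tmp_path):
        rng = np.random.default_rng(0)
        for cls in ("ants", "bees"):
            d = tmp_path / cls
            d.mkdir()
            for i in range(2):
                arr = rng.integers(0, 255, size=(20, 24, 3), dtype=np.uint8)
                Image.fromarray(arr).save(d / f"img{i}.png")
        return tmp_path

    def test_loads_resizes_and_normalizes(self, folder):
        ds = load_image_folder(folder, resize_to=(32, 32))
        assert ds.class_names == ["ants", "bees"]
        assert ds.payload.shape == (4, 32, 32, 3)
        assert ds.payload.min() >= 0.0 and ds.payload.max() <= 1.0
        assert ds.sample_ids[0] == "ants/img0.png"

    def test_grayscale_replicated_to_three_channels(self, folder):
        gray = Image.fromarray(
            np.full((10, 10), 128, dtype=np.uint8), mode="L"
        )
        gray.save(folder / "ants" / "gray.png")
        ds = load_image_folder(folder, resize_to=(8, 8))
        row = ds.sample_ids.index("ants/gray.png")
        img = ds.payload[row]
        np.testing.assert_array_equal(img[..., 0], img[..., 1])
        np.testing.assert_array_equal(img[..., 0], img[..., 2])

    def test_undecodable_file_skipped_with_warning(self, folder, caplog):
        (folder / "ants" / "broken.png").write_bytes(b"not an image")
        with caplog.at_level("WARNING"):
            ds = load_image_folder(folder, resize_to=(8, 8))
        assert "broken.png" in caplog.text
        assert len(ds) == 4

    def test_empty_class_directory_rejected_by_name(self, folder):
        (folder / "wasps").mkdir()
        with pytest.raises(ValueError, match="wasps"):
            load_image_folder(folder, resize_to=(8, 8))


class TestManifest:
    def test_round_trip_identity(self, tmp_path):
        mapping = {"base": ["a", "b"], "pool": ["c"], "held": []}
        path = tmp_path / "m.json"
        save_manifest(mapping, path)
        assert load_manifest(path) == mapping

    def test_unknown_ids_rejected_and_listed(
        self, tmp_path, random_feature_dataset
    ):
        ds = random_feature_dataset(1, 3)
        path = tmp_path / "m.json"
        save_manifest({"base": ["s00000", "ghost"]}, path)
        with pytest.raises(KeyError, match="ghost"):
            load_manifest(path, ds)


class TestEmbeddingTables:
    @pytest.mark.parametrize("suffix", [".csv", ".tsv", ".npz"])
    def test_round_trip(self, tmp_path, suffix):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(6, 4))
        ids = [f"x{i}" for i in range(6)]
        labels = [0, 0, 1, 1, 2, 2]
        path = tmp_path / f"emb{suffix}"
        save_embeddings(path, ids, labels, values)
        ds = load_embeddings(path)
        assert ds.sample_ids == ids
        assert ds.labels.tolist() == labels
        np.testing.assert_allclose(ds.payload, values, rtol=0, atol=1e-12)
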