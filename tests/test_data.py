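"""Ingestion, augmentation recipe, splitting, and the synthetic generator."""

import os

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from msfnet.data import (
    DEFAULT_RECIPE,
    DatasetManifest,
    Record,
    SplitSpec,
    adjust_brightness,
    augment_dataset,
    generate_synthetic_dataset,
    generate_synthetic_manifest,
    hflip,
    load_image_folder,
    load_record_image,
    manifest_from_csv,
    manifest_to_csv,
    rotate180,
    split_dataset,
    synthesize_image,
    vflip,
)
from msfnet.errors import ConfigurationError, DataError, ValidationError


def _write_folder(root, classes=("a", "b"), n=3, size=8):
    rng = np.random.default_rng(0)
    for cls in classes:
        d = root / cls
        d.mkdir(parents=True)
        for i in range(n):
            img = rng.integers(0, 255, (size, size, 3), dtype=np.uint8)
            Image.fromarray(img).save(d / f"{cls}{i}.png")
    return str(root)


class TestImageFolder:
    def test_scan_is_deterministic_and_ordered(self, tmp_path):
        root = _write_folder(tmp_path)
        m1 = load_image_folder(root)
        m2 = load_image_folder(root)
        assert len(m1) == 6 and m1.classes == ("a", "b")
        assert [r.identifier for r in m1.records] == [r.identifier for r in m2.records]
        assert [r.identifier for r in m1.records] == sorted(r.identifier for r in m1.records)

    def test_corrupt_file_goes_to_exclusion_report(self, tmp_path):
        root = _write_folder(tmp_path)
        bad = tmp_path / "a" / "zz_corrupt.png"
        bad.write_bytes(b"not an image at all")
        m = load_image_folder(root)
        assert len(m) == 6
        assert len(m.exclusions) == 1
        assert m.exclusions[0][0].endswith("zz_corrupt.png")

    def test_empty_class_warns(self, tmp_path):
        root = _write_folder(tmp_path)
        (tmp_path / "c_empty").mkdir()
        with pytest.warns(UserWarning, match="no images"):
            m = load_image_folder(root)
        assert "c_empty" in m.classes

    def test_missing_root_raises(self):
        with pytest.raises(DataError):
            load_image_folder("/nonexistent/path")


class TestAugmentations:
    def test_rotate180_involution_and_2x2_instance(self, rng):
        img = rng.integers(0, 255, (6, 4, 3), dtype=np.uint8)
        np.testing.assert_array_equal(rotate180(rotate180(img)), img)
        two = np.arange(12, dtype=np.uint8).reshape(2, 2, 3)
        out = rotate180(two)
        # [[a,b],[c,d]] -> [[d,c],[b,a]] per pixel
        np.testing.assert_array_equal(out[0, 0], two[1, 1])
        np.testing.assert_array_equal(out[0, 1], two[1, 0])
        np.testing.assert_array_equal(out[1, 0], two[0, 1])
        np.testing.assert_array_equal(out[1, 1], two[0, 0])
        np.testing.assert_array_equal(rotate180(img), hflip(vflip(img)))

    def test_hflip_involution_and_row_instance(self, rng):
        img = rng.integers(0, 255, (5, 7, 3), dtype=np.uint8)
        np.testing.assert_array_equal(hflip(hflip(img)), img)
        row = np.array([[[1] * 3, [2] * 3, [3] * 3]], dtype=np.uint8)
        np.testing.assert_array_equal(hflip(row)[0, :, 0], [3, 2, 1])
        one = np.array([[[9, 9, 9]]], dtype=np.uint8)
        np.testing.assert_array_equal(rotate180(one), one)

    def test_brightness_factor_semantics(self):
        uniform = np.full((4, 4, 3), 100, dtype=np.uint8)
        np.testing.assert_array_equal(adjust_brightness(uniform, 0.7), 70)
        img = np.arange(48, dtype=np.uint8).reshape(4, 4, 3)
        np.testing.assert_array_equal(adjust_brightness(img, 1.0), img)
        sat = np.full((2, 2, 3), 255, dtype=np.uint8)
        np.testing.assert_array_equal(adjust_brightness(sat, 2.0), 255)
        with pytest.raises(ValidationError):
            adjust_brightness(img, 0.0)

    @given(
        factor=st.floats(0.1, 3.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None)
    def test_augmentations_preserve_shape_and_range(self, factor, seed):
        img = np.random.default_rng(seed).integers(0, 256, (5, 6, 3), dtype=np.uint8)
        for out in (rotate180(img), hflip(img), adjust_brightness(img, factor)):
            assert out.shape == img.shape
            assert out.dtype == np.uint8


class TestAugmentDataset:
    def _manifest(self, n=3):
        rng = np.random.default_rng(1)
        recs = tuple(
            Record(rng.integers(0, 255, (6, 6, 3), dtype=np.uint8), "a", f"a/{i}")
            for i in range(n)
        )
        return DatasetManifest(recs, ("a",))

    def test_emits_originals_plus_three_variants(self):
        out = augment_dataset(self._manifest(3))
        assert len(out) == 12
        assert [r.label for r in out.records] == ["a"] * 12
        provs = [r.provenance for r in out.records]
        assert provs.count("original") == 3
        for name, _ in DEFAULT_RECIPE:
            assert provs.count(name) == 3

    def test_per_class_cap_deterministic_truncation(self):
        out = augment_dataset(self._manifest(3), per_class_cap=10)
        assert len(out) == 10
        # originals first, then whole variant waves in recipe order
        provs = [r.provenance for r in out.records]
        assert provs[:3] == ["original"] * 3
        assert provs[3:6] == ["rotate180"] * 3
        assert provs[6:9] == ["brightness0.7"] * 3
        assert provs[9:] == ["hflip"]

    def test_variant_pixels_match_transform(self):
        m = self._manifest(1)
        out = augment_dataset(m)
        src = load_record_image(m.records[0])
        by_prov = {r.provenance: r for r in out.records}
        np.testing.assert_array_equal(load_record_image(by_prov["rotate180"]), rotate180(src))
        np.testing.assert_array_equal(load_record_image(by_prov["hflip"]), hflip(src))
        np.testing.assert_array_equal(
            load_record_image(by_prov["brightness0.7"]), adjust_brightness(src, 0.7)
        )

    def test_materialized_augmentation_writes_files(self, tmp_path):
        root = _write_folder(tmp_path / "src", classes=("a",), n=2)
        m = load_image_folder(root)
        out = augment_dataset(m, out_dir=str(tmp_path / "aug"))
        assert len(out) == 8
        for r in out.records:
            assert isinstance(r.image, str) and os.path.exists(r.image)


class TestSplitting:
    def test_ninety_ten_on_22000_records(self):
        recs = tuple(Record(f"img{i}.png", "a", str(i)) for i in range(22000))
        m = DatasetManifest(recs, ("a",))
        train, val, test = split_dataset(m, SplitSpec(ratios=(0.9, 0.0, 0.1), seed=0))
        assert (len(train), val, len(test)) == (19800, None, 2200)

    def test_eight_one_one_on_ten_records(self):
        recs = tuple(Record(f"{i}.png", "a", str(i)) for i in range(10))
        m = DatasetManifest(recs, ("a",))
        train, val, test = split_dataset(m, SplitSpec(seed=1))
        assert (len(train), len(val), len(test)) == (8, 1, 1)

    def test_stratified_apportionment_per_class(self):
        recs = []
        for c in "abcde":
            recs += [Record(f"{c}{i}.png", c, f"{c}/{i}") for i in range(100)]
        m = DatasetManifest(tuple(recs), tuple("abcde"))
        train, val, test = split_dataset(m, SplitSpec(seed=2))
        for part, expected in ((train, 80), (val, 10), (test, 10)):
            for c in "abcde":
                assert part.class_counts()[c] == expected

    @given(n=st.integers(1, 200), seed=st.integers(0, 2**16))
    @settings(max_examples=30, deadline=None)
    def test_partition_is_disjoint_and_exhaustive(self, n, seed):
        recs = tuple(Record(f"{i}.png", "a", str(i)) for i in range(n))
        m = DatasetManifest(recs, ("a",))
        parts = split_dataset(m, SplitSpec(seed=seed, stratified=False))
        ids = [r.identifier for p in parts if p is not None for r in p.records]
        assert sorted(ids) == sorted(r.identifier for r in recs)
        assert len(set(ids)) == n

    def test_deterministic_given_seed(self):
        recs = tuple(Record(f"{i}.png", "a", str(i)) for i in range(37))
        m = DatasetManifest(recs, ("a",))
        a = split_dataset(m, SplitSpec(seed=5))
        b = split_dataset(m, SplitSpec(seed=5))
        assert [r.identifier for r in a[0].records] == [r.identifier for r in b[0].records]

    def test_bad_ratios_rejected(self):
        with pytest.raises(ConfigurationError):
            SplitSpec(ratios=(0.5, 0.2, 0.2))


class TestSyntheticGenerator:
    def test_same_seed_byte_identical_folder(self, tmp_path):
        m1 = generate_synthetic_dataset(str(tmp_path / "x"), 2, (24, 24), seed=9)
        m2 = generate_synthetic_dataset(str(tmp_path / "y"), 2, (24, 24), seed=9)
        for r1, r2 in zip(m1.records, m2.records):
            assert open(r1.image, "rb").read() == open(r2.image, "rb").read()

    def test_balanced_counts_and_vocabulary(self, tmp_path):
        m = generate_synthetic_dataset(str(tmp_path / "z"), 3, (16, 16), seed=0)
        assert len(m) == 15
        assert m.classes == ("cbb", "cbsd", "cgm", "cmd", "healthy")
        assert all(v == 3 for v in m.class_counts().values())

    def test_healthy_leaves_are_green_dominant(self):
        rng = np.random.default_rng(4)
        imgs = [synthesize_image("healthy", np.random.default_rng([4, i]), (32, 32)) for i in range(8)]
        means = np.stack([im.reshape(-1, 3).mean(axis=0) for im in imgs]).mean(axis=0)
        assert means[1] > means[0]  # G > R

    def test_classes_separable_by_channel_means(self):
        """Nearest-centroid on RGB means beats chance by a wide margin."""
        m = generate_synthetic_manifest(n_per_class=50, image_size=(32, 32), seed=21)
        feats = np.stack(
            [load_record_image(r).reshape(-1, 3).mean(axis=0) for r in m.records]
        )
        y = m.labels()
        centroids = np.stack([feats[y == c].mean(axis=0) for c in range(5)])
        pred = np.argmin(
            ((feats[:, None, :] - centroids[None]) ** 2).sum(axis=2), axis=1
        )
        assert (pred == y).mean() > 0.5  # chance is 0.2

    def test_imbalanced_generation(self, tmp_path):
        m = generate_synthetic_dataset(
            str(tmp_path / "imb"), {"cbb": 4, "cbsd": 1, "cgm": 1, "cmd": 1, "healthy": 1},
            (16, 16), seed=0,
        )
        assert m.class_counts()["cbb"] == 4 and len(m) == 8


def test_manifest_csv_roundtrip(tmp_path):
    root = _write_folder(tmp_path / "d")
    m = load_image_folder(root)
    path = str(tmp_path / "manifest.csv")
    manifest_to_csv(m, path)
    back = manifest_from_csv(path)
    assert len(back) == len(m) and back.classes == m.classes
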