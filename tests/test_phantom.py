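"""Phantom generation, augmentation and dataset round-trips."""

import hashlib

import numpy as np
import pytest
from skimage.morphology import dilation as _dilate
from skimage.transform import rotate as sk_rotate

_BOX = np.ones((3, 3), bool)

from plaqueseg import (PLAQUE_CLASSES, PhantomGeometry, PhantomSpec, augment,
                       build_dataset, draw_geometry, generate_phantom,
                       load_manifest, load_sample, render_phantom)
from plaqueseg.phantom import _LEVEL, _WALL


class TestGeneratePhantom:
    def test_same_seed_is_bit_identical(self, small_spec):
        a = generate_phantom(small_spec, np.random.default_rng(7))
        b = generate_phantom(small_spec, np.random.default_rng(7))
        np.testing.assert_array_equal(a.image, b.image)
        for cls in PLAQUE_CLASSES:
            np.testing.assert_array_equal(a.masks[cls], b.masks[cls])
        assert a.case_id == b.case_id

    def test_no_sectors_gives_plain_ring(self):
        spec = PhantomSpec(image_size=64, plaque_classes=(),
                           sectors_per_class=(0, 0), noise_sigma=0.0)
        s = generate_phantom(spec, np.random.default_rng(0))
        for cls in PLAQUE_CLASSES:
            assert s.masks[cls].sum() == 0
        # the vessel wall is present: some pixels sit at the wall level
        assert (np.isclose(s.image[:, :, 0], _WALL)).sum() > 100

    def test_sector_mask_matches_polar_oracle(self):
        """60-degree calcified sector vs brute-force per-pixel polar test."""
        size = 128
        geo = PhantomGeometry(lumen_radius=0.3, wall_thickness=0.3,
                              sectors=(("calcified", 17.0, 60.0),))
        spec = PhantomSpec(image_size=size, noise_sigma=0.0)
        sample = render_phantom(geo, spec, np.random.default_rng(0))
        expected = np.zeros((size, size), np.uint8)
        c = (size - 1) / 2.0
        for i in range(size):
            for j in range(size):
                r = np.hypot(j - c, i - c) / (size / 2.0)
                ang = np.degrees(np.arctan2(i - c, j - c)) % 360.0
                if 0.3 <= r < 0.6 and (ang - 17.0) % 360.0 < 60.0:
                    expected[i, j] = 1
        np.testing.assert_array_equal(sample.masks["calcified"], expected)

    def test_class_intensity_ordering_without_noise(self):
        spec = PhantomSpec(image_size=96, noise_sigma=0.0,
                           sectors_per_class=(1, 1))
        rng = np.random.default_rng(21)
        geo = draw_geometry(spec, rng)
        s = render_phantom(geo, spec, rng)
        gray = s.image[:, :, 0]
        calcified = gray[s.masks["calcified"] == 1].mean()
        fibrous = gray[s.masks["fibrous"] == 1].mean()
        # plain-wall pixels: at the wall level, outside every plaque mask
        any_mask = np.any([s.masks[c] for c in PLAQUE_CLASSES], axis=0)
        wall = gray[np.isclose(gray, _WALL) & ~any_mask].mean()
        assert calcified < wall < fibrous

    def test_masks_of_distinct_classes_are_disjoint(self, small_spec):
        rng = np.random.default_rng(3)
        for _ in range(5):
            s = generate_phantom(small_spec, rng)
            total = sum(s.masks[c].astype(int) for c in PLAQUE_CLASSES)
            assert total.max() <= 1

    def test_impossible_geometry_rejected(self):
        spec = PhantomSpec(image_size=64,
                           wall_thickness_range=(0.01, 0.02))
        with pytest.raises(ValueError, match="wall too thin"):
            draw_geometry(spec, np.random.default_rng(0))


class TestAugment:
    @pytest.fixture
    def sample(self, small_spec):
        return generate_phantom(small_spec, np.random.default_rng(11))

    def test_rotate_zero_is_identity(self, sample):
        out = augment(sample, "rotate", angle=0.0)
        np.testing.assert_array_equal(out.image, sample.image)
        np.testing.assert_array_equal(out.masks["lipid"],
                                      sample.masks["lipid"])

    def test_flip_twice_restores_original(self, sample):
        twice = augment(augment(sample, "flip", axis="horizontal"),
                        "flip", axis="horizontal")
        np.testing.assert_array_equal(twice.image, sample.image)
        for cls in PLAQUE_CLASSES:
            np.testing.assert_array_equal(twice.masks[cls],
                                          sample.masks[cls])

    def test_quarter_turn_conserves_mask_pixel_count(self, sample):
        for angle in (90.0, 180.0, 270.0):
            out = augment(sample, "rotate", angle=angle)
            for cls in PLAQUE_CLASSES:
                assert out.masks[cls].sum() == sample.masks[cls].sum()

    def test_quarter_turn_matches_rot90_exactly(self, sample):
        out = augment(sample, "rotate", angle=90.0)
        np.testing.assert_array_equal(out.image,
                                      np.rot90(sample.image, 1, axes=(0, 1)))
        np.testing.assert_array_equal(out.masks["calcified"],
                                      np.rot90(sample.masks["calcified"]))

    def test_arbitrary_rotation_keeps_mask_image_lockstep(self, sample):
        """Independently rotated mask agrees within a 1-pixel band."""
        angle = 37.0
        out = augment(sample, "rotate", angle=angle)
        for cls in PLAQUE_CLASSES:
            oracle = sk_rotate(sample.masks[cls].astype(float), angle,
                               order=1, preserve_range=True) >= 0.5
            got = out.masks[cls].astype(bool)
            assert (got & ~_dilate(oracle, _BOX)).sum() == 0
            assert (oracle & ~_dilate(got, _BOX)).sum() == 0

    def test_noise_touches_image_only(self, sample):
        out = augment(sample, "add_noise", np.random.default_rng(0),
                      sigma=0.05)
        assert not np.array_equal(out.image, sample.image)
        assert out.image.min() >= 0.0 and out.image.max() <= 1.0
        for cls in PLAQUE_CLASSES:
            np.testing.assert_array_equal(out.masks[cls], sample.masks[cls])

    def test_metadata_updated_case_preserved(self, sample):
        out = augment(sample, "flip", axis="vertical")
        assert out.case_id == sample.case_id
        assert "flip(vertical)" in out.augmentation_tag

    def test_unknown_transform_rejected(self, sample):
        with pytest.raises(ValueError, match="unknown transform"):
            augment(sample, "shear")


class TestBuildDataset:
    def test_no_augmentation_case(self, tmp_path, small_spec):
        man = build_dataset(small_spec, 10, 10, tmp_path,
                            np.random.default_rng(5))
        assert len(man.entries) == 10
        assert all(e["tag"] == "original" for e in man.entries)

    def test_counts_and_group_keys(self, small_dataset):
        assert len(small_dataset.entries) == 40
        assert len(small_dataset.groups) == 20

    def test_round_trip_reproduces_binary_masks(self, small_dataset):
        for entry in small_dataset.entries[:5]:
            s = load_sample(small_dataset, entry)
            s.validate()
            assert s.image.shape == (64, 64, 3)

    def test_plaque_free_fraction(self, tmp_path, small_spec):
        man = build_dataset(small_spec, 10, 10, tmp_path / "pf",
                            np.random.default_rng(5),
                            plaque_free_fraction=0.2)
        n_free = sum(not any(e[f"has_{c}"] for c in PLAQUE_CLASSES)
                     for e in man.entries)
        assert n_free == 2

    def test_manifest_save_and_load(self, small_dataset, tmp_path):
        path = small_dataset.save(tmp_path / "manifest.json")
        loaded = load_manifest(path)
        assert loaded.entries == small_dataset.entries
        assert (tmp_path / "manifest.csv").exists()

    def test_same_seed_gives_identical_png_bytes(self, tmp_path, small_spec):
        def digest(root):
            h = hashlib.sha256()
            for p in sorted(root.rglob("*.png")):
                h.update(p.read_bytes())
            return h.hexdigest()
        build_dataset(small_spec, 5, 10, tmp_path / "a",
                      np.random.default_rng(13))
        build_dataset(small_spec, 5, 10, tmp_path / "b",
                      np.random.default_rng(13))
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_augmented_below_originals_rejected(self, tmp_path, small_spec):
        with pytest.raises(ValueError):
            build_dataset(small_spec, 10, 5, tmp_path,
                          np.random.default_rng(0))
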