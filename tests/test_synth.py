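"""Synthetic scene generator: determinism, annotation rules, noise
statistics and dataset apportionment."""

import numpy as np
import pytest

from vegdet import synth
from vegdet.data import read_yolo_labels


def small_cfg(**kw):
    return synth.GeneratorConfig(image_size=128, **kw)


class TestGenerateScene:
    def test_same_spec_is_byte_identical(self):
        spec = synth.sample_scene(7, seed=11, cfg=small_cfg())
        img1, b1 = synth.generate_scene(spec)
        img2, b2 = synth.generate_scene(spec)
        assert np.array_equal(img1, img2)
        assert b1 == b2

    def test_lesion_free_leaf_gets_one_healthy_box(self):
        spec = synth.SceneSpec(
            image_size=128, crop=1,
            leaves=[synth.Leaf((64, 64), (30, 20), 15.0, (50, 120, 50))],
            lesions=[], illumination=synth.IlluminationSpec(),
            noise=synth.NoiseSpec(), seed=0)
        _, boxes = synth.generate_scene(spec)
        assert len(boxes) == 1
        assert boxes[0].class_id == 5      # cucumber healthy

    def test_small_radius_bound_gives_sub20px_boxes(self):
        cfg = small_cfg(lesion_radius_range=(3.0, 9.0), small_fraction=1.0,
                        small_radius_max=9.0)
        for seed in range(5):
            spec = synth.sample_scene(2, seed=seed, cfg=cfg)
            _, boxes = synth.generate_scene(spec)
            for b in boxes:
                if b.class_id % 5 != 0:    # disease boxes only
                    assert b.w * 128 < 20 and b.h * 128 < 20

    def test_lesion_outside_leaf_rejected(self):
        spec = synth.SceneSpec(
            image_size=128, crop=0,
            leaves=[synth.Leaf((40, 40), (20, 12), 0.0, (60, 120, 50))],
            lesions=[synth.Lesion(0, 1, (120, 120), 4.0)],
            illumination=synth.IlluminationSpec(),
            noise=synth.NoiseSpec(), seed=0)
        with pytest.raises(synth.SceneError, match="outside"):
            synth.generate_scene(spec)

    def test_boxes_inside_unit_square(self):
        for seed in range(8):
            spec = synth.sample_scene(seed % 15, seed=seed, cfg=small_cfg())
            _, boxes = synth.generate_scene(spec)
            for b in boxes:
                assert 0 <= b.cx - b.w / 2 + 1e-9
                assert b.cx + b.w / 2 <= 1 + 1e-9
                assert 0 <= b.cy - b.h / 2 + 1e-9
                assert b.cy + b.h / 2 <= 1 + 1e-9


class TestIllumination:
    def test_zero_strength_identity(self, rng):
        img = (rng.random((32, 32, 3)) * 255).astype(np.uint8)
        out = synth.apply_illumination(img, synth.IlluminationSpec())
        assert np.array_equal(out, img)

    def test_gradient_monotone_along_direction(self):
        img = np.full((64, 64, 3), 128, np.uint8)
        means = []
        for strength in (0.0, 0.2, 0.4):
            out = synth.apply_illumination(
                img, synth.IlluminationSpec(direction=0.0,
                                            strength=strength))
            left = out[:, :32].mean()
            right = out[:, 32:].mean()
            means.append(right - left)
        assert means[0] == pytest.approx(0.0)
        assert means[0] < means[1] < means[2]

    def test_output_clipped(self):
        img = np.full((32, 32, 3), 240, np.uint8)
        spec = synth.IlluminationSpec(strength=0.5,
                                      spots=[(16, 16, 8, 1.0)])
        out = synth.apply_illumination(img, spec)
        assert out.max() <= 255 and out.min() >= 0


class TestNoise:
    def test_gaussian_zero_sigma_identity(self, rng):
        img = (rng.random((16, 16, 3)) * 255).astype(np.uint8)
        assert np.array_equal(synth.add_gaussian_noise(img, 0.0, 1), img)

    def test_gaussian_std_matches_parameter(self):
        img = np.full((512, 512, 3), 128, np.uint8)
        sigma = 0.2
        noisy = synth.add_gaussian_noise(img, sigma, seed=3)
        emp = (noisy.astype(float) - 128).std() / 255
        assert emp == pytest.approx(sigma, rel=0.02)

    def test_gaussian_different_seeds_differ(self):
        img = np.full((32, 32, 3), 128, np.uint8)
        a = synth.add_gaussian_noise(img, 0.1, 1)
        b = synth.add_gaussian_noise(img, 0.1, 2)
        assert not np.array_equal(a, b)

    def test_salt_pepper_density(self):
        img = np.full((200, 200, 3), 128, np.uint8)
        out = synth.add_salt_pepper(img, 0.05, seed=5)
        frac = ((out == 0) | (out == 255)).all(axis=2).mean()
        assert 0.04 <= frac <= 0.06

    def test_salt_pepper_extremes(self):
        img = np.full((32, 32, 3), 128, np.uint8)
        assert np.array_equal(synth.add_salt_pepper(img, 0.0, 1), img)
        out = synth.add_salt_pepper(img, 1.0, 1)
        assert np.all((out == 0) | (out == 255))


class TestDataset:
    def test_apportionment_examples(self):
        assert synth.apportion(150, (7, 2, 1)) == [105, 30, 15]
        assert synth.apportion(15000, (7, 2, 1)) == [10500, 3000, 1500]
        assert synth.apportion(1000, (7, 2, 1)) == [700, 200, 100]

    def test_default_class_list_has_15(self):
        assert len(synth.CLASS_NAMES) == 15

    def test_dataset_on_disk(self, tmp_path):
        desc = synth.generate_dataset(
            30, tmp_path / "ds", class_ids=list(range(5)), seed=4,
            cfg=small_cfg(), names=synth.CLASS_NAMES[:5])
        counts = {sp: len(desc.items(sp)) for sp in ("train", "val", "test")}
        assert counts == {"train": 21, "val": 6, "test": 3}
        # per-class balance within each split differs by <= 1
        for sp in counts:
            per = {}
            for img, _ in desc.items(sp):
                cid = int(img.stem.split("_c")[-1])
                per[cid] = per.get(cid, 0) + 1
            assert max(per.values()) - min(per.values()) <= 1
        # labels round-trip and lie in range
        for img, lab in desc.items("train"):
            for b in read_yolo_labels(lab, nc=15):
                assert 0 <= b.cx <= 1

    def test_regeneration_is_byte_identical(self, tmp_path):
        a = synth.generate_dataset(10, tmp_path / "a", seed=9,
                                   cfg=small_cfg())
        b = synth.generate_dataset(10, tmp_path / "b", seed=9,
                                   cfg=small_cfg())
        for (ia, la), (ib, lb) in zip(a.items("train"), b.items("train")):
            assert la.read_bytes() == lb.read_bytes()
            assert ia.read_bytes() == ib.read_bytes()

    def test_bad_ratio_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="positive"):
            synth.generate_dataset(10, tmp_path, ratio=(7, 0, 1))
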