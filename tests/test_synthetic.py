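"""Synthetic bimodal generator: determinism, class balance, effect-size
behaviour, augmentation statistics, splitting laws and the disk round trip."""

import numpy as np
import pytest

from modnet import (AugmentSpec, BimodalSample, SyntheticSpec, ValidationError,
                    augment, flip, generate_dataset, read_real_dataset,
                    save_dataset, split)


class TestGeneration:
    def test_same_seed_is_bitwise_identical(self):
        spec = SyntheticSpec(n_groups=10, height=16, width=16, n_slices=2, seed=5)
        a = generate_dataset(spec)
        b = generate_dataset(spec)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.image, sb.image)
            assert np.array_equal(sa.volume, sb.volume)
            assert sa.label == sb.label and sa.sample_id == sb.sample_id

    def test_different_seeds_differ(self):
        s1 = generate_dataset(SyntheticSpec(n_groups=4, height=16, width=16,
                                            n_slices=2, seed=1))
        s2 = generate_dataset(SyntheticSpec(n_groups=4, height=16, width=16,
                                            n_slices=2, seed=2))
        assert not np.array_equal(s1[0].image, s2[0].image)

    def test_shapes_and_value_range(self, tiny_dataset):
        for s in tiny_dataset:
            s.validate()
            assert s.image.shape == (1, 16, 16)
            assert s.volume.shape == (2, 16, 16)
            assert 0.0 <= s.image.min() and s.image.max() <= 1.0
            assert 0.0 <= s.volume.min() and s.volume.max() <= 1.0
            assert s.label in (0, 1, 2)

    def test_majority_class_frequency_at_n_1000(self):
        """Class 0 has probability 0.5; at n=1000 its count should land inside
        a generous (≈2.6 sigma) binomial window."""
        spec = SyntheticSpec(n_groups=1000, height=8, width=8, n_slices=1, seed=17)
        labels = [s.label for s in generate_dataset(spec)]
        n0 = labels.count(0)
        assert 459 <= n0 <= 541
        assert set(labels) == {0, 1, 2}

    def test_intensity_cue_monotone_in_class_at_effect_one(self):
        spec = SyntheticSpec(n_groups=150, height=32, width=32, n_slices=2,
                             seed=23, effect_size=1.0)
        data = generate_dataset(spec)
        means = [np.mean([s.image.mean() for s in data if s.label == k])
                 for k in range(3)]
        assert means[0] < means[1] < means[2]

    def test_zero_effect_size_removes_class_cues(self):
        spec = SyntheticSpec(n_groups=150, height=32, width=32, n_slices=2,
                             seed=23, effect_size=0.0)
        data = generate_dataset(spec)
        means = [np.mean([s.image.mean() for s in data if s.label == k])
                 for k in range(3)]
        assert max(means) - min(means) < 0.02

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticSpec(n_classes=3, class_probs=(0.5, 0.5))
        with pytest.raises(ValidationError):
            SyntheticSpec(class_probs=(0.6, 0.25, 0.25))
        with pytest.raises(ValidationError):
            SyntheticSpec(class_probs=(-0.1, 0.85, 0.25))

    def test_spec_dict_round_trip(self):
        spec = SyntheticSpec(n_groups=7, seed=9, effect_size=0.5)
        assert SyntheticSpec.from_dict(spec.to_dict()) == spec


class TestAugmentation:
    def test_noise_statistics_over_1000_draws(self):
        """At p_noise=0.6 the noise branch fires 600 +- 40 times in 1,000
        draws, and every drawn variance lies inside [0.01, 0.05]."""
        spec = AugmentSpec(crop=False, flip=False, rotate=False)
        sample = BimodalSample(image=np.full((1, 8, 8), 0.5),
                               volume=np.full((2, 8, 8), 0.5), label=0)
        rng = np.random.default_rng(123)
        applied, variances = 0, []
        for _ in range(1000):
            info = {}
            augment(sample, spec, rng, info=info)
            if info["noise_applied"]:
                applied += 1
                variances.append(info["noise_var"])
        assert 560 <= applied <= 640
        assert all(0.01 <= v <= 0.05 for v in variances)

    def test_noop_augmentation_is_identity(self):
        spec = AugmentSpec(p_noise=0.0, crop=False, flip=False, rotate=False)
        sample = BimodalSample(image=np.random.default_rng(0).random((1, 8, 8)),
                               volume=np.random.default_rng(1).random((2, 8, 8)),
                               label=1)
        out = augment(sample, spec, np.random.default_rng(2))
        assert np.allclose(out.image, sample.image)
        assert np.allclose(out.volume, sample.volume)
        assert out.label == sample.label

    def test_output_stays_in_unit_interval(self, tiny_dataset):
        spec = AugmentSpec()
        rng = np.random.default_rng(7)
        for s in tiny_dataset[:5]:
            out = augment(s, spec, rng)
            assert out.image.min() >= 0.0 and out.image.max() <= 1.0
            assert out.volume.min() >= 0.0 and out.volume.max() <= 1.0
            assert out.image.shape == s.image.shape
            assert out.volume.shape == s.volume.shape

    def test_flip_is_an_involution(self, tiny_dataset):
        s = tiny_dataset[0]
        for axis in ("horizontal", "vertical"):
            twice = flip(flip(s, axis), axis)
            assert np.array_equal(twice.image, s.image)
            assert np.array_equal(twice.volume, s.volume)

    def test_invalid_augment_specs_rejected(self):
        with pytest.raises(ValidationError):
            AugmentSpec(p_noise=1.5)
        with pytest.raises(ValidationError):
            AugmentSpec(noise_var_range=(0.05, 0.01))
        with pytest.raises(ValidationError):
            AugmentSpec(noise_var_range=(0.0, 0.05))


class TestSplit:
    def _dataset(self, n=100, seed=31):
        return generate_dataset(SyntheticSpec(n_groups=n, height=8, width=8,
                                              n_slices=1, seed=seed))

    def test_100_samples_give_64_16_20(self):
        tr, va, te = split(self._dataset(100), seed=0)
        assert (len(tr), len(va), len(te)) == (64, 16, 20)

    def test_partition_is_disjoint_and_exhaustive(self):
        data = self._dataset(100)
        tr, va, te = split(data, seed=4)
        ids = [s.sample_id for part in (tr, va, te) for s in part]
        assert len(ids) == len(set(ids)) == len(data)
        assert set(ids) == {s.sample_id for s in data}

    def test_deterministic_per_seed_and_varies_across_seeds(self):
        data = self._dataset(60)
        a = split(data, seed=2)
        b = split(data, seed=2)
        c = split(data, seed=3)
        assert [s.sample_id for s in a[2]] == [s.sample_id for s in b[2]]
        assert [s.sample_id for s in a[2]] != [s.sample_id for s in c[2]]

    def test_stratification_roughly_preserves_class_shares(self):
        data = self._dataset(200, seed=8)
        tr, va, te = split(data, seed=1)
        overall = np.bincount([s.label for s in data], minlength=3) / len(data)
        for part in (tr, te):
            share = np.bincount([s.label for s in part], minlength=3) / len(part)
            assert np.abs(share - overall).max() < 0.06

    def test_too_small_dataset_rejected_and_rare_class_warns(self):
        with pytest.raises(ValidationError):
            split(self._dataset(100)[:4], seed=0)
        rare = self._dataset(100)[:12]
        for s in rare[:2]:
            s.label = 2  # force a thin class
        with pytest.warns(UserWarning):
            split(rare, seed=0)


class TestDiskRoundTrip:
    def test_save_and_reload_within_quantisation(self, tmp_path, tiny_dataset):
        subset = tiny_dataset[:4]
        spec = SyntheticSpec(n_groups=4, height=16, width=16, n_slices=2, seed=3)
        manifest = save_dataset(subset, str(tmp_path), spec=spec)
        loaded = read_real_dataset(str(tmp_path))
        assert len(loaded) == 4
        for orig, back in zip(subset, loaded):
            assert back.label == orig.label
            assert back.sample_id == orig.sample_id
            assert np.abs(back.image - orig.image).max() <= 1.0 / 255 + 1e-9
            assert np.abs(back.volume - orig.volume).max() <= 1.0 / 255 + 1e-9
        assert manifest.endswith("manifest.csv")
        assert (tmp_path / "spec.json").exists()

    def test_resize_on_load(self, tmp_path, tiny_dataset):
        save_dataset(tiny_dataset[:2], str(tmp_path))
        loaded = read_real_dataset(str(tmp_path), size=(8, 8))
        assert loaded[0].image.shape == (1, 8, 8)
        assert loaded[0].volume.shape[1:] == (8, 8)

    def test_missing_manifest_and_missing_image_error_with_path(self, tmp_path):
        with pytest.raises(ValidationError, match="manifest"):
            read_real_dataset(str(tmp_path / "nowhere"))
        (tmp_path / "manifest.csv").write_text(
            "sample_id,image,volume_dir,label\ns0,s0/image.png,s0/vol,0\n")
        with pytest.raises(ValidationError, match="s0/image.png"):
            read_real_dataset(str(tmp_path))
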