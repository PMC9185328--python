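import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from troposearch.preprocessing import (
    Augmenter,
    DatasetBundle,
    build_augmenter,
    clean_dataset,
    compute_snr,
    encode_categories,
    load_image_tree,
    resize_to_input,
    scale,
    split_dataset,
)
from troposearch.search_space import build_default_space, map_solution
from troposearch.synthetic import SyntheticSpec, generate, write_image_tree


def _img(values):
    return np.asarray(values, dtype=float).reshape(-1, 1, 1)


class TestScaling:
    def test_normalize_divides_by_max(self):
        assert np.allclose(scale(_img([0, 2, 4]), "normalize").ravel(), [0, 0.5, 1])

    def test_minmax_maps_endpoints_to_unit_interval(self):
        assert np.allclose(scale(_img([2, 4]), "minmax").ravel(), [0, 1])

    def test_standardize_yields_zero_mean_unit_std(self, rng):
        img = rng.random((64, 64, 1))
        out = scale(img, "standard")
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, derandomize=True)
    def test_output_invariants_for_random_images(self, seed):
        img = np.random.default_rng(seed).random((8, 8, 1)) + 0.01
        assert scale(img, "normalize").max() == pytest.approx(1.0, abs=1e-9)
        mm = scale(img, "minmax")
        assert mm.min() == pytest.approx(0.0, abs=1e-9)
        assert mm.max() == pytest.approx(1.0, abs=1e-9)
        ma = scale(img, "maxabs")
        assert -1.0 - 1e-9 <= ma.min() and ma.max() <= 1.0 + 1e-9
        sd = scale(img, "standard")
        assert abs(sd.mean()) < 1e-9 and abs(sd.std() - 1.0) < 1e-9

    def test_table_aliases_accepted(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        assert np.allclose(scale(img, "Min-Max"), scale(img, "minmax"))
        assert np.allclose(scale(img, "Standard"), scale(img, "standardize"))

    @pytest.mark.parametrize(
        "img,tech",
        [
            (_img([0, 0, 0]), "normalize"),
            (_img([5, 5, 5]), "standard"),
            (_img([3, 3]), "minmax"),
            (_img([0, 0]), "maxabs"),
        ],
    )
    def test_degenerate_inputs_raise(self, img, tech):
        with pytest.raises(ValueError):
            scale(img, tech)

    def test_unknown_technique_rejected(self):
        with pytest.raises(ValueError):
            scale(_img([1, 2]), "robust")


class TestResize:
    def test_target_shape_reached_from_grayscale(self, rng):
        out = resize_to_input(rng.random((256, 256, 1)))
        assert out.shape == (128, 128, 3)

    def test_identity_size_preserves_shape(self, rng):
        out = resize_to_input(rng.random((128, 128, 3)))
        assert out.shape == (128, 128, 3)

    def test_constant_image_stays_constant(self):
        out = resize_to_input(np.full((200, 100, 1), 0.7))
        assert np.allclose(out, 0.7)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            resize_to_input(np.empty((0, 10)))


class TestSNR:
    def test_constant_image_has_infinite_snr(self):
        assert compute_snr(np.full((5, 5, 1), 0.4)) == np.inf

    def test_constructed_ratio(self):
        img = _img([1.15 - 1.0, 1.15 + 1.0])  # mean 1.15, std 1.0
        assert compute_snr(img) == pytest.approx(1.15)

    def test_symmetric_noise_is_flagged_below_threshold(self):
        img = np.random.default_rng(0).normal(0.5, 0.5, (64, 64, 1))
        assert compute_snr(img) < 1.15


class TestCleaning:
    def test_constant_images_all_retained(self):
        bundle = DatasetBundle(
            images=[np.full((4, 4, 1), v) for v in (0.2, 0.5, 0.9)],
            labels=[0, 0, 0], class_names=["a"],
        )
        kept, removed = clean_dataset(bundle)
        assert removed == 0 and len(kept) == 3

    def test_removes_exactly_the_injected_noisy_images(self):
        bundle, manifest = generate(
            SyntheticSpec(K=4, n_per_class=25, noisy_fraction=0.1, seed=3)
        )
        kept, removed = clean_dataset(bundle, 1.15)
        assert removed == int(manifest.noisy.sum()) == 10
        kept_names = set(kept.paths)
        assert kept_names == set(manifest.loc[~manifest.noisy, "filename"])

    def test_zero_threshold_is_vacuous(self):
        bundle, _ = generate(SyntheticSpec(K=2, n_per_class=5, noisy_fraction=0.4, seed=0))
        kept, removed = clean_dataset(bundle, threshold=0.0)
        assert removed == 0 and len(kept) == len(bundle)

    def test_idempotent(self):
        bundle, _ = generate(SyntheticSpec(K=2, n_per_class=10, noisy_fraction=0.2, seed=5))
        once, r1 = clean_dataset(bundle)
        twice, r2 = clean_dataset(once)
        assert r2 == 0
        assert [np.array_equal(a, b) for a, b in zip(once.images, twice.images)]

    def test_all_noise_warns_instead_of_failing(self):
        noisy = np.random.default_rng(0).normal(0.0, 1.0, (8, 8, 1))
        bundle = DatasetBundle(images=[noisy], labels=[0], class_names=["a"])
        with pytest.warns(UserWarning):
            kept, removed = clean_dataset(bundle, threshold=5.0)
        assert removed == 1 and len(kept) == 0


class TestEncoding:
    def test_adni_style_ordering(self):
        assert encode_categories(["NC", "MCI", "AD"]) == {"NC": 0, "MCI": 1, "AD": 2}

    def test_single_class(self):
        assert encode_categories(["only"]) == {"only": 0}

    def test_four_classes_get_consecutive_codes(self):
        codes = encode_categories(["a", "b", "c", "d"])
        assert sorted(codes.values()) == [0, 1, 2, 3]

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            encode_categories(["x", "x"])


class TestSplitting:
    @staticmethod
    def _bundle(counts, seed=0):
        gen = np.random.default_rng(seed)
        images, labels = [], []
        for c, n in enumerate(counts):
            for _ in range(n):
                images.append(gen.random((4, 4, 1)))
                labels.append(c)
        return DatasetBundle(images=images, labels=labels,
                             class_names=[f"c{i}" for i in range(len(counts))])

    def test_fifteen_percent_test_share(self):
        bundle = split_dataset(self._bundle([100] * 4), seed=0)
        assert int((bundle.split == "test").sum()) == 60
        for c in range(4):
            assert int(((bundle.split == "test") & (bundle.labels == c)).sum()) == 15

    def test_partition_covers_every_image_once(self):
        bundle = split_dataset(self._bundle([40, 60, 30]), seed=1)
        assert set(bundle.split) <= {"train", "validation", "test"}
        assert len(bundle.split) == len(bundle)

    def test_same_seed_reproduces_assignment(self):
        a = split_dataset(self._bundle([30, 30]), seed=7).split
        b = split_dataset(self._bundle([30, 30]), seed=7).split
        assert np.array_equal(a, b)

    def test_stratification_within_one_image_for_unbalanced_classes(self):
        counts = [37, 81, 52]
        bundle = split_dataset(self._bundle(counts), test_fraction=0.15, seed=2)
        for c, n in enumerate(counts):
            got = int(((bundle.split == "test") & (bundle.labels == c)).sum())
            assert abs(got - 0.15 * n) <= 1

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._bundle([1, 50]), seed=0)


class TestAugmenter:
    def test_identity_configuration_is_pixel_exact(self, rng):
        aug = Augmenter(brightness_range=(1.0, 1.0), seed=0)
        img = rng.random((16, 16, 1))
        assert np.array_equal(aug(img), img)

    def test_disabled_augmenter_passes_through(self, rng):
        sol = np.zeros(16)
        sol[6] = 0.9  # augmentation off
        cfg = map_solution(sol, build_default_space())
        aug = build_augmenter(cfg, seed=0)
        img = rng.random((16, 16, 1))
        assert np.array_equal(aug(img), img)

    def test_balancing_equalizes_class_counts(self, rng):
        images = [rng.random((8, 8, 1)) for _ in range(150)]
        labels = np.array([0] * 50 + [1] * 100)
        aug = Augmenter(rotation_deg=5, seed=1)
        _, out_labels = aug.balanced_epoch(images, labels)
        assert np.bincount(out_labels).tolist() == [100, 100]

    def test_sampled_rotation_angles_respect_the_configured_bound(self):
        aug = Augmenter(rotation_deg=13, seed=3)
        angles = [aug.sample_params()["angle"] for _ in range(1000)]
        assert all(-13 <= a <= 13 for a in angles)
        assert max(angles) > 6 and min(angles) < -6  # the range is exercised

    def test_brightness_sampled_within_the_configured_pair(self):
        aug = Augmenter(brightness_range=(0.54, 0.8), seed=4)
        factors = [aug.sample_params()["brightness"] for _ in range(500)]
        assert all(0.54 <= f <= 0.8 for f in factors)


class TestImageTreeReader:
    def test_round_trip_through_png_tree(self, tmp_path):
        bundle, _ = generate(SyntheticSpec(K=3, n_per_class=4, seed=2))
        write_image_tree(bundle, tmp_path / "tree")
        loaded = load_image_tree(tmp_path / "tree")
        assert loaded.class_names == bundle.class_names
        assert np.array_equal(loaded.labels, bundle.labels)
        for a, b in zip(loaded.images, bundle.images):
            assert np.allclose(a, b, atol=1e-12)

    def test_missing_directory_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_image_tree(tmp_path / "nope")
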