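"""Generator, Gaussian degradation and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifmtl import (
    BlurSpec,
    LABELS,
    SynthSpec,
    ValidationError,
    blur_dataset,
    gaussian_blur,
    generate_dataset,
    split_dataset,
)
from ifmtl.case import IFCase, N_STAINS
from ifmtl.synthetic import gaussian_kernel_2d
from ifmtl.reference_tables import COHORT_COUNTS, TEST_COUNTS


def brute_force_blur(channels: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct double-loop 2-D convolution with reflect padding (oracle)."""
    k = kernel.shape[0]
    r = k // 2
    out = np.zeros_like(channels, dtype=np.float64)
    for c in range(channels.shape[0]):
        # edge-including reflection (np.pad "symmetric" == ndimage "reflect")
        img = np.pad(channels[c].astype(np.float64), r, mode="symmetric")
        for i in range(channels.shape[1]):
            for j in range(channels.shape[2]):
                out[c, i, j] = np.sum(img[i : i + k, j : j + k] * kernel)
    return np.clip(out, 0.0, 1.0)


class TestGenerateDataset:
    def test_balanced_counts_and_labels(self, small_dataset):
        assert len(small_dataset) == 20
        for label in LABELS:
            assert sum(c.label == label for c in small_dataset) == 5

    def test_seeded_determinism(self):
        spec = SynthSpec(n_per_class=3, image_size=32, seed=11)
        a = generate_dataset(spec)
        b = generate_dataset(SynthSpec(n_per_class=3, image_size=32, seed=11))
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.channels, cb.channels)
            np.testing.assert_array_equal(ca.deposit_mask, cb.deposit_mask)

    def test_case_invariants(self, small_dataset):
        for c in small_dataset:
            c.validate()
            assert c.channels.shape[0] == N_STAINS
            assert c.quality_gt == 1

    def test_deposit_masks_nonempty(self, small_dataset):
        for c in small_dataset:
            if c.label in ("IgAN", "MN", "LN"):
                assert c.deposit_mask.sum() > 0

    def test_full_house_all_stains_positive_in_mask(self):
        """LN with all stains positive: in-mask mean exceeds out-of-mask
        mean in every one of the seven channels."""
        spec = SynthSpec(
            n_per_class=4,
            image_size=48,
            seed=5,
            stain_gains={"LN": (0.9, 0.8, 0.8, 0.9, 0.8, 0.85, 0.75)},
        )
        for case in generate_dataset(spec):
            if case.label != "LN":
                continue
            m = case.deposit_mask
            inside = case.channels[:, m].mean(axis=1)
            outside = case.channels[:, ~m].mean(axis=1)
            assert np.all(inside > outside)

    def test_channel_mean_classifier_beats_chance(self, small_dataset):
        """The class-conditional stain profiles alone already carry signal:
        a nearest-centroid rule on the 7 channel means beats 0.25."""
        from sklearn.neighbors import NearestCentroid

        train, test = split_dataset(small_dataset, 0.8, seed=3)
        Xtr = np.array([c.channels.mean(axis=(1, 2)) for c in train])
        Xte = np.array([c.channels.mean(axis=(1, 2)) for c in test])
        model = NearestCentroid().fit(Xtr, [c.label for c in train])
        acc = np.mean(model.predict(Xte) == np.array([c.label for c in test]))
        assert acc > 0.25

    @pytest.mark.parametrize(
        "field,value", [("n_per_class", 0), ("image_size", 8), ("noise_sd", -0.1)]
    )
    def test_invalid_spec_names_field(self, field, value):
        with pytest.raises(ValidationError, match=field):
            generate_dataset(SynthSpec(**{field: value}))


class TestGaussianBlur:
    def test_sigma_zero_is_identity(self, small_dataset):
        case = small_dataset[0]
        out = gaussian_blur(case, BlurSpec(sigma=0.0))
        np.testing.assert_array_equal(out.channels, case.channels)
        assert out.quality_gt == 0
        assert out.label == case.label

    def test_constant_image_preserved(self):
        case = IFCase("const", np.full((7, 24, 24), 0.5, np.float32), "IgAN")
        out = gaussian_blur(case, BlurSpec(sigma=2.5))
        np.testing.assert_allclose(out.channels, 0.5, atol=1e-6)

    def test_impulse_response_equals_kernel(self):
        """A centered unit impulse maps to the explicit normalized kernel."""
        blur = BlurSpec(sigma=1.5)
        k2 = gaussian_kernel_2d(blur)
        r = k2.shape[0] // 2
        size = 2 * k2.shape[0] + 1
        channels = np.zeros((7, size, size), np.float32)
        channels[:, size // 2, size // 2] = 1.0
        out = gaussian_blur(IFCase("imp", channels, "MN"), blur)
        lo, hi = size // 2 - r, size // 2 + r + 1
        for c in range(7):
            np.testing.assert_allclose(out.channels[c, lo:hi, lo:hi], k2, atol=1e-6)

    def test_matches_brute_force_convolution(self, rng):
        """Separable implementation == direct double-loop 2-D oracle, 8x8."""
        channels = rng.random((7, 8, 8)).astype(np.float32)
        blur = BlurSpec(sigma=1.2)
        out = gaussian_blur(IFCase("x", channels, "DN"), blur)
        oracle = brute_force_blur(channels, gaussian_kernel_2d(blur))
        np.testing.assert_allclose(out.channels, oracle, atol=1e-6)

    def test_blur_reduces_total_variation(self, small_dataset):
        for case in small_dataset[:4]:
            out = gaussian_blur(case, BlurSpec(sigma=2.0))
            tv = lambda x: np.abs(np.diff(x, axis=1)).sum() + np.abs(
                np.diff(x, axis=2)
            ).sum()
            assert tv(out.channels) < tv(case.channels)

    def test_negative_sigma_rejected(self, small_dataset):
        with pytest.raises(ValidationError, match="sigma"):
            gaussian_blur(small_dataset[0], BlurSpec(sigma=-1.0))

    @settings(max_examples=20, deadline=None)
    @given(sigma=st.floats(0.3, 4.0))
    def test_constant_mean_preserved_any_sigma(self, sigma):
        case = IFCase("c", np.full((7, 20, 20), 0.25, np.float32), "LN")
        out = gaussian_blur(case, BlurSpec(sigma=sigma))
        assert abs(float(out.channels.mean()) - 0.25) < 1e-6

    def test_blur_dataset_per_case_sigma_deterministic(self, small_dataset):
        a = blur_dataset(small_dataset[:4], (1.0, 3.0), seed=9)
        b = blur_dataset(small_dataset[:4], (1.0, 3.0), seed=9)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.channels, cb.channels)
            assert ca.quality_gt == 0


class TestSplitDataset:
    def test_ratio_arithmetic(self, small_dataset):
        train, test = split_dataset(small_dataset, 0.8, seed=0)
        assert len(train) == 16 and len(test) == 4
        for label in LABELS:
            assert sum(c.label == label for c in test) == 1

    def test_partition_property(self, small_dataset):
        train, test = split_dataset(small_dataset, 0.8, seed=1)
        ids_train = {c.case_id for c in train}
        ids_test = {c.case_id for c in test}
        assert ids_train | ids_test == {c.case_id for c in small_dataset}
        assert ids_train & ids_test == set()

    def test_deterministic_given_seed(self, small_dataset):
        t1 = split_dataset(small_dataset, 0.8, seed=2)
        t2 = split_dataset(small_dataset, 0.8, seed=2)
        assert [c.case_id for c in t1[0]] == [c.case_id for c in t2[0]]

    def test_reference_cohort_bookkeeping(self):
        """With the documented per-class test-count override, the historical
        655/348/201/404 cohort recomposes to 1289 train / 319 test exactly."""
        cases = []
        for label, (total, _, _) in COHORT_COUNTS.items():
            for i in range(total):
                cases.append(
                    IFCase(f"{label}_{i}", np.zeros((7, 16, 16), np.float32), label)
                )
        train, test = split_dataset(cases, 0.8, seed=0, test_counts=TEST_COUNTS)
        assert len(train) == 1289 and len(test) == 319
        for label, (total, n_train, n_test) in COHORT_COUNTS.items():
            assert sum(c.label == label for c in train) == n_train
            assert sum(c.label == label for c in test) == n_test

    def test_small_class_rejected(self):
        cases = [IFCase("a", np.zeros((7, 16, 16), np.float32), "IgAN")]
        with pytest.raises(ValidationError, match="IgAN"):
            split_dataset(cases, 0.8, seed=0)
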