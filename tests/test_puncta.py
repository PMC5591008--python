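"""Unit and property tests for puncta segmentation and volumetry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmjkit.puncta import (
    DegenerateHistogramError,
    label_and_measure,
    max_entropy_threshold,
    median_denoise,
    quantify,
    segment_local_max_entropy,
)
from nmjkit.stack import ImageStack

from _oracles import brute_force_max_entropy, naive_local_segmentation
from conftest import random_stack


# ------------------------------------------------------------ median filter

class TestMedianDenoise:
    def test_constant_stack_unchanged(self, flat_stack):
        out = median_denoise(flat_stack, kernel=3)
        np.testing.assert_array_equal(out.voxels, flat_stack.voxels)
        assert out.spacing == flat_stack.spacing

    def test_salt_voxel_removed(self):
        vox = np.zeros((1, 9, 9), dtype=np.uint8)
        vox[0, 4, 4] = 255
        stack = ImageStack(vox, spacing=(0.25, 0.1, 0.1))
        assert median_denoise(stack, kernel=3).voxels[0, 4, 4] == 0

    def test_kernel_one_is_identity(self, small_puncta):
        stack, _ = small_puncta
        out = median_denoise(stack, kernel=1)
        np.testing.assert_array_equal(out.voxels, stack.voxels)

    def test_filtering_is_per_slice(self):
        # a bright plane in z must not bleed into neighbouring slices
        vox = np.zeros((3, 9, 9), dtype=np.uint8)
        vox[1] = 100
        stack = ImageStack(vox, spacing=(0.25, 0.1, 0.1))
        out = median_denoise(stack, kernel=3).voxels
        assert out[0].max() == 0 and out[2].max() == 0 and out[1].min() == 100

    @pytest.mark.parametrize("kernel", [0, 2, 4])
    def test_even_or_zero_kernel_rejected(self, flat_stack, kernel):
        with pytest.raises(ValueError):
            median_denoise(flat_stack, kernel=kernel)


# ------------------------------------------------------- entropy threshold

class TestMaxEntropyThreshold:
    def test_uniform_histogram_midpoint(self):
        # argmax of ln(t+1) + ln(255-t) sits at the midpoint
        assert max_entropy_threshold(np.ones(256, dtype=int)) == 127

    def test_two_equal_spikes_tie_to_smallest(self):
        hist = np.zeros(256, dtype=int)
        hist[10] = 7
        hist[200] = 7
        # every t in [10, 199] scores H_b + H_f = 0; smallest wins
        assert max_entropy_threshold(hist) == 10

    def test_degenerate_histogram_raises(self):
        hist = np.zeros(256, dtype=int)
        hist[42] = 100
        with pytest.raises(DegenerateHistogramError):
            max_entropy_threshold(hist)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hist = rng.integers(0, 30, size=256)
        if np.count_nonzero(hist) < 2:
            hist[[3, 200]] = 5
        assert max_entropy_threshold(hist) == brute_force_max_entropy(hist)

    def test_sparse_histograms_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            hist = np.zeros(256, dtype=int)
            levels = rng.choice(256, size=rng.integers(2, 8), replace=False)
            hist[levels] = rng.integers(1, 50, size=len(levels))
            assert max_entropy_threshold(hist) == brute_force_max_entropy(hist)


# ---------------------------------------------------------- segmentation

class TestSegmentation:
    def test_all_zero_stack_empty_mask(self):
        stack = ImageStack(np.zeros((2, 20, 20), dtype=np.uint8), (0.25, 0.1, 0.1))
        assert not segment_local_max_entropy(stack).any()

    def test_low_cut_is_inclusive(self):
        # a stack whose maximum is exactly the cutoff yields nothing
        stack = ImageStack(
            np.full((2, 20, 20), 20, dtype=np.uint8), (0.25, 0.1, 0.1)
        )
        assert not segment_local_max_entropy(stack, low_cut=20).any()

    def test_single_bright_voxel(self):
        vox = np.full((1, 31, 31), 5, dtype=np.uint8)
        vox[0, 15, 15] = 200
        stack = ImageStack(vox, (0.25, 0.1, 0.1))
        mask = segment_local_max_entropy(stack)
        expected = np.zeros_like(vox, dtype=bool)
        expected[0, 15, 15] = True
        np.testing.assert_array_equal(mask, expected)

    def test_window_must_be_odd_and_fit(self, flat_stack):
        with pytest.raises(ValueError):
            segment_local_max_entropy(flat_stack, window=14)
        with pytest.raises(ValueError):
            segment_local_max_entropy(flat_stack, window=41)

    def test_equals_naive_definition_on_random_stack(self):
        stack = random_stack(seed=11)
        mask = segment_local_max_entropy(stack)
        oracle = naive_local_segmentation(stack.voxels)
        np.testing.assert_array_equal(mask, oracle)

    def test_low_cut_monotonicity(self):
        stack = random_stack(seed=12)
        lower = segment_local_max_entropy(stack, low_cut=20)
        higher = segment_local_max_entropy(stack, low_cut=60)
        # raising the cutoff can only remove foreground
        assert not (higher & ~lower).any()

    def test_translation_equivariance(self):
        vox = np.full((3, 40, 40), 8, dtype=np.uint8)
        vox[1, 18:21, 18:21] = 180
        stack = ImageStack(vox, (0.25, 0.1, 0.1))
        mask = segment_local_max_entropy(stack)
        shifted = ImageStack(np.roll(vox, (2, 3), axis=(1, 2)), (0.25, 0.1, 0.1))
        mask_shifted = segment_local_max_entropy(shifted)
        np.testing.assert_array_equal(np.roll(mask, (2, 3), axis=(1, 2)), mask_shifted)


# ------------------------------------------------------- label and measure

class TestLabelAndMeasure:
    SPACING = (0.25, 0.1, 0.1)

    def test_single_block_volume(self):
        mask = np.zeros((4, 6, 6), dtype=bool)
        mask[1:3, 2:4, 2:4] = True
        table = label_and_measure(mask, self.SPACING)
        assert len(table) == 1
        assert table["voxel_count"].iloc[0] == 8
        assert table["volume_um3"].iloc[0] == pytest.approx(8 * 0.0025)

    def test_separated_blocks(self):
        mask = np.zeros((3, 10, 10), dtype=bool)
        mask[1, 1:3, 1:3] = True
        mask[1, 6:8, 6:8] = True
        assert len(label_and_measure(mask, self.SPACING)) == 2

    def test_diagonal_touch_connectivity(self):
        mask = np.zeros((1, 4, 4), dtype=bool)
        mask[0, 1, 1] = True
        mask[0, 2, 2] = True
        assert len(label_and_measure(mask, self.SPACING, connectivity=26)) == 1
        assert len(label_and_measure(mask, self.SPACING, connectivity=6)) == 2

    def test_empty_mask_empty_table(self):
        table = label_and_measure(np.zeros((2, 5, 5), dtype=bool), self.SPACING)
        assert len(table) == 0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_volume_conservation(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((4, 16, 16)) < 0.2
        table = label_and_measure(mask, self.SPACING)
        voxel_volume = np.prod(self.SPACING)
        assert table["voxel_count"].sum() == mask.sum()
        assert table["volume_um3"].sum() == pytest.approx(
            mask.sum() * voxel_volume, rel=1e-12
        )


# ----------------------------------------------------------------- quantify

class TestQuantify:
    def _table(self, volumes):
        return pd.DataFrame(
            {"id": range(1, len(volumes) + 1), "voxel_count": 1,
             "volume_um3": volumes, "zc": 0.0, "yc": 0.0, "xc": 0.0}
        )

    def test_count_density(self):
        q = quantify(self._table([0.1] * 30), 100.0, "axonal_length")
        assert q.count_density == pytest.approx(0.3)

    def test_volume_density(self):
        q = quantify(self._table([2.5, 2.5]), 50_000.0, "muscle_surface_area")
        assert q.volume_density == pytest.approx(1e-4)

    def test_empty_table(self):
        q = quantify(self._table([]), 10.0, "axonal_length")
        assert q.puncta_count == 0
        assert q.count_density == 0.0 and q.volume_density == 0.0

    def test_invalid_normalizer(self):
        with pytest.raises(ValueError):
            quantify(self._table([1.0]), 0.0, "axonal_length")
        with pytest.raises(ValueError):
            quantify(self._table([1.0]), 10.0, "nonsense")
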