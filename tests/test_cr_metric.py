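"""Correlation ratio: binning, sorted index, bin statistics and eta."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coralign import cr_metric as cr
from coralign.affine_register import AffineTransform
from coralign.volume_io import Volume

from conftest import random_volume


def _vol(data, spacing=(1, 1, 1)):
    return Volume(np.asarray(data, dtype=float), spacing, (0, 0, 0))


def _full(shape):
    return np.ones(shape, dtype=bool)


class TestBinReference:
    def test_unit_width_bins(self):
        vol = _vol(np.arange(256.0).reshape(4, 8, 8))
        binned = cr.bin_reference(vol, 256)
        np.testing.assert_array_equal(
            binned.bin_of_voxel, np.arange(256).reshape(4, 8, 8)
        )
        assert not binned.degenerate

    def test_constant_volume_flagged_degenerate(self):
        binned = cr.bin_reference(_vol(np.full((4, 4, 4), 9.0)), 8)
        assert binned.degenerate
        assert set(np.unique(binned.bin_of_voxel)) == {0}

    def test_edge_arithmetic(self):
        # range ~[0, 1), 4 bins: 0.74 * 4 -> bin 2
        vol = _vol(np.array([0.0, 0.25, 0.74, 0.9999]).reshape(4, 1, 1))
        binned = cr.bin_reference(vol, 4)
        assert binned.bin_of_voxel[2, 0, 0] == 2

    def test_maximum_goes_to_last_bin(self):
        vol = _vol(np.array([0.0, 1.0, 2.0, 4.0]).reshape(4, 1, 1))
        binned = cr.bin_reference(vol, 4)
        assert binned.bin_of_voxel[3, 0, 0] == 3

    def test_empty_mask_rejected(self):
        with pytest.raises(cr.CRError, match="mask"):
            cr.bin_reference(_vol(np.zeros((4, 4, 4))), 4,
                             mask=np.zeros((4, 4, 4), bool))


class TestSortedIndex:
    def test_hand_counted_example(self):
        binned = cr.BinnedReference(
            bin_of_voxel=np.array([2, 0, 1, 0]).reshape(4, 1, 1),
            n_bins=3,
            bin_edges=np.arange(4.0),
            mask=_full((4, 1, 1)),
        )
        index = cr.build_sorted_index(binned)
        np.testing.assert_array_equal(index.entries, [1, 3, 2, 0])
        np.testing.assert_array_equal(index.bin_start, [0, 2, 3])
        np.testing.assert_array_equal(index.bin_end, [2, 3, 4])

    def test_single_bin_preserves_linear_order(self):
        binned = cr.bin_reference(_vol(np.full((3, 3, 3), 5.0)), 4)
        index = cr.build_sorted_index(binned)
        np.testing.assert_array_equal(index.entries, np.arange(27))

    def test_bin_slices_partition_all_voxels(self, rng):
        vol = random_volume(rng, (10, 10, 10))
        index = cr.build_sorted_index(cr.bin_reference(vol, 16))
        assert sorted(index.entries.tolist()) == list(range(1000))
        for i in range(16):
            assert index.bin_start[i] <= index.bin_end[i]


class TestSampleTransformed:
    def test_identity_self_sampling(self, rng):
        vol = random_volume(rng, (8, 8, 8))
        values, overlap = cr.sample_transformed(vol, AffineTransform.identity(), vol)
        assert overlap.all()
        np.testing.assert_allclose(values, vol.data, atol=1e-12)

    def test_half_field_translation_overlap(self, rng):
        vol = random_volume(rng, (16, 16, 16))
        t = AffineTransform.from_params([8.0, 0, 0, 0, 0, 0])
        _, overlap = cr.sample_transformed(vol, t, vol)
        frac = overlap.mean()
        assert 0.4 < frac < 0.6

    def test_translation_beyond_extent_empties_overlap(self, rng):
        vol = random_volume(rng, (8, 8, 8))
        t = AffineTransform.from_params([100.0, 0, 0, 0, 0, 0])
        values, overlap = cr.sample_transformed(vol, t, vol)
        assert not overlap.any()
        index = cr.build_sorted_index(cr.bin_reference(vol, 8))
        stats = cr.accumulate_bin_stats(index, values, overlap)
        with pytest.raises(cr.CRError, match="overlap"):
            cr.correlation_ratio(stats)

    def test_singular_transform_rejected(self, rng):
        vol = random_volume(rng, (8, 8, 8))
        bad = np.eye(4)
        bad[0, 0] = 0.0
        with pytest.raises(cr.CRError, match="singular"):
            cr.sample_transformed(vol, bad, vol)


class TestAccumulateBinStats:
    def test_single_bin_counts(self):
        binned = cr.bin_reference(_vol(np.zeros((3, 1, 1)) + 1.0), 4)
        index = cr.build_sorted_index(binned)
        values = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        stats = cr.accumulate_bin_stats(index, values, _full((3, 1, 1)))
        assert stats.count[0] == 3
        assert stats.sum[0] == 6.0
        assert stats.sum_sq[0] == 14.0

    def test_masked_voxel_excluded(self):
        binned = cr.bin_reference(_vol(np.zeros((3, 1, 1))), 2)
        index = cr.build_sorted_index(binned)
        values = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        overlap = np.array([True, False, True]).reshape(3, 1, 1)
        stats = cr.accumulate_bin_stats(index, values, overlap)
        assert stats.count[0] == 2
        assert stats.sum[0] == 4.0
        assert stats.sum_sq[0] == 10.0

    @pytest.mark.parametrize("n_partitions", [4, 13])
    def test_partition_invariance(self, rng, n_partitions):
        vol = random_volume(rng, (12, 12, 12))
        index = cr.build_sorted_index(cr.bin_reference(vol, 16))
        values = rng.normal(size=(12, 12, 12))
        overlap = rng.random((12, 12, 12)) > 0.2
        ref = cr.accumulate_bin_stats(index, values, overlap, n_partitions=1)
        alt = cr.accumulate_bin_stats(index, values, overlap, n_partitions=n_partitions)
        np.testing.assert_array_equal(ref.count, alt.count)
        np.testing.assert_array_equal(ref.sum, alt.sum)
        np.testing.assert_array_equal(ref.sum_sq, alt.sum_sq)


def _eta_sorted(binned, values, overlap):
    index = cr.build_sorted_index(binned)
    stats = cr.accumulate_bin_stats(index, values, overlap)
    return cr.correlation_ratio(stats).eta


class TestCorrelationRatio:
    def test_deterministic_dependence_gives_one(self):
        vol = _vol(np.arange(256.0).reshape(4, 8, 8))
        binned = cr.bin_reference(vol, 256)
        eta = _eta_sorted(binned, vol.data, _full(vol.shape))
        assert eta == 1.0

    def test_no_functional_dependence_gives_zero(self):
        ref = _vol(np.array([0.0, 0.0, 1.0, 1.0]).reshape(4, 1, 1))
        binned = cr.bin_reference(ref, 2)
        values = np.array([0.0, 1.0, 0.0, 1.0]).reshape(4, 1, 1)
        eta = _eta_sorted(binned, values, _full((4, 1, 1)))
        assert eta == 0.0

    def test_hand_computed_intermediate_value(self):
        ref = _vol(np.array([0.0, 0.0, 1.0, 1.0]).reshape(4, 1, 1))
        binned = cr.bin_reference(ref, 2)
        values = np.array([1.0, 2.0, 3.0, 5.0]).reshape(4, 1, 1)
        eta = _eta_sorted(binned, values, _full((4, 1, 1)))
        assert eta == pytest.approx(1.0 - 2.5 / 8.75, abs=1e-12)

    def test_zero_variance_rejected(self):
        ref = _vol(np.arange(4.0).reshape(4, 1, 1))
        binned = cr.bin_reference(ref, 2)
        values = np.full((4, 1, 1), 3.0)
        index = cr.build_sorted_index(binned)
        stats = cr.accumulate_bin_stats(index, values, _full((4, 1, 1)))
        with pytest.raises(cr.CRError, match="variance"):
            cr.correlation_ratio(stats)

    def test_eta_is_one_iff_constant_within_bins(self, rng):
        ref = _vol(np.repeat(np.arange(8.0), 8).reshape(4, 4, 4))
        binned = cr.bin_reference(ref, 8)
        values = ref.data * 3.0 + 1.0  # constant within each bin
        assert _eta_sorted(binned, values, _full((4, 4, 4))) == 1.0
        noisy = values + rng.normal(size=values.shape)
        assert _eta_sorted(binned, noisy, _full((4, 4, 4))) < 1.0


class TestDirectOracle:
    def test_agrees_on_hand_examples(self):
        ref = _vol(np.array([0.0, 0.0, 1.0, 1.0]).reshape(4, 1, 1))
        binned = cr.bin_reference(ref, 2)
        for values in ([0, 1, 0, 1], [1, 2, 3, 5]):
            values = np.asarray(values, dtype=float).reshape(4, 1, 1)
            eta_fast = _eta_sorted(binned, values, _full((4, 1, 1)))
            eta_direct = cr.correlation_ratio_direct(binned, values, _full((4, 1, 1)))
            assert eta_fast == pytest.approx(eta_direct, abs=1e-14)

    def test_sorted_path_matches_direct_on_random_sweep(self, rng):
        """50 random instances, 8^3-16^3: |delta eta| < 1e-10."""
        worst = 0.0
        for _ in range(50):
            n = int(rng.integers(8, 17))
            vol = random_volume(rng, (n, n, n))
            n_bins = int(rng.integers(2, 33))
            binned = cr.bin_reference(vol, n_bins)
            values = rng.normal(size=(n, n, n))
            overlap = rng.random((n, n, n)) > 0.1
            eta_fast = _eta_sorted(binned, values, overlap)
            eta_direct = cr.correlation_ratio_direct(binned, values, overlap)
            worst = max(worst, abs(eta_fast - eta_direct))
        assert worst < 1e-10

    def test_storage_order_permutation_invariance(self, rng):
        vol = random_volume(rng, (6, 6, 6))
        values = rng.normal(size=(6, 6, 6))
        binned = cr.bin_reference(vol, 8)
        eta0 = cr.correlation_ratio_direct(binned, values, _full((6, 6, 6)))
        perm = rng.permutation(216)
        vol_p = _vol(vol.data.ravel()[perm].reshape(6, 6, 6))
        values_p = values.ravel()[perm].reshape(6, 6, 6)
        eta1 = cr.correlation_ratio_direct(
            cr.bin_reference(vol_p, 8), values_p, _full((6, 6, 6))
        )
        assert eta0 == pytest.approx(eta1, abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 12))
def test_eta_bounds_and_total_variance_law(seed, n_bins):
    """0 <= eta <= 1 and sum_i N_i sigma_i^2 <= N sigma^2 on fuzzed inputs."""
    rng = np.random.default_rng(seed)
    shape = (6, 6, 6)
    ref = Volume(rng.normal(size=shape), (1, 1, 1), (0, 0, 0))
    values = rng.normal(size=shape)
    overlap = rng.random(shape) > 0.3
    binned = cr.bin_reference(ref, n_bins)
    index = cr.build_sorted_index(binned)
    stats = cr.accumulate_bin_stats(index, values, overlap)
    try:
        result = cr.correlation_ratio(stats)
    except cr.CRError:
        return
    assert 0.0 <= result.eta <= 1.0
    occupied = stats.count > 1
    within = np.sum(stats.sum_sq[occupied] - stats.sum[occupied] ** 2 / stats.count[occupied])
    assert within <= result.n_overlap * result.sigma_sq * (1 + 1e-9) + 1e-12
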