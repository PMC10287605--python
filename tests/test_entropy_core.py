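import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lemap import (
    KernelConfig,
    Volume,
    kernel_entropy,
    local_entropy_map,
    normalize_map,
    smooth_map,
)
from conftest import as_entropy_map, brute_force_entropy_map


class TestKernelEntropy:
    def test_single_symbol_is_zero(self):
        assert kernel_entropy(np.full(125, 40.0)) == 0.0

    def test_all_distinct_is_log_n(self):
        assert kernel_entropy(np.arange(125.0)) == pytest.approx(math.log(125), abs=1e-12)

    def test_two_symbol_split(self):
        # 100 copies of 40 HU and 25 of 60 HU: direct one-line evaluation
        values = np.array([40.0] * 100 + [60.0] * 25)
        expected = -(0.8 * math.log(0.8) + 0.2 * math.log(0.2))
        assert kernel_entropy(values) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5004, abs=5e-5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kernel_entropy(np.array([]))

    @given(st.lists(st.integers(-1000, 1000), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance_and_bounds(self, values):
        v = np.array(values, dtype=float)
        h = kernel_entropy(v)
        assert 0.0 <= h <= math.log(len(values)) + 1e-12
        rng = np.random.default_rng(0)
        assert kernel_entropy(rng.permutation(v)) == h

    @given(st.lists(st.integers(-500, 500), min_size=2, max_size=60),
           st.sampled_from([2.0, 5.0, 10.0]))
    @settings(max_examples=50, deadline=None)
    def test_coarsening_never_increases_entropy(self, values, width):
        v = np.array(values, dtype=float)
        assert kernel_entropy(v, width) <= kernel_entropy(v, 1.0) + 1e-12


class TestLocalEntropyMap:
    def test_constant_volume_maps_to_zero(self):
        v = Volume(data=np.full((20, 20, 20), 37.0))
        m = local_entropy_map(v, KernelConfig(k=5))
        np.testing.assert_array_equal(m.data, 0.0)

    @pytest.mark.parametrize("k", [3, 5])
    def test_matches_brute_force_exactly(self, k, random_volume):
        m = local_entropy_map(random_volume, KernelConfig(k=k))
        oracle = brute_force_entropy_map(random_volume.data, k)
        np.testing.assert_array_equal(m.data, oracle)

    def test_bounds_on_iid_volume(self, rng):
        v = Volume(data=rng.integers(0, 125, size=(16, 16, 16)).astype(float))
        m = local_entropy_map(v, KernelConfig(k=5))
        assert np.all(m.data >= 0.0)
        assert np.all(m.data <= math.log(125) + 1e-12)

    def test_coarsening_monotone_per_voxel(self, random_volume):
        fine = local_entropy_map(random_volume, KernelConfig(k=3, quantization_bin_width=1.0))
        coarse = local_entropy_map(random_volume, KernelConfig(k=3, quantization_bin_width=20.0))
        assert np.all(coarse.data <= fine.data + 1e-12)

    def test_exclude_border_marks_shell_missing(self, random_volume):
        m = local_entropy_map(
            random_volume, KernelConfig(k=5, padding_mode="exclude-border")
        )
        assert m.data.shape == random_volume.data.shape
        assert np.isnan(m.data[0]).all() and np.isnan(m.data[:, :, -2]).all()
        interior = m.data[2:-2, 2:-2, 2:-2]
        assert np.isfinite(interior).all()
        reflect = local_entropy_map(random_volume, KernelConfig(k=5))
        np.testing.assert_array_equal(interior, reflect.data[2:-2, 2:-2, 2:-2])

    def test_volume_smaller_than_kernel_rejected_without_padding(self):
        v = Volume(data=np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="smaller than kernel"):
            local_entropy_map(v, KernelConfig(k=5, padding_mode="exclude-border"))

    def test_determinism(self, random_volume):
        a = local_entropy_map(random_volume, KernelConfig(k=3))
        b = local_entropy_map(random_volume, KernelConfig(k=3))
        np.testing.assert_array_equal(a.data, b.data)

    def test_invalid_kernel_config(self):
        with pytest.raises(ValueError):
            KernelConfig(k=4)
        with pytest.raises(ValueError):
            KernelConfig(k=1)
        with pytest.raises(ValueError):
            KernelConfig(quantization_bin_width=0.0)


class TestSmoothMap:
    def test_constant_map_unchanged(self):
        m = as_entropy_map(np.full((12, 12, 12), 2.5))
        sm = smooth_map(m, sigma=1.0)
        np.testing.assert_allclose(sm.data, 2.5, atol=1e-12)
        assert sm.smoothed and sm.smooth_sigma == 1.0

    def test_impulse_response_matches_explicit_gaussian_kernel(self):
        # independent oracle: sampled 1D Gaussian, normalized over the
        # truncation radius, separably outer-multiplied
        sigma, h = 1.0, 10.0
        data = np.zeros((17, 17, 17))
        data[8, 8, 8] = h
        sm = smooth_map(as_entropy_map(data), sigma=sigma)
        r = int(4 * sigma + 0.5)
        x = np.arange(-r, r + 1)
        w = np.exp(-0.5 * (x / sigma) ** 2)
        w /= w.sum()
        assert sm.data[8, 8, 8] == pytest.approx(h * w[r] ** 3, rel=1e-10)
        assert sm.data[8, 8, 9] == pytest.approx(h * w[r] ** 2 * w[r + 1], rel=1e-10)

    def test_interior_impulse_mass_preserved(self):
        data = np.zeros((17, 17, 17))
        data[8, 8, 8] = 5.0
        sm = smooth_map(as_entropy_map(data), sigma=1.0)
        assert abs(sm.data.sum() - 5.0) / 5.0 < 1e-3

    def test_double_smoothing_and_bad_sigma_rejected(self):
        m = smooth_map(as_entropy_map(np.zeros((8, 8, 8))), sigma=1.0)
        with pytest.raises(ValueError, match="already smoothed"):
            smooth_map(m)
        with pytest.raises(ValueError, match="sigma"):
            smooth_map(as_entropy_map(np.zeros((8, 8, 8))), sigma=0.0)

    def test_excluded_border_stays_missing(self, random_volume):
        m = local_entropy_map(random_volume, KernelConfig(k=3, padding_mode="exclude-border"))
        sm = smooth_map(m)
        assert np.isnan(sm.data[0]).all()
        assert np.isfinite(sm.data[1:-1, 1:-1, 1:-1]).all()


class TestNormalizeMap:
    def test_liver_mean_becomes_one(self, rng, ball_mask):
        m = as_entropy_map(rng.uniform(0.5, 4.0, size=(20, 20, 20)))
        liver = ball_mask((20, 20, 20), (6, 6, 6), 4)
        nm = normalize_map(m, liver)
        assert nm.data[liver.data].mean() == pytest.approx(1.0, abs=1e-9)
        assert nm.normalized and nm.norm_reference > 0

    def test_scale_invariance(self, rng, ball_mask):
        data = rng.uniform(0.5, 4.0, size=(16, 16, 16))
        liver = ball_mask((16, 16, 16), (5, 5, 5), 3)
        a = normalize_map(as_entropy_map(data), liver)
        b = normalize_map(as_entropy_map(3.7 * data), liver)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)

    def test_division_oracle(self, ball_mask):
        # liver region at 0.75 nats, one tumor voxel at 0.91 nats
        data = np.full((16, 16, 16), 0.75)
        data[12, 12, 12] = 0.91
        liver = ball_mask((16, 16, 16), (5, 5, 5), 3)
        nm = normalize_map(as_entropy_map(data), liver)
        assert nm.data[12, 12, 12] == pytest.approx(0.91 / 0.75, abs=1e-12)
        assert nm.data[12, 12, 12] == pytest.approx(1.2133, abs=1e-4)

    def test_constant_zero_liver_rejected(self, ball_mask):
        m = as_entropy_map(np.zeros((16, 16, 16)))
        liver = ball_mask((16, 16, 16), (5, 5, 5), 3)
        with pytest.raises(ValueError, match="undefined"):
            normalize_map(m, liver)

    def test_subtraction_variant(self, rng, ball_mask):
        data = rng.uniform(0.5, 4.0, size=(16, 16, 16))
        liver = ball_mask((16, 16, 16), (5, 5, 5), 3)
        nm = normalize_map(as_entropy_map(data), liver, method="subtract")
        assert nm.data[liver.data].mean() == pytest.approx(0.0, abs=1e-9)
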