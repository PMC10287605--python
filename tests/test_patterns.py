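import numpy as np
import pytest

from lemap import (
    Mask,
    PATTERN_LABELS,
    classify_pattern,
    classify_voxels,
    split_rim_core,
)
from lemap.patterns import HYPER, HYPO, ISO, VoxelClassField
from conftest import as_entropy_map


def _cube_mask(shape, lo, hi):
    data = np.zeros(shape, dtype=bool)
    data[lo:hi, lo:hi, lo:hi] = True
    return Mask(data=data)


def _field(classes, tumor, liver_mean=0.75, liver_sd=0.05, z=1.0):
    return VoxelClassField(classes=classes, tumor=tumor, liver_mean=liver_mean,
                           liver_sd=liver_sd, z_cutoff=z)


class TestClassifyVoxels:
    def _setup(self, map_value=0.75):
        data = np.full((16, 16, 16), map_value)
        tumor = _cube_mask((16, 16, 16), 9, 14)
        liver = _cube_mask((16, 16, 16), 1, 6)
        return data, tumor, liver

    def test_threshold_arithmetic(self, rng):
        data, tumor, liver = self._setup()
        data[liver.data] = 0.75 + 0.05 * rng.standard_normal(liver.n_voxels)
        m = as_entropy_map(data)
        field = classify_voxels(m, tumor, liver, z_cutoff=1.0)
        mu, sd = field.liver_mean, field.liver_sd
        for value, expected in ((0.91, HYPER), (mu + 0.5 * sd, ISO), (mu - 2.0 * sd, HYPO)):
            probe = data.copy()
            probe[10, 10, 10] = value
            f = classify_voxels(as_entropy_map(probe), tumor, liver, z_cutoff=1.0)
            assert f.classes[10, 10, 10] == expected

    def test_map_equal_to_liver_mean_is_all_iso(self, rng):
        data, tumor, liver = self._setup()
        data[liver.data] += 0.01 * rng.standard_normal(liver.n_voxels)
        f = classify_voxels(as_entropy_map(data), tumor, liver)
        # tumor voxels sit exactly at the (pre-noise) liver mean
        assert (f.classes[tumor.data] == ISO).mean() > 0.99

    def test_zero_cutoff_leaves_no_iso_band(self, rng):
        data, tumor, liver = self._setup()
        data += 0.05 * rng.standard_normal(data.shape)
        f = classify_voxels(as_entropy_map(data), tumor, liver, z_cutoff=0.0)
        assert (f.classes[tumor.data] != ISO).all()

    def test_constant_liver_rejected(self):
        data, tumor, liver = self._setup()
        with pytest.raises(ValueError, match="SD is zero"):
            classify_voxels(as_entropy_map(data), tumor, liver)

    def test_overlapping_masks_rejected(self, rng):
        data, tumor, _ = self._setup()
        with pytest.raises(ValueError, match="disjoint"):
            classify_voxels(as_entropy_map(data), tumor, tumor)


class TestSplitRimCore:
    def test_cube_shell_and_core_counts(self):
        tumor = _cube_mask((15, 15, 15), 3, 12)  # 9x9x9 solid cube
        shell, core, empty = split_rim_core(tumor, rim_width=1)
        assert shell.n_voxels == 9**3 - 7**3 == 386
        assert core.n_voxels == 7**3 == 343
        assert not empty

    def test_rim_wider_than_radius_gives_empty_core(self):
        tumor = _cube_mask((10, 10, 10), 4, 7)
        shell, core, empty = split_rim_core(tumor, rim_width=5)
        assert empty and core.n_voxels == 0
        np.testing.assert_array_equal(shell.data, tumor.data)

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_property_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        from scipy import ndimage
        blob = ndimage.gaussian_filter(rng.standard_normal((24, 24, 24)), 3) > 0.1
        if not blob.any():
            blob[12, 12, 12] = True
        tumor = Mask(data=blob)
        shell, core, _ = split_rim_core(tumor, rim_width=rng.integers(1, 4))
        assert not (shell.data & core.data).any()
        np.testing.assert_array_equal(shell.data | core.data, tumor.data)

    def test_validation(self):
        with pytest.raises(ValueError, match="empty"):
            split_rim_core(Mask(data=np.zeros((5, 5, 5), dtype=bool)))
        with pytest.raises(ValueError, match="rim_width"):
            split_rim_core(_cube_mask((8, 8, 8), 2, 6), rim_width=0)


class TestClassifyPattern:
    """Geometric ground truths built directly as class fields.

    boundary/core margins are zeroed here: these fields are exact, not
    map-derived, so no point-spread compensation applies.
    """

    kw = dict(rim_width=2, boundary_margin=0, core_margin=0)

    def test_uniform_hyper_is_homogeneous(self):
        tumor = _cube_mask((20, 20, 20), 4, 16)
        classes = np.where(tumor.data, HYPER, ISO).astype(np.int8)
        res = classify_pattern(_field(classes, tumor), tumor, **self.kw)
        assert res.label == "homogeneous"
        assert res.hyper_surface_fraction == 1.0
        assert res.rim_subtype == "none"

    def test_hyper_shell_iso_core_is_complete_rim(self):
        tumor = _cube_mask((20, 20, 20), 4, 16)
        shell, core, _ = split_rim_core(tumor, rim_width=2)
        classes = np.full(tumor.data.shape, HYPO, dtype=np.int8)
        classes[core.data] = ISO
        classes[shell.data] = HYPER
        res = classify_pattern(_field(classes, tumor), tumor, **self.kw)
        assert res.label == "peripheral_rim"
        assert res.rim_subtype == "complete"
        assert res.rim_coverage_fraction == 1.0
        assert res.core_homogeneity_fraction == 1.0
        # verify the reported fractions by direct counting
        assert res.hyper_surface_fraction == pytest.approx(
            shell.n_voxels / tumor.n_voxels, abs=1e-12
        )

    def test_partial_shell_is_incomplete_rim(self):
        tumor = _cube_mask((20, 20, 20), 4, 16)
        shell, core, _ = split_rim_core(tumor, rim_width=2)
        classes = np.full(tumor.data.shape, ISO, dtype=np.int8)
        classes[shell.data] = HYPER
        # knock out ~15% of the shell
        idx = np.argwhere(shell.data)
        out = idx[: int(0.15 * len(idx))]
        classes[tuple(out.T)] = ISO
        res = classify_pattern(_field(classes, tumor), tumor, **self.kw)
        assert res.label == "peripheral_rim"
        assert res.rim_subtype == "incomplete"
        assert 0.75 <= res.rim_coverage_fraction < 0.999

    def test_scattered_without_shell_enrichment_is_inhomogeneous(self):
        rng = np.random.default_rng(7)
        tumor = _cube_mask((20, 20, 20), 4, 16)
        classes = np.where(
            tumor.data & (rng.random(tumor.data.shape) < 0.5), HYPER, ISO
        ).astype(np.int8)
        res = classify_pattern(_field(classes, tumor), tumor, **self.kw)
        assert res.label == "inhomogeneous"
        assert res.rim_coverage_fraction < 0.75

    def test_rim_with_scattered_core_is_mixed(self):
        rng = np.random.default_rng(3)
        tumor = _cube_mask((20, 20, 20), 4, 16)
        shell, core, _ = split_rim_core(tumor, rim_width=2)
        classes = np.where(
            tumor.data & (rng.random(tumor.data.shape) < 0.5), HYPER, ISO
        ).astype(np.int8)
        classes[shell.data] = HYPER
        res = classify_pattern(_field(classes, tumor), tumor, **self.kw)
        assert res.label == "mixed"
        assert res.rim_subtype == "complete"

    def test_rim_only_lesion_flagged_and_classified(self):
        tumor = _cube_mask((10, 10, 10), 4, 7)
        classes = np.where(tumor.data, HYPER, ISO).astype(np.int8)
        res = classify_pattern(_field(classes, tumor), tumor, rim_width=5,
                               boundary_margin=0, core_margin=0)
        assert res.core_empty
        assert res.label == "peripheral_rim"

    def test_label_set_is_the_four_patterns(self):
        assert set(PATTERN_LABELS) == {
            "homogeneous", "inhomogeneous", "peripheral_rim", "mixed"
        }

    @pytest.mark.parametrize("frac", [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    def test_monotone_scatter_never_reads_as_rim(self, frac):
        rng = np.random.default_rng(int(frac * 10))
        tumor = _cube_mask((20, 20, 20), 4, 16)
        classes = np.where(
            tumor.data & (rng.random(tumor.data.shape) < frac), HYPER, ISO
        ).astype(np.int8)
        res = classify_pattern(_field(classes, tumor), tumor, **self.kw)
        assert res.label != "peripheral_rim"

    def test_determinism(self):
        tumor = _cube_mask((20, 20, 20), 4, 16)
        rng = np.random.default_rng(1)
        classes = np.where(
            tumor.data & (rng.random(tumor.data.shape) < 0.3), HYPER, HYPO
        ).astype(np.int8)
        r1 = classify_pattern(_field(classes, tumor), tumor, **self.kw)
        r2 = classify_pattern(_field(classes.copy(), tumor), tumor, **self.kw)
        assert r1.to_dict() == r2.to_dict()
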