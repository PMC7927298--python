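"""PSMD, WMH classification and loads, Dice index."""

import numpy as np
import pytest

import csvdnet as cn
from csvdnet.exceptions import UndefinedMetricError, ValidationError
from csvdnet.markers import LesionMasks, SkeletonSample, ventricle_distance_mm


def make_masks(wmh, vent, dims=(1.0, 1.0, 1.0), icv=1483.7, vent_ml=25.4):
    return LesionMasks(wmh=wmh, ventricles=vent, voxel_dims=dims, icv_ml=icv, ventricle_ml=vent_ml)


class TestPsmd:
    def test_constant_sample_zero_width(self):
        s = SkeletonSample(np.full(1000, 2.0e-4))
        assert cn.psmd(s) == 0.0

    def test_uniform_grid_analytic_width(self):
        s = SkeletonSample(np.linspace(1e-9, 1e-3, 10001))
        assert cn.psmd(s) == pytest.approx(0.9e-3, abs=1e-7)

    def test_normal_sample_matches_quantile_width(self):
        rng = np.random.default_rng(0)
        sd = 2.0e-5
        s = SkeletonSample(np.abs(rng.normal(2.0e-4, sd, size=100_000)))
        expected = 2 * 1.6449 * sd
        assert cn.psmd(s) == pytest.approx(expected, rel=0.02)

    def test_translation_invariance_and_linearity(self, rng):
        v = rng.uniform(1e-4, 9e-4, size=5000)
        base = cn.psmd(SkeletonSample(v))
        assert cn.psmd(SkeletonSample(v + 3e-4)) == pytest.approx(base, rel=1e-9)
        assert cn.psmd(SkeletonSample(v * 2.5)) == pytest.approx(2.5 * base, rel=1e-9)

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            cn.psmd(SkeletonSample(np.linspace(1e-4, 2e-4, 10)))

    def test_empty_sample_rejected(self):
        with pytest.raises(UndefinedMetricError):
            SkeletonSample(np.array([]))


class TestExtractSkeleton:
    def test_scan_order_extraction(self):
        md = np.arange(27, dtype=float).reshape(3, 3, 3) + 1.0
        mask = np.zeros((3, 3, 3), bool)
        mask.ravel()[[1, 5, 9, 13, 20]] = True
        s = cn.extract_skeleton_sample(md, mask)
        np.testing.assert_array_equal(s.md_values, [2.0, 6.0, 10.0, 14.0, 21.0])

    def test_zero_voxels_excluded(self):
        md = np.ones((2, 2, 2))
        md[0, 0, 0] = 0.0
        s = cn.extract_skeleton_sample(md, np.ones((2, 2, 2), bool))
        assert s.n_voxels == 7

    def test_empty_mask_rejected(self):
        with pytest.raises(UndefinedMetricError):
            cn.extract_skeleton_sample(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))


def brute_force_distance(wmh, vent, dims):
    """O(n^2) per-voxel minimum distance oracle."""
    wmh_idx = np.argwhere(wmh).astype(float) * np.asarray(dims)
    vent_idx = np.argwhere(vent).astype(float) * np.asarray(dims)
    d = np.linalg.norm(wmh_idx[:, None, :] - vent_idx[None, :, :], axis=-1)
    return d.min(axis=1)


class TestClassifyWmh:
    def test_near_voxel_is_periventricular(self):
        vent = np.zeros((30, 30, 30), bool)
        vent[15, 15, 15] = True
        wmh = np.zeros_like(vent)
        wmh[15, 15, 20] = True  # 5 mm away
        pv, dp = cn.classify_wmh(make_masks(wmh, vent))
        assert pv[15, 15, 20] and not dp.any()

    def test_far_voxel_is_deep(self):
        vent = np.zeros((40, 40, 40), bool)
        vent[20, 20, 20] = True
        wmh = np.zeros_like(vent)
        wmh[20, 20, 35] = True  # 15 mm away
        pv, dp = cn.classify_wmh(make_masks(wmh, vent))
        assert dp[20, 20, 35] and not pv.any()

    def test_boundary_voxel_inclusive(self):
        vent = np.zeros((25, 25, 25), bool)
        vent[12, 12, 2] = True
        wmh = np.zeros_like(vent)
        wmh[12, 12, 12] = True  # exactly 10 mm
        pv, _ = cn.classify_wmh(make_masks(wmh, vent))
        assert pv[12, 12, 12]

    def test_anisotropic_voxels_respected(self):
        vent = np.zeros((20, 20, 20), bool)
        vent[10, 10, 10] = True
        wmh = np.zeros_like(vent)
        wmh[10, 10, 16] = True  # 6 voxels * 2 mm = 12 mm along z
        pv, dp = cn.classify_wmh(make_masks(wmh, vent, dims=(1.0, 1.0, 2.0)))
        assert dp[10, 10, 16]

    def test_matches_brute_force_oracle_on_random_volume(self):
        rng = np.random.default_rng(42)
        shape = (30, 30, 30)
        vent = np.zeros(shape, bool)
        vent.ravel()[rng.choice(vent.size, 40, replace=False)] = True
        wmh = np.zeros(shape, bool)
        wmh.ravel()[rng.choice(wmh.size, 300, replace=False)] = True
        m = make_masks(wmh, vent, dims=(0.9, 1.1, 1.3))
        pv, dp = cn.classify_wmh(m)
        oracle = brute_force_distance(wmh, vent, m.voxel_dims) <= 10.0 + 1e-9
        np.testing.assert_array_equal(pv[wmh], oracle)
        assert not (pv & dp).any()
        assert ((pv | dp) == wmh).all()

    def test_empty_ventricles_rejected(self):
        wmh = np.zeros((5, 5, 5), bool)
        wmh[0, 0, 0] = True
        with pytest.raises(ValidationError):
            cn.classify_wmh(make_masks(wmh, np.zeros((5, 5, 5), bool)))


class TestLoads:
    def test_table_median_arithmetic(self):
        # printed cohort medians: WMH 0.6 mL, brain 1483.7 mL, ventricles 25.4 mL
        m = make_masks(np.zeros((4, 4, 4), bool), np.ones((4, 4, 4), bool))
        mk = cn.wmh_loads(m, pwmh_ml=0.5, dwmh_ml=0.1)
        assert mk.wmh_load == pytest.approx(100 * 0.6 / (1483.7 - 25.4), rel=1e-12)
        assert round(mk.wmh_load, 2) == 0.04

    def test_zero_volume_floored_log(self):
        m = make_masks(np.zeros((4, 4, 4), bool), np.ones((4, 4, 4), bool))
        with pytest.warns(UserWarning, match="floored"):
            mk = cn.wmh_loads(m, pwmh_ml=0.0, dwmh_ml=0.0)
        assert mk.wmh_load == 0.0
        floor = 100 * (m.voxel_volume_ml / 2) / m.brain_tissue_ml
        assert mk.log_wmh_load == pytest.approx(np.log10(floor))

    def test_load_inversely_proportional_to_brain_volume(self):
        m1 = make_masks(np.zeros((4, 4, 4), bool), np.ones((4, 4, 4), bool), icv=1025.0, vent_ml=25.0)
        m2 = make_masks(np.zeros((4, 4, 4), bool), np.ones((4, 4, 4), bool), icv=2025.0, vent_ml=25.0)
        l1 = cn.wmh_loads(m1, 1.0, 0.5).wmh_load
        l2 = cn.wmh_loads(m2, 1.0, 0.5).wmh_load
        assert l1 == pytest.approx(2 * l2)

    def test_volume_identity(self):
        rng = np.random.default_rng(1)
        vent = np.zeros((20, 20, 20), bool)
        vent[8:12, 8:12, 8:12] = True
        wmh = np.zeros_like(vent)
        wmh.ravel()[rng.choice(wmh.size, 200, replace=False)] = True
        wmh &= ~vent
        m = make_masks(wmh, vent)
        mk = cn.compute_markers(SkeletonSample(np.full(100, 7e-4)), m)
        assert mk.wmh_ml == pytest.approx(mk.pwmh_ml + mk.dwmh_ml, abs=m.voxel_volume_ml)


class TestDice:
    def test_identical_masks(self):
        a = np.zeros((5, 5, 5), bool)
        a[1:3] = True
        assert cn.dice(a, a) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros_like(a)
        a[0], b[3] = True, True
        assert cn.dice(a, b) == 0.0

    def test_partial_overlap_arithmetic(self):
        a = np.zeros(200, bool)
        b = np.zeros(200, bool)
        a[:100] = True
        b[37:137] = True  # overlap 63
        assert cn.dice(a, b) == pytest.approx(0.63)

    def test_symmetry(self, rng):
        a = rng.random((6, 6, 6)) > 0.5
        b = rng.random((6, 6, 6)) > 0.5
        assert cn.dice(a, b) == cn.dice(b, a)

    def test_both_empty_defined_as_one(self):
        with pytest.warns(UserWarning):
            assert cn.dice(np.zeros(5, bool), np.zeros(5, bool)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cn.dice(np.zeros(4, bool), np.zeros(5, bool))
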