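import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import pervimap as pm
from pervimap.errors import GeometryError, UndefinedRatioError, ValidationError
from pervimap.geometry import ReferenceGrid
from pervimap.perviousness import (
    SphericalROI,
    compute_all_maps,
    compute_map,
    summarize,
    two_roi_tai,
    void_fraction,
)

from conftest import make_volume

hu_arrays = hnp.arrays(
    dtype=float,
    shape=(4, 4, 4),
    elements=st.floats(min_value=-200, max_value=400, allow_nan=False),
)


class TestComputeMap:
    @pytest.mark.parametrize(
        "minu,subt,expected",
        [(80.0, 50.0, 30.0), (40.0, 50.0, 0.0), (55.0, 55.0, 0.0)],
    )
    def test_clipped_subtraction(self, minu, subt, expected):
        a = make_volume(np.full((3, 3, 3), minu))
        b = make_volume(np.full((3, 3, 3), subt))
        out = compute_map(a, b, "P1")
        assert np.allclose(out.voxels, expected)

    def test_grid_mismatch_is_geometry_error(self):
        a = make_volume(np.zeros((3, 3, 3)), spacing=(1, 1, 1))
        b = make_volume(np.zeros((3, 3, 3)), spacing=(0.5, 0.5, 0.5))
        with pytest.raises(GeometryError):
            compute_map(a, b, "P1")

    def test_validity_is_intersection(self):
        val_a = np.ones((3, 3, 3), dtype=bool)
        val_a[0] = False
        val_b = np.ones((3, 3, 3), dtype=bool)
        val_b[:, 0] = False
        a = make_volume(np.full((3, 3, 3), 10.0), validity=val_a)
        b = make_volume(np.zeros((3, 3, 3)), validity=val_b)
        out = compute_map(a, b, "P2")
        assert np.array_equal(out.validity, val_a & val_b)
        assert np.all(out.voxels[~out.validity] == 0)

    @settings(max_examples=25, deadline=None)
    @given(cta=hu_arrays, ctv=hu_arrays)
    def test_clipping_conservation_and_disjoint_support(self, cta, ctv):
        """P2 - P3 reconstructs CTV - CTA and no voxel is in both maps."""
        vcta, vctv = make_volume(cta), make_volume(ctv)
        p2 = compute_map(vctv, vcta, "P2")
        p3 = compute_map(vcta, vctv, "P3")
        assert np.allclose(p2.voxels - p3.voxels, ctv - cta, atol=1e-9)
        assert np.all(np.minimum(p2.voxels, p3.voxels) == 0)


class TestComputeAllMaps:
    def test_equal_cta_ctv_gives_zero_dynamic_maps(self, rng):
        ncct = make_volume(rng.normal(40, 5, (4, 4, 4)))
        cta = make_volume(rng.normal(60, 5, (4, 4, 4)))
        maps = compute_all_maps(ncct, cta, pm.CTVolume(cta.voxels.copy(), cta.grid))
        assert not maps["P2"].voxels.any()
        assert not maps["P3"].voxels.any()

    def test_monotone_in_added_ctv_offset(self, rng):
        ncct = make_volume(rng.normal(40, 5, (5, 5, 5)))
        cta = make_volume(rng.normal(50, 8, (5, 5, 5)))
        ctv = make_volume(rng.normal(50, 8, (5, 5, 5)))
        p2 = compute_map(ctv, cta, "P2")
        c = 7.0
        p2c = compute_map(ctv.with_voxels(ctv.voxels + c), cta, "P2")
        pos = p2.voxels > 0
        assert np.allclose(p2c.voxels[pos] - p2.voxels[pos], c)
        assert p2c.voxels.mean() >= p2.voxels.mean()

    def test_phantom_channel_dominates_top_decile_of_p2(self, clean_phantom):
        """The designed pervious channel carries the strongest late uptake."""
        from pervimap.phantom import AnatomyTemplate

        pat = clean_phantom
        maps = compute_all_maps(pat.ncct, pat.cta, pat.ctv)
        mask = pat.mask.as_bool()
        vals = maps["P2"].voxels[mask]
        w_channel = (
            AnatomyTemplate(pat.spec).unjittered_weights()["channel"]
            .reshape(pat.ncct.grid.shape)[mask]
        )
        top = vals >= np.quantile(vals, 0.9)
        assert (w_channel[top] > 0.25).mean() > 0.95


class TestSummarize:
    def _maps(self, p1, p2, p3, grid):
        val = np.ones(p1.shape, dtype=bool)
        return {
            k: pm.PerviousnessMap(k, v, val, grid)
            for k, v in (("P1", p1), ("P2", p2), ("P3", p3))
        }

    def test_mean_includes_clipped_zeros(self):
        grid = ReferenceGrid((4, 1, 1), (1, 1, 1))
        p2 = np.array([10.0, 0.0, 0.0, 2.0]).reshape(4, 1, 1)
        zeros = np.zeros((4, 1, 1))
        maps = self._maps(zeros, p2, zeros, grid)
        mask = pm.ThrombusMask(np.ones((4, 1, 1), dtype=np.uint8), grid)
        s = summarize(maps, mask, "p")
        assert s.mean_P2 == pytest.approx(3.0)
        assert s.mean_P1 == 0.0 and s.mean_P3 == 0.0

    def test_volume_is_count_times_voxel_volume_on_default_spacing(self):
        grid = ReferenceGrid((6, 6, 6), (0.5, 0.5, 0.7))
        zeros = np.zeros((6, 6, 6))
        maps = self._maps(zeros, zeros, zeros, grid)
        vox = np.zeros((6, 6, 6), dtype=np.uint8)
        vox[1:4, 2, 3] = 1  # n = 3
        s = summarize(maps, pm.ThrombusMask(vox, grid), "p")
        assert s.n_voxels == 3
        assert s.volume_mm3 == pytest.approx(3 * 0.175)

    def test_mask_outside_valid_field_raises(self):
        grid = ReferenceGrid((3, 3, 3), (1, 1, 1))
        val = np.zeros((3, 3, 3), dtype=bool)
        val[0] = True
        maps = {
            k: pm.PerviousnessMap(k, np.zeros((3, 3, 3)), val, grid)
            for k in ("P1", "P2", "P3")
        }
        vox = np.zeros((3, 3, 3), dtype=np.uint8)
        vox[2, 2, 2] = 1
        with pytest.raises(ValidationError, match="valid field"):
            summarize(maps, pm.ThrombusMask(vox, grid), "p")


def brute_force_roi_mean(vol, roi):
    """Independent sphere-membership oracle: explicit voxel enumeration."""
    r = roi.diameter_mm / 2.0
    vals = []
    for i in range(vol.grid.shape[0]):
        for j in range(vol.grid.shape[1]):
            for k in range(vol.grid.shape[2]):
                w = vol.grid.index_to_world((i, j, k))
                if np.sum((w - np.asarray(roi.center_mm)) ** 2) <= r * r:
                    vals.append(vol.voxels[i, j, k])
    return float(np.mean(vals))


class TestScalarMeasures:
    def test_identical_volumes_give_zero_tai(self, rng):
        vox = rng.normal(50, 10, (12, 12, 12))
        ncct = make_volume(vox)
        cta = make_volume(vox.copy())
        rois = [SphericalROI((5.0, 5.0, 5.0), 2.0)]
        assert two_roi_tai(ncct, cta, rois) == pytest.approx(0.0)

    def test_constant_offset_gives_offset(self, rng):
        vox = rng.normal(50, 10, (12, 12, 12))
        ncct = make_volume(vox)
        cta = make_volume(vox + 15.0)
        rois = [SphericalROI((4.0, 5.0, 6.0), 2.0), SphericalROI((7.0, 6.0, 5.0), 1.5)]
        assert two_roi_tai(ncct, cta, rois) == pytest.approx(15.0)

    def test_roi_means_match_brute_force_oracle(self, rng):
        ncct = make_volume(rng.normal(50, 15, (10, 10, 10)))
        cta = make_volume(rng.normal(80, 15, (10, 10, 10)))
        rois = [
            SphericalROI((4.2, 5.1, 4.8), 2.0),
            SphericalROI((6.0, 4.0, 5.5), 1.6),
            SphericalROI((5.5, 6.2, 4.1), 1.2),
        ]
        expected = np.mean([brute_force_roi_mean(cta, r) for r in rois]) - np.mean(
            [brute_force_roi_mean(ncct, r) for r in rois]
        )
        assert two_roi_tai(ncct, cta, rois) == pytest.approx(expected, abs=1e-6)

    def test_roi_outside_volume_is_geometry_error(self, rng):
        vol = make_volume(rng.normal(0, 1, (6, 6, 6)))
        with pytest.raises(GeometryError):
            two_roi_tai(vol, vol, [SphericalROI((20.0, 3.0, 3.0), 2.0)])

    def test_whole_mask_tiling_equals_mask_mean(self, rng):
        """Scalar TAI from ROIs tiling the clot equals the P1 mask mean."""
        ncct = make_volume(rng.normal(50, 5, (14, 14, 14)))
        cta = make_volume(ncct.voxels + rng.uniform(1.0, 30.0, (14, 14, 14)))
        rois = [
            SphericalROI((4.0, 7.0, 7.0), 2.0),
            SphericalROI((7.0, 7.0, 7.0), 2.0),
            SphericalROI((10.0, 7.0, 7.0), 2.0),
        ]
        coords = ncct.grid.world_coordinates()
        members = []
        for roi in rois:
            d2 = ((coords - np.asarray(roi.center_mm)) ** 2).sum(axis=-1)
            members.append(d2 <= (roi.diameter_mm / 2) ** 2)
        sizes = {int(m.sum()) for m in members}
        assert len(sizes) == 1  # equal-size disjoint ROIs tile the mask
        mask_arr = np.logical_or.reduce(members)
        maps = compute_all_maps(ncct, cta, cta)
        s = summarize(
            maps,
            pm.ThrombusMask(mask_arr.astype(np.uint8), ncct.grid),
            "p",
        )
        assert s.mean_P1 == pytest.approx(two_roi_tai(ncct, cta, rois), abs=1e-9)

    @pytest.mark.parametrize(
        "d_thrombus,expected", [(200.0, 1.0), (0.0, 0.0), (20.0, 0.1)]
    )
    def test_void_fraction_limits(self, d_thrombus, expected):
        base = make_volume(np.full((10, 10, 10), 40.0))
        cta_vox = np.full((10, 10, 10), 40.0)
        cta_vox[:5] += d_thrombus  # clot half
        cta_vox[5:] += 200.0  # contralateral half
        cta = make_volume(cta_vox)
        thrombus = [SphericalROI((2.0, 5.0, 5.0), 2.0)]
        contra = [SphericalROI((7.5, 5.0, 5.0), 2.0)]
        assert void_fraction(base, cta, thrombus, contra) == pytest.approx(expected)

    def test_nonpositive_blood_delta_is_undefined(self):
        vol = make_volume(np.full((6, 6, 6), 40.0))
        rois = [SphericalROI((3.0, 3.0, 3.0), 2.0)]
        with pytest.raises(UndefinedRatioError):
            void_fraction(vol, vol, rois, rois)
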