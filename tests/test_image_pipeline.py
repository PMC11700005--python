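"""Voxel-wise map pipeline: averaging, normalization, contrast/ADC, ROI stats."""

import numpy as np
import pytest

from tddscope.image_pipeline import (
    DwImageSet,
    VolumeMeta,
    adc_map,
    contrast_map,
    direction_geomean,
    normalize_and_filter,
    read_bvals_bvecs,
    roi_stats,
)

SHAPE = (8, 8, 4)


def _meta(b, wid, td, direction=(1, 0, 0), polarity=1):
    return VolumeMeta(b=b, waveform_id=wid, td_ms=td, direction=direction,
                      polarity=polarity)


def _make_set(spec, shape=SHAPE):
    """spec: list of (meta, fill_value or array)."""
    vols, meta = [], []
    for m, v in spec:
        vols.append(np.full(shape, float(v)) if np.isscalar(v) else v)
        meta.append(m)
    return DwImageSet(data=np.stack(vols, axis=-1), meta=meta)


class TestDirectionGeomean:
    def test_identical_volumes_unchanged(self):
        spec = [(_meta(1000, "WF1", 26, (d, 0, 0)), 0.7) for d in (1, 2, 3)]
        s = _make_set(spec)
        np.testing.assert_allclose(direction_geomean(s, "WF1", 1000), 0.7)

    def test_two_directions_sqrt_product(self):
        s = _make_set(
            [
                (_meta(1000, "WF1", 26, (1, 0, 0)), 0.4),
                (_meta(1000, "WF1", 26, (0, 1, 0)), 0.9),
            ]
        )
        np.testing.assert_allclose(
            direction_geomean(s, "WF1", 1000), np.sqrt(0.4 * 0.9)
        )

    def test_background_gradient_polarity_cancellation(self):
        # signals exp(-b (D +/- eps)): the cross term cancels in the pair
        b, D, eps = 1.0, 2.0, 0.3
        s = _make_set(
            [
                (_meta(1000, "WF1", 26, (1, 0, 0), +1), np.exp(-b * (D + eps))),
                (_meta(1000, "WF1", 26, (1, 0, 0), -1), np.exp(-b * (D - eps))),
            ]
        )
        np.testing.assert_allclose(
            direction_geomean(s, "WF1", 1000), np.exp(-b * D), rtol=1e-12
        )

    def test_nonpositive_intensity_masked(self):
        vol = np.full(SHAPE, 0.5)
        vol[0, 0, 0] = -1.0
        s = _make_set([(_meta(1000, "WF1", 26), vol)])
        out = direction_geomean(s, "WF1", 1000)
        assert np.isnan(out[0, 0, 0]) and out[1, 1, 1] == pytest.approx(0.5)


class TestNormalizeAndFilter:
    def _basic_set(self, sb=0.5, s0=2.0):
        return _make_set(
            [
                (_meta(0, "WF1", 26), s0),
                (_meta(1000, "WF1", 26, (1, 0, 0)), s0 * sb),
                (_meta(1000, "WF1", 26, (0, 1, 0)), s0 * sb),
            ]
        )

    def test_b0_normalization(self):
        norm = normalize_and_filter(self._basic_set(sb=0.5))
        assert norm.normalized
        np.testing.assert_allclose(norm.data[..., 0], 0.5)

    def test_idempotent(self):
        norm = normalize_and_filter(self._basic_set())
        again = normalize_and_filter(norm)
        assert again is norm

    def test_missing_b0_rejected(self):
        s = _make_set([(_meta(1000, "WF1", 26), 0.5)])
        with pytest.raises(ValueError, match="b=0"):
            normalize_and_filter(s)

    def test_median_filter_removes_impulse(self):
        vol = np.full(SHAPE, 1.0)
        vol[4, 4, 2] = 50.0
        s = _make_set([(_meta(0, "WF1", 26), 2.0), (_meta(1000, "WF1", 26), vol)])
        norm = normalize_and_filter(s)
        assert norm.data[4, 4, 2, 0] == pytest.approx(0.5)

    def test_constant_image_unchanged_by_filter(self):
        norm = normalize_and_filter(self._basic_set(sb=0.8))
        np.testing.assert_allclose(norm.data[..., 0], 0.8)

    def test_supersampled_filter_matches_on_constant(self):
        norm = normalize_and_filter(self._basic_set(sb=0.8), supersample=2)
        np.testing.assert_allclose(norm.data[..., 0], 0.8)


class TestContrastMap:
    def _norm_set(self, s1=0.4, s3=0.55):
        return _make_set(
            [
                (_meta(0, "WF1", 26), 1.0),
                (_meta(2500, "WF1", 26), s1),
                (_meta(0, "WF3", 80), 1.0),
                (_meta(2500, "WF3", 80), s3),
            ]
        )

    def test_voxelwise_difference(self):
        norm = normalize_and_filter(self._norm_set())
        cmap = contrast_map(norm, ("WF3", "WF1"), 2500)
        np.testing.assert_allclose(cmap, 0.15, atol=1e-12)

    def test_antisymmetry_is_guarded_by_ordering(self):
        norm = normalize_and_filter(self._norm_set())
        with pytest.raises(ValueError, match="ordering"):
            contrast_map(norm, ("WF1", "WF3"), 2500)

    def test_water_region_near_zero(self):
        norm = normalize_and_filter(self._norm_set(s1=0.37, s3=0.37))
        cmap = contrast_map(norm, ("WF3", "WF1"), 2500)
        np.testing.assert_allclose(cmap, 0.0, atol=1e-12)

    def test_requires_normalized_input(self):
        with pytest.raises(ValueError, match="normalized"):
            contrast_map(self._norm_set(), ("WF3", "WF1"), 2500)


class TestAdcMap:
    def test_exact_exponential_recovery(self):
        adc_true = 1.0e-3  # mm^2/s
        spec = [(_meta(0, "WF1", 26), 1.0)]
        for b in (500, 1000, 2000):
            spec.append((_meta(b, "WF1", 26), np.exp(-b * adc_true)))
        norm = normalize_and_filter(_make_set(spec))
        adc = adc_map(norm, "WF1")
        np.testing.assert_allclose(adc, adc_true, rtol=1e-9)

    def test_nonpositive_voxels_masked(self):
        vol = np.full(SHAPE, np.exp(-1.0))
        vol[2, 2, 2] = -0.5
        spec = [(_meta(0, "WF1", 26), 1.0), (_meta(1000, "WF1", 26), vol)]
        norm = normalize_and_filter(_make_set(spec))
        # the impulse is repaired by the median filter; bypass it to test the
        # fit guard directly
        norm.data[2, 2, 2, 0] = np.nan
        adc = adc_map(norm, "WF1")
        assert np.isnan(adc[2, 2, 2])
        assert adc[0, 0, 0] == pytest.approx(1.0e-3, rel=1e-9)


class TestRoiStats:
    def test_no_exclusion_on_uniformish_data(self):
        vals = np.arange(1.0, 11.0)
        vol = np.pad(vals, (0, 6)).reshape(4, 4, 1)
        mask = np.zeros_like(vol, dtype=bool)
        mask.flat[:10] = True
        st = roi_stats(vol, mask)
        assert st.mean == pytest.approx(5.5)
        assert st.n_before == st.n_after == 10

    def test_tukey_fence_excludes_outlier(self):
        vals = np.concatenate([np.arange(1.0, 11.0), [100.0]])
        vol = np.pad(vals, (0, 5)).reshape(4, 4, 1)
        mask = np.zeros_like(vol, dtype=bool)
        mask.flat[:11] = True
        st = roi_stats(vol, mask)
        assert st.n_before == 11 and st.n_after == 10
        assert st.mean == pytest.approx(5.5)

    def test_constant_roi_zero_sd(self):
        vol = np.full(SHAPE, 0.3)
        mask = np.zeros(SHAPE, dtype=bool)
        mask[:2] = True
        st = roi_stats(vol, mask)
        assert st.sd == 0.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_stats(np.ones(SHAPE), np.zeros(SHAPE, dtype=bool))


class TestIO:
    def test_nifti_sidecar_roundtrip(self, tmp_path):
        s = _make_set(
            [
                (_meta(0, "WF1", 26), 2.0),
                (_meta(1000, "WF1", 26, (0.707107, 0.707107, 0)), 1.0),
            ]
        )
        s.save(tmp_path / "dwi")
        back = DwImageSet.load(tmp_path / "dwi")
        np.testing.assert_allclose(back.data, s.data, rtol=1e-6)
        assert back.meta[1].b == 1000
        assert back.meta[1].waveform_id == "WF1"

    def test_fsl_bval_bvec_reader(self, tmp_path):
        (tmp_path / "b.bval").write_text("0 1000 1000\n")
        (tmp_path / "b.bvec").write_text(
            "1 0 0\n0 1 0\n0 0 1\n"
        )
        bvals, bvecs = read_bvals_bvecs(tmp_path / "b.bval", tmp_path / "b.bvec")
        assert bvals.tolist() == [0.0, 1000.0, 1000.0]
        assert bvecs.shape == (3, 3)
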