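"""Segmentation handling: 2D ROI rule, normalization, quantization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prostarad.grid import Volume, VolumeGrid
from prostarad.roi import (
    NormalizedRegion,
    SegmentationRecord,
    extract_2d_roi,
    normalize_intensities,
    quantize,
    quantize_volume,
)


def make_record(mask, spacing=(1.0, 1.0, 1.0), label="lesion", dim="3D"):
    grid = VolumeGrid(mask.shape, spacing)
    return SegmentationRecord("s0_voi0", "s0", label, Volume(mask, grid), dim=dim)


def region_stats(values):
    """NormalizedRegion with the mu +/- 3 sigma clamp applied to raw values."""
    values = np.asarray(values, dtype=float)
    mu, sigma = values.mean(), values.std()
    lo, hi = (mu - 3 * sigma, mu + 3 * sigma) if sigma > 0 else (mu, mu)
    return NormalizedRegion(np.clip(values, lo, hi), mu, sigma, lo, hi)


def ellipsoid_mask(shape, spacing, center_mm, semiaxes_mm):
    idx = np.indices(shape, dtype=float)
    rel = [
        (idx[a] * spacing[a] - center_mm[a]) / semiaxes_mm[a] for a in range(3)
    ]
    return rel[0] ** 2 + rel[1] ** 2 + rel[2] ** 2 <= 1.0


class TestExtract2dRoi:
    def test_single_slice_voi_returns_that_slice(self):
        mask = np.zeros((6, 6, 5), dtype=bool)
        mask[2:4, 2:4, 3] = True
        roi = extract_2d_roi(make_record(mask))
        assert roi.dim == "2D"
        assert roi.slice_index == 3
        assert np.array_equal(roi.mask.data, mask)

    def test_equatorial_slice_of_ellipsoid(self):
        # in-plane extent is maximal where the ellipsoid is widest
        shape, spacing = (24, 24, 11), (1.0, 1.0, 3.0)
        mask = ellipsoid_mask(shape, spacing, (12.0, 12.0, 15.0), (8.0, 5.0, 7.0))
        roi = extract_2d_roi(make_record(mask, spacing))
        assert roi.slice_index == 5  # z = 15 mm
        assert mask[:, :, 5].sum() == roi.n_voxels

    def test_tie_broken_to_lower_slice(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:4, 2, 1] = True
        mask[1:4, 2, 4] = True
        roi = extract_2d_roi(make_record(mask))
        assert roi.slice_index == 1

    def test_anisotropic_spacing_changes_winner(self):
        # 3 pixels along x vs 2 along y: physical spacing decides
        mask = np.zeros((8, 8, 2), dtype=bool)
        mask[1:4, 1, 0] = True      # length 2 * sx
        mask[1, 1:3, 1] = True      # length 1 * sy
        roi_iso = extract_2d_roi(make_record(mask, (1.0, 1.0, 1.0)))
        assert roi_iso.slice_index == 0
        roi_aniso = extract_2d_roi(make_record(mask, (1.0, 3.0, 1.0)))
        assert roi_aniso.slice_index == 1

    def test_invariant_to_storage_order(self):
        rng = np.random.default_rng(3)
        mask = rng.random((10, 9, 7)) < 0.3
        mask[4, 4, 3] = True  # non-empty
        a = extract_2d_roi(make_record(mask.copy()))
        b = extract_2d_roi(make_record(np.asfortranarray(mask)))
        assert a.slice_index == b.slice_index

    def test_requires_3d_record(self):
        mask = np.zeros((4, 4, 3), dtype=bool)
        mask[1:3, 1:3, 1] = True
        rec = make_record(mask, dim="2D")
        with pytest.raises(ValueError):
            extract_2d_roi(rec)


class TestSegmentationRecord:
    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_record(np.zeros((4, 4, 4), dtype=bool))

    def test_2d_record_must_live_on_one_slice(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = mask[1, 1, 2] = True
        with pytest.raises(ValueError):
            make_record(mask, dim="2D")

    def test_outcome_coding(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        assert make_record(mask, label="lesion").outcome == 1
        assert make_record(mask, label="healthy").outcome == 0


class TestNormalize:
    def test_constant_region_returned_unchanged(self):
        mask = np.ones((3, 3, 1), dtype=bool)
        vol = Volume(np.full((3, 3, 1), 7.0), VolumeGrid((3, 3, 1)))
        region = normalize_intensities(vol, make_record(mask))
        assert region.sigma == 0.0
        assert region.lo == region.hi == 7.0
        assert np.all(region.values == 7.0)

    def test_outlier_clamped_to_mu_plus_3sigma(self, rng):
        vals = rng.standard_normal(1000)
        mu, sigma = vals.mean(), vals.std()
        vals = np.append(vals, mu + 10 * sigma)
        vol = Volume(vals.reshape(-1, 1, 1), VolumeGrid((1001, 1, 1)))
        region = normalize_intensities(vol, make_record(np.ones((1001, 1, 1), dtype=bool)))
        assert region.values.max() == pytest.approx(region.hi)
        assert region.hi == pytest.approx(region.mu + 3 * region.sigma)
        assert len(region.values) == 1001

    def test_population_sigma_used(self):
        vals = np.array([0.0, 2.0]).reshape(2, 1, 1)
        region = normalize_intensities(
            Volume(vals, VolumeGrid((2, 1, 1))), make_record(np.ones((2, 1, 1), dtype=bool))
        )
        assert region.sigma == pytest.approx(1.0)  # 1/N, not 1/(N-1)


class TestQuantize:
    def test_endpoints_map_to_extreme_levels(self):
        region = NormalizedRegion(np.array([0.0, 1.0]), 0.5, 0.5, 0.0, 1.0)
        assert list(quantize(region, 2)) == [1, 2]

    def test_uniform_grid_hits_each_level_once(self):
        vals = np.linspace(0.0, 1.0, 256)
        region = NormalizedRegion(vals, 0.5, 0.3, 0.0, 1.0)
        q = quantize(region, 256)
        assert np.array_equal(np.sort(q), np.arange(1, 257))

    def test_constant_region_all_level_one(self):
        region = NormalizedRegion(np.full(9, 4.2), 4.2, 0.0, 4.2, 4.2)
        assert np.all(quantize(region, 32) == 1)

    def test_rejects_single_level(self):
        region = NormalizedRegion(np.array([0.0, 1.0]), 0.5, 0.5, 0.0, 1.0)
        with pytest.raises(ValueError):
            quantize(region, 1)

    def test_histogram_conserves_counts(self, rng):
        mask = rng.random((7, 7, 5)) < 0.4
        mask[3, 3, 2] = True
        vol = Volume(rng.normal(size=(7, 7, 5)), VolumeGrid((7, 7, 5)))
        q = quantize_volume(vol, make_record(mask), 32)
        assert (q > 0).sum() == mask.sum()
        counts = np.bincount(q[mask], minlength=33)[1:]
        assert counts.sum() == mask.sum()

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        vals=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
            min_size=2,
            max_size=60,
        ),
        levels=st.integers(2, 64),
    )
    def test_levels_always_in_range_and_counts_conserved(self, vals, levels):
        region = region_stats(np.asarray(vals))
        q = quantize(region, levels)
        assert len(q) == len(vals)
        assert q.min() >= 1 and q.max() <= levels
        assert np.bincount(q, minlength=levels + 1)[1:].sum() == len(vals)

    def test_affine_intensity_map_leaves_levels_unchanged(self, rng):
        mask = rng.random((6, 6, 4)) < 0.5
        mask[2, 2, 2] = True
        data = rng.normal(size=(6, 6, 4))
        g = VolumeGrid((6, 6, 4))
        rec = make_record(mask)
        q1 = quantize_volume(Volume(data, g), rec, 32)
        q2 = quantize_volume(Volume(2.5 * data + 17.0, g), rec, 32)
        assert np.array_equal(q1, q2)
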