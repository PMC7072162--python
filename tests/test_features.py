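"""Radiomic feature computation against brute-force oracles."""

import numpy as np
import pytest

from prostarad.features import (
    FIRST_ORDER_NAMES,
    GLCM_NAMES,
    build_glcm,
    extract_feature_table,
    feature_catalog,
    first_order_features,
    glcm_features,
    segmentation_features,
)
from prostarad.grid import Volume, VolumeGrid
from prostarad.roi import NormalizedRegion, normalize_intensities, quantize_volume
from test_roi import make_record

from _naive import naive_first_order, naive_glcm, naive_glcm_features


def region_from(values):
    values = np.asarray(values, dtype=float)
    mu, sigma = values.mean(), values.std()
    lo, hi = (mu - 3 * sigma, mu + 3 * sigma) if sigma > 0 else (mu, mu)
    return NormalizedRegion(np.clip(values, lo, hi), mu, sigma, lo, hi)


class TestFirstOrder:
    def test_constant_region_degenerate_values(self):
        f = first_order_features(region_from(np.full(20, 5.0)))
        assert f["variance"] == 0.0
        assert f["entropy"] == 0.0
        assert f["uniformity"] == 1.0
        assert f["max"] == f["mean"] == f["median"] == f["min"] == 5.0
        assert f["skewness"] == 0.0 and f["kurtosis"] == 0.0

    def test_one_to_eight_arithmetic(self):
        f = first_order_features(region_from(np.arange(1.0, 9.0)))
        assert f["mean"] == pytest.approx(4.5)
        assert f["variance"] == pytest.approx(5.25)
        assert f["mad"] == pytest.approx(2.0)
        assert f["energy"] == pytest.approx(204.0)
        assert f["rms"] == pytest.approx(np.sqrt(25.5))
        assert f["max"] == 8.0 and f["min"] == 1.0 and f["median"] == 4.5

    def test_two_equal_mass_bins(self):
        f = first_order_features(region_from(np.repeat([0.0, 1.0], 500)), nbins=2)
        assert f["entropy"] == pytest.approx(1.0)
        assert f["uniformity"] == pytest.approx(0.5)

    def test_catalog_size(self):
        f = first_order_features(region_from(np.arange(10.0)))
        assert len(f) == 13
        assert set(f) == set(FIRST_ORDER_NAMES)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        region = region_from(rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 4), 150))
        ours = first_order_features(region)
        ref = naive_first_order(region.values, region.lo, region.hi)
        for name in FIRST_ORDER_NAMES:
            assert ours[name] == pytest.approx(ref[name], rel=1e-10, abs=1e-12), name

    def test_affine_invariance_of_shape_statistics(self, rng):
        x = rng.normal(size=300)
        f1 = first_order_features(region_from(x))
        f2 = first_order_features(region_from(3.0 * x + 10.0))
        for name in ("entropy", "uniformity", "skewness", "kurtosis"):
            assert f1[name] == pytest.approx(f2[name], rel=1e-9)
        assert f2["mean"] == pytest.approx(3.0 * f1["mean"] + 10.0, rel=1e-9)
        assert f2["std"] == pytest.approx(3.0 * f1["std"], rel=1e-9)


class TestGlcm:
    def test_constant_region_is_point_mass(self):
        q = np.ones((3, 3, 3), dtype=np.int64)
        P = build_glcm(q, np.ones((3, 3, 3), dtype=bool), levels=4)
        assert P[0, 0] == 1.0
        assert P.sum() == 1.0

    def test_2x2_slab_hand_counts(self):
        # levels [[1,1],[1,2]]: 12 symmetrized in-plane pairs,
        # 6 of (1,1) and 3 each of (1,2)/(2,1)
        q = np.zeros((2, 2, 1), dtype=np.int64)
        q[:, :, 0] = [[1, 1], [1, 2]]
        P = build_glcm(q, np.ones((2, 2, 1), dtype=bool), levels=2)
        assert P[0, 0] == pytest.approx(6 / 12)
        assert P[0, 1] == pytest.approx(3 / 12)
        assert P[1, 0] == pytest.approx(3 / 12)
        assert P[1, 1] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_triple_loop_oracle_3d(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.integers(1, 9, (5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.7
        mask[2, 2, 2] = True
        q = np.where(mask, q, 0)
        ours = build_glcm(q, mask, levels=8)
        ref = naive_glcm(q, mask, levels=8)
        assert np.allclose(ours, ref, atol=1e-12)

    def test_matches_triple_loop_oracle_2d(self, rng):
        q = rng.integers(1, 5, (6, 6, 1))
        mask = np.ones((6, 6, 1), dtype=bool)
        ours = build_glcm(q, mask, levels=4)
        ref = naive_glcm(q, mask, levels=4, planar=True)
        assert np.allclose(ours, ref, atol=1e-12)

    def test_symmetry_and_normalization(self, rng):
        q = rng.integers(1, 33, (8, 8, 6))
        mask = rng.random((8, 8, 6)) < 0.6
        mask[4, 4, 3] = True
        q = np.where(mask, q, 0)
        P = build_glcm(q, mask, levels=32)
        assert np.allclose(P, P.T)
        assert P.sum() == pytest.approx(1.0)
        feats = glcm_features(P)
        assert feats["entropy"] <= 2 * np.log2(32) + 1e-12
        assert 0 < feats["energy"] <= 1

    def test_single_voxel_degenerate_conventions(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        q = np.where(mask, 5, 0)
        P = build_glcm(q, mask, levels=8)
        assert P.sum() == 0.0
        f = glcm_features(P)
        assert f["energy"] == 1.0 and f["homogeneity"] == 1.0
        assert all(f[n] == 0.0 for n in GLCM_NAMES if n not in ("energy", "homogeneity"))


class TestGlcmFeatures:
    def test_point_mass(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        f = glcm_features(P)
        assert f["energy"] == 1.0
        assert f["contrast"] == 0.0
        assert f["entropy"] == 0.0
        assert f["homogeneity"] == 1.0
        assert f["sum_average"] == 2.0
        assert f["autocorrelation"] == 1.0
        assert f["correlation"] == 0.0  # zero marginal variance, flagged convention

    def test_uniform_matrix(self):
        L = 8
        P = np.full((L, L), 1.0 / L**2)
        f = glcm_features(P)
        assert f["energy"] == pytest.approx(1.0 / L**2)
        assert f["entropy"] == pytest.approx(2 * np.log2(L))

    def test_hand_matrix_against_naive_sums(self, rng):
        P = rng.random((3, 3))
        P = P + P.T
        P = P / P.sum()
        ours = glcm_features(P)
        ref = naive_glcm_features(P)
        for name in GLCM_NAMES:
            assert ours[name] == pytest.approx(ref[name], rel=1e-10), name

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            glcm_features(np.ones((3, 3)))


class TestFeatureTable:
    def test_catalog_counts(self):
        assert len(feature_catalog("std3D")) == 44
        assert len(feature_catalog("adv3D")) == 104
        assert len(feature_catalog("adv2D")) == 104
        with pytest.raises(ValueError):
            feature_catalog("nope")

    def test_missing_map_failure_names_the_map(self):
        mask = np.zeros((5, 5, 3), dtype=bool)
        mask[1:4, 1:4, 1] = True
        rec = make_record(mask)
        maps = {"T2W": Volume(np.random.default_rng(0).normal(size=(5, 5, 3)), rec.mask.grid)}
        with pytest.raises(KeyError, match="ADC"):
            segmentation_features(maps, rec, "std3D")

    def test_table_shapes_and_labels(self, tiny_cohort, tiny_maps):
        table = extract_feature_table(tiny_maps, tiny_cohort.segmentations, "std3D")
        assert table.shape == (9, 45)  # 44 features + label
        assert set(table["label"]) == {0, 1}
        assert np.isfinite(table.drop(columns="label").to_numpy()).all()

    def test_adv2d_uses_single_slice(self, tiny_cohort, tiny_maps):
        seg = tiny_cohort.segmentations[0]
        maps = tiny_maps[seg.subject_id]
        f3 = segmentation_features(maps, seg, "adv3D")
        f2 = segmentation_features(maps, seg, "adv2D")
        assert len(f3) == len(f2) == 104
        # 2D region is a subset of the VOI: energy (a sum) cannot exceed it
        assert f2["T2W.first.energy"] <= f3["T2W.first.energy"]
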