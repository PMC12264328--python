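"""Preprocessing and 105-feature extraction contracts."""

import numpy as np
import pytest

from radstab.errors import DegenerateInputError, ParameterError
from radstab.radfeat import (
    FEATURE_NAMES,
    RadiomicsConfig,
    discretize,
    extract_feature_table,
    extract_features,
    feature_manifest,
    intensity_window,
    preprocess_for_radiomics,
)


def ellipsoid_mask(shape, radii, spacing=(1.0, 1.0, 1.0)):
    zz, yy, xx = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing[::-1])], indexing="ij"
    )
    c = [0.5 * n * s for n, s in zip(shape, spacing[::-1])]
    return (
        ((zz - c[0]) / radii[0]) ** 2
        + ((yy - c[1]) / radii[1]) ** 2
        + ((xx - c[2]) / radii[2]) ** 2
    ) <= 1.0


class TestIntensityWindow:
    def test_rescale_contract(self, rng):
        x = rng.normal(50, 10, size=(4, 8, 8))
        w = intensity_window(x)
        assert w.min() == pytest.approx(0.0)
        assert w.max() == pytest.approx(255.0)

    def test_clamp_above_upper_bound(self, rng):
        x = rng.normal(0, 1, size=1000)
        x[0] = 1e6  # far above mu + 4 sigma
        w = intensity_window(x)
        assert w[0] == pytest.approx(255.0)

    def test_five_voxel_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 100.0])
        mu, sd = x.mean(), x.std()
        lo, hi = mu - 0.5 * sd, mu + 4.0 * sd
        clipped = [min(max(v, lo), hi) for v in x]  # brute-force clamp
        cmin, cmax = min(clipped), max(clipped)
        expected = [(v - cmin) / (cmax - cmin) * 255.0 for v in clipped]
        assert np.allclose(intensity_window(x), expected)

    def test_constant_image_maps_to_zero(self):
        assert np.all(intensity_window(np.full(10, 7.0)) == 0.0)


class TestPreprocess:
    def test_identity_resample_and_zscore(self, rng):
        cfg = RadiomicsConfig()
        img = rng.normal(100, 20, size=(4, 10, 10))
        mask = np.zeros_like(img, bool)
        mask[1:3, 3:7, 3:7] = True
        out, m, sp = preprocess_for_radiomics(img, mask, cfg, cfg.target_spacing)
        assert out.shape == img.shape and np.array_equal(m, mask)
        assert abs(out.mean()) <= 1e-9 and abs(out.std() - 1) <= 1e-9

    def test_downsample_preserves_mask_volume(self):
        # nearest-neighbour 2x downsampling of a solid box keeps the
        # physical volume within one boundary voxel layer (counting oracle)
        cfg = RadiomicsConfig(target_spacing=(2.0, 2.0, 2.0), normalization=False)
        mask = np.zeros((8, 20, 20), bool)
        mask[2:6, 4:16, 4:16] = True
        img = np.random.default_rng(0).normal(size=mask.shape)
        _, m2, _ = preprocess_for_radiomics(img, mask, cfg, (1.0, 1.0, 1.0))
        vol_in = mask.sum() * 1.0
        vol_out = m2.sum() * 8.0
        boundary = mask & ~np.pad(mask, 1)[2:, 1:-1, 1:-1]  # one-layer bound
        layer = (mask.sum() - np.count_nonzero(
            np.logical_and.reduce(
                [mask, np.roll(mask, 1, 0), np.roll(mask, -1, 0)]
            )
        )) * 8.0
        assert abs(vol_out - vol_in) <= max(layer, 8.0 * boundary.sum())

    def test_discretize_bin_count(self, rng):
        lev = discretize(rng.normal(size=500), 64)
        assert lev.min() >= 1 and lev.max() <= 64
        assert len(np.unique(lev)) <= 64

    def test_empty_roi_signalled(self, rng):
        cfg = RadiomicsConfig()
        img = rng.normal(size=(3, 6, 6))
        with pytest.raises(DegenerateInputError):
            preprocess_for_radiomics(img, np.zeros_like(img, bool), cfg,
                                     cfg.target_spacing)


class TestExtractFeatures:
    def test_roster_is_105_and_finite(self, rng):
        mask = ellipsoid_mask((8, 24, 24), (3.0, 8.0, 8.0))
        img = rng.normal(0, 1, size=mask.shape)
        feats = extract_features(img, mask, spacing=(1.0, 1.0, 1.0))
        assert len(feats) == 105
        assert tuple(feats) == FEATURE_NAMES
        assert all(np.isfinite(v) for v in feats.values())

    def test_deterministic(self, rng):
        mask = ellipsoid_mask((6, 16, 16), (2.5, 6.0, 6.0))
        img = rng.normal(size=mask.shape)
        a = extract_features(img, mask, spacing=(1.0, 1.0, 1.0))
        b = extract_features(img.copy(), mask.copy(), spacing=(1.0, 1.0, 1.0))
        assert a == b

    def test_constant_roi_texture_limits(self):
        mask = ellipsoid_mask((6, 16, 16), (2.5, 6.0, 6.0))
        img = np.where(mask, 5.0, 0.0)
        feats = extract_features(img, mask, spacing=(1.0, 1.0, 1.0))
        assert feats["firstorder_Variance"] == 0.0
        assert feats["glcm_Contrast"] == 0.0

    def test_slice_averaging_contract(self):
        mask = np.zeros((2, 6, 6), bool)
        mask[:, 1:5, 1:5] = True
        img = np.zeros((2, 6, 6))
        img[0] = 10.0
        img[1] = 20.0
        feats = extract_features(img, mask, spacing=(1.0, 1.0, 1.0))
        assert feats["firstorder_Mean"] == pytest.approx(15.0)

    def test_mesh_volume_scales_cubically(self):
        small = ellipsoid_mask((16, 32, 32), (4.0, 9.0, 9.0))
        big = ellipsoid_mask((32, 64, 64), (8.0, 18.0, 18.0))
        rng = np.random.default_rng(1)
        fs = extract_features(rng.normal(size=small.shape), small,
                              spacing=(1.0, 1.0, 1.0))
        fb = extract_features(rng.normal(size=big.shape), big,
                              spacing=(1.0, 1.0, 1.0))
        assert fb["shape_MeshVolume"] == pytest.approx(
            8.0 * fs["shape_MeshVolume"], rel=0.05
        )

    def test_mesh_volume_monotone_under_nesting(self, rng):
        from scipy import ndimage

        mask = ellipsoid_mask((8, 24, 24), (3.0, 9.0, 9.0))
        img = rng.normal(size=mask.shape)
        vols = []
        for _ in range(3):
            f = extract_features(img, mask, spacing=(1.0, 1.0, 1.0))
            vols.append(f["shape_MeshVolume"])
            mask = ndimage.binary_erosion(mask)
        assert vols[0] >= vols[1] >= vols[2]

    def test_mean_invariant_to_outside_intensities(self, rng):
        mask = ellipsoid_mask((6, 16, 16), (2.5, 6.0, 6.0))
        img = rng.normal(size=mask.shape)
        img2 = img.copy()
        img2[~mask] = rng.normal(100, 50, size=(~mask).sum())
        a = extract_features(img, mask, spacing=(1.0, 1.0, 1.0))
        b = extract_features(img2, mask, spacing=(1.0, 1.0, 1.0))
        assert a["firstorder_Mean"] == b["firstorder_Mean"]
        assert a["firstorder_Median"] == b["firstorder_Median"]

    def test_empty_mask_raises(self, rng):
        with pytest.raises(DegenerateInputError):
            extract_features(rng.normal(size=(3, 6, 6)),
                             np.zeros((3, 6, 6), bool))

    def test_single_voxel_roi_signals_undefined_not_zero(self, rng):
        mask = np.zeros((3, 6, 6), bool)
        mask[1, 3, 3] = True
        feats = extract_features(rng.normal(size=(3, 6, 6)), mask,
                                 spacing=(1.0, 1.0, 1.0))
        assert np.isnan(feats["glcm_Contrast"])  # no co-occurring pairs
        assert np.isfinite(feats["firstorder_Mean"])

    def test_manifest_roundtrip(self):
        import json

        m = json.loads(feature_manifest())
        assert m["n_features"] == 105
        assert m["features"] == list(FEATURE_NAMES)

    def test_bad_config_rejected(self):
        with pytest.raises(ParameterError):
            RadiomicsConfig(n_bins=1)
        with pytest.raises(ParameterError):
            RadiomicsConfig(categories=("shape", "wavelet"))


class TestFeatureTable:
    def test_table_keys_and_columns(self, tiny_cohort):
        table = extract_feature_table(
            tiny_cohort[:4], {"GT": [s.gt_mask for s in tiny_cohort[:4]]}
        )
        assert len(table) == 4
        assert set(FEATURE_NAMES) <= set(table.columns)
        assert table["mask_source"].unique().tolist() == ["GT"]
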