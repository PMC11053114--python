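"""Feature formula edge cases, independent formula evaluation, tiling behaviour."""

import numpy as np
import pytest

from deltarad import texture
from deltarad.preprocessing import QuantizationConfig
from deltarad.types import ROIMask, VolumeImage

from conftest import line_roi, make_quantized
from _oracles import random_quantized_roi

ISO = (1.0, 1.0, 1.0)


class TestGLCMFeatures:
    def test_perfect_diagonal_matrix_correlation_one(self):
        n = 4
        m = texture.TextureMatrix(kind="GLCM", matrix=np.eye(n) / n)
        assert texture.glcm_features(m)["GLCM_Correlation"] == pytest.approx(1.0)

    def test_flat_texture_correlation_missing(self):
        q = make_quantized(np.ones((2, 3, 2), int))
        feats = texture.glcm_features(texture.glcm(q, 1))
        assert np.isnan(feats["GLCM_Correlation"])

    def test_toy_matrix_matches_direct_formulas(self):
        rng = np.random.default_rng(0)
        p = rng.random((4, 4))
        p = (p + p.T) / 2
        p /= p.sum()
        feats = texture.glcm_features(texture.TextureMatrix(kind="GLCM", matrix=p))
        i = np.arange(1, 5)
        px = p.sum(axis=1)
        mu = (i * px).sum()
        var = ((i - mu) ** 2 * px).sum()
        num = sum(
            ii * jj * p[ii - 1, jj - 1] for ii in i for jj in i
        ) - mu**2
        assert feats["GLCM_Correlation"] == pytest.approx(num / var)
        assert feats["GLCM_Contrast"] == pytest.approx(
            sum((ii - jj) ** 2 * p[ii - 1, jj - 1] for ii in i for jj in i)
        )
        assert feats["GLCM_Energy"] == pytest.approx((p**2).sum())
        assert feats["GLCM_Entropy"] == pytest.approx(-(p * np.log2(p)).sum())


class TestGLRLMFeatures:
    def test_single_run_normalizations_are_one(self):
        m = texture.TextureMatrix(kind="GLRLM", matrix=np.array([[0, 0, 1]]))
        feats = texture.glrlm_features(m, n_voxels=3)
        assert feats["GLRLM_GLN"] == pytest.approx(1.0)
        assert feats["GLRLM_RLN"] == pytest.approx(1.0)

    def test_two_equal_runs_different_levels(self):
        # r = {(level1, len2): 1, (level2, len2): 1} -> GLN = 1, RLN = 2
        m = texture.TextureMatrix(kind="GLRLM", matrix=np.array([[0, 1], [0, 1]]))
        feats = texture.glrlm_features(m, n_voxels=4)
        assert feats["GLRLM_GLN"] == pytest.approx(1.0)
        assert feats["GLRLM_RLN"] == pytest.approx(2.0)

    def test_random_matrix_matches_direct_formulas(self):
        rng = np.random.default_rng(1)
        r = rng.integers(0, 5, size=(5, 4)).astype(float)
        r[0, 0] += 1
        feats = texture.glrlm_features(texture.TextureMatrix(kind="GLRLM", matrix=r), 30)
        nr = r.sum()
        i = np.arange(1, 6)[:, None]
        j = np.arange(1, 5)[None, :]
        assert feats["GLRLM_SRE"] == pytest.approx((r / j**2).sum() / nr)
        assert feats["GLRLM_LRE"] == pytest.approx((r * j**2).sum() / nr)
        assert feats["GLRLM_GLN"] == pytest.approx((r.sum(1) ** 2).sum() / nr)
        assert feats["GLRLM_RLN"] == pytest.approx((r.sum(0) ** 2).sum() / nr)
        assert feats["GLRLM_HGRE"] == pytest.approx((r * i**2).sum() / nr)


class TestGLSZMFeatures:
    def test_all_unit_zones_zone_percentage_one(self):
        arr = np.arange(1, 9).reshape(2, 2, 2)
        q = make_quantized(arr)
        feats = texture.glszm_features(texture.glszm(q), q.n_voxels)
        assert feats["GLSZM_ZP"] == pytest.approx(1.0)

    def test_single_zone_has_zero_size_variance(self):
        q = make_quantized(np.ones((1, 2, 2), int))
        feats = texture.glszm_features(texture.glszm(q), 4)
        assert feats["GLSZM_ZSV"] == pytest.approx(0.0)

    def test_random_matrix_matches_direct_formulas(self):
        rng = np.random.default_rng(2)
        z = rng.integers(0, 4, size=(4, 6)).astype(float)
        z[1, 2] += 1
        feats = texture.glszm_features(texture.TextureMatrix(kind="GLSZM", matrix=z), 50)
        nz = z.sum()
        i = np.arange(1, 5)[:, None]
        j = np.arange(1, 7)[None, :]
        pj = z / nz
        mu = (pj * j).sum()
        assert feats["GLSZM_ZSV"] == pytest.approx((pj * (j - mu) ** 2).sum())
        assert feats["GLSZM_LZHGE"] == pytest.approx((z * i**2 * j**2).sum() / nz)
        assert feats["GLSZM_SZLGE"] == pytest.approx((z / (i**2 * j**2)).sum() / nz)
        assert feats["GLSZM_ZP"] == pytest.approx(nz / 50)


class TestNGTDMFeatures:
    def test_constant_roi_degenerate_conventions(self):
        q = make_quantized(np.ones((2, 3, 2), int))
        feats = texture.ngtdm_features(texture.ngtdm(q), q.n_voxels)
        assert feats["NGTDM_Coarseness"] == texture.COARSENESS_CAP
        assert feats["NGTDM_Contrast"] == 0.0

    def test_two_level_line_matches_hand_evaluation(self):
        # from the [1,2,1] line: n=(2,1), s=(2,1), p=(2/3,1/3), N=3, Ng=2
        q = line_roi([1, 2, 1])
        feats = texture.ngtdm_features(texture.ngtdm(q), 3)
        ps = 2 / 3 * 2 + 1 / 3 * 1
        assert feats["NGTDM_Coarseness"] == pytest.approx(1 / ps)
        # contrast: [1/(Ng(Ng-1)) * sum p_i p_j (i-j)^2] * [sum s / N]
        contrast = (2 * (2 / 3) * (1 / 3) * 1) / 2 * (3 / 3)
        assert feats["NGTDM_Contrast"] == pytest.approx(contrast)
        # busyness denominator sum|i p_i - j p_j| vanishes here (1*2/3 == 2*1/3)
        assert feats["NGTDM_Busyness"] == 0.0
        strength = (2 * ((2 / 3) + (1 / 3)) * 1) / 3.0
        assert feats["NGTDM_Strength"] == pytest.approx(strength)

    def test_random_roi_matches_formula_oracle(self):
        rng = np.random.default_rng(3)
        levels, mask = random_quantized_roi(rng, max_shape=(5, 5, 3))
        q = make_quantized(levels, mask)
        m = texture.ngtdm(q)
        feats = texture.ngtdm_features(m, q.n_voxels)
        present = m.p_i > 0
        lv = np.arange(1, len(m.p_i) + 1, dtype=float)[present]
        pp, ss = m.p_i[present], m.s_i[present]
        n_total = m.n_i.sum()
        ng = present.sum()
        ps = float((m.p_i * m.s_i).sum())
        assert feats["NGTDM_Coarseness"] == pytest.approx(min(1 / ps, texture.COARSENESS_CAP))
        if ng > 1:
            contrast = (
                sum(
                    pp[a] * pp[b] * (lv[a] - lv[b]) ** 2
                    for a in range(ng)
                    for b in range(ng)
                )
                / (ng * (ng - 1))
                * m.s_i.sum()
                / n_total
            )
            assert feats["NGTDM_Contrast"] == pytest.approx(contrast)
            strength = (
                sum(
                    (pp[a] + pp[b]) * (lv[a] - lv[b]) ** 2
                    for a in range(ng)
                    for b in range(ng)
                )
                / m.s_i.sum()
            )
            assert feats["NGTDM_Strength"] == pytest.approx(strength)


class TestGlobalFeatures:
    def test_symmetric_sample_zero_skewness(self):
        data = np.array([-1.0, 0.0, 1.0]).reshape(1, 3, 1)
        feats = texture.global_features(
            VolumeImage(data, ISO), ROIMask(np.ones((1, 3, 1)), ISO)
        )
        assert feats["Global_Skewness"] == pytest.approx(0.0)

    def test_gaussian_sample_kurtosis_near_three(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(100, 100, 10))
        feats = texture.global_features(
            VolumeImage(data, ISO), ROIMask(np.ones(data.shape), ISO)
        )
        assert feats["Global_Kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_matches_direct_moment_computation(self):
        rng = np.random.default_rng(5)
        data = rng.exponential(size=(4, 5, 3))
        mask = rng.random((4, 5, 3)) < 0.8
        mask.ravel()[:3] = True
        feats = texture.global_features(VolumeImage(data, ISO), ROIMask(mask, ISO))
        g = data[mask]
        m2 = ((g - g.mean()) ** 2).mean()
        m3 = ((g - g.mean()) ** 3).mean()
        m4 = ((g - g.mean()) ** 4).mean()
        assert feats["Global_Mean"] == pytest.approx(g.mean())
        assert feats["Global_Skewness"] == pytest.approx(m3 / m2**1.5)
        assert feats["Global_Kurtosis"] == pytest.approx(m4 / m2**2)

    def test_zero_variance_gives_missing_higher_moments(self):
        feats = texture.global_features(
            VolumeImage(np.full((2, 2, 2), 3.0), ISO), ROIMask(np.ones((2, 2, 2)), ISO)
        )
        assert np.isnan(feats["Global_Skewness"]) and np.isnan(feats["Global_Kurtosis"])


class TestVolumeNormalization:
    def test_identity_at_single_voxel(self):
        for name in texture.VOLUME_NORMALIZATION_EXPONENTS:
            assert texture.volume_normalize(name, 3.5, 1) == pytest.approx(3.5)

    def test_unknown_feature_rejected(self):
        with pytest.raises(KeyError):
            texture.volume_normalize("GLCM_Correlation", 1.0, 10)

    def test_tiling_leaves_vn_features_stable(self):
        """Doubling the ROI by tiling shifts raw GLN ~2x and Coarseness ~0.5x,
        while the VN companions stay within 5%."""
        rng = np.random.default_rng(6)
        block = rng.integers(1, 7, size=(4, 6, 6)).astype(np.int32)
        tiled = np.concatenate([block, block], axis=0)
        q1 = make_quantized(block, np.ones(block.shape, bool), n_bins=6)
        q2 = make_quantized(tiled, np.ones(tiled.shape, bool), n_bins=6)
        f1 = texture.glrlm_features(texture.glrlm(q1), q1.n_voxels)
        f2 = texture.glrlm_features(texture.glrlm(q2), q2.n_voxels)
        assert f2["GLRLM_GLN"] / f1["GLRLM_GLN"] == pytest.approx(2.0, rel=0.1)
        assert f2["GLRLM_GLN_VN"] == pytest.approx(f1["GLRLM_GLN_VN"], rel=0.05)
        n1 = texture.ngtdm_features(texture.ngtdm(q1), q1.n_voxels)
        n2 = texture.ngtdm_features(texture.ngtdm(q2), q2.n_voxels)
        assert n2["NGTDM_Coarseness"] / n1["NGTDM_Coarseness"] == pytest.approx(0.5, rel=0.1)
        assert n2["NGTDM_Coarseness_VN"] == pytest.approx(n1["NGTDM_Coarseness_VN"], rel=0.05)


class TestExtractAll:
    def _phantom(self, seed=0):
        rng = np.random.default_rng(seed)
        img = VolumeImage(rng.normal(size=(6, 10, 10)), ISO)
        mask = np.zeros((6, 10, 10), bool)
        mask[1:5, 2:8, 2:8] = True
        return img, ROIMask(mask, ISO)

    def test_roster_schema(self):
        img, roi = self._phantom()
        fv = texture.extract_all(img, roi, qc=QuantizationConfig(16))
        assert set(fv.values) == set(texture.DEFAULT_ROSTER) | {"ProstateVolume"}
        assert len(texture.DEFAULT_ROSTER) == 42

    def test_deterministic(self):
        img, roi = self._phantom(1)
        f1 = texture.extract_all(img, roi, qc=QuantizationConfig(16))
        f2 = texture.extract_all(img, roi, qc=QuantizationConfig(16))
        assert f1.values == f2.values

    def test_composition_matches_individual_classes(self):
        from deltarad.preprocessing import quantize_fixed_bin_number

        img, roi = self._phantom(2)
        qc = QuantizationConfig(16)
        fv = texture.extract_all(img, roi, qc=qc)
        q = quantize_fixed_bin_number(img, roi, qc)
        direct = {}
        direct.update(texture.glcm_features(texture.glcm(q, 1)))
        direct.update(texture.glrlm_features(texture.glrlm(q), q.n_voxels))
        direct.update(texture.glszm_features(texture.glszm(q), q.n_voxels))
        direct.update(texture.ngtdm_features(texture.ngtdm(q), q.n_voxels))
        direct.update(texture.global_features(img, roi))
        for name in texture.DEFAULT_ROSTER:
            assert fv.values[name] == pytest.approx(direct[name]), name

    def test_flat_image_keeps_vector_alive(self):
        img = VolumeImage(np.full((4, 6, 6), 5.0), ISO)
        roi = ROIMask(np.ones((4, 6, 6)), ISO)
        fv = texture.extract_all(img, roi, qc=QuantizationConfig(16))
        assert np.isnan(fv.values["GLCM_Correlation"])
        assert fv.values["NGTDM_Coarseness"] == texture.COARSENESS_CAP
        assert fv.values["ProstateVolume"] == pytest.approx(144.0)
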