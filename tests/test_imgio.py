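"""Volume I/O, masking, geometry, spike detection and high-pass filtering."""

import numpy as np
import pytest
import nibabel as nib
from scipy import stats

from painsig import imgio
from painsig.errors import GeometryError, InvalidConfigError
from painsig.imgio import (BrainMask, VolumeGeometry, detect_spikes,
                           dct_drift_basis, dct_highpass, flip_lr_volume,
                           gaussian_smooth, isotropic_geometry, read_volume,
                           spike_features, unvectorize, vectorize,
                           write_volume)


@pytest.fixture
def geom():
    return isotropic_geometry((6, 7, 8), 2.0)


@pytest.fixture
def mask(geom):
    inc = np.zeros(geom.shape, dtype=bool)
    inc[1:-1, 1:-1, 1:-1] = True
    return BrainMask(geom, inc)


class TestVolumeIO:
    def test_roundtrip_preserves_values_and_affine(self, tmp_path, geom, rng):
        vol = rng.normal(size=geom.shape)
        path = tmp_path / "v.nii"
        write_volume(vol, geom, path)
        back, geom2 = read_volume(path)
        assert np.allclose(back, vol, atol=1e-6)  # float32 storage
        assert np.allclose(geom2.affine, geom.affine)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii")

    def test_non_ras_input_reoriented_by_axis_permutation(self, tmp_path, rng):
        # LPS volume: canonicalization must flip the first two axes.
        data = rng.normal(size=(5, 6, 7)).astype(np.float32)
        lps = np.diag([-2.0, -2.0, 2.0, 1.0])
        nib.save(nib.Nifti1Image(data, lps), tmp_path / "lps.nii")
        vol, geom = read_volume(tmp_path / "lps.nii")
        oracle = data[::-1, ::-1, :]  # explicit axis-reversal oracle
        assert np.allclose(vol, oracle, atol=1e-6)
        assert np.all(np.diag(geom.affine)[:3] > 0)
        # round-trip through canonical orientation keeps the values
        write_volume(vol, geom, tmp_path / "ras.nii")
        back, _ = read_volume(tmp_path / "ras.nii")
        assert np.allclose(back, vol, atol=1e-6)

    def test_singular_affine_rejected(self):
        aff = np.diag([1.0, 1.0, 0.0, 1.0])
        with pytest.raises(GeometryError):
            VolumeGeometry((4, 4, 4), aff)


class TestVectorize:
    def test_ones_volume_gives_ones_vector(self, geom, mask):
        img = vectorize(np.ones(geom.shape), mask)
        assert img.values.shape == (mask.V,)
        assert np.all(img.values == 1.0)

    def test_section_retraction(self, geom, mask, rng):
        vec = rng.normal(size=mask.V)
        assert np.array_equal(vectorize(unvectorize(vec, mask), mask).values,
                              vec)
        vol = rng.normal(size=geom.shape)
        out = unvectorize(vectorize(vol, mask))
        assert np.array_equal(out[mask.include], vol[mask.include])
        assert np.all(out[~mask.include] == 0)

    def test_shape_mismatch_is_an_error(self, mask):
        with pytest.raises(GeometryError):
            vectorize(np.zeros((3, 3, 3)), mask)


class TestFlip:
    def test_involution(self, rng):
        vol = rng.normal(size=(6, 5, 4))
        assert np.array_equal(flip_lr_volume(flip_lr_volume(vol)), vol)

    def test_symmetric_volume_unchanged(self, rng):
        half = rng.normal(size=(3, 5, 4))
        vol = np.concatenate([half, half[::-1]], axis=0)
        assert np.array_equal(flip_lr_volume(vol), vol)

    def test_single_voxel_index_arithmetic(self):
        vol = np.zeros((20, 8, 8))
        vol[2, 5, 7] = 3.5
        out = flip_lr_volume(vol)
        assert out[17, 5, 7] == 3.5
        assert np.count_nonzero(out) == 1


class TestSmooth:
    def test_zero_fwhm_is_identity(self, rng):
        vol = rng.normal(size=(8, 8, 8))
        assert np.array_equal(gaussian_smooth(vol, 0.0, 2.0), vol)

    def test_constant_volume_unchanged(self):
        vol = np.full((8, 8, 8), 3.0)
        assert np.allclose(gaussian_smooth(vol, 8.0, 2.0), vol, atol=1e-10)

    def test_mean_preserved(self, rng):
        vol = rng.normal(size=(10, 10, 10))
        sm = gaussian_smooth(vol, 8.0, 2.0)
        assert abs(sm.mean() - vol.mean()) < 1e-6

    def test_delta_matches_separable_convolution_oracle(self):
        # dense separable-kernel convolution, reflective boundary
        n, fwhm, vs = 11, 6.0, 2.0
        vol = np.zeros((n, n, n))
        vol[5, 5, 5] = 1.0
        out = gaussian_smooth(vol, fwhm, vs)

        sigma = fwhm / (vs * (2 * np.sqrt(2 * np.log(2))))
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        k /= k.sum()

        def conv1d(a, axis):
            a = np.moveaxis(a, axis, 0)
            padded = np.concatenate([a[radius - 1::-1], a, a[:-radius - 1:-1]])
            res = np.empty_like(a)
            for i in range(a.shape[0]):
                res[i] = np.tensordot(k, padded[i:i + 2 * radius + 1], axes=(0, 0))
            return np.moveaxis(res, 0, axis)

        oracle = conv1d(conv1d(conv1d(vol, 0), 1), 2)
        assert np.abs(out - oracle).max() < 1e-8

    def test_negative_fwhm_rejected(self):
        with pytest.raises(InvalidConfigError):
            gaussian_smooth(np.zeros((5, 5, 5)), -1.0, 2.0)


class TestSpikes:
    def test_distances_match_quadratic_form_oracle_plain(self, rng):
        # enough volumes that the plain empirical covariance is used
        series = rng.normal(size=(6, 6, 4, 40))
        rep = detect_spikes(series, alpha=0.05)
        assert not rep.shrinkage_used
        feats = spike_features(series)
        dev = feats - feats.mean(axis=0)
        prec = np.linalg.inv(np.cov(feats, rowvar=False, ddof=1))
        oracle = np.array([d @ prec @ d for d in dev])
        assert np.abs(rep.distances - oracle).max() < 1e-8

    def test_distances_match_quadratic_form_oracle_shrinkage(self, rng):
        # 10 volumes, 4 slices → shrinkage regime (T < 2·features)
        from sklearn.covariance import LedoitWolf

        series = rng.normal(size=(5, 5, 4, 10))
        with pytest.warns(UserWarning):
            rep = detect_spikes(series, alpha=0.05)
        assert rep.shrinkage_used
        feats = spike_features(series)
        dev = feats - feats.mean(axis=0)
        cov = LedoitWolf().fit(feats).covariance_
        oracle = np.array([d @ np.linalg.solve(cov, d) for d in dev])
        assert np.abs(rep.distances - oracle).max() < 1e-6

    def test_extreme_outlier_flagged(self, rng):
        series = rng.normal(size=(6, 6, 4, 40))
        series[..., 13] += 50.0
        rep = detect_spikes(series, alpha=0.05)
        assert 13 in rep.flagged

    def test_null_flag_rate_bounded_by_alpha(self):
        # Bonferroni-corrected chi2 threshold keeps the family-wise rate low
        flagged = total = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            rep = detect_spikes(r.normal(size=(6, 6, 4, 40)), alpha=0.05)
            flagged += rep.flagged.size
            total += 40
        assert flagged / total <= 0.05

    def test_threshold_is_bonferroni_chi2(self, rng):
        series = rng.normal(size=(6, 6, 4, 40))
        rep = detect_spikes(series, alpha=0.05)
        assert rep.threshold == pytest.approx(
            stats.chi2.ppf(1 - 0.05 / 40, df=8))

    def test_too_few_volumes_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            detect_spikes(rng.normal(size=(4, 4, 4, 2)))


class TestHighpass:
    def test_in_span_cosine_removed(self):
        T, tr = 200, 1.3
        basis = dct_drift_basis(T, tr, 224.0)
        assert basis.shape[1] >= 1
        slow = 5.0 * basis[:, 0] + 2.0  # slowest drift + offset
        out = dct_highpass(slow, 224.0, tr)
        assert np.abs(out).max() < 1e-6

    def test_fast_component_preserved(self, rng):
        T, tr = 200, 1.3
        t = np.arange(T) * tr
        basis = dct_drift_basis(T, tr, 224.0)
        fast = np.sin(2 * np.pi * t / 20.0)
        out = dct_highpass(3 * basis[:, -1] + fast, 224.0, tr)
        # oracle: explicit projection onto the drift span
        B = np.column_stack([np.ones(T) / np.sqrt(T), basis])
        oracle = fast - B @ (B.T @ fast)
        assert np.corrcoef(out, fast)[0, 1] > 0.99
        assert np.allclose(out, oracle, atol=1e-10)

    def test_residual_orthogonal_to_basis(self, rng):
        T, tr = 150, 2.0
        y = rng.normal(size=(T, 5))
        out = dct_highpass(y, 100.0, tr)
        basis = dct_drift_basis(T, tr, 100.0)
        assert np.abs(basis.T @ out).max() < 1e-8
        assert np.abs(out.mean(axis=0)).max() < 1e-10
        assert (out.var(axis=0) <= y.var(axis=0)).all()

    def test_cutoff_too_small_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            dct_highpass(rng.normal(size=20), 3.0, 2.0)
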