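"""Unit and property tests for loading, voxel selection and conditioning."""

import nibabel as nib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsdetect import bold_io
from bsdetect.errors import (
    BandError,
    ConstantSeriesError,
    DimensionalityError,
    EmptySelectionError,
    MetadataError,
)
from conftest import make_matrix


def _write_nifti(path, data, tr=2.0):
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.eye(4))
    if data.ndim == 4:
        img.header.set_zooms((1.0, 1.0, 1.0, tr))
    nib.save(img, str(path))


class TestLoadBold:
    def test_header_tr_passthrough(self, tmp_path):
        path = tmp_path / "run.nii.gz"
        _write_nifti(path, np.zeros((10, 10, 10, 50)) + 1.0, tr=2.0)
        run = bold_io.load_bold(path)
        assert run.n_frames == 50
        assert run.tr == 2.0

    def test_tr_override_wins_over_zero_header(self, tmp_path):
        path = tmp_path / "run.nii.gz"
        _write_nifti(path, np.ones((4, 4, 4, 5)), tr=0.0)
        assert bold_io.load_bold(path, tr_override=2.0).tr == 2.0
        with pytest.raises(MetadataError):
            bold_io.load_bold(path)

    def test_3d_image_rejected(self, tmp_path):
        path = tmp_path / "vol.nii.gz"
        _write_nifti(path, np.ones((4, 4, 4)))
        with pytest.raises(DimensionalityError):
            bold_io.load_bold(path)

    def test_nonfinite_voxels_flagged_and_zeroed(self):
        data = np.ones((3, 3, 3, 6))
        data[1, 1, 1, 2] = np.nan
        run = bold_io.BoldRun(data=data, tr=2.0, affine=np.eye(4))
        assert run.nonfinite_mask[1, 1, 1]
        assert np.isfinite(run.data).all()


class TestTsnr:
    def test_hand_computed_ratio(self):
        # series (100, 102, 98, 100): mean 100, population SD sqrt(2)
        data = np.array([100.0, 102.0, 98.0, 100.0]).reshape(1, 1, 1, 4)
        tsnr = bold_io.compute_tsnr(bold_io.BoldRun(data, 2.0, np.eye(4)))
        assert tsnr.values[0, 0, 0] == pytest.approx(100 / np.sqrt(2), abs=1e-4)
        assert tsnr.values[0, 0, 0] == pytest.approx(70.7107, abs=1e-4)

    def test_constant_voxel_flagged_infinite(self):
        data = np.full((1, 1, 1, 3), 5.0)
        tsnr = bold_io.compute_tsnr(bold_io.BoldRun(data, 2.0, np.eye(4)))
        assert np.isinf(tsnr.values[0, 0, 0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        data = 100 + rng.standard_normal((4, 4, 4, 20))
        run1 = bold_io.BoldRun(data, 2.0, np.eye(4))
        run3 = bold_io.BoldRun(3 * data, 2.0, np.eye(4))
        np.testing.assert_allclose(
            bold_io.compute_tsnr(run1).values,
            bold_io.compute_tsnr(run3).values,
            rtol=1e-12,
        )


class TestBuildVoxelSet:
    def _run_with_tsnr(self, tsnr_values):
        # construct a run whose per-voxel tSNR equals tsnr_values exactly:
        # series (m - s, m + s) has mean m, population SD s -> tSNR m/s
        shape = tsnr_values.shape
        sd = 1.0
        mean = tsnr_values * sd
        data = np.stack([mean - sd, mean + sd], axis=-1)
        run = bold_io.BoldRun(data, 2.0, np.eye(4))
        return run, bold_io.compute_tsnr(run)

    def test_tsnr_floor_omits_strictly_below(self):
        vals = np.full((10, 10, 1), 50.0)
        vals.flat[:7] = 14.9
        run, tsnr = self._run_with_tsnr(vals)
        mask = bold_io.VolumeMap(np.ones((10, 10, 1)), "mask")
        voxels = bold_io.build_voxel_set(run, mask, tsnr, tsnr_min=15.0)
        assert len(voxels) == 93

    def test_floor_boundary_is_retained(self):
        vals = np.array([[[15.0]], [[14.999]]])
        run, tsnr = self._run_with_tsnr(vals)
        mask = bold_io.VolumeMap(np.ones((2, 1, 1)), "mask")
        voxels = bold_io.build_voxel_set(run, mask, tsnr, tsnr_min=15.0)
        assert len(voxels) == 1
        assert tuple(voxels.indices[0]) == (0, 0, 0)

    def test_disabled_filter_keeps_all_masked(self):
        vals = np.full((4, 4, 2), 5.0)
        run, tsnr = self._run_with_tsnr(vals)
        mask_arr = np.zeros((4, 4, 2))
        mask_arr[1:3, 1:3, :] = 1
        voxels = bold_io.build_voxel_set(
            run, bold_io.VolumeMap(mask_arr, "mask"), tsnr, tsnr_min=0.0
        )
        assert len(voxels) == int(mask_arr.sum())

    def test_all_constant_raises_empty_selection(self):
        data = np.full((3, 3, 3, 4), 7.0)
        run = bold_io.BoldRun(data, 2.0, np.eye(4))
        tsnr = bold_io.compute_tsnr(run)
        mask = bold_io.VolumeMap(np.ones((3, 3, 3)), "mask")
        with pytest.raises(EmptySelectionError, match="constant"):
            bold_io.build_voxel_set(run, mask, tsnr)

    def test_deterministic_c_scan_order(self):
        rng = np.random.default_rng(1)
        data = 100 + rng.standard_normal((5, 4, 3, 10))
        run = bold_io.BoldRun(data, 2.0, np.eye(4))
        tsnr = bold_io.compute_tsnr(run)
        mask = bold_io.VolumeMap(np.ones((5, 4, 3)), "mask")
        a = bold_io.build_voxel_set(run, mask, tsnr, tsnr_min=0)
        b = bold_io.build_voxel_set(run, mask, tsnr, tsnr_min=0)
        np.testing.assert_array_equal(a.indices, b.indices)
        # C order: lexicographically ascending (x, y, z)
        flat = np.ravel_multi_index(tuple(a.indices.T), (5, 4, 3))
        assert np.all(np.diff(flat) > 0)


class TestDetrendBandpass:
    tr = 2.0

    def test_cubic_trend_annihilated(self):
        t = np.arange(200)
        row = 1.0 + 0.5 * t - 0.01 * t**2 + 1e-4 * t**3
        out = bold_io.detrend_and_bandpass(make_matrix(row[None, :], self.tr))
        assert np.abs(out.values).max() < 1e-9 * np.abs(row).max()

    def test_in_band_cosine_passes_unchanged(self):
        n = 200
        k = 10  # f = 10 / (200 * 2) = 0.025 Hz, inside 0.005-0.12
        row = np.cos(2 * np.pi * k * np.arange(n) / n)
        out = bold_io.detrend_and_bandpass(
            make_matrix(row[None, :], self.tr), poly_order=0
        )
        np.testing.assert_allclose(out.values[0], row - row.mean(), atol=1e-9)

    def test_out_of_band_cosine_removed(self):
        n = 200
        k = 90  # f = 0.225 Hz > 0.12
        row = np.cos(2 * np.pi * k * np.arange(n) / n)
        out = bold_io.detrend_and_bandpass(make_matrix(row[None, :], self.tr))
        assert np.abs(out.values).max() < 1e-9

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        mat = make_matrix(rng.standard_normal((5, 150)), self.tr)
        once = bold_io.detrend_and_bandpass(mat)
        twice = bold_io.detrend_and_bandpass(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_output_orthogonal_to_removed_basis(self):
        rng = np.random.default_rng(3)
        n = 120
        mat = make_matrix(rng.standard_normal((3, n)), self.tr)
        out = bold_io.detrend_and_bandpass(mat).values
        x = np.linspace(-1, 1, n)
        for deg in range(4):
            poly = np.polynomial.legendre.Legendre.basis(deg)(x)
            dots = out @ poly
            assert np.all(
                np.abs(dots)
                < 1e-6 * np.linalg.norm(out, axis=1) * np.linalg.norm(poly)
            )
        for k in range(1, n // 2 + 1):
            f = k / (n * self.tr)
            if 0.005 <= f <= 0.12:
                continue
            for wave in (np.cos, np.sin):
                reg = wave(2 * np.pi * k * np.arange(n) / n)
                if np.linalg.norm(reg) < 1e-9:
                    continue
                dots = out @ reg
                assert np.all(
                    np.abs(dots)
                    < 1e-6 * np.linalg.norm(out, axis=1) * np.linalg.norm(reg)
                )

    def test_rows_end_zero_mean(self):
        rng = np.random.default_rng(4)
        out = bold_io.detrend_and_bandpass(
            make_matrix(rng.standard_normal((10, 100)), self.tr)
        )
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-10)

    def test_band_above_nyquist_rejected(self):
        mat = make_matrix(np.random.default_rng(5).standard_normal((2, 50)), 2.0)
        with pytest.raises(BandError):
            bold_io.detrend_and_bandpass(mat, band=(0.005, 0.3))


class TestSmoothGaussian:
    def _run(self, data):
        return bold_io.BoldRun(np.asarray(data, float), 2.0, np.eye(4))

    def test_fwhm_zero_is_identity(self):
        run = self._run(np.random.default_rng(6).random((5, 5, 5, 3)) + 1)
        out = bold_io.smooth_gaussian(run, 0.0)
        assert out is run

    def test_constant_volume_preserved_interior(self):
        run = self._run(np.full((9, 9, 9, 2), 4.0))
        out = bold_io.smooth_gaussian(run, 2.0)
        np.testing.assert_allclose(out.data[4, 4, 4], 4.0, rtol=1e-6)

    def test_impulse_matches_direct_summation(self):
        # direct-convolution oracle: center value of a smoothed unit impulse
        # equals the separable Gaussian kernel peak normalized over the grid
        n = 15
        data = np.zeros((n, n, n, 2))
        data[7, 7, 7, 0] = 1.0
        fwhm = 2.0  # voxel size 1 mm
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        out = bold_io.smooth_gaussian(self._run(data), fwhm)
        x = np.arange(n) - 7
        g = np.exp(-(x**2) / (2 * sigma**2))
        g /= g.sum()
        expected = g[7] ** 3  # peak of the separable normalized kernel
        assert out.data[7, 7, 7, 0] == pytest.approx(expected, rel=1e-4)

    def test_mask_renormalization_keeps_constant(self):
        n = 9
        data = np.full((n, n, n, 2), 3.0)
        mask_arr = np.zeros((n, n, n))
        mask_arr[2:7, 2:7, 2:7] = 1
        out = bold_io.smooth_gaussian(
            self._run(data), 2.0, mask=bold_io.VolumeMap(mask_arr, "mask")
        )
        inside = out.data[mask_arr > 0, 0]
        np.testing.assert_allclose(inside, 3.0, rtol=1e-6)


class TestZscoreRows:
    def test_hand_computed(self):
        out = bold_io.zscore_rows(make_matrix(np.array([[1.0, 2.0, 3.0]])))
        np.testing.assert_allclose(
            out.values[0], [-1.2247, 0.0, 1.2247], atol=1e-4
        )

    def test_idempotent_on_zscored_rows(self):
        rng = np.random.default_rng(7)
        once = bold_io.zscore_rows(make_matrix(rng.standard_normal((4, 60))))
        twice = bold_io.zscore_rows(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_constant_row_rejected(self):
        with pytest.raises(ConstantSeriesError):
            bold_io.zscore_rows(make_matrix(np.array([[5.0, 5.0, 5.0]])))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rows_have_zero_mean_unit_sd(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((8, 40)) * rng.uniform(0.5, 10) + rng.uniform(-5, 5)
        out = bold_io.zscore_rows(make_matrix(vals)).values
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1), 1, atol=1e-10)
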