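"""Unit and property tests for the preprocessing chain."""

import numpy as np
import pytest

import kurtica as kt
from kurtica.errors import KurticaError, ShapeMismatchError

from conftest import single_voxel_volume


def make_volume(data, tr=2.0, voxel=3.0):
    return kt.Volume4D(
        data=np.asarray(data, dtype=np.float64),
        voxel_size_mm=(voxel,) * 3,
        tr_seconds=tr,
        affine=np.eye(4),
    )


def full_mask(vol):
    return kt.Mask3D(data=np.ones(vol.spatial_shape, dtype=bool), affine=vol.affine)


class TestTrim:
    def test_drops_first_ten(self):
        vol = make_volume(np.random.default_rng(0).standard_normal((2, 2, 2, 200)))
        out = kt.trim_initial_volumes(vol, 10)
        assert out.nt == 190
        assert np.array_equal(out.data, vol.data[..., 10:])

    def test_zero_drop_is_identity(self):
        vol = make_volume(np.random.default_rng(1).standard_normal((2, 2, 2, 20)))
        assert np.array_equal(kt.trim_initial_volumes(vol, 0).data, vol.data)

    def test_too_short_raises_with_counts(self):
        vol = make_volume(np.zeros((1, 1, 1, 5)) + np.arange(5))
        with pytest.raises(KurticaError, match="10.*5|5.*10"):
            kt.trim_initial_volumes(vol, 10)


class TestSliceTiming:
    def test_reference_slice_unchanged(self):
        rng = np.random.default_rng(2)
        vol = make_volume(rng.standard_normal((2, 2, 4, 30)))
        out = kt.slice_timing_correct(vol, n_slices=4, ref_slice=2)
        assert np.abs(out.data[:, :, 2] - vol.data[:, :, 2]).max() < 1e-12

    def test_half_tr_shift_of_sinusoid(self):
        # slice 0 of a 4-slice volume referenced to slice 2 is shifted by
        # TR/2; compare to the analytically shifted sinusoid (TR = 1 s)
        tr, f, nt = 1.0, 0.04, 100
        t = np.arange(nt) * tr
        series = np.sin(2 * np.pi * f * t)
        data = np.tile(series, (1, 1, 4, 1))
        vol = make_volume(data, tr=tr)
        out = kt.slice_timing_correct(vol, n_slices=4, ref_slice=2)
        expected = np.sin(2 * np.pi * f * (t + 0.5 * tr))
        err = np.abs(out.data[0, 0, 0, 1:-1] - expected[1:-1]).max()
        assert err < 0.02

    def test_constant_series_unchanged(self):
        vol = make_volume(np.full((2, 2, 3, 20), 5.0))
        out = kt.slice_timing_correct(vol)
        assert np.abs(out.data - 5.0).max() < 1e-12

    def test_slice_count_mismatch_raises(self):
        vol = make_volume(np.zeros((2, 2, 3, 20)))
        with pytest.raises(KurticaError, match="n_slices"):
            kt.slice_timing_correct(vol, n_slices=32, ref_slice=0)


class TestDetrend:
    def test_exact_line_removed_mean_preserved(self):
        t = np.arange(50, dtype=float)
        series = 2.0 + 0.5 * t
        vol, mask = single_voxel_volume(series)
        out = kt.detrend_linear(vol, mask)
        res = out.data[0, 0, 0]
        assert np.abs(res - (2.0 + 0.5 * t.mean())).max() < 1e-10
        slope = np.polyfit(t, res, 1)[0]
        assert abs(slope) < 1e-10

    def test_sinusoid_amplitude_nearly_preserved(self):
        t = np.arange(190, dtype=float)
        series = np.sin(2 * np.pi * 0.03 * 2.0 * t)  # 0.03 Hz at TR = 2 s
        vol, mask = single_voxel_volume(series)
        out = kt.detrend_linear(vol, mask)
        res = out.data[0, 0, 0] - out.data[0, 0, 0].mean()
        amp_ratio = res.std() / series.std()
        assert abs(amp_ratio - 1.0) < 0.02

    def test_linearity_line_plus_sinusoid(self):
        t = np.arange(190, dtype=float)
        sine = np.sin(2 * np.pi * 0.03 * 2.0 * t)
        line = 1.5 - 0.2 * t
        v1, mask = single_voxel_volume(sine)
        v2, _ = single_voxel_volume(sine + line)
        r1 = kt.detrend_linear(v1, mask).data.ravel()
        r2 = kt.detrend_linear(v2, mask).data.ravel()
        assert np.abs((r2 - r2.mean()) - (r1 - r1.mean())).max() < 1e-10

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        vol = make_volume(rng.standard_normal((3, 2, 2, 60)))
        mask = full_mask(vol)
        once = kt.detrend_linear(vol, mask)
        twice = kt.detrend_linear(once, mask)
        assert np.abs(twice.data - once.data).max() < 1e-10

    def test_out_of_mask_untouched(self):
        rng = np.random.default_rng(4)
        vol = make_volume(rng.standard_normal((3, 2, 2, 40)) + np.arange(40) * 0.3)
        mask_data = np.zeros(vol.spatial_shape, dtype=bool)
        mask_data[0, 0, 0] = True
        mask = kt.Mask3D(data=mask_data, affine=vol.affine)
        out = kt.detrend_linear(vol, mask)
        assert np.array_equal(out.data[~mask_data], vol.data[~mask_data])
        assert not np.array_equal(out.data[mask_data], vol.data[mask_data])


class TestBandpass:
    # spectral checks use the central half of the series, outside the
    # zero-phase filter's edge transients
    MID = slice(128, 384)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(512) * 2.0
        vol, mask = single_voxel_volume(np.sin(2 * np.pi * 0.04 * t), tr=2.0)
        out = kt.bandpass_filter(vol, mask)
        amp = np.abs(out.data[0, 0, 0, self.MID]).max()
        assert 0.9 <= amp <= 1.0

    def test_stopband_attenuated_20db(self):
        t = np.arange(512) * 2.0
        in_band = np.sin(2 * np.pi * 0.04 * t)
        out_band = np.sin(2 * np.pi * 0.15 * t)
        v1, mask = single_voxel_volume(in_band, tr=2.0)
        v2, _ = single_voxel_volume(out_band, tr=2.0)
        rms1 = kt.bandpass_filter(v1, mask).data[0, 0, 0, self.MID].std()
        rms2 = kt.bandpass_filter(v2, mask).data[0, 0, 0, self.MID].std()
        assert 20 * np.log10(rms1 / rms2) >= 20.0

    def test_constant_series_unchanged(self):
        vol, mask = single_voxel_volume(np.full(128, 7.5), tr=2.0)
        out = kt.bandpass_filter(vol, mask)
        assert np.abs(out.data - 7.5).max() < 1e-10

    def test_band_monotonicity(self):
        # output/input RMS ratio across 0.005, 0.04, 0.2 Hz peaks at 0.04
        t = np.arange(512) * 2.0
        ratios = []
        for f in (0.005, 0.04, 0.2):
            vol, mask = single_voxel_volume(np.sin(2 * np.pi * f * t), tr=2.0)
            out = kt.bandpass_filter(vol, mask)
            centered = out.data - out.data.mean()
            ratios.append(centered.std() / vol.data.std())
        assert np.argmax(ratios) == 1

    def test_invalid_band_names_nyquist(self):
        vol, mask = single_voxel_volume(np.zeros(64) + np.arange(64), tr=2.0)
        with pytest.raises(KurticaError, match="Nyquist"):
            kt.bandpass_filter(vol, mask, 0.01, 0.3)


class TestNuisanceRegression:
    def test_perfect_regression_leaves_constant(self):
        rng = np.random.default_rng(5)
        col = rng.standard_normal(80)
        vol, mask = single_voxel_volume(3.0 + col)
        nuis = kt.NuisanceTable({"m": col})
        out = kt.regress_nuisance(vol, mask, nuis)
        assert np.abs(out.data - out.data.mean()).max() < 1e-8

    def test_orthogonal_regressor_no_change(self):
        t = np.arange(128, dtype=float)
        series = np.sin(2 * np.pi * t / 16)
        orth = np.cos(2 * np.pi * t / 16)  # orthogonal over full periods
        vol, mask = single_voxel_volume(series)
        out = kt.regress_nuisance(vol, mask, kt.NuisanceTable({"m": orth}))
        assert np.abs(out.data.ravel() - series).max() < 1e-8

    def test_removes_motion_contamination(self):
        rng = np.random.default_rng(6)
        signal = np.sin(2 * np.pi * 0.03 * 2.0 * np.arange(200))
        motion = np.cumsum(rng.standard_normal(200)) * 0.1
        vol, mask = single_voxel_volume(signal + 0.7 * motion)
        out = kt.regress_nuisance(vol, mask, kt.NuisanceTable({"m": motion}))
        resid = out.data.ravel()
        r = np.corrcoef(resid, signal)[0, 1]
        assert r > 0.99

    def test_rank_deficient_design_lists_columns(self):
        rng = np.random.default_rng(7)
        col = rng.standard_normal(50)
        vol, mask = single_voxel_volume(rng.standard_normal(50))
        nuis = kt.NuisanceTable({"a": col, "b": 2.0 * col})
        with pytest.raises(KurticaError, match="collinear"):
            kt.regress_nuisance(vol, mask, nuis)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(8)
        vol = make_volume(rng.standard_normal((4, 4, 4, 3)))
        out = kt.smooth_gaussian(vol, (0.0, 0.0, 0.0))
        assert np.array_equal(out.data, vol.data)

    def test_uniform_volume_unchanged(self):
        vol = make_volume(np.full((6, 6, 6, 2), 3.3))
        out = kt.smooth_gaussian(vol, (9.0, 9.0, 9.0))
        assert np.abs(out.data - 3.3).max() < 1e-10

    def test_impulse_matches_sampled_gaussian(self):
        # closed-form: separable product of normalized sampled 1-D kernels
        n, c = 21, 10
        data = np.zeros((n, n, n, 1))
        data[c, c, c, 0] = 1.0
        vol = make_volume(data, voxel=3.0)
        out = kt.smooth_gaussian(vol, (9.0, 9.0, 9.0))
        sigma = 9.0 / (2.0 * np.sqrt(2.0 * np.log(2.0))) / 3.0
        radius = int(4.0 * sigma + 0.5)
        offs = np.arange(-radius, radius + 1)
        g = np.exp(-0.5 * (offs / sigma) ** 2)
        g /= g.sum()
        expected = np.zeros((n, n, n))
        sl = slice(c - radius, c + radius + 1)
        expected[sl, sl, sl] = g[:, None, None] * g[None, :, None] * g[None, None, :]
        interior = slice(3, n - 3)
        assert np.abs(out.data[interior, interior, interior, 0]
                      - expected[interior, interior, interior]).max() < 1e-6

    def test_spatial_mean_conserved(self):
        rng = np.random.default_rng(9)
        vol = make_volume(rng.standard_normal((8, 8, 8, 3)))
        out = kt.smooth_gaussian(vol, (9.0, 9.0, 9.0))
        for t in range(3):
            assert abs(out.data[..., t].mean() - vol.data[..., t].mean()) < 1e-8


class TestRunPreprocessing:
    def test_all_disabled_is_identity(self, phantom_bundle):
        _, vol, _, nuis, mask = phantom_bundle
        cfg = kt.PreprocessConfig(
            trim=False, slice_timing=False, detrend=False,
            bandpass=False, nuisance=False, smooth=False,
        )
        out, log = kt.run_preprocessing(vol, mask, nuis, cfg)
        assert np.array_equal(out.data, vol.data)
        assert log == []

    def test_default_provenance_lists_six_stages(self, phantom_bundle):
        _, vol, _, nuis, mask = phantom_bundle
        _, log = kt.run_preprocessing(vol, mask, nuis)
        assert len(log) == 6
        stages = [entry.split()[0] for entry in log]
        assert stages == [
            "trim_initial_volumes", "slice_timing_correct", "detrend_linear",
            "bandpass_filter", "regress_nuisance", "smooth_gaussian",
        ]

    def test_full_chain_deterministic(self, phantom_bundle):
        _, vol, _, nuis, mask = phantom_bundle
        out1, _ = kt.run_preprocessing(vol, mask, nuis)
        out2, _ = kt.run_preprocessing(vol, mask, nuis)
        assert np.array_equal(out1.data, out2.data)

    def test_mask_respected_by_temporal_stages(self, phantom_bundle):
        _, vol, _, nuis, mask_full = phantom_bundle
        mask_data = np.zeros(vol.spatial_shape, dtype=bool)
        mask_data[4:16, 4:16, 2:6] = True
        mask = kt.Mask3D(data=mask_data, affine=vol.affine)
        cfg = kt.PreprocessConfig(trim=False, slice_timing=False, smooth=False)
        out, _ = kt.run_preprocessing(vol, mask, nuis, cfg)
        assert np.array_equal(out.data[~mask_data], vol.data[~mask_data])


class TestNiftiRoundtrip:
    def test_volume_roundtrip(self, tmp_path, phantom_bundle):
        from kurtica.io import read_volume, write_volume

        _, vol, _, _, _ = phantom_bundle
        p = tmp_path / "vol.nii"
        write_volume(vol, p)
        back = read_volume(p)
        assert np.array_equal(back.data, vol.data)
        assert back.tr_seconds == pytest.approx(vol.tr_seconds)
        assert back.voxel_size_mm == pytest.approx(vol.voxel_size_mm)
        assert np.allclose(back.affine, vol.affine)

    def test_mask_roundtrip(self, tmp_path, phantom_bundle):
        from kurtica.io import read_mask, write_mask

        _, _, truth, _, _ = phantom_bundle
        p = tmp_path / "mask.nii"
        write_mask(truth.masks[0], p)
        back = read_mask(p)
        assert np.array_equal(back.data, truth.masks[0].data)

    def test_nuisance_tsv_roundtrip(self, tmp_path, phantom_bundle):
        _, _, _, nuis, _ = phantom_bundle
        p = tmp_path / "nuis.tsv"
        nuis.to_tsv(p)
        back = kt.NuisanceTable.from_tsv(p)
        assert list(back.columns.columns) == list(nuis.columns.columns)
        assert np.array_equal(back.columns.to_numpy(), nuis.columns.to_numpy())
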