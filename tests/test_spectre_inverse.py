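import numpy as np
import pytest

from spectre_eeg import _spectral
from spectre_eeg import forward_sim as fsim
from spectre_eeg import spectre_inverse as sinv
from spectre_eeg import tissue_model as tmod
from conftest import band_power_of_reconstruction


def make_recording(data, fs, positions=None, reference="none"):
    n = data.shape[0]
    if positions is None:
        positions = np.c_[np.arange(n) * 3.0, np.zeros(n), np.zeros(n)]
    sensors = fsim.SensorArray(
        [f"C{i}" for i in range(n)], positions, reference=reference
    )
    return fsim.EEGRecording(data=data, fs=fs, sensors=sensors)


class TestBandTransform:
    def test_unit_sinusoid_amplitude(self):
        fs, dur, f0 = 128.0, 2.0, 10.0
        t = np.arange(int(fs * dur)) / fs
        rec = make_recording(np.sin(2 * np.pi * f0 * t)[None, :], fs)
        freqs, coeffs = sinv.band_transform(rec, sinv.BandSpec(8, 12))
        amp = np.abs(coeffs[0, np.argmin(np.abs(freqs - f0))])
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_out_of_band_leakage_small(self):
        fs, dur, f0 = 128.0, 2.0, 10.0
        t = np.arange(int(fs * dur)) / fs
        rec = make_recording(np.sin(2 * np.pi * f0 * t)[None, :], fs)
        _, out = sinv.band_transform(rec, sinv.BandSpec(20, 30))
        assert np.max(np.abs(out)) < 0.01

    def test_parseval(self):
        rng = np.random.default_rng(0)
        fs, n = 64.0, 256
        x = rng.standard_normal((2, n))
        x -= x.mean(axis=1, keepdims=True)
        rec = make_recording(x, fs)
        # all positive-frequency bins below Nyquist
        freqs, coeffs = sinv.band_transform(rec, sinv.BandSpec(0, fs / 2))
        nyq = np.fft.rfft(x, axis=1)[:, -1]  # excluded Nyquist bin
        power = np.sum(np.abs(coeffs) ** 2, axis=1) / 2 + np.abs(nyq / n) ** 2
        np.testing.assert_allclose(power, np.mean(x**2, axis=1), rtol=1e-10)

    def test_short_recording_rejected(self):
        rec = make_recording(np.zeros((1, 16)), 64.0)
        with pytest.raises(sinv.InverseError, match="short"):
            sinv.band_transform(rec, sinv.BandSpec(8, 9))

    def test_empty_band_rejected(self):
        rec = make_recording(np.zeros((1, 256)), 64.0)
        with pytest.raises(sinv.InverseError):
            sinv.band_transform(rec, sinv.BandSpec(10.0, 10.01))


class TestInvertLaplacian:
    def test_sine_eigenfunction(self):
        L = 32
        x = np.arange(L)
        f = np.sin(2 * np.pi * x / L)[:, None] * np.ones((1, 4))
        out = sinv.invert_laplacian(f, 1.0)
        np.testing.assert_allclose(out, -((L / (2 * np.pi)) ** 2) * f, atol=1e-10)

    def test_constant_maps_to_zero(self):
        np.testing.assert_allclose(sinv.invert_laplacian(np.full((8, 8), 3.0)), 0.0)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal((16, 16, 16))
        back = _spectral.laplacian(sinv.invert_laplacian(f, 0.5), 0.5)
        np.testing.assert_allclose(back, f - f.mean(), atol=1e-10 * np.abs(f).max())


def uniform_fields(n=16, voxel=2.0, label=tmod.GM):
    affine = np.diag([voxel, voxel, voxel, 1.0])
    grid = tmod.TissueGrid(np.full((n, n, n), label, dtype=np.int16), voxel, affine)
    return tmod.build_property_fields(grid, smooth_width=0.0)


class TestApplyR:
    def test_homogeneous_fields_annihilate(self):
        fields = uniform_fields()
        rng = np.random.default_rng(2)
        phi = rng.standard_normal((16, 16, 16)) + 1j * rng.standard_normal(
            (16, 16, 16)
        )
        out = sinv.apply_R(phi, fields, omega=2 * np.pi * 10)
        assert np.max(np.abs(out)) < 1e-12 * np.max(np.abs(phi))

    def test_conductivity_gradient_term_closed_form(self):
        """Constant permittivity, sinusoidal isotropic conductivity, plane
        wave: R reduces to -P * (grad SigmaEps . grad phi) with an analytic
        gradient."""
        n, voxel = 32, 2.0
        fields = uniform_fields(n, voxel)
        x = np.arange(n) * voxel * 1e-3  # meters
        L = n * voxel * 1e-3
        s = 100.0 * (1.5 + np.sin(2 * np.pi * x / L))[:, None, None]
        s = s * np.ones((1, n, n))
        eps_c = 2.0e7
        fields.sigma = s * eps_c * tmod.EPS0  # keep bookkeeping consistent
        fields.eps_rel = np.full((n, n, n), eps_c)
        fields.Sigma = np.eye(3) * s[..., None, None]
        if hasattr(fields, "_inverse_cache"):
            del fields._inverse_cache
        k = 2 * np.pi * 3 / L
        phi = np.exp(1j * k * x)[:, None, None] * np.ones((1, n, n))
        omega = 2 * np.pi * 10
        out = sinv.apply_R(phi, fields, omega)

        ds_dx = 100.0 * (2 * np.pi / L) * np.cos(2 * np.pi * x / L)
        sig_t = s[:, 0, 0] * eps_c
        P = (sig_t + 1j * omega * eps_c) / (sig_t**2 + omega**2 * eps_c**2)
        expected = (
            -P * (ds_dx * eps_c) * (1j * k * np.exp(1j * k * x))
        )[:, None, None] * np.ones((1, n, n))
        np.testing.assert_allclose(
            out, expected, rtol=1e-8, atol=1e-8 * np.abs(expected).max()
        )

    def test_against_finite_difference_oracle(self):
        """Independent discretization: second-order central differences on a
        smooth periodic field agree with the spectral evaluation."""
        n, voxel = 24, 2.0
        fields = uniform_fields(n, voxel)
        h = voxel * 1e-3
        x = np.arange(n) * h
        L = n * h
        xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
        s = 80.0 * (1.5 + 0.5 * np.sin(2 * np.pi * xx / L) * np.cos(2 * np.pi * yy / L))
        eps = 3e7 * (1.0 + 0.2 * np.sin(2 * np.pi * zz / L))
        fields.sigma = s * eps * tmod.EPS0
        fields.eps_rel = eps
        fields.Sigma = np.eye(3) * s[..., None, None]
        if hasattr(fields, "_inverse_cache"):
            del fields._inverse_cache
        phi = np.exp(2j * np.pi * (xx + yy - zz) / L)
        omega = 2 * np.pi * 10
        out = sinv.apply_R(phi, fields, omega)

        def d(f, ax):
            return (np.roll(f, -1, axis=ax) - np.roll(f, 1, axis=ax)) / (2 * h)

        sig_t = s * eps
        sbar = sig_t
        P = (sbar + 1j * omega * eps) / (sbar**2 + omega**2 * eps**2)
        bracket = np.zeros_like(phi)
        for i in range(3):
            bracket += 1j * omega * d(eps, i) * d(phi, i)
            bracket -= d(sig_t, i) * d(phi, i)
        fd = P * bracket
        err = np.abs(out - fd).max() / np.abs(out).max()
        assert err < 0.05  # O(h^2) agreement on a smooth field

    def test_grid_mismatch_rejected(self):
        fields = uniform_fields(16)
        with pytest.raises(sinv.InverseError):
            sinv.apply_R(np.zeros((8, 8, 8)), fields, 1.0)


class TestReconstructBand:
    def test_zero_recording_gives_zero_potential(self, small32):
        grid, fields, sensors = small32
        rec = fsim.EEGRecording(np.zeros((len(sensors), 128)), 64.0, sensors)
        sp = sinv.reconstruct_band(rec, grid, fields, sinv.BandSpec(8, 12))
        assert np.all(sp.phi == 0)

    def test_k0_returns_scaled_seed(self, small32):
        grid, fields, sensors = small32
        rng = np.random.default_rng(3)
        rec = fsim.EEGRecording(
            rng.standard_normal((len(sensors), 128)), 64.0, sensors
        )
        cfg = sinv.ReconstructionConfig(K=0)
        sp = sinv.reconstruct_band(rec, grid, fields, sinv.BandSpec(9, 11), cfg)
        freqs, coeffs = sinv.band_transform(rec, sinv.BandSpec(9, 11))
        vox = grid.world_to_voxel(sensors.positions)
        for b in range(len(freqs)):
            seed = sinv._splat(coeffs[:, b], vox, grid.shape, cfg.seed_splat_fwhm)
            phi0 = _spectral.invert_laplacian(seed, fields.spacing_m)
            alpha = sinv._fit_alpha(phi0, vox, coeffs[:, b])
            np.testing.assert_allclose(sp.phi[b], alpha * phi0, rtol=1e-12)

    def test_pipeline_linear_in_recording(self, shallow_study32):
        st = shallow_study32
        sp1 = sinv.reconstruct_band(
            st["rec"], st["grid"], st["fields"], sinv.BandSpec(8, 12)
        )
        scaled = fsim.EEGRecording(
            3.0 * st["rec"].data, st["rec"].fs, st["rec"].sensors
        )
        sp3 = sinv.reconstruct_band(
            scaled, st["grid"], st["fields"], sinv.BandSpec(8, 12)
        )
        np.testing.assert_allclose(sp3.phi, 3.0 * sp1.phi, rtol=1e-8)

    def test_sensor_residual_does_not_diverge(self, shallow_study32):
        """The sensor-fit residual stays negligible relative to the data
        power across all iterations on the noiseless fixture; growth would
        flag a divergent operator iteration."""
        st = shallow_study32
        sp = sinv.reconstruct_band(
            st["rec"], st["grid"], st["fields"], sinv.BandSpec(8, 12),
            sinv.ReconstructionConfig(K=10, tol=1e-30),
        )
        _, coeffs = sinv.band_transform(st["rec"], sinv.BandSpec(8, 12))
        for b, resid in enumerate(sp.residual_history):
            data_power = np.sum(np.abs(coeffs[:, b]) ** 2)
            # the scaled fit is always better than the trivial zero fit and
            # iteration never makes it blow up
            assert np.max(resid) <= 0.5 * data_power
            assert resid[-1] <= 5.0 * resid[0]

    def test_shallow_source_band_power_recovery(self, shallow_study32):
        """On a superficial source the reconstruction recovers the spatial
        band-power pattern well (the deep-source case is probed separately
        in the acceptance suite)."""
        st = shallow_study32
        mask = tmod.brain_mask(st["grid"])
        power = band_power_of_reconstruction(st)
        r = np.corrcoef(st["gt_band_power"][mask], power[mask])[0, 1]
        assert r > 0.5

    def test_noise_degrades_gracefully(self, shallow_study32):
        st = shallow_study32
        mask = tmod.brain_mask(st["grid"])
        gt = st["gt_band_power"][mask]
        r_clean = np.corrcoef(
            gt, band_power_of_reconstruction(st)[mask]
        )[0, 1]
        rs = []
        for s in range(3):
            noisy = fsim.sample_sensors(
                st["field"], st["sensors"], st["grid"], snr_db=10.0, seed=100 + s
            )
            rs.append(
                np.corrcoef(gt, band_power_of_reconstruction(st, rec=noisy)[mask])[
                    0, 1
                ]
            )
        assert min(rs) >= 0.9 * r_clean


class TestTimeDomain:
    def _single_bin_potential(self, grid, f_hz, iv, coeff=1.0):
        phi = np.zeros((1,) + grid.shape, dtype=complex)
        phi[0][iv] = coeff
        return sinv.SpectralPotential(bins_hz=[f_hz], phi=phi, grid=grid)

    def test_single_bin_is_cosine(self, small32):
        grid = small32[0]
        fs, n = 64.0, 128
        sp = self._single_bin_potential(grid, 8.0, (4, 5, 6))
        field = sinv.to_time_domain(sp, fs, n)
        t = np.arange(n) / fs
        np.testing.assert_allclose(
            field.phi[4, 5, 6], np.cos(2 * np.pi * 8.0 * t), atol=1e-12
        )
        assert np.isrealobj(field.phi)

    def test_round_trip_band_coefficients(self, small32):
        grid, fields, sensors = small32
        rng = np.random.default_rng(4)
        fs, n = 64.0, 128
        bins = np.array([8.0, 9.0, 10.0])
        phi = rng.standard_normal((3,) + grid.shape) + 1j * rng.standard_normal(
            (3,) + grid.shape
        )
        sp = sinv.SpectralPotential(bins_hz=bins, phi=phi, grid=grid)
        field = sinv.to_time_domain(sp, fs, n)
        rec = fsim.sample_sensors(
            field,
            fsim.SensorArray(
                sensors.names, sensors.positions, reference="none"
            ),
            grid,
        )
        freqs, coeffs = sinv.band_transform(rec, sinv.BandSpec(7.5, 10.5))
        vox = grid.world_to_voxel(sensors.positions)
        for b, f_hz in enumerate(bins):
            expected = sinv._trilinear(phi[b], vox)
            got = coeffs[:, np.argmin(np.abs(freqs - f_hz))]
            np.testing.assert_allclose(got, expected, rtol=0.01)

    def test_band_above_nyquist_rejected(self, small32):
        grid = small32[0]
        sp = self._single_bin_potential(grid, 40.0, (1, 1, 1))
        with pytest.raises(sinv.InverseError):
            sinv.to_time_domain(sp, 64.0, 64)


class TestBandPower:
    def test_quadratic_scaling_and_parseval(self, small32):
        grid = small32[0]
        rng = np.random.default_rng(5)
        phi = rng.standard_normal((2,) + grid.shape) + 1j * rng.standard_normal(
            (2,) + grid.shape
        )
        sp = sinv.SpectralPotential(bins_hz=[8.0, 10.0], phi=phi, grid=grid)
        pm = sinv.band_power_map(sp)
        sp2 = sinv.SpectralPotential(bins_hz=[8.0, 10.0], phi=2 * phi, grid=grid)
        np.testing.assert_allclose(sinv.band_power_map(sp2), 4 * pm)
        # time-domain variance equals half the band power (orthogonal bins)
        field = sinv.to_time_domain(sp, 64.0, 128)
        np.testing.assert_allclose(
            np.var(field.phi, axis=-1), pm / 2, rtol=1e-10
        )
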