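"""Generator correctness: reference lines, background families, noise, composition."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

import pinncal as pc
from pinncal.spectra import WavelengthGrid


class TestWavelengthGrid:
    def test_uniform_grid_spacing(self):
        grid = pc.make_wavelength_grid(350, 1049, 700)
        assert grid.n_points == 700
        assert grid.spacing == pytest.approx(1.0)
        assert grid.values[0] == 350 and grid.values[-1] == 1049

    def test_three_point_grid(self):
        grid = pc.make_wavelength_grid(0, 2, 3)
        np.testing.assert_allclose(grid.values, [0, 1, 2])

    @pytest.mark.parametrize(
        "start,stop,n", [(500, 400, 10), (400, 400, 10), (0, 1, 1)]
    )
    def test_invalid_arguments(self, start, stop, n):
        with pytest.raises(ValueError):
            pc.make_wavelength_grid(start, stop, n)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            WavelengthGrid(np.array([1.0, 3.0, 2.0]))


class TestReferenceSpectrum:
    def test_peak_value_at_line_centre(self):
        # at 656.3 nm the first term is exactly I_1 and the second is
        # 60*exp(-1810.1...) which underflows to zero
        grid = WavelengthGrid(np.array([486.1, 656.3, 700.0]))
        ref = pc.reference_spectrum(pc.scenario_peaks("N01")[0], grid)
        assert ref.intensities[1] == pytest.approx(180.0, rel=1e-12)

    def test_two_sigma_point(self):
        # lambda_1 + 2*sigma_1 puts the exponent at exactly -1
        grid = WavelengthGrid(np.array([656.3, 660.3]))
        ref = pc.reference_spectrum(pc.scenario_peaks("N01")[0], grid)
        assert ref.intensities[1] == pytest.approx(180.0 * np.exp(-1), rel=1e-12)

    def test_single_peak_symmetry(self):
        peaks = (pc.PeakParams(100.0, 500.0, 3.0),)
        for delta in (0.5, 2.0, 7.7):
            grid = WavelengthGrid(np.array([500.0 - delta, 500.0 + delta]))
            vals = pc.reference_spectrum(peaks, grid).intensities
            assert vals[0] == pytest.approx(vals[1], rel=1e-14)

    def test_argmax_at_main_line(self, default_grid):
        ref = pc.reference_set_for("N01", default_grid)
        peak_idx = int(np.argmax(ref.matrix[0]))
        nearest = int(np.argmin(np.abs(default_grid.values - 656.3)))
        assert peak_idx == nearest

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            pc.PeakParams(1.0, 500.0, 0.0)
        with pytest.raises(ValueError):
            pc.PeakParams(-1.0, 500.0, 1.0)

    def test_n06_has_two_distinct_references(self, default_grid):
        refs = pc.reference_set_for("N06", default_grid)
        assert refs.n_agents == 2
        main = [default_grid.values[np.argmax(row)] for row in refs.matrix]
        assert main[0] == pytest.approx(656.0, abs=1.0)
        assert main[1] == pytest.approx(587.0, abs=1.0)


class TestBackgrounds:
    def test_n01_constant_ten(self, default_grid):
        cfg = pc.ScenarioConfig("N01", seed=1)
        bg = pc.background_sample(cfg, default_grid, np.random.default_rng(1))
        np.testing.assert_array_equal(bg.intensities, 10.0)

    def test_n03_peak_at_500(self):
        grid = WavelengthGrid(np.array([425.0, 500.0, 575.0]))
        cfg = pc.ScenarioConfig("N03", seed=1)
        bg = pc.background_sample(cfg, grid, np.random.default_rng(0))
        assert bg.intensities[1] == pytest.approx(50.0)
        # one sigma (75 nm) away on either side
        assert bg.intensities[0] == pytest.approx(50.0 * np.exp(-0.5))
        assert bg.intensities[2] == pytest.approx(50.0 * np.exp(-0.5))

    def test_n02_level_in_range_and_flat(self, default_grid):
        cfg = pc.ScenarioConfig("N02", seed=5)
        for _ in range(5):
            bg = pc.background_sample(cfg, default_grid, np.random.default_rng(5))
            assert np.ptp(bg.intensities) == 0
            assert 10.0 <= bg.intensities[0] <= 60.0

    def test_n04_hand_value(self):
        # eps1=2, eps2=0.5 puts the bump centre at 600 nm with amplitude 100
        ds = pc.synthesize_dataset(pc.ScenarioConfig("N04", n_samples=50, seed=3))
        lam = ds.grid.values
        eps1 = ds.nuisance_draws["eps1"]
        eps2 = ds.nuisance_draws["eps2"]
        expected = 50.0 * eps1[:, None] * np.exp(
            -((lam[None, :] - 500.0 - 200.0 * eps2[:, None]) ** 2) / (2 * 75.0**2)
        )
        np.testing.assert_allclose(ds.background_component, expected, rtol=1e-12)
        manual = 50.0 * 2.0 * np.exp(-((600.0 - 500.0 - 200.0 * 0.5) ** 2) / (2 * 75**2))
        assert manual == pytest.approx(100.0)

    def test_gaussian_fit_recovers_eps(self):
        """Every unsteady shaped background is 50*eps1*Gaussian for a recoverable (eps1, eps2)."""
        ds = pc.synthesize_dataset(
            pc.ScenarioConfig("N04", n_samples=5, seed=9, noise_sd=0.0)
        )
        lam = ds.grid.values

        def shape(x, a, mu):
            return a * np.exp(-((x - mu) ** 2) / (2 * 75.0**2))

        for i in range(ds.n_samples):
            popt, _ = curve_fit(
                shape, lam, ds.background_component[i], p0=(100.0, 600.0)
            )
            eps1_hat = popt[0] / 50.0
            assert eps1_hat == pytest.approx(ds.nuisance_draws["eps1"][i], abs=1e-6)
            eps2_hat = (popt[1] - 500.0) / 200.0
            assert eps2_hat == pytest.approx(ds.nuisance_draws["eps2"][i], abs=1e-6)

    def test_unknown_scenario_rejected(self, default_grid):
        with pytest.raises(ValueError):
            pc.ScenarioConfig("N99")


class TestNoise:
    def test_zero_sd_is_silent(self, default_grid):
        s = pc.noise_sample(default_grid, 0.0, np.random.default_rng(0))
        assert not s.intensities.any()

    def test_negative_sd_rejected(self, default_grid):
        with pytest.raises(ValueError):
            pc.noise_sample(default_grid, -1.0, np.random.default_rng(0))

    def test_moments_at_large_n(self):
        grid = pc.make_wavelength_grid(0, 99999, 100000)
        draws = pc.noise_sample(grid, 5.0, np.random.default_rng(42)).intensities
        assert abs(draws.mean()) < 3 * 5.0 / np.sqrt(draws.size)
        assert draws.std() == pytest.approx(5.0, rel=0.02)


class TestDatasetComposition:
    def test_components_sum_exactly(self):
        for scenario in pc.SCENARIO_IDS:
            ds = pc.synthesize_dataset(
                pc.ScenarioConfig(scenario, n_samples=8, seed=2)
            )
            np.testing.assert_array_equal(
                ds.measured,
                ds.agent_component + ds.background_component + ds.noise_component,
            )

    def test_concentrations_within_range(self):
        ds = pc.synthesize_dataset(pc.ScenarioConfig("N06", n_samples=200, seed=4))
        assert ds.concentrations.shape == (200, 2)
        assert ds.concentrations.min() >= 0.0
        assert ds.concentrations.max() <= 2.0

    def test_noiseless_unit_concentration_identity(self):
        ds = pc.synthesize_dataset(
            pc.ScenarioConfig(
                "N01", n_samples=3, seed=6, noise_sd=0.0, concentration_range=(1.0, 1.0 + 1e-12)
            )
        )
        expected = ds.references.matrix[0] + 10.0
        for row in ds.measured:
            np.testing.assert_allclose(row, expected, rtol=1e-9)

    def test_seed_determinism_bitwise(self):
        a = pc.synthesize_dataset(pc.ScenarioConfig("N04", n_samples=15, seed=77))
        b = pc.synthesize_dataset(pc.ScenarioConfig("N04", n_samples=15, seed=77))
        assert a.measured.tobytes() == b.measured.tobytes()
        assert a.concentrations.tobytes() == b.concentrations.tobytes()
        c = pc.synthesize_dataset(pc.ScenarioConfig("N04", n_samples=15, seed=78))
        assert a.measured.tobytes() != c.measured.tobytes()

    def test_measurements_only_strips_components(self, n01_small):
        stripped = n01_small.without_components()
        assert stripped.agent_component.size == 0
        assert stripped.measured.shape == n01_small.measured.shape

    def test_labelled_sample_view(self, n01_small):
        s = n01_small.sample(0)
        total = (
            s.components["agent"].intensities
            + s.components["background"].intensities
            + s.components["noise"].intensities
        )
        np.testing.assert_array_equal(s.measured.intensities, total)
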