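"""Physics-informed loss terms: identities, brute-force oracle, alpha heuristic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pinncal as pc
from pinncal.spectra import ReferenceSet, Spectrum, WavelengthGrid


def _brute_force_reconstruction(measured, c, refs, background):
    """Term-by-term summation oracle, scalar loops only."""
    total = 0.0
    n_samples = measured.shape[0]
    for b in range(n_samples):
        for l in range(measured.shape[1]):
            model = 0.0
            for j in range(refs.shape[0]):
                model += c[b, j] * refs[j, l]
            total += (measured[b, l] - model - background[b, l]) ** 2
    return total / n_samples


def _toy_refs(n_points=6, n_agents=1, seed=0):
    rng = np.random.default_rng(seed)
    grid = WavelengthGrid(np.arange(n_points, dtype=float))
    return ReferenceSet(grid, rng.uniform(0, 10, (n_agents, n_points)))


class TestReconstructionLoss:
    def test_exact_reconstruction_is_zero(self):
        refs = _toy_refs(10)
        c = np.array([[1.7]])
        bg = np.full((1, 10), 3.0)
        measured = c @ refs.matrix + bg
        assert pc.reconstruction_loss(measured, c, refs, bg) == pytest.approx(0.0, abs=1e-18)

    def test_all_ones_residual_sums_points(self, default_grid):
        refs = pc.reference_set_for("N01", default_grid)
        measured = np.ones((1, 700))
        assert pc.reconstruction_loss(
            measured, np.zeros((1, 1)), refs, np.zeros((1, 700))
        ) == pytest.approx(700.0)

    def test_two_class_exact_reconstruction(self, default_grid):
        refs = pc.reference_set_for("N06", default_grid)
        c = np.array([[0.4, 1.3], [2.0, 0.1]])
        bg = np.tile(np.linspace(5, 8, 700), (2, 1))
        measured = c @ refs.matrix + bg
        assert pc.reconstruction_loss(measured, c, refs, bg) == pytest.approx(0.0, abs=1e-18)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        n_points=st.integers(2, 10),
        n_agents=st.integers(1, 3),
        n_samples=st.integers(1, 4),
        seed=st.integers(0, 1000),
    )
    def test_matches_brute_force_oracle(self, n_points, n_agents, n_samples, seed):
        rng = np.random.default_rng(seed)
        refs = _toy_refs(n_points, n_agents, seed)
        measured = rng.normal(0, 50, (n_samples, n_points))
        c = rng.uniform(0, 2, (n_samples, n_agents))
        bg = rng.normal(0, 20, (n_samples, n_points))
        fast = pc.reconstruction_loss(measured, c, refs, bg)
        slow = _brute_force_reconstruction(measured, c, refs.matrix, bg)
        assert fast == pytest.approx(slow, rel=1e-12)

    def test_grid_mismatch_rejected(self):
        refs = _toy_refs(6)
        with pytest.raises(ValueError):
            pc.reconstruction_loss(np.ones((1, 5)), np.ones((1, 1)), refs, np.ones((1, 5)))


class TestSmoothnessLoss:
    def test_constant_background_is_smooth(self):
        assert pc.smoothness_loss(np.full((1, 50), 7.0), spacing=1.0) == 0.0

    def test_unit_ramp_700_points(self):
        ramp = np.arange(700.0)
        assert pc.smoothness_loss(ramp, spacing=1.0) == pytest.approx(699.0)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(3)
        bg = rng.normal(size=(2, 40))
        assert pc.smoothness_loss(2 * bg, spacing=1.0) == pytest.approx(
            4 * pc.smoothness_loss(bg, spacing=1.0)
        )

    def test_spacing_division(self):
        bg = np.arange(10.0)
        assert pc.smoothness_loss(bg, spacing=2.0) == pytest.approx(9 * 0.25)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            pc.smoothness_loss(np.ones((1, 1)), spacing=1.0)


class TestTotalLoss:
    def test_alpha_zero_disables_regulariser(self):
        refs = _toy_refs(8)
        rng = np.random.default_rng(1)
        measured = rng.normal(0, 10, (2, 8))
        c = rng.uniform(0, 2, (2, 1))
        bg = rng.normal(0, 5, (2, 8))
        breakdown = pc.total_loss(measured, c, refs, bg, alpha=0.0)
        assert breakdown.total == breakdown.reconstruction

    def test_exact_fit_zero_for_any_alpha(self):
        refs = _toy_refs(8)
        c = np.array([[0.5]])
        bg = np.full((1, 8), 2.0)
        measured = c @ refs.matrix + bg
        for alpha in (0.0, 0.1, 100.0):
            assert pc.total_loss(measured, c, refs, bg, alpha).total == pytest.approx(0.0, abs=1e-18)

    def test_decomposition_identity(self):
        refs = _toy_refs(9, 2, seed=4)
        rng = np.random.default_rng(5)
        measured = rng.normal(0, 30, (3, 9))
        c = rng.uniform(0, 2, (3, 2))
        bg = rng.normal(0, 10, (3, 9))
        for alpha in (0.0, 0.017, 3.5):
            br = pc.total_loss(measured, c, refs, bg, alpha)
            assert br.total == br.reconstruction + alpha * br.smoothness

    def test_negative_alpha_rejected(self):
        refs = _toy_refs(4)
        with pytest.raises(ValueError):
            pc.total_loss(np.ones((1, 4)), np.ones((1, 1)), refs, np.ones((1, 4)), -0.1)

    def test_linear_response_hook_reproduces_linear_model(self):
        refs = _toy_refs(12, 2, seed=8)
        rng = np.random.default_rng(9)
        measured = rng.normal(0, 20, (3, 12))
        c = rng.uniform(0, 2, (3, 2))
        bg = rng.normal(0, 5, (3, 12))

        def linear_response(conc, grid):
            return np.atleast_2d(conc) @ refs.matrix

        with_hook = pc.total_loss(measured, c, refs, bg, 0.3, response=linear_response)
        without = pc.total_loss(measured, c, refs, bg, 0.3)
        assert with_hook.total == pytest.approx(without.total, rel=1e-14)

    def test_nonlinear_response_changes_the_model_term(self):
        refs = _toy_refs(12, 1, seed=8)
        c = np.array([[1.5]])
        bg = np.zeros((1, 12))
        measured = (c**2) @ refs.matrix  # instrument responds quadratically

        def quadratic(conc, grid):
            return (np.atleast_2d(conc) ** 2) @ refs.matrix

        assert pc.total_loss(measured, c, refs, bg, 0.0, response=quadratic).total == 0.0
        assert pc.total_loss(measured, c, refs, bg, 0.0).total > 0.0


class TestAlphaHeuristic:
    def test_toy_triangle(self):
        tri = Spectrum(WavelengthGrid(np.array([0.0, 1.0, 2.0])), np.array([0.0, 1.0, 0.0]))
        assert pc.alpha_heuristic(tri) == pytest.approx(0.25)

    def test_intensity_scale_invariance(self, default_grid):
        refs = pc.reference_set_for("N01", default_grid)
        scaled = ReferenceSet(default_grid, 37.5 * refs.matrix)
        assert pc.alpha_heuristic(scaled) == pytest.approx(pc.alpha_heuristic(refs), rel=1e-12)

    def test_grid_translation_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 5, 64)
        a = Spectrum(WavelengthGrid(np.arange(64.0)), vals)
        b = Spectrum(WavelengthGrid(np.arange(64.0) + 123.0), vals)
        assert pc.alpha_heuristic(a) == pytest.approx(pc.alpha_heuristic(b), rel=1e-12)

    def test_quarters_when_derivative_doubles(self):
        # same sum(I0), doubled derivative magnitude: the feature scale ell
        # halves, so the weight ell^2 quarters
        grid = WavelengthGrid(np.arange(8.0))
        slow = Spectrum(grid, np.array([0.0, 1, 2, 3, 3, 2, 1, 0.0]))
        fast = Spectrum(grid, np.array([0.0, 2, 2, 4, 0, 2, 2, 0.0]))
        assert np.sum(slow.intensities) == np.sum(fast.intensities)
        d_slow = np.abs(np.diff(slow.intensities)).sum()
        d_fast = np.abs(np.diff(fast.intensities)).sum()
        assert d_fast == 2 * d_slow
        assert pc.alpha_heuristic(fast) == pytest.approx(pc.alpha_heuristic(slow) / 4)

    def test_constant_reference_degenerate(self):
        flat = Spectrum(WavelengthGrid(np.arange(5.0)), np.full(5, 3.0))
        with pytest.raises(ValueError):
            pc.alpha_heuristic(flat)

    def test_multiclass_is_mean_of_per_class(self, default_grid):
        refs = pc.reference_set_for("N06", default_grid)
        singles = [
            pc.alpha_heuristic(Spectrum(default_grid, row)) for row in refs.matrix
        ]
        assert pc.alpha_heuristic(refs) == pytest.approx(np.mean(singles), rel=1e-12)
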