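"""Reaction-diffusion integration: fixed points, wavelengths, reproducibility."""

import numpy as np
import pytest

from digituring import (
    GridSpec,
    choose_grid,
    classify_turing,
    kinetic_model_from_matrix,
    simulate,
)
from digituring.simulate import default_dt


class TestGridSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(1, (80.0,), (8,))  # too few points
        with pytest.raises(ValueError):
            GridSpec(1, (-1.0,), (64,))
        with pytest.raises(ValueError):
            GridSpec(3, (10.0,), (64,))
        with pytest.raises(ValueError):
            GridSpec(1, (10.0,), (64,), boundary="absorbing")

    def test_2d_scalar_extent_broadcast(self):
        g = GridSpec(2, (40.0,), (32,))
        assert g.extent == (40.0, 40.0)
        assert g.shape == (32, 32)


class TestSimulate:
    def test_zero_noise_stays_homogeneous(self, reference_model):
        g = GridSpec(1, (80.0,), (64,))
        r = simulate(reference_model, g, t_end=20.0, seed=0, noise_amplitude=0.0)
        assert np.abs(r.fields).max() == 0.0

    def test_reference_pattern_wavelength(self, reference_run):
        """Dominant wavelength within 15% of 2*pi/k_max (k_max^2 ~ 0.4 from
        the closed-form dispersion minimum of h(k^2))."""
        from digituring.metrics import summarize_pattern

        assert reference_run.converged
        s = summarize_pattern(reference_run)
        predicted = 2 * np.pi / np.sqrt(0.4)
        assert abs(s.dominant_wavelength[0] / predicted - 1) < 0.15

    def test_stable_model_decays_to_uniform(self):
        m = kinetic_model_from_matrix([[-1.0, 0.5], [0.2, -2.0]], [1.0, 10.0])
        assert classify_turing(m).turing_class == "none"
        g = GridSpec(1, (80.0,), (64,))
        r = simulate(m, g, t_end=60.0, seed=3, noise_amplitude=1e-3)
        assert r.final_fields().std() < 1e-3 * 1e-3

    def test_bit_reproducible(self, reference_model):
        g = GridSpec(1, (80.0,), (64,))
        r1 = simulate(reference_model, g, t_end=30.0, seed=9)
        r2 = simulate(reference_model, g, t_end=30.0, seed=9)
        np.testing.assert_array_equal(r1.fields, r2.fields)

    def test_snapshot_count_and_shapes(self, reference_run):
        assert len(reference_run.times) >= 20
        n_nodes = reference_run.model.n_nodes
        assert reference_run.fields.shape[1] == n_nodes
        assert reference_run.fields.shape[2] == reference_run.grid.n_points[0]

    def test_timestep_convergence(self, reference_model, reference_run):
        """Halving dt changes the final field by < 1% in relative L2."""
        r2 = simulate(
            reference_model,
            reference_run.grid,
            t_end=200.0,
            seed=42,
            dt=reference_run.dt_used / 2,
        )
        rel = np.linalg.norm(r2.final_fields() - reference_run.final_fields())
        rel /= np.linalg.norm(reference_run.final_fields())
        assert rel < 0.01

    def test_translation_equivariance_periodic(self, reference_model):
        """Cyclically shifting the initial noise shifts the final pattern."""
        g = GridSpec(1, (80.0,), (64,))
        rng = np.random.default_rng(5)
        u0 = 1e-3 * rng.standard_normal((2, 64))
        shift = 17
        r1 = simulate(reference_model, g, t_end=150.0, initial_field=u0)
        r2 = simulate(
            reference_model, g, t_end=150.0, initial_field=np.roll(u0, shift, axis=1)
        )
        np.testing.assert_allclose(
            np.roll(r1.final_fields(), shift, axis=1),
            r2.final_fields(),
            atol=1e-8,
        )

    def test_wavelength_consistent_across_seeds(
        self, reference_model, reference_classification
    ):
        """Across seeds the selected wavelength tracks the dispersion peak."""
        from digituring.metrics import summarize_pattern

        g = choose_grid(reference_model, 8)
        predicted = reference_classification.dispersion.wavelength
        for seed in range(5):
            r = simulate(reference_model, g, t_end=200.0, seed=seed)
            s = summarize_pattern(r, allow_unconverged=True)
            assert abs(s.dominant_wavelength[0] / predicted - 1) < 0.15

    def test_linear_regime_growth_rate(
        self, reference_model, reference_classification
    ):
        """The k_max Fourier mode initially grows at lambda_max (within 10%)."""
        d = reference_classification.dispersion
        g = choose_grid(reference_model, 8)
        t_fold = 1.0 / d.lambda_max
        r = simulate(
            reference_model, g, t_end=t_fold, seed=2, n_snapshots=11
        )
        mode = int(round(g.extent[0] / (2 * np.pi / d.k_max)))
        amps = np.abs(np.fft.rfft(r.fields[:, 0], axis=1))[:, mode]
        slope = np.polyfit(r.times, np.log(amps), 1)[0]
        assert abs(slope / d.lambda_max - 1) < 0.10

    def test_2d_simulation_patterns(self, reference_model):
        from digituring.metrics import summarize_pattern

        g = GridSpec(2, (43.0,), (32,))
        r = simulate(reference_model, g, t_end=150.0, seed=1)
        s = summarize_pattern(r, allow_unconverged=True)
        assert s.amplitude[0] > 0.05  # patterned, not decayed
        predicted = 2 * np.pi / np.sqrt(0.4)
        assert abs(s.dominant_wavelength[0] / predicted - 1) < 0.25

    def test_blowup_reported_with_diagnosis(self):
        from digituring.simulate import SimulationError

        # strongly unstable homogeneous state with negligible saturation
        m = kinetic_model_from_matrix(
            [[5.0, 0.0], [0.0, 5.0]], [1.0, 1.0], saturation=1e-12
        )
        g = GridSpec(1, (80.0,), (64,))
        with pytest.raises(SimulationError, match="saturation"):
            simulate(m, g, t_end=2000.0, seed=0, noise_amplitude=10.0)


class TestChooseGrid:
    def test_extent_is_whole_wavelengths(self, reference_model, reference_classification):
        g = choose_grid(reference_model, 8)
        lam = 2 * np.pi / reference_classification.dispersion.k_max
        np.testing.assert_allclose(g.extent[0], 8 * lam)
        assert g.n_points[0] >= 16 * 8

    def test_single_wavelength(self, reference_model, reference_classification):
        g = choose_grid(reference_model, 1)
        lam = 2 * np.pi / reference_classification.dispersion.k_max
        np.testing.assert_allclose(g.extent[0], lam)

    def test_non_turing_model_rejected(self):
        m = kinetic_model_from_matrix([[-1.0, 0.0], [0.0, -2.0]], [1.0, 10.0])
        with pytest.raises(ValueError, match="none"):
            choose_grid(m, 8)


def test_default_dt_scales_with_stiffness():
    m1 = kinetic_model_from_matrix([[1.0, -1.0], [3.0, -2.0]], [1.0, 10.0])
    m2 = kinetic_model_from_matrix([[10.0, -10.0], [30.0, -20.0]], [1.0, 10.0])
    assert default_dt(m2) == pytest.approx(default_dt(m1) / 10)
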