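"""Pattern quantification: wavelengths, stripes, phase calls."""

import dataclasses

import numpy as np
import pytest

from digituring import (
    GridSpec,
    check_phase_claims,
    kinetic_model_from_matrix,
    simulate,
    summarize_pattern,
)
from digituring.metrics import amplitude_timeseries
from digituring.simulate import SimulationResult


def synthetic_result(profiles, extent=80.0, boundary="periodic"):
    """Wrap hand-built final profiles in a SimulationResult (synthetic stand-in)."""
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    A = -np.eye(n)
    m = kinetic_model_from_matrix(A, np.ones(n))
    fields = np.stack([profiles, profiles])  # two identical snapshots
    return SimulationResult(
        model=m,
        grid=GridSpec(1, (extent,), (profiles.shape[1],), boundary),
        times=np.array([0.0, 1.0]),
        fields=fields,
        seed=None,
        converged=True,
        dt_used=0.1,
        noise_amplitude=0.0,
    )


class TestSummarize:
    def test_pure_mode_wavelength_and_stripes(self):
        """sin(2*pi*4x/L) on a periodic domain: wavelength L/4, 4 stripes."""
        x = np.linspace(0, 1, 128, endpoint=False)
        r = synthetic_result([np.sin(2 * np.pi * 4 * x)], extent=80.0)
        s = summarize_pattern(r)
        assert s.dominant_wavelength[0] == pytest.approx(20.0)
        assert s.stripe_count[0] == 4

    def test_anti_phase_profiles_correlate_negatively(self):
        x = np.linspace(0, 1, 128, endpoint=False)
        u = np.sin(2 * np.pi * 4 * x)
        s = summarize_pattern(synthetic_result([u, -u]))
        assert s.phase_matrix[0, 1] == pytest.approx(-1.0)
        assert s.in_phase_calls[0, 1] == -1

    def test_phase_matrix_structure(self):
        rng = np.random.default_rng(0)
        s = summarize_pattern(synthetic_result(rng.standard_normal((3, 64))))
        np.testing.assert_allclose(s.phase_matrix, s.phase_matrix.T)
        np.testing.assert_allclose(np.diag(s.phase_matrix), 1.0)
        assert (np.abs(s.phase_matrix) <= 1.0).all()

    def test_scale_invariance(self):
        x = np.linspace(0, 1, 128, endpoint=False)
        u = np.sin(2 * np.pi * 5 * x) + 0.3 * np.sin(2 * np.pi * 10 * x)
        v = np.cos(2 * np.pi * 5 * x)
        s1 = summarize_pattern(synthetic_result([u, v]))
        s2 = summarize_pattern(synthetic_result([17.0 * u, 17.0 * v]))
        np.testing.assert_allclose(s1.dominant_wavelength, s2.dominant_wavelength)
        np.testing.assert_array_equal(s1.stripe_count, s2.stripe_count)
        np.testing.assert_allclose(s1.phase_matrix, s2.phase_matrix, atol=1e-12)

    def test_stripe_count_consistent_with_wavelength(self, reference_run):
        """On periodic domains: stripes == round(extent / wavelength) +- 1."""
        s = summarize_pattern(reference_run)
        for i in range(2):
            expected = round(reference_run.grid.extent[0] / s.dominant_wavelength[i])
            assert abs(s.stripe_count[i] - expected) <= 1

    def test_periodic_wraparound_stripe_merging(self):
        x = np.linspace(0, 1, 128, endpoint=False)
        # stripe straddling the domain edge: cos peaks at x=0 and x=1
        r = synthetic_result([np.cos(2 * np.pi * 3 * x)])
        assert summarize_pattern(r).stripe_count[0] == 3

    def test_flat_profile_degenerate(self):
        s = summarize_pattern(synthetic_result([np.zeros(64)]))
        assert np.isnan(s.dominant_wavelength[0])
        assert s.stripe_count[0] == 0

    def test_unconverged_rejected_without_override(self, reference_model):
        g = GridSpec(1, (80.0,), (64,))
        r = simulate(reference_model, g, t_end=5.0, seed=0)
        r = dataclasses.replace(r, converged=False)
        with pytest.raises(ValueError, match="converged"):
            summarize_pattern(r)
        summarize_pattern(r, allow_unconverged=True)  # override works

    def test_linear_phase_prediction_matches_simulation(
        self, reference_run, reference_classification
    ):
        """Leading-eigenvector signs predict the simulated phase relations."""
        s = summarize_pattern(reference_run)
        predicted = reference_classification.predicted_phase
        row = s.phase_matrix[0]
        for i in range(len(row)):
            if abs(row[i]) > s.phase_threshold:
                assert np.sign(row[i]) == predicted[0] * predicted[i]


class TestClaims:
    def test_same_node_claim_passes(self):
        x = np.linspace(0, 1, 64, endpoint=False)
        s = summarize_pattern(synthetic_result([np.sin(2 * np.pi * 3 * x)]))
        report = check_phase_claims(s, [("N0", "N0", "in")])
        assert report.passed
        assert report.verdicts[0].correlation == pytest.approx(1.0)

    def test_empty_claims_vacuous_pass(self):
        s = summarize_pattern(synthetic_result([np.ones(64) * 0.0]))
        assert check_phase_claims(s, []).passed

    def test_unknown_node_rejected(self):
        x = np.linspace(0, 1, 64, endpoint=False)
        s = summarize_pattern(synthetic_result([np.sin(2 * np.pi * 3 * x)]))
        with pytest.raises(KeyError, match="GREM1"):
            check_phase_claims(s, [("N0", "GREM1", "out")])

    def test_out_of_phase_claim(self):
        x = np.linspace(0, 1, 64, endpoint=False)
        u = np.sin(2 * np.pi * 3 * x)
        s = summarize_pattern(synthetic_result([u, -u]))
        assert check_phase_claims(s, [("N0", "N1", "out")]).passed
        assert not check_phase_claims(s, [("N0", "N1", "in")]).passed

    def test_bad_relation_keyword_rejected(self):
        x = np.linspace(0, 1, 64, endpoint=False)
        s = summarize_pattern(synthetic_result([np.sin(2 * np.pi * 3 * x)]))
        with pytest.raises(ValueError, match="'in' or 'out'"):
            check_phase_claims(s, [("N0", "N0", "sideways")])


class TestAmplitudeTimeseries:
    def test_zero_noise_all_zero(self, reference_model):
        g = GridSpec(1, (80.0,), (64,))
        r = simulate(reference_model, g, t_end=10.0, seed=0, noise_amplitude=0.0)
        _, amp = amplitude_timeseries(r, "N0")
        np.testing.assert_array_equal(amp, 0.0)

    def test_growth_then_plateau(self, reference_run):
        """Amplitude rises monotonically then plateaus within a 5% band."""
        times, amp = amplitude_timeseries(reference_run, "N0")
        assert len(amp) == len(times)
        assert (amp >= 0).all()
        peak = amp.max()
        settled = amp[amp > 0.95 * peak]
        assert len(settled) >= 3  # plateau reached
        assert settled.std() / settled.mean() < 0.05
        rising = amp[: int(np.argmax(amp > 0.95 * peak)) + 1]
        assert (np.diff(rising) > -1e-6).all()

    def test_unknown_node_rejected(self, reference_run):
        with pytest.raises(KeyError):
            amplitude_timeseries(reference_run, "SHH")
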