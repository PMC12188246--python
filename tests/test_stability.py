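"""Dispersion relations, Turing classification and the two-node oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from digituring import (
    build_kinetic_model,
    load_circuit,
    classify_turing,
    dispersion_relation,
    kinetic_model_from_matrix,
    two_node_oracle,
)
from digituring.network import Interaction, NetworkTopology, Node
from digituring.stability import ModelError, default_k_grid


class TestBuildKineticModel:
    def test_matrix_from_magnitudes(self):
        t = NetworkTopology(
            "t2",
            (Node("U", True, 1.0), Node("V", True, 10.0)),
            (
                Interaction("U", "U", 1),
                Interaction("V", "U", -1),
                Interaction("U", "V", 1),
            ),
        )
        m = build_kinetic_model(
            t,
            {("U", "U"): 2.0, ("V", "U"): 1.0, ("U", "V"): 3.0},
            decay=[1.0, 2.0],
        )
        np.testing.assert_allclose(
            m.interaction_matrix, [[1.0, -1.0], [3.0, -2.0]]
        )

    def test_sign_pattern_matches_topology(self):
        t = load_circuit("wnt3")
        m = build_kinetic_model(
            t,
            {(e.source, e.target): 1.0 for e in t.interactions},
            decay=np.ones(3),
        )
        for e in t.interactions:
            i, j = t.index(e.target), t.index(e.source)
            assert np.sign(m.strengths[i, j]) == e.sign

    def test_missing_magnitude_names_edge(self):
        t = load_circuit("wnt3")
        strengths = {(e.source, e.target): 1.0 for e in t.interactions}
        strengths.pop(("SFRP2", "WNT2"))
        with pytest.raises(ModelError, match="SFRP2->WNT2"):
            build_kinetic_model(t, strengths, decay=np.ones(3))

    def test_nonpositive_decay_rejected(self):
        t = load_circuit("wnt3")
        strengths = {(e.source, e.target): 1.0 for e in t.interactions}
        with pytest.raises(ModelError, match="decay"):
            build_kinetic_model(t, strengths, decay=[1.0, 0.0, 1.0])


class TestDispersion:
    def test_closed_form_band_and_growth(self, reference_model):
        """h(k^2) = D1 D2 k^4 - (D2 a11 + D1 a22) k^2 + det A has roots
        k^2 = (8 +- sqrt(24))/20 for the reference system."""
        d = dispersion_relation(reference_model)
        lo, hi = (8 - np.sqrt(24)) / 20, (8 + np.sqrt(24)) / 20
        assert d.unstable_band is not None
        np.testing.assert_allclose(d.unstable_band[0] ** 2, lo, rtol=1e-6)
        np.testing.assert_allclose(d.unstable_band[1] ** 2, hi, rtol=1e-6)
        assert d.lambda_max > 0
        assert lo < d.k_max**2 < hi

    def test_growth_at_zero_equals_matrix_eigenvalue(self, reference_model):
        d = dispersion_relation(reference_model)
        expected = np.linalg.eigvals(reference_model.interaction_matrix).real.max()
        np.testing.assert_allclose(d.growth_rate[0], expected, atol=1e-12)

    def test_no_diffusion_growth_constant(self):
        m = kinetic_model_from_matrix([[-1.0, 2.0], [-1.0, -2.0]], [0.0, 0.0])
        k = np.linspace(0, 3, 32)
        d = dispersion_relation(m, k_grid=k)
        np.testing.assert_allclose(d.growth_rate, d.growth_rate[0])

    def test_diagonal_decay_always_negative(self):
        m = kinetic_model_from_matrix([[-1.0, 0.0], [0.0, -2.0]], [1.0, 10.0])
        d = dispersion_relation(m)
        assert (d.growth_rate < 0).all()
        assert d.unstable_band is None

    def test_empty_grid_rejected(self, reference_model):
        with pytest.raises(ValueError):
            dispersion_relation(reference_model, k_grid=np.array([]))

    def test_refined_kmax_close_to_fine_grid_argmax(self, reference_model):
        """The local refinement lands within a coarse step of a 10x-finer scan."""
        coarse = default_k_grid(reference_model, 64)
        fine = default_k_grid(reference_model, 640)
        d_coarse = dispersion_relation(reference_model, k_grid=coarse)
        d_fine = dispersion_relation(reference_model, k_grid=fine, refine=False)
        step = coarse[1] - coarse[0] if len(coarse) > 1 else np.inf
        k_fine = d_fine.wavenumber_grid[np.argmax(d_fine.growth_rate)]
        assert abs(d_coarse.k_max - k_fine) < step

    def test_eigenvector_sign_convention(self, reference_classification):
        v = reference_classification.dispersion.leading_eigenvector
        np.testing.assert_allclose(np.linalg.norm(v), 1.0)
        assert v[np.argmax(np.abs(v))] > 0


class TestClassification:
    def test_reference_is_activator_inhibitor_in_phase(
        self, reference_classification
    ):
        c = reference_classification
        assert c.turing_class == "turing_I"
        assert c.mechanism == "activator_inhibitor"
        assert tuple(c.predicted_phase) == (1, 1)

    def test_substrate_depletion_out_of_phase(self):
        m = kinetic_model_from_matrix([[1.0, 1.0], [-3.0, -2.0]], [1.0, 10.0])
        c = classify_turing(m)
        assert c.turing_class == "turing_I"
        assert c.mechanism == "substrate_depletion"
        assert tuple(c.predicted_phase) == (1, -1)

    def test_equal_diffusion_never_destabilizes(self):
        m = kinetic_model_from_matrix([[1.0, -1.0], [3.0, -2.0]], [7.0, 7.0])
        assert classify_turing(m).turing_class == "none"

    def test_unstable_homogeneous_state_is_not_turing(self):
        m = kinetic_model_from_matrix([[1.0, -1.0], [0.5, -2.0]], [1.0, 10.0])
        c = classify_turing(m)
        assert not c.stable_homogeneous
        assert c.turing_class == "none"

    def test_turing_II_with_nondiffusible_activator(self):
        # self-activating non-diffusible species escapes diffusion damping
        m = kinetic_model_from_matrix([[1.0, -1.0], [3.0, -2.0]], [0.0, 10.0])
        assert classify_turing(m).turing_class == "turing_II"


class TestTwoNodeOracle:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((1, -1, 3, -2, 1, 10), "turing_I"),
            ((1, -1, 3, -2, 1, 5), "none"),  # (D2 a + D1 d)^2 = 9 < 4 D1 D2 det = 20
            ((-1, -1, 3, -2, 1, 10), "none"),  # no self-activating species
        ],
    )
    def test_worked_examples(self, args, expected):
        assert two_node_oracle(*args).turing_class == expected

    def test_agrees_with_numerical_classifier(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            a, b, c, d = rng.uniform(-5, 5, 4)
            D1, D2 = rng.uniform(0, 10, 2)
            m = kinetic_model_from_matrix([[a, b], [c, d]], [D1, D2])
            assert (
                classify_turing(m).turing_class
                == two_node_oracle(a, b, c, d, D1, D2).turing_class
            )


@st.composite
def stable_matrices(draw):
    """Random 2x2 matrices conditioned on a stable homogeneous state."""
    vals = draw(
        st.lists(
            st.floats(-5, 5, allow_nan=False, allow_infinity=False),
            min_size=4,
            max_size=4,
        )
    )
    A = np.array(vals).reshape(2, 2)
    eigs = np.linalg.eigvals(A).real
    if eigs.max() >= -1e-6:
        A = A - (eigs.max() + 0.5) * np.eye(2)
    return A


class TestProperties:
    @given(A=stable_matrices(), d=st.floats(0.1, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_equal_diffusion_theorem(self, A, d):
        """Uniform diffusion only shifts eigenvalues by -k^2 d: never Turing."""
        m = kinetic_model_from_matrix(A, [d, d])
        assert classify_turing(m).turing_class == "none"

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, seed):
        """Relabeling species permutes phases and preserves class/mechanism."""
        rng = np.random.default_rng(seed)
        A = rng.uniform(-4, 4, (3, 3))
        A -= (np.linalg.eigvals(A).real.max() + 0.5) * np.eye(3)
        D = np.array([1.0, 0.0, rng.uniform(5, 50)])
        perm = rng.permutation(3)
        m1 = kinetic_model_from_matrix(A, D)
        m2 = kinetic_model_from_matrix(A[np.ix_(perm, perm)], D[perm])
        c1, c2 = classify_turing(m1), classify_turing(m2)
        assert c1.turing_class == c2.turing_class
        if c1.turing_class != "none":
            assert c1.mechanism == c2.mechanism
            np.testing.assert_array_equal(c1.predicted_phase[perm], c2.predicted_phase)
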