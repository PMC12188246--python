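"""Shared fixtures: reference models and cached circuit realizations."""

from __future__ import annotations

import numpy as np
import pytest

from digituring import (
    SearchSpec,
    load_circuit,
    choose_grid,
    classify_turing,
    kinetic_model_from_matrix,
    sample_turing_parameters,
    simulate,
)
from digituring.workflow import realize_circuit


@pytest.fixture(scope="session")
def reference_model():
    """The classical two-species activator-inhibitor reference system."""
    return kinetic_model_from_matrix([[1.0, -1.0], [3.0, -2.0]], [1.0, 10.0])


@pytest.fixture(scope="session")
def reference_classification(reference_model):
    return classify_turing(reference_model)


@pytest.fixture(scope="session")
def reference_run(reference_model, reference_classification):
    """Converged 8-wavelength periodic 1D run of the reference system."""
    grid = choose_grid(
        reference_model, 8, classification=reference_classification
    )
    return simulate(reference_model, grid, t_end=200.0, seed=42)


@pytest.fixture(scope="session")
def wnt3_search():
    topo = load_circuit("wnt3")
    return sample_turing_parameters(
        SearchSpec(topology=topo, n_samples=20_000, seed=1)
    )


@pytest.fixture(scope="session")
def wnt3_realization():
    """A wnt3 hit realized as a converged in-phase pattern."""
    topo = load_circuit("wnt3")
    _, realization = realize_circuit(topo, n_samples=20_000, seed=1)
    assert realization is not None, "wnt3 should realize an in-phase pattern"
    return realization
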