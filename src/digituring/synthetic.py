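"""Synthetic networks and known-answer oracle systems.

Everything here is generated, never downloaded: random sign-constrained
topologies for property tests, and a suite of small kinetic models whose
Turing classifications are known from closed-form two-species analysis or an
exhaustive dispersion scan.  Generators emit the same in-memory types (and
config dialect) as the hand-written circuits, so fixtures and canonical
circuits share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import Interaction, NetworkTopology, Node
from .stability import KineticModel, kinetic_model_from_matrix


def random_topology(
    n_nodes: int,
    edge_probability: float,
    sign_bias: float = 0.5,
    diffusible_fraction: float = 0.5,
    seed: int = 0,
) -> NetworkTopology:
    """A seeded random signed digraph (self-edges included).

    Each ordered node pair (including self-pairs) carries an edge with
    probability ``edge_probability``; each edge is positive with probability
    ``sign_bias``; each node is diffusible with probability
    ``diffusible_fraction`` (diffusion coefficient 1).
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    for name, p in (
        ("edge_probability", edge_probability),
        ("sign_bias", sign_bias),
        ("diffusible_fraction", diffusible_fraction),
    ):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [f"N{i}" for i in range(n_nodes)]
    diffusible = rng.uniform(size=n_nodes) < diffusible_fraction
    nodes = tuple(
        Node(
            name=names[i],
            diffusible=bool(diffusible[i]),
            default_diffusion=1.0 if diffusible[i] else 0.0,
        )
        for i in range(n_nodes)
    )
    edges = []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if rng.uniform() < edge_probability:
                sign = 1 if rng.uniform() < sign_bias else -1
                edges.append(Interaction(source=names[i], target=names[j], sign=sign))
    return NetworkTopology(
        id=f"random_n{n_nodes}_seed{seed}", nodes=nodes, interactions=tuple(edges)
    )


@dataclass(frozen=True)
class KnownSystem:
    """A kinetic model with its expected classification."""

    name: str
    model: KineticModel
    expected_class: str
    expected_mechanism: Optional[str]
    expected_phase: Optional[tuple[int, ...]]
    description: str


def known_answer_suite() -> list[KnownSystem]:
    """Small systems whose classifications are known independently.

    The two-species entries follow from the closed-form Turing conditions
    (tests re-derive them through the analytic oracle rather than trusting
    these labels); the three-species entry has a non-diffusible intermediate
    and is verified by exhaustive dispersion scan at test time.
    """
    suite = []

    # classical activator-inhibitor: slow self-enhancing activator, fast
    # diffusing inhibitor it induces; pattern in-phase
    suite.append(
        KnownSystem(
            name="activator_inhibitor_2node",
            model=kinetic_model_from_matrix(
                [[1.0, -1.0], [3.0, -2.0]], [1.0, 10.0], topology_id="ai2"
            ),
            expected_class="turing_I",
            expected_mechanism="activator_inhibitor",
            expected_phase=(1, 1),
            description="activator induces fast inhibitor that represses it",
        )
    )
    # substrate depletion: activator consumes the fast-diffusing substrate
    # that fuels it; pattern out-of-phase
    suite.append(
        KnownSystem(
            name="substrate_depletion_2node",
            model=kinetic_model_from_matrix(
                [[1.0, 1.0], [-3.0, -2.0]], [1.0, 10.0], topology_id="sd2"
            ),
            expected_class="turing_I",
            expected_mechanism="substrate_depletion",
            expected_phase=(1, -1),
            description="activator depletes the fast substrate feeding it",
        )
    )
    # equal diffusion cannot destabilize a stable state (eigenvalues only
    # shift by -k^2 d)
    suite.append(
        KnownSystem(
            name="equal_diffusion_stable",
            model=kinetic_model_from_matrix(
                [[1.0, -1.0], [3.0, -2.0]], [5.0, 5.0], topology_id="eq2"
            ),
            expected_class="none",
            expected_mechanism=None,
            expected_phase=None,
            description="same cross-signs but uniform diffusion: no instability",
        )
    )
    # decoupled decaying species: growth negative at every wavenumber
    suite.append(
        KnownSystem(
            name="diagonal_decay",
            model=kinetic_model_from_matrix(
                [[-1.0, 0.0], [0.0, -2.0]], [1.0, 10.0], topology_id="diag2"
            ),
            expected_class="none",
            expected_mechanism=None,
            expected_phase=None,
            description="pure decay, no interactions",
        )
    )
    # three species with a non-diffusible intermediate: the self-activation
    # runs through a two-step positive loop (ligand -> cell-autonomous
    # transducer -> ligand), restrained by a fast diffusible antagonist --
    # the motif of the three-node digit-patterning WNT circuit
    suite.append(
        KnownSystem(
            name="loop_activation_3node",
            model=kinetic_model_from_matrix(
                [
                    [-0.25, 1.25, -5.0],
                    [1.25, -1.5, 0.0],
                    [0.0, 1.0, -1.5],
                ],
                [1.0, 0.0, 62.0],
                topology_id="loop3",
            ),
            expected_class="turing_I",
            expected_mechanism="activator_inhibitor",
            expected_phase=(1, 1, 1),
            description="non-diffusible intermediate closes the activation loop",
        )
    )
    return suite
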