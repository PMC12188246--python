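"""Regulatory network topologies for digit-interdigit patterning circuits.

A :class:`NetworkTopology` is a small signed directed graph: nodes are gene
products (ligands, transcription factors, extracellular modulators) annotated
with whether they diffuse through the tissue, and edges are regulatory
interactions carrying a sign (+1 activation, -1 repression) that may be left
ambiguous for later enumeration.  The five canonical circuits of the
BMP-SOX9-WNT digit-patterning model ship as validated config files and are
loaded with :func:`load_circuit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional

ROLE_TAGS = ("ligand", "transcription_factor", "modulator", "antagonist")

#: sign value representing an ambiguous (undetermined) regulatory sign
AMBIGUOUS = None

CIRCUIT_IDS = ("bsw3", "wnt3", "wnt4", "bsw5", "combined6")


class TopologyError(ValueError):
    """Raised when a topology violates its structural invariants."""


@dataclass(frozen=True)
class Node:
    """A network species.

    ``default_diffusion`` is the diffusion coefficient (length^2/time, arbitrary
    units) used when a kinetic model does not override it; it must be 0 exactly
    when the node is non-diffusible.
    """

    name: str
    diffusible: bool
    default_diffusion: float = 0.0
    role_tag: str = "transcription_factor"

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise TopologyError("node name must be a non-empty string")
        if self.role_tag not in ROLE_TAGS:
            raise TopologyError(
                f"node {self.name!r}: role_tag {self.role_tag!r} not in {ROLE_TAGS}"
            )
        if self.default_diffusion < 0:
            raise TopologyError(f"node {self.name!r}: negative diffusion")
        if self.diffusible and self.default_diffusion == 0:
            raise TopologyError(
                f"node {self.name!r}: diffusible nodes need default_diffusion > 0"
            )
        if not self.diffusible and self.default_diffusion != 0:
            raise TopologyError(
                f"node {self.name!r}: non-diffusible nodes must have diffusion 0"
            )


@dataclass(frozen=True)
class Interaction:
    """A signed regulatory edge ``source -> target``.

    ``sign`` is +1, -1 or :data:`AMBIGUOUS` (``None``).  ``tested`` marks
    interactions verified by modelling (vs. hypothetical ones); hypothetical
    edges participate in analysis by default and can be filtered out.
    """

    source: str
    target: str
    sign: Optional[int]
    tested: bool = True

    def __post_init__(self) -> None:
        if self.sign not in (1, -1, AMBIGUOUS):
            raise TopologyError(
                f"edge {self.source}->{self.target}: sign must be +1, -1 or ambiguous"
            )

    @property
    def is_ambiguous(self) -> bool:
        return self.sign is AMBIGUOUS


@dataclass(frozen=True)
class NetworkTopology:
    """An ordered node list plus signed interaction list.

    Node order is significant: every matrix built from a topology (interaction
    matrix, diffusion vector, eigenvectors) inherits it.
    """

    id: str
    nodes: tuple[Node, ...]
    interactions: tuple[Interaction, ...]
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "interactions", tuple(self.interactions))
        if not self.nodes:
            raise TopologyError("topology needs at least one node")
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise TopologyError(f"duplicate node names in topology {self.id!r}")
        name_set = set(names)
        seen: set[tuple[str, str]] = set()
        for e in self.interactions:
            if e.source not in name_set or e.target not in name_set:
                raise TopologyError(
                    f"edge {e.source}->{e.target} references unknown node"
                )
            key = (e.source, e.target)
            if key in seen:
                raise TopologyError(f"duplicate edge {e.source}->{e.target}")
            seen.add(key)

    # -- convenience accessors -------------------------------------------------

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, name: str) -> int:
        try:
            return self.node_names.index(name)
        except ValueError:
            raise KeyError(
                f"node {name!r} not in topology {self.id!r} "
                f"(nodes: {', '.join(self.node_names)})"
            ) from None

    def node(self, name: str) -> Node:
        return self.nodes[self.index(name)]

    def edge(self, source: str, target: str) -> Interaction:
        for e in self.interactions:
            if e.source == source and e.target == target:
                return e
        raise KeyError(f"no edge {source}->{target} in topology {self.id!r}")

    @property
    def ambiguous_edges(self) -> tuple[Interaction, ...]:
        return tuple(e for e in self.interactions if e.is_ambiguous)

    def diffusion_defaults(self) -> tuple[float, ...]:
        return tuple(n.default_diffusion for n in self.nodes)

    def without_untested(self) -> "NetworkTopology":
        """Drop hypothetical (untested) edges."""
        kept = tuple(e for e in self.interactions if e.tested)
        return replace(self, interactions=kept)


@dataclass(frozen=True)
class ValidationReport:
    """Report-only outcome of :func:`validate_topology`."""

    topology_id: str
    violations: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_topology(t: NetworkTopology) -> ValidationReport:
    """Check a topology for structural problems and pattern-forming capacity.

    Structural violations (duplicate edges, dangling endpoints) are normally
    impossible for a constructed :class:`NetworkTopology` but are reported for
    topologies deserialized with relaxed checking.  Warnings flag topologies
    that cannot support a finite-wavelength Turing pattern (no diffusible node)
    or any negative feedback (no negative edge).
    """
    violations: list[str] = []
    warnings: list[str] = []
    names = set()
    for n in t.nodes:
        if n.name in names:
            violations.append(f"duplicate node name {n.name!r}")
        names.add(n.name)
    seen = set()
    for e in t.interactions:
        if e.source not in names:
            violations.append(f"edge {e.source}->{e.target}: unknown source")
        if e.target not in names:
            violations.append(f"edge {e.source}->{e.target}: unknown target")
        key = (e.source, e.target)
        if key in seen:
            violations.append(f"duplicate edge {e.source}->{e.target}")
        seen.add(key)
    if not any(n.diffusible for n in t.nodes):
        warnings.append(
            "no diffusible node: no finite-wavelength Turing pattern possible"
        )
    if not any(e.sign == -1 for e in t.interactions) and not t.ambiguous_edges:
        warnings.append("no negative edge: homogeneous state cannot be stabilized")
    return ValidationReport(t.id, tuple(violations), tuple(warnings))


def merge_topologies(a: NetworkTopology, b: NetworkTopology) -> NetworkTopology:
    """Union of two circuits sharing consistently-annotated nodes.

    Shared node names must agree on diffusibility; shared edges must agree on
    sign.  Node order is a's order followed by b's new nodes; likewise edges.
    A ``tested`` edge wins over a hypothetical duplicate.
    """
    a_nodes = {n.name: n for n in a.nodes}
    for n in b.nodes:
        if n.name in a_nodes:
            prev = a_nodes[n.name]
            if prev.diffusible != n.diffusible:
                raise TopologyError(
                    f"merge conflict: node {n.name!r} diffusible={prev.diffusible} "
                    f"in {a.id!r} but diffusible={n.diffusible} in {b.id!r}"
                )
    nodes = list(a.nodes) + [n for n in b.nodes if n.name not in a_nodes]
    edges: dict[tuple[str, str], Interaction] = {
        (e.source, e.target): e for e in a.interactions
    }
    for e in b.interactions:
        key = (e.source, e.target)
        if key in edges:
            prev = edges[key]
            if prev.sign != e.sign:
                raise TopologyError(
                    f"merge conflict: edge {e.source}->{e.target} has sign "
                    f"{prev.sign} in {a.id!r} but {e.sign} in {b.id!r}"
                )
            if e.tested and not prev.tested:
                edges[key] = e
        else:
            edges[key] = e
    return NetworkTopology(
        id=f"{a.id}+{b.id}" if a.id != b.id else a.id,
        nodes=tuple(nodes),
        interactions=tuple(edges.values()),
        notes=(a.notes or b.notes),
    )


def load_circuit(circuit_id: str) -> NetworkTopology:
    """Load one of the five canonical digit-patterning circuits.

    ``bsw3``      four-node core BMP-SOX9-WNT model (BMP2, SOX9, WNT2, CTNNB1)
    ``wnt3``      three-node WNT2 / beta-catenin / SFRP2 activator-inhibitor
    ``wnt4``      wnt3 plus the WNT modulator SULF1
    ``bsw5``      extended BSW model with SULF1 downstream of SOX9
    ``combined6`` merged wnt4 + bsw5 network, six nodes
    """
    if circuit_id not in CIRCUIT_IDS:
        raise KeyError(
            f"unknown circuit {circuit_id!r}; valid ids: {', '.join(CIRCUIT_IDS)}"
        )
    from .io import read_network_config  # local import to avoid a cycle

    ref = resources.files("digituring") / "circuits" / f"{circuit_id}.json"
    with resources.as_file(ref) as path:
        return read_network_config(path)
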