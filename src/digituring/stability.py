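"""Linearized kinetics, dispersion relations and Turing classification.

The linearized reaction-diffusion system about the homogeneous state is

    du/dt = A u + D_i laplacian(u_i)

where ``A = S - diag(decay)`` collects signed regulatory strengths ``S``
(entry ``S[i, j]`` = effect of node j on the production rate of node i,
1/time) and first-order decay, and ``D`` holds diffusion coefficients
(length^2/time; 0 for non-diffusible species).  A spatial Fourier mode of
wavenumber k grows at rate ``max Re eig(A - k^2 diag(D))``; the dispersion
relation is this growth rate as a function of k.  A Turing (diffusion-driven)
instability needs the homogeneous state stable (growth < 0 at k = 0) and some
finite-k band unstable; the dispersion maximum k_max predicts the pattern
wavelength 2*pi/k_max and the leading eigenvector there predicts which
species peak together (in-phase) and which in complementary territories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .network import AMBIGUOUS, Interaction, NetworkTopology, Node

#: growth rates within this margin of zero are treated as marginal (-> no call)
DEFAULT_TOLERANCE = 1e-9

DEFAULT_K_POINTS = 256


class ModelError(ValueError):
    """Raised for kinetic models inconsistent with their topology."""


@dataclass(frozen=True)
class KineticModel:
    """A concrete parameterization of a topology's sign pattern.

    ``strengths`` holds signed edge strengths only (decay excluded), so the
    full interaction matrix is ``A = strengths - diag(decay)``.
    ``saturation`` is the coefficient of the cubic bounding term used by the
    simulator; it does not affect linear analysis.
    """

    topology: NetworkTopology
    strengths: np.ndarray
    decay: np.ndarray
    diffusion: np.ndarray
    saturation: float = 1.0

    def __post_init__(self) -> None:
        n = self.topology.n_nodes
        S = np.asarray(self.strengths, dtype=float)
        decay = np.asarray(self.decay, dtype=float)
        D = np.asarray(self.diffusion, dtype=float)
        if S.shape != (n, n):
            raise ModelError(f"strengths must be {n}x{n}, got {S.shape}")
        if decay.shape != (n,) or np.any(decay <= 0):
            raise ModelError("decay must be a positive length-n vector")
        if D.shape != (n,) or np.any(D < 0):
            raise ModelError("diffusion must be a nonnegative length-n vector")
        if self.saturation <= 0:
            raise ModelError("saturation must be positive")
        for i, node in enumerate(self.topology.nodes):
            if node.diffusible and D[i] == 0:
                raise ModelError(f"diffusible node {node.name!r} has diffusion 0")
            if not node.diffusible and D[i] != 0:
                raise ModelError(f"non-diffusible node {node.name!r} has diffusion != 0")
        # sign pattern of strengths must transcribe the topology's edges
        edge_sign = np.zeros((n, n))
        for e in self.topology.interactions:
            if e.sign is AMBIGUOUS:
                raise ModelError(
                    f"ambiguous edge {e.source}->{e.target}: resolve via "
                    "enumerate_completions before building a kinetic model"
                )
            edge_sign[self.topology.index(e.target), self.topology.index(e.source)] = e.sign
        # an entry of 0 on an existing edge is allowed: a (perturbation-)
        # silenced interaction, not a sign violation
        mismatched = (np.sign(S) != edge_sign) & (S != 0)
        mismatched |= (edge_sign == 0) & (S != 0)
        if np.any(mismatched):
            i, j = np.argwhere(mismatched)[0]
            raise ModelError(
                f"strengths[{i},{j}] sign {np.sign(S[i, j]):.0f} does not match "
                f"edge sign {edge_sign[i, j]:.0f} "
                f"({self.topology.node_names[j]}->{self.topology.node_names[i]})"
            )
        object.__setattr__(self, "strengths", S)
        object.__setattr__(self, "decay", decay)
        object.__setattr__(self, "diffusion", D)

    @property
    def interaction_matrix(self) -> np.ndarray:
        """A = strengths - diag(decay); entry [i, j] = effect of j on i."""
        return self.strengths - np.diag(self.decay)

    @property
    def n_nodes(self) -> int:
        return self.topology.n_nodes

    @property
    def node_names(self) -> tuple[str, ...]:
        return self.topology.node_names


def build_kinetic_model(
    t: NetworkTopology,
    strengths: Mapping[tuple[str, str], float],
    decay: Sequence[float] | Mapping[str, float],
    diffusion_overrides: Optional[Mapping[str, float]] = None,
    saturation: float = 1.0,
) -> KineticModel:
    """Realize a topology's sign pattern as a concrete kinetic model.

    ``strengths`` maps each edge ``(source, target)`` to a positive magnitude;
    the matrix entry becomes ``sign * magnitude``.  ``decay`` gives positive
    first-order decay rates (by node order or by name).  Diffusion defaults to
    each node's ``default_diffusion`` unless overridden.
    """
    if t.ambiguous_edges:
        names = ", ".join(f"{e.source}->{e.target}" for e in t.ambiguous_edges)
        raise ModelError(
            f"topology {t.id!r} has ambiguous edges ({names}); "
            "enumerate completions first"
        )
    n = t.n_nodes
    S = np.zeros((n, n))
    strengths = dict(strengths)
    for e in t.interactions:
        key = (e.source, e.target)
        if key not in strengths:
            raise ModelError(f"missing magnitude for edge {e.source}->{e.target}")
        mag = strengths.pop(key)
        if mag <= 0:
            raise ModelError(
                f"magnitude for edge {e.source}->{e.target} must be positive"
            )
        S[t.index(e.target), t.index(e.source)] = e.sign * mag
    if strengths:
        extra = ", ".join(f"{s}->{tg}" for s, tg in strengths)
        raise ModelError(f"magnitudes given for nonexistent edges: {extra}")
    if isinstance(decay, Mapping):
        decay_vec = np.array([decay[name] for name in t.node_names], dtype=float)
    else:
        decay_vec = np.asarray(decay, dtype=float)
    if decay_vec.shape != (n,) or np.any(decay_vec <= 0):
        raise ModelError("decay must be positive for every node")
    D = np.array(t.diffusion_defaults(), dtype=float)
    for name, val in (diffusion_overrides or {}).items():
        D[t.index(name)] = val
    return KineticModel(t, S, decay_vec, D, saturation)


def kinetic_model_from_matrix(
    A: np.ndarray,
    diffusion: Sequence[float],
    saturation: float = 1.0,
    names: Optional[Sequence[str]] = None,
    topology_id: str = "matrix",
) -> KineticModel:
    """Wrap a raw interaction matrix (decay folded into the diagonal).

    Builds the matching topology from A's sign pattern.  A nonnegative
    diagonal entry ``a_ii`` is split into a self-edge of strength ``a_ii + 1``
    and decay 1; a negative one becomes pure decay ``-a_ii``.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ModelError("A must be square")
    D = np.asarray(diffusion, dtype=float)
    if names is None:
        names = [f"N{i}" for i in range(n)]
    decay = np.empty(n)
    S = A.copy()
    for i in range(n):
        if A[i, i] >= 0:
            decay[i] = 1.0
            S[i, i] = A[i, i] + 1.0
        else:
            decay[i] = -A[i, i]
            S[i, i] = 0.0
    nodes = tuple(
        Node(
            name=names[i],
            diffusible=bool(D[i] > 0),
            default_diffusion=float(D[i]),
            role_tag="transcription_factor",
        )
        for i in range(n)
    )
    edges = []
    for i in range(n):
        for j in range(n):
            if S[i, j] != 0:
                edges.append(
                    Interaction(source=names[j], target=names[i], sign=int(np.sign(S[i, j])))
                )
    topo = NetworkTopology(id=topology_id, nodes=nodes, interactions=tuple(edges))
    return KineticModel(topo, S, decay, D, saturation)


# -- dispersion relation ------------------------------------------------------


@dataclass(frozen=True)
class DispersionResult:
    """Growth rate versus wavenumber for one kinetic model."""

    wavenumber_grid: np.ndarray
    growth_rate: np.ndarray
    k_max: float
    lambda_max: float
    unstable_band: Optional[tuple[float, float]]
    leading_eigenvector: np.ndarray
    oscillatory: bool

    @property
    def wavelength(self) -> float:
        """Predicted pattern wavelength 2*pi/k_max (inf for k_max = 0)."""
        return 2 * np.pi / self.k_max if self.k_max > 0 else np.inf


def default_k_grid(m: KineticModel, n_points: int = DEFAULT_K_POINTS) -> np.ndarray:
    """Wavenumber grid with k^2 uniform on [0, 4 * max self-strength / min D].

    The upper end comfortably exceeds any unstable band: instability requires
    a diffusible route to suppress faster than the strongest self-activation.
    Falls back to the largest matrix entry when no positive self-strength or
    no diffusible node exists.
    """
    self_strength = np.diag(m.strengths)  # a_ii + decay_i
    scale = float(self_strength.max(initial=0.0))
    if scale <= 0:
        scale = float(np.abs(m.interaction_matrix).max())
    if scale <= 0:
        scale = 1.0
    d_pos = m.diffusion[m.diffusion > 0]
    k2_hi = 4.0 * scale / d_pos.min() if d_pos.size else 1.0
    return np.sqrt(np.linspace(0.0, k2_hi, n_points))


def _growth_at(A: np.ndarray, D: np.ndarray, k: float) -> float:
    return float(np.linalg.eigvals(A - k * k * np.diag(D)).real.max())


def _leading_eigenpair(M: np.ndarray) -> tuple[complex, np.ndarray]:
    """Eigenpair with largest real part; ties broken by smaller |imag|."""
    w, V = np.linalg.eig(M)
    order = np.lexsort((np.abs(w.imag), -w.real))
    idx = order[0]
    return w[idx], V[:, idx]


def dispersion_relation(
    m: KineticModel,
    k_grid: Optional[np.ndarray] = None,
    tolerance: float = DEFAULT_TOLERANCE,
    refine: bool = True,
) -> DispersionResult:
    """Evaluate max Re eig(A - k^2 diag(D)) over a wavenumber grid.

    The grid argmax is refined by bounded local search between its neighbors,
    and the unstable band edges are refined by root bracketing.  The leading
    eigenvector at k_max is returned real, unit-norm, with its
    largest-magnitude component positive.
    """
    if k_grid is None:
        k_grid = default_k_grid(m)
    k_grid = np.asarray(k_grid, dtype=float)
    if k_grid.size == 0:
        raise ValueError("k_grid must be non-empty")
    if k_grid[0] != 0.0 or np.any(np.diff(k_grid) <= 0):
        raise ValueError("k_grid must be sorted ascending and start at 0")

    A = m.interaction_matrix
    D = m.diffusion
    # batched eigenvalues over the whole grid
    M = A[None, :, :] - (k_grid**2)[:, None, None] * np.diag(D)[None, :, :]
    growth = np.linalg.eigvals(M).real.max(axis=1)

    j = int(np.argmax(growth))
    k_max = float(k_grid[j])
    lambda_max = float(growth[j])
    if refine and k_grid.size > 1:
        lo = k_grid[max(j - 1, 0)]
        hi = k_grid[min(j + 1, k_grid.size - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda k: -_growth_at(A, D, k),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10 * max(hi, 1.0)},
            )
            if -res.fun >= lambda_max:
                k_max = float(res.x)
                lambda_max = float(-res.fun)

    unstable = growth > tolerance
    band: Optional[tuple[float, float]] = None
    g = lambda k: _growth_at(A, D, k) - tolerance
    if unstable.any():
        i0 = int(np.argmax(unstable))
        i1 = int(len(unstable) - 1 - np.argmax(unstable[::-1]))
        if i0 == 0:
            k_lo = float(k_grid[0])
        else:
            k_lo = float(brentq(g, k_grid[i0 - 1], k_grid[i0]))
        if i1 == len(k_grid) - 1:
            k_hi = float(k_grid[-1])
        else:
            k_hi = float(brentq(g, k_grid[i1], k_grid[i1 + 1]))
        band = (k_lo, k_hi)
    elif lambda_max > tolerance and k_max > 0:
        # band narrower than the grid spacing, found only by refinement
        lo_anchor = k_grid[k_grid < k_max]
        hi_anchor = k_grid[k_grid > k_max]
        k_lo = float(brentq(g, lo_anchor[-1], k_max)) if lo_anchor.size else 0.0
        k_hi = float(brentq(g, k_max, hi_anchor[0])) if hi_anchor.size else k_max
        band = (k_lo, k_hi)

    lam, vec = _leading_eigenpair(A - k_max * k_max * np.diag(D))
    v = vec.real
    if np.linalg.norm(v) < 1e-12:  # purely imaginary eigenvector phase
        v = vec.imag
    v = v / np.linalg.norm(v)
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return DispersionResult(
        wavenumber_grid=k_grid,
        growth_rate=growth,
        k_max=k_max,
        lambda_max=lambda_max,
        unstable_band=band,
        leading_eigenvector=v,
        oscillatory=bool(abs(lam.imag) > tolerance),
    )


# -- Turing classification ----------------------------------------------------


@dataclass(frozen=True)
class TuringClassification:
    """Outcome of diffusion-driven instability analysis.

    ``turing_class`` is ``"none"``, ``"turing_I"`` (finite unstable band;
    growth decays again at large k, selecting a finite wavelength) or
    ``"turing_II"`` (growth stays positive as k grows, no intrinsic
    wavelength).  ``mechanism`` applies an operational reading of the
    classical labels: the most strongly patterning node is taken as the local
    activator; a diffusible partner feeding it positively while patterning
    out-of-phase marks substrate depletion, one repressing it while patterning
    in-phase marks activator-inhibitor.
    """

    stable_homogeneous: bool
    turing_class: str
    mechanism: Optional[str]
    predicted_phase: np.ndarray
    oscillatory: bool
    dispersion: Optional[DispersionResult] = field(default=None, repr=False)
    notes: str = ""

    @property
    def is_turing(self) -> bool:
        return self.turing_class in ("turing_I", "turing_II")


def _classify_mechanism(m: KineticModel, v: np.ndarray) -> tuple[str, str]:
    """Apply the operational activator-inhibitor / substrate-depletion rule."""
    A = m.interaction_matrix
    activator = int(np.argmax(v))
    act_sign = np.sign(v[activator])
    if act_sign <= 0:
        return "other", "no positive eigenvector component to anchor an activator"
    substrate = inhibitor = None
    for j in range(m.n_nodes):
        if j == activator or m.diffusion[j] == 0 or A[activator, j] == 0:
            continue
        same_phase = np.sign(v[j]) == act_sign
        if substrate is None and not same_phase and A[activator, j] > 0:
            substrate = j
        if inhibitor is None and same_phase and A[activator, j] < 0:
            inhibitor = j
    # a depleted substrate is the more specific signature, so it wins when a
    # partner of each kind exists (keeps the call permutation-invariant)
    if substrate is not None:
        return "substrate_depletion", (
            f"{m.node_names[substrate]} is a diffusible out-of-phase species "
            f"feeding the local activator {m.node_names[activator]}"
        )
    if inhibitor is not None:
        return "activator_inhibitor", (
            f"{m.node_names[inhibitor]} is a diffusible in-phase species "
            f"repressing the local activator {m.node_names[activator]}"
        )
    return "other", "no diffusible partner matches either classical pattern"


def classify_turing(
    m: KineticModel,
    tolerance: float = DEFAULT_TOLERANCE,
    k_grid: Optional[np.ndarray] = None,
    dispersion: Optional[DispersionResult] = None,
) -> TuringClassification:
    """Decide Turing compatibility of a kinetic model.

    Marginal growth rates (|growth| <= tolerance) are conservatively treated
    as not establishing instability, so near-degenerate models classify as
    ``none``.
    """
    if dispersion is None:
        dispersion = dispersion_relation(m, k_grid=k_grid, tolerance=tolerance)
    growth = dispersion.growth_rate
    stable = bool(growth[0] < -tolerance)
    band = dispersion.unstable_band
    growth_end = growth[-1]

    turing_class = "none"
    if stable and band is not None and dispersion.lambda_max > tolerance:
        if growth_end > tolerance:
            turing_class = "turing_II"
        elif growth_end < -tolerance:
            turing_class = "turing_I"
        # marginal at the upper end: leave as none (conservative)

    phase = np.sign(dispersion.leading_eigenvector)
    phase[np.abs(dispersion.leading_eigenvector) < 1e-8] = 0.0
    mechanism = None
    notes = ""
    if turing_class != "none":
        mechanism, notes = _classify_mechanism(m, dispersion.leading_eigenvector)
        if dispersion.oscillatory:
            notes += "; leading eigenvalue is complex (oscillatory character)"
    return TuringClassification(
        stable_homogeneous=stable,
        turing_class=turing_class,
        mechanism=mechanism,
        predicted_phase=phase,
        oscillatory=dispersion.oscillatory,
        dispersion=dispersion,
        notes=notes,
    )


def two_node_oracle(
    a: float,
    b: float,
    c: float,
    d: float,
    D1: float,
    D2: float,
    tolerance: float = DEFAULT_TOLERANCE,
) -> TuringClassification:
    """Closed-form classification of the two-species system.

    For ``A = [[a, b], [c, d]]`` with diffusion ``(D1, D2)`` the classical
    conditions are: trace < 0 and det > 0 (homogeneous stability), and
    ``D2*a + D1*d > 0`` with ``(D2*a + D1*d)^2 > 4*D1*D2*det`` (some k^2 makes
    ``h(k^2) = D1*D2*k^4 - (D2*a + D1*d)*k^2 + det`` negative).  The growth
    rate is evaluated analytically at the optimal k^2; agreement with the
    numerical classifier is a test-suite invariant, not an implementation
    dependency.
    """
    if D1 == 0 and D2 == 0:
        raise ValueError("need at least one diffusible species")
    A = np.array([[a, b], [c, d]], dtype=float)
    det = a * d - b * c
    # eigenvalue-based stability with the same marginality tolerance as the
    # numerical classifier (equivalent to trace < 0 and det > 0)
    stable = bool(np.linalg.eigvals(A).real.max() < -tolerance)

    turing_class = "none"
    k2_star = 0.0
    if stable:
        p = D2 * a + D1 * d
        if D1 > 0 and D2 > 0:
            if p > 0 and p * p > 4 * D1 * D2 * det:
                k2_star = p / (2 * D1 * D2)
                lam = _growth_at(A, np.array([D1, D2]), np.sqrt(k2_star))
                if lam > tolerance:
                    # growth -> -inf as k -> inf when both species diffuse
                    turing_class = "turing_I"
        else:
            # one non-diffusible species: growth tends to its diagonal entry
            resid = a if D1 == 0 else d
            if resid > tolerance and p > 0:
                turing_class = "turing_II"
                k2_star = np.inf

    phase = np.zeros(2)
    mechanism = None
    oscillatory = False
    if turing_class == "turing_I":
        lam, vec = _leading_eigenpair(A - k2_star * np.diag([D1, D2]))
        v = vec.real
        v = v / np.linalg.norm(v)
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        phase = np.sign(v)
        oscillatory = bool(abs(lam.imag) > tolerance)
        activator = 0 if a > 0 else 1
        other = 1 - activator
        cross_in = A[activator, other]
        if phase[other] == phase[activator] and cross_in < 0:
            mechanism = "activator_inhibitor"
        elif phase[other] != phase[activator] and cross_in > 0:
            mechanism = "substrate_depletion"
        else:
            mechanism = "other"
    return TuringClassification(
        stable_homogeneous=stable,
        turing_class=turing_class,
        mechanism=mechanism,
        predicted_phase=phase,
        oscillatory=oscillatory,
        dispersion=None,
        notes="closed-form two-species analysis",
    )
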