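"""Nonlinear reaction-diffusion integration on 1D/2D grids.

The simulated kinetics are the linearized interactions bounded by a cubic
self-saturation,

    du_i/dt = sum_j A_ij u_j - s * u_i^3 + D_i laplacian(u_i),

where u_i is the deviation of species i from the homogeneous state (may be
negative).  The cubic term is the minimal bounded closure that preserves both
the u = 0 fixed point and the linear Turing analysis.  Integration is
semi-implicit: reaction explicit, diffusion implicit in transform space (FFT
for periodic boundaries, DCT for zero-flux), which keeps the stiff diffusion
term unconditionally stable.  Trajectories are bit-reproducible given
(seed, grid, dt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import fft as sfft

from .stability import KineticModel, TuringClassification, classify_turing

BLOWUP_THRESHOLD = 1e6
MAX_DT_HALVINGS = 6
DEFAULT_NOISE_AMPLITUDE = 1e-3
CONVERGENCE_THRESHOLD = 1e-3  # relative L2 change per unit time


class SimulationError(RuntimeError):
    """Numerical failure during integration."""


@dataclass(frozen=True)
class GridSpec:
    """Spatial domain: 1D or 2D, periodic or zero-flux boundaries."""

    dimensionality: int
    extent: tuple[float, ...]
    n_points: tuple[int, ...]
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if self.dimensionality not in (1, 2):
            raise ValueError("dimensionality must be 1 or 2")
        extent = tuple(float(e) for e in np.atleast_1d(self.extent))
        n_points = tuple(int(n) for n in np.atleast_1d(self.n_points))
        if len(extent) == 1 and self.dimensionality == 2:
            extent = extent * 2
        if len(n_points) == 1 and self.dimensionality == 2:
            n_points = n_points * 2
        if len(extent) != self.dimensionality or len(n_points) != self.dimensionality:
            raise ValueError("extent/n_points must match dimensionality")
        if any(e <= 0 for e in extent):
            raise ValueError("extent must be positive")
        if any(n < 16 for n in n_points):
            raise ValueError("need at least 16 grid points per axis")
        if self.boundary not in ("periodic", "zero_flux"):
            raise ValueError("boundary must be 'periodic' or 'zero_flux'")
        object.__setattr__(self, "extent", extent)
        object.__setattr__(self, "n_points", n_points)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.n_points

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(e / n for e, n in zip(self.extent, self.n_points))

    def laplacian_symbol(self) -> np.ndarray:
        """-k^2 eigenvalues of the Laplacian on this grid, per transform mode."""
        k2_axes = []
        for e, n in zip(self.extent, self.n_points):
            if self.boundary == "periodic":
                k = 2 * np.pi * np.fft.fftfreq(n, d=e / n)
            else:  # zero-flux / DCT-II modes cos(pi m x / L)
                k = np.pi * np.arange(n) / e
            k2_axes.append(k**2)
        if self.dimensionality == 1:
            return -k2_axes[0]
        return -(k2_axes[0][:, None] + k2_axes[1][None, :])


@dataclass(frozen=True)
class SimulationResult:
    """Seeded space-time trajectory of all species."""

    model: KineticModel
    grid: GridSpec
    times: np.ndarray
    fields: np.ndarray  # (n_snapshots, n_nodes, *spatial)
    seed: Optional[int]
    converged: bool
    dt_used: float
    noise_amplitude: float

    @property
    def node_names(self) -> tuple[str, ...]:
        return self.model.node_names

    def profile(self, node: str, snapshot: int = -1) -> np.ndarray:
        """Spatial profile of one species at a stored snapshot."""
        return self.fields[snapshot, self.model.topology.index(node)]

    def final_fields(self) -> np.ndarray:
        return self.fields[-1]

    def shifted_positive(self) -> np.ndarray:
        """Fields shifted so every species is nonnegative (plotting view)."""
        mins = self.fields.min(axis=(0,) + tuple(range(2, self.fields.ndim)))
        return self.fields - mins.reshape((1, -1) + (1,) * (self.fields.ndim - 2))


def _transforms(grid: GridSpec):
    axes = tuple(range(1, 1 + grid.dimensionality))
    if grid.boundary == "periodic":
        fwd = lambda u: sfft.fftn(u, axes=axes)
        inv = lambda U: sfft.ifftn(U, axes=axes).real
    else:
        fwd = lambda u: sfft.dctn(u, type=2, norm="ortho", axes=axes)
        inv = lambda U: sfft.idctn(U, type=2, norm="ortho", axes=axes)
    return fwd, inv


def default_dt(m: KineticModel) -> float:
    """Explicit-reaction step limit: 0.1 / max absolute row sum of A."""
    row_sum = np.abs(m.interaction_matrix).sum(axis=1).max()
    return 0.1 / max(row_sum, 1e-12)


def _integrate(
    m: KineticModel,
    grid: GridSpec,
    t_end: float,
    u0: np.ndarray,
    dt: float,
    snapshot_times: np.ndarray,
    schedule: Sequence[tuple[float, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    n_steps = max(int(np.ceil(t_end / dt)), 1)
    dt = t_end / n_steps
    fwd, inv = _transforms(grid)
    lap = grid.laplacian_symbol()
    denom = 1.0 - dt * m.diffusion.reshape((-1,) + (1,) * grid.dimensionality) * lap
    s = m.saturation

    snap_steps = np.rint(snapshot_times / dt).astype(int)
    snap_steps = np.clip(snap_steps, 0, n_steps)
    snap_lookup = {}
    for step, t_snap in zip(snap_steps, snapshot_times):
        snap_lookup.setdefault(int(step), []).append(t_snap)

    # per-step interaction matrix from the piecewise-constant schedule
    starts = np.array([t0 for t0, _ in schedule])
    mats = [A for _, A in schedule]
    step_times = np.arange(n_steps) * dt
    mat_idx = np.searchsorted(starts, step_times, side="right") - 1
    mat_idx = np.clip(mat_idx, 0, len(mats) - 1)

    u = u0.copy()
    fields, times = [], []
    for t_snap in snap_lookup.get(0, []):
        fields.append(u.copy())
        times.append(t_snap)
    for step in range(n_steps):
        A = mats[mat_idx[step]]
        r = np.einsum("ij,j...->i...", A, u) - s * u**3
        u = inv(fwd(u + dt * r) / denom)
        if not np.all(np.abs(u) < BLOWUP_THRESHOLD):
            raise SimulationError(
                f"field exceeded {BLOWUP_THRESHOLD:g} at t={(step + 1) * dt:g}"
            )
        for t_snap in snap_lookup.get(step + 1, []):
            fields.append(u.copy())
            times.append(t_snap)
    return np.array(times), np.array(fields)


def simulate(
    m: KineticModel,
    g: GridSpec,
    t_end: float,
    seed: Optional[int] = None,
    noise_amplitude: float = DEFAULT_NOISE_AMPLITUDE,
    dt: Optional[float] = None,
    n_snapshots: int = 21,
    initial_field: Optional[np.ndarray] = None,
    schedule: Optional[Sequence[tuple[float, np.ndarray]]] = None,
    convergence_threshold: float = CONVERGENCE_THRESHOLD,
) -> SimulationResult:
    """Integrate from seeded Gaussian noise to (ideally) a patterned state.

    The initial condition is ``noise_amplitude * N(0, 1)`` per species and
    grid point from ``numpy.random.default_rng(seed)``, unless an explicit
    ``initial_field`` is given.  ``schedule`` optionally replaces the
    interaction matrix piecewise in time (used by the perturbation module);
    entries are ``(t_start, A)`` and the first must start at 0.  On numerical
    blow-up the step size is halved and integration restarted, up to
    6 times.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if n_snapshots < 2:
        raise ValueError("need at least 2 snapshots")
    shape = (m.n_nodes,) + g.shape
    if initial_field is not None:
        u0 = np.asarray(initial_field, dtype=float)
        if u0.shape != shape:
            raise ValueError(f"initial_field must have shape {shape}")
    else:
        rng = np.random.default_rng(seed)
        u0 = noise_amplitude * rng.standard_normal(shape)

    if schedule is None:
        schedule = [(0.0, m.interaction_matrix)]
    if schedule[0][0] != 0.0:
        raise ValueError("schedule must start at t=0")

    dt_used = dt if dt is not None else default_dt(m)
    snapshot_times = np.linspace(0.0, t_end, n_snapshots)
    last_error: Optional[SimulationError] = None
    for _ in range(MAX_DT_HALVINGS + 1):
        try:
            times, fields = _integrate(
                m, g, t_end, u0, dt_used, snapshot_times, schedule
            )
            break
        except SimulationError as exc:
            last_error = exc
            dt_used /= 2
    else:
        raise SimulationError(
            f"blow-up persists after {MAX_DT_HALVINGS} dt halvings "
            f"(last: {last_error}); consider a larger saturation strength"
        )

    norm_last = np.linalg.norm(fields[-1])
    norm_diff = np.linalg.norm(fields[-1] - fields[-2])
    dt_snap = times[-1] - times[-2]
    rel_change = norm_diff / (max(norm_last, 1e-12) * dt_snap)
    converged = bool(rel_change < convergence_threshold)
    return SimulationResult(
        model=m,
        grid=g,
        times=times,
        fields=fields,
        seed=seed,
        converged=converged,
        dt_used=t_end / max(int(np.ceil(t_end / dt_used)), 1),
        noise_amplitude=noise_amplitude,
    )


def choose_grid(
    m: KineticModel,
    wavelengths: int,
    points_per_wavelength: int = 16,
    boundary: str = "periodic",
    classification: Optional[TuringClassification] = None,
) -> GridSpec:
    """1D grid sized to hold a whole number of predicted pattern wavelengths.

    Requires a finite-wavelength (turing_I) model; the extent is
    ``wavelengths * 2*pi/k_max`` and the resolution at least 16 points per
    wavelength (rounded up to a power of two for transform efficiency).
    """
    if wavelengths < 1:
        raise ValueError("wavelengths must be >= 1")
    if classification is None:
        classification = classify_turing(m)
    if classification.turing_class != "turing_I":
        raise ValueError(
            f"model classifies as {classification.turing_class!r}: no finite "
            "predicted wavelength to resolve"
        )
    k_max = classification.dispersion.k_max
    extent = wavelengths * 2 * np.pi / k_max
    n_min = points_per_wavelength * wavelengths
    n_points = 1 << int(np.ceil(np.log2(max(n_min, 16))))
    return GridSpec(
        dimensionality=1, extent=(extent,), n_points=(n_points,), boundary=boundary
    )
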