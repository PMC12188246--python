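"""Quantification of simulated patterns.

Summaries cover per-species amplitude (spatial standard deviation), dominant
wavelength (discrete Fourier/cosine spectrum peak), stripe count (connected
regions above the spatial mean), and the pairwise phase relations carried by
the digit-interdigit model's claims: two species are called in-phase when
their final spatial profiles correlate positively (peaking in the same
territories, e.g. interdigit WNT2/SFRP2) and out-of-phase when the
correlation is negative (complementary digit vs interdigit territories, e.g.
SULF1 vs SFRP2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .simulate import SimulationResult

#: |correlation| below this threshold gives an "undetermined" phase call
DEFAULT_PHASE_THRESHOLD = 0.3


@dataclass(frozen=True)
class PatternSummary:
    """Per-node pattern statistics plus the pairwise phase matrix."""

    node_names: tuple[str, ...]
    amplitude: np.ndarray
    dominant_wavelength: np.ndarray
    stripe_count: np.ndarray
    phase_matrix: np.ndarray
    in_phase_calls: np.ndarray  # +1 in-phase, -1 out-of-phase, 0 undetermined
    phase_threshold: float

    def correlation(self, a: str, b: str) -> float:
        i, j = self.node_names.index(a), self.node_names.index(b)
        return float(self.phase_matrix[i, j])

    def phase_call(self, a: str, b: str) -> str:
        i, j = self.node_names.index(a), self.node_names.index(b)
        return {1: "in", -1: "out", 0: "undetermined"}[int(self.in_phase_calls[i, j])]


def _dominant_wavelength_1d(profile: np.ndarray, extent: float, periodic: bool) -> float:
    x = profile - profile.mean()
    if np.allclose(x, 0.0):
        return float("nan")
    if periodic:
        power = np.abs(np.fft.rfft(x)) ** 2
        power[0] = 0.0
        mode = int(np.argmax(power))
        return extent / mode if mode else float("nan")
    power = sfft.dct(x, type=2, norm="ortho") ** 2
    power[0] = 0.0
    mode = int(np.argmax(power))
    return 2 * extent / mode if mode else float("nan")


def _dominant_wavelength_2d(
    field: np.ndarray, extent: tuple[float, float], periodic: bool
) -> float:
    """Wavelength from the radially averaged power spectrum."""
    x = field - field.mean()
    if np.allclose(x, 0.0):
        return float("nan")
    ny, nx = x.shape
    power = np.abs(np.fft.fft2(x)) ** 2
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=extent[0] / ny)
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=extent[1] / nx)
    k_mag = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    dk = 2 * np.pi / max(extent)
    bins = np.rint(k_mag / dk).astype(int)
    radial = np.bincount(bins.ravel(), weights=power.ravel())
    counts = np.bincount(bins.ravel())
    radial = radial / np.maximum(counts, 1)
    radial[0] = 0.0
    peak = int(np.argmax(radial))
    return 2 * np.pi / (peak * dk) if peak else float("nan")


def _stripe_count(field: np.ndarray, periodic: bool) -> int:
    """Connected regions above the spatial mean (periodic adjacency respected)."""
    mask = field > field.mean()
    if not mask.any() or mask.all():
        return 0
    if field.ndim == 1:
        edges = np.diff(mask.astype(int))
        count = int(np.sum(edges == 1)) + int(mask[0])
        if periodic and mask[0] and mask[-1]:
            count -= 1
        return count
    labels, count = ndimage.label(mask)
    if periodic:
        # merge components that touch across each wrapped edge
        merges = set()
        for axis in range(field.ndim):
            first = np.take(labels, 0, axis=axis)
            last = np.take(labels, -1, axis=axis)
            touching = (first > 0) & (last > 0)
            merges.update(zip(first[touching].ravel(), last[touching].ravel()))
        parent = {i: i for i in range(1, count + 1)}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in merges:
            parent[find(int(a))] = find(int(b))
        count = len({find(i) for i in range(1, count + 1)})
    return int(count)


def summarize_pattern(
    r: SimulationResult,
    phase_threshold: float = DEFAULT_PHASE_THRESHOLD,
    allow_unconverged: bool = False,
) -> PatternSummary:
    """Summarize the final snapshot of a simulation.

    Refuses non-converged runs unless ``allow_unconverged`` (transient
    snapshots are not meaningful pattern summaries).
    """
    if not r.converged and not allow_unconverged:
        raise ValueError(
            "simulation has not converged; pass allow_unconverged=True to force"
        )
    final = r.final_fields()
    n = final.shape[0]
    periodic = r.grid.boundary == "periodic"
    spatial_axes = tuple(range(1, final.ndim))

    amplitude = final.std(axis=spatial_axes)
    wavelengths = np.empty(n)
    stripes = np.zeros(n, dtype=int)
    for i in range(n):
        if r.grid.dimensionality == 1:
            wavelengths[i] = _dominant_wavelength_1d(
                final[i], r.grid.extent[0], periodic
            )
        else:
            wavelengths[i] = _dominant_wavelength_2d(final[i], r.grid.extent, periodic)
        stripes[i] = _stripe_count(final[i], periodic)

    flat = final.reshape(n, -1)
    centered = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms > 1e-12, norms, 1.0)
    corr = (centered / safe[:, None]) @ (centered / safe[:, None]).T
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2, -1.0, 1.0)

    calls = np.zeros_like(corr, dtype=int)
    calls[corr > phase_threshold] = 1
    calls[corr < -phase_threshold] = -1
    return PatternSummary(
        node_names=r.node_names,
        amplitude=amplitude,
        dominant_wavelength=wavelengths,
        stripe_count=stripes,
        phase_matrix=corr,
        in_phase_calls=calls,
        phase_threshold=phase_threshold,
    )


@dataclass(frozen=True)
class ClaimVerdict:
    node_a: str
    node_b: str
    expected: str  # "in" or "out"
    correlation: float
    passed: bool


@dataclass(frozen=True)
class ClaimReport:
    verdicts: tuple[ClaimVerdict, ...]

    @property
    def passed(self) -> bool:
        return all(v.passed for v in self.verdicts)


_EXPECTED_ALIASES = {
    "in": "in",
    "in-phase": "in",
    "in_phase": "in",
    "out": "out",
    "out-of-phase": "out",
    "out_of_phase": "out",
}


def check_phase_claims(
    s: PatternSummary, claims: Sequence[tuple[str, str, str]]
) -> ClaimReport:
    """Check expected in/out-of-phase relations against measured correlations.

    Each claim is ``(node_a, node_b, "in" | "out")``.  An empty claim list
    passes vacuously.  A claim passes when the measured phase call matches;
    undetermined correlations (|r| below the summary's threshold) fail.
    """
    verdicts = []
    for node_a, node_b, expected_raw in claims:
        expected = _EXPECTED_ALIASES.get(str(expected_raw).lower())
        if expected is None:
            raise ValueError(
                f"claim ({node_a}, {node_b}): expected relation must be 'in' or "
                f"'out', got {expected_raw!r}"
            )
        for name in (node_a, node_b):
            if name not in s.node_names:
                raise KeyError(
                    f"claim references unknown node {name!r} "
                    f"(nodes: {', '.join(s.node_names)})"
                )
        call = s.phase_call(node_a, node_b)
        verdicts.append(
            ClaimVerdict(
                node_a=node_a,
                node_b=node_b,
                expected=expected,
                correlation=s.correlation(node_a, node_b),
                passed=call == expected,
            )
        )
    return ClaimReport(tuple(verdicts))


def amplitude_timeseries(
    r: SimulationResult, node: str
) -> tuple[np.ndarray, np.ndarray]:
    """(times, spatial standard deviation) of one species across snapshots."""
    idx = r.model.topology.index(node)
    per_node = r.fields[:, idx]
    amp = per_node.std(axis=tuple(range(1, per_node.ndim)))
    return r.times, amp
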