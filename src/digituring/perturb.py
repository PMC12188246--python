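"""Transient perturbation protocols: in-silico disrupt-and-recover.

Models the experimental logic of transiently blocking a secreted signal (a
porcupine-inhibitor-style block of WNT ligand secretion): during a time
window the regulatory strengths touching the targeted species are scaled by a
factor (< 1 = inhibition, 0 = complete block), then restored.  Because a
Turing pattern's position and spacing are maintained dynamically, a
sufficiently strong block collapses the pattern and restoration lets it
self-reorganize -- typically with the same wavelength but shifted stripe
positions.  Recovery is therefore judged on amplitude and wavelength, not on
stripe position; the pattern-shift score reports positional change
separately.

Inhibition scales interaction strengths, never decay: blocking secretion
removes a species' influence on others (``scale_outgoing_effect``, the
natural mode for ligand nodes) or the regulatory drive onto it
(``scale_incoming_production``), while turnover of what is already present
continues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .metrics import _dominant_wavelength_1d, _dominant_wavelength_2d
from .simulate import GridSpec, SimulationResult, simulate
from .stability import KineticModel, TuringClassification, classify_turing

MODES = ("scale_incoming_production", "scale_outgoing_effect")


@dataclass(frozen=True)
class PerturbationProtocol:
    """Scale interactions of ``target_nodes`` by ``factor`` on [t_on, t_off)."""

    target_nodes: tuple[str, ...]
    factor: float
    t_on: float
    t_off: float
    mode: str = "scale_outgoing_effect"

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_nodes", tuple(self.target_nodes))
        if not self.target_nodes:
            raise ValueError("need at least one target node")
        if self.factor < 0:
            raise ValueError("factor must be nonnegative")
        if not 0 <= self.t_on < self.t_off:
            raise ValueError("need 0 <= t_on < t_off")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def perturbed_model(m: KineticModel, p: PerturbationProtocol) -> KineticModel:
    """The kinetic model as modified during the perturbation window.

    Only edge strengths are scaled; decay and diffusion are untouched, so the
    diagonal becomes ``factor * self_edge - decay`` for a targeted node.
    """
    idx = [m.topology.index(name) for name in p.target_nodes]
    S = m.strengths.copy()
    if p.mode == "scale_outgoing_effect":
        S[:, idx] *= p.factor
    else:
        S[idx, :] *= p.factor
    return KineticModel(
        topology=m.topology,
        strengths=S,
        decay=m.decay,
        diffusion=m.diffusion,
        saturation=m.saturation,
    )


def perturbed_classification(
    m: KineticModel, p: PerturbationProtocol
) -> TuringClassification:
    """Linear classification of the within-window model.

    Predicts whether the pattern should collapse during the window: a
    perturbed class of ``none`` means the patterned state loses its linear
    support and amplitude must decay.
    """
    return classify_turing(perturbed_model(m, p))


def plan_recovery_protocol(
    m: KineticModel,
    target_nodes: Iterable[str],
    factor: float,
    mode: str = "scale_outgoing_effect",
    establish_efolds: float = 14.0,
    collapse_efolds: float = 6.0,
    recover_efolds: float = 16.0,
) -> tuple[PerturbationProtocol, float]:
    """Size a disrupt-and-recover window from the model's linear timescales.

    The pattern grows at ``lambda_max`` and, while inhibited, decays at the
    perturbed model's growth rate evaluated at the pattern wavenumber.  The
    window is long enough to collapse amplitude by ``collapse_efolds``
    e-foldings (e^-6 is ~0.2% of baseline) but short enough to leave a
    remnant that re-seeds the pattern on restoration; recovery gets
    ``recover_efolds`` growth e-foldings.  Returns ``(protocol, t_end)``.
    """
    from .stability import _growth_at

    cls = classify_turing(m)
    if cls.turing_class != "turing_I":
        raise ValueError(
            f"model classifies as {cls.turing_class!r}; need a finite-wavelength "
            "pattern to disrupt"
        )
    lam = cls.dispersion.lambda_max
    k_max = cls.dispersion.k_max
    p_probe = PerturbationProtocol(
        target_nodes=tuple(target_nodes), factor=factor, t_on=0.0, t_off=1.0, mode=mode
    )
    mp = perturbed_model(m, p_probe)
    decay_rate = -_growth_at(mp.interaction_matrix, mp.diffusion, k_max)
    if decay_rate <= 0:
        raise ValueError(
            "perturbed model still amplifies the pattern mode; no collapse "
            "window can be planned for this factor"
        )
    t_on = establish_efolds / lam
    t_off = t_on + collapse_efolds / decay_rate
    t_end = t_off + recover_efolds / lam
    return (
        PerturbationProtocol(
            target_nodes=tuple(target_nodes),
            factor=factor,
            t_on=t_on,
            t_off=t_off,
            mode=mode,
        ),
        t_end,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Amplitude collapse/recovery metrics for one perturbation run."""

    reference_node: str
    baseline_amplitude: float
    min_amplitude_window: float
    final_amplitude: float
    recovery_ratio: float
    pattern_shift: float  # 1 - corr(pre-perturbation, final profile)
    final_wavelength: float
    predicted_wavelength: float
    perturbed_class: str

    def as_dict(self) -> dict:
        return {
            "reference_node": self.reference_node,
            "baseline_amplitude": self.baseline_amplitude,
            "min_amplitude_window": self.min_amplitude_window,
            "final_amplitude": self.final_amplitude,
            "recovery_ratio": self.recovery_ratio,
            "pattern_shift": self.pattern_shift,
            "final_wavelength": self.final_wavelength,
            "predicted_wavelength": self.predicted_wavelength,
            "perturbed_class": self.perturbed_class,
        }


def run_perturbation(
    m: KineticModel,
    g: GridSpec,
    p: PerturbationProtocol,
    t_end: float,
    seed: Optional[int] = None,
    noise_amplitude: float = 1e-3,
    n_snapshots: int = 81,
    reference_node: Optional[str] = None,
    dt: Optional[float] = None,
) -> tuple[SimulationResult, RecoveryReport]:
    """Simulate with a transient scaling window and quantify recovery.

    The unperturbed model should be turing_I and ``t_on`` late enough for the
    pattern to establish; the report's baseline is the reference node's
    amplitude at the last snapshot before ``t_on``.  ``n_snapshots`` is a
    minimum: storage is densified so the inhibition window always contains
    several snapshots.  With ``factor == 1`` the trajectory is identical to
    the unperturbed run for the same seed.
    """
    if not p.t_off <= t_end:
        raise ValueError(
            f"perturbation window [{p.t_on}, {p.t_off}) extends beyond t_end={t_end}"
        )
    n_snapshots = min(
        1001, max(n_snapshots, int(np.ceil(4 * t_end / (p.t_off - p.t_on))) + 1)
    )
    A0 = m.interaction_matrix
    A1 = perturbed_model(m, p).interaction_matrix
    schedule = [(0.0, A0), (p.t_on, A1), (p.t_off, A0)]
    result = simulate(
        m,
        g,
        t_end,
        seed=seed,
        noise_amplitude=noise_amplitude,
        dt=dt,
        n_snapshots=n_snapshots,
        schedule=schedule,
    )

    pre_mask = result.times < p.t_on
    if not pre_mask.any():
        raise ValueError("no snapshot precedes t_on; increase n_snapshots")
    i_pre = int(np.flatnonzero(pre_mask)[-1])
    window_mask = (result.times >= p.t_on) & (result.times < p.t_off)

    amps_pre = result.fields[i_pre].std(axis=tuple(range(1, result.fields[i_pre].ndim)))
    if reference_node is None:
        ref_idx = int(np.argmax(amps_pre))
        reference_node = m.node_names[ref_idx]
    else:
        ref_idx = m.topology.index(reference_node)

    ref_series = result.fields[:, ref_idx]
    amp_series = ref_series.std(axis=tuple(range(1, ref_series.ndim)))
    baseline = float(amp_series[i_pre])
    min_window = float(amp_series[window_mask].min()) if window_mask.any() else np.nan
    final = float(amp_series[-1])

    pre_profile = ref_series[i_pre].ravel()
    final_profile = ref_series[-1].ravel()
    denom = pre_profile.std() * final_profile.std()
    if denom > 1e-12:
        corr = float(
            np.mean(
                (pre_profile - pre_profile.mean())
                * (final_profile - final_profile.mean())
            )
            / denom
        )
    else:
        corr = 0.0

    if g.dimensionality == 1:
        wavelength = _dominant_wavelength_1d(
            final_profile, g.extent[0], g.boundary == "periodic"
        )
    else:
        wavelength = _dominant_wavelength_2d(
            ref_series[-1], g.extent, g.boundary == "periodic"
        )
    base_cls = classify_turing(m)
    predicted = (
        2 * np.pi / base_cls.dispersion.k_max
        if base_cls.dispersion.k_max > 0
        else np.nan
    )
    report = RecoveryReport(
        reference_node=reference_node,
        baseline_amplitude=baseline,
        min_amplitude_window=min_window,
        final_amplitude=final,
        recovery_ratio=final / baseline if baseline > 0 else np.nan,
        pattern_shift=1.0 - corr,
        final_wavelength=float(wavelength),
        predicted_wavelength=float(predicted),
        perturbed_class=perturbed_classification(m, p).turing_class,
    )
    return result, report
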