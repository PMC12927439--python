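"""The outer surrogate-accelerated saddle-search loop.

One outer iteration: evaluate the true PES at the current midpoint, append
the observation, refit hyperparameters (FPS subset, barrier, oscillation
retries), factorize the surrogate over the full history, and relax the
dimer *on the surrogate* until either the surrogate thinks it has converged
or a proposed step leaves the data-driven trust region.  Either way the
true PES is consulted at the resulting midpoint; convergence is declared
only when the *true* RMS atomic force drops below the tolerance.

The trust region around the training set follows an earned-exploration
schedule: the allowed distance from a candidate to its nearest training
configuration starts at a minimal safe radius and saturates exponentially
toward a maximal exploration distance as data accumulates, capped by a
physical ceiling that shrinks with system size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .dimer import DimerSettings, rms_force, run_dimer
from .geometry import AtomicConfiguration, intensive_emd, one_d_max_log
from .gp import IllConditionedModelError, Observation, SurrogateCalculator, SurrogateModel
from .hyperopt import HyperoptConfig, optimize_hyperparameters
from .kernel import KernelParams, PairTypeMap
from .surfaces import Calculator, CountingCalculator

__all__ = [
    "TrustRadiusConfig",
    "ControllerConfig",
    "SearchResult",
    "OuterIteration",
    "earned_threshold",
    "physical_ceiling",
    "trust_threshold",
    "accept_candidate",
    "run_otgpd",
]


@dataclass
class TrustRadiusConfig:
    """Earned-exploration trust radius parameters (Angstrom)."""

    t_min: float = 0.1  # minimal safe radius
    dt_explore: float = 0.4  # maximal additional earned distance
    n_half: int = 10  # data count at 50% of the earned growth
    a_floor: float = 0.2  # lower bound of the physical ceiling
    a_atoms: float = 5.0  # ceiling scale, Angstrom * atoms

    def __post_init__(self) -> None:
        if min(self.t_min, self.dt_explore, self.n_half, self.a_floor, self.a_atoms) <= 0:
            raise ValueError("all trust-radius parameters must be positive")

    @property
    def k(self) -> float:
        """Saturation rate ln 2 / n_half."""
        return float(np.log(2.0) / self.n_half)


def earned_threshold(n_data: int, cfg: TrustRadiusConfig) -> float:
    """T_min + dT_explore * (1 - exp(-k * N)); strictly increasing in N."""
    if n_data < 0:
        raise ValueError("data count cannot be negative")
    return cfg.t_min + cfg.dt_explore * (1.0 - np.exp(-cfg.k * n_data))


def physical_ceiling(n_atoms: int, cfg: TrustRadiusConfig) -> float:
    """max(a_floor, a_atoms / N_atoms): size-aware cap on the trust radius."""
    if n_atoms < 1:
        raise ValueError("need at least one atom")
    return max(cfg.a_floor, cfg.a_atoms / n_atoms)


def trust_threshold(n_data: int, n_atoms: int, cfg: TrustRadiusConfig) -> float:
    """The more restrictive of the earned and physical bounds."""
    return min(earned_threshold(n_data, cfg), physical_ceiling(n_atoms, cfg))


def accept_candidate(
    candidate: AtomicConfiguration,
    training: list[AtomicConfiguration],
    threshold: float,
    metric: Callable[[AtomicConfiguration, AtomicConfiguration], float] = intensive_emd,
) -> bool:
    """Accept iff the distance to the nearest training configuration <= threshold."""
    if not training:
        raise ValueError("empty training set")
    nearest = min(metric(candidate, x) for x in training)
    return nearest <= threshold


@dataclass
class ControllerConfig:
    """Everything the outer loop needs, with conservative defaults."""

    trust: TrustRadiusConfig = field(default_factory=TrustRadiusConfig)
    hyperopt: HyperoptConfig = field(default_factory=HyperoptConfig)
    inner_dimer: DimerSettings = field(default_factory=lambda: DimerSettings(max_translations=10_000))
    sigma_c2: float = 1.0
    sigma_f2_init: float = 1.0
    length_scale_init: float = 1.0
    energy_nugget: float = 1e-8
    gradient_nugget: float = 1e-8
    max_pes_calls: int = 300
    max_outer_iterations: int = 100
    force_tol: float = 0.01  # eV/A, on the TRUE PES
    reoptimize_every: int = 1  # hyperparameter refits per outer iteration


@dataclass
class OuterIteration:
    """Per-outer-iteration trace record."""

    n_data: int
    theta: float
    log_params: np.ndarray
    subset_size: int
    inner_stop: str
    inner_steps: int
    true_rms_force: float
    energy: float
    configuration: AtomicConfiguration | None = None


@dataclass
class SearchResult:
    """Outcome of a surrogate-accelerated (or plain) saddle search."""

    configuration: AtomicConfiguration
    converged: bool
    n_pes_calls: int
    n_surrogate_steps: int
    saddle_energy: float
    barrier_energy: float
    final_rms_force: float
    orientation: np.ndarray
    trace: list[OuterIteration] = field(default_factory=list)
    stop_reason: str = ""
    mode: str = "otgpd"


def _metric_for_mode(mode: str):
    return one_d_max_log if mode == "gpdimer" else intensive_emd


def run_otgpd(
    pes: Calculator,
    initial: AtomicConfiguration,
    initial_direction: np.ndarray,
    config: ControllerConfig | None = None,
    mode: str = "otgpd",
) -> SearchResult:
    """Run the surrogate-accelerated saddle search.

    Modes: ``otgpd`` (EMD trust metric, FPS subset, barrier, HOD),
    ``gpdimer`` (legacy baseline: fixed-index log-ratio trust metric,
    full-history hyperparameter fits, no barrier or oscillation control),
    ``dimer`` (no surrogate at all; plain dimer on the true PES).
    """
    config = config or ControllerConfig()
    counter = CountingCalculator(pes)

    if mode == "dimer":
        settings = DimerSettings(
            max_translations=config.max_pes_calls,
            force_tol=config.force_tol,
            max_step=config.inner_dimer.max_step,
            ratio_at_limit=config.inner_dimer.ratio_at_limit,
            separation=config.inner_dimer.separation,
            rotation_force_tol=config.inner_dimer.rotation_force_tol,
            max_rotations=config.inner_dimer.max_rotations,
        )
        e0, _ = pes.evaluate(initial)
        res = run_dimer(counter, initial, initial_direction, settings)
        return SearchResult(
            configuration=res.configuration,
            converged=res.converged,
            n_pes_calls=counter.count,
            n_surrogate_steps=0,
            saddle_energy=res.energy,
            barrier_energy=res.energy - e0,
            final_rms_force=rms_force(res.gradient, res.configuration),
            orientation=res.orientation,
            stop_reason=res.stop_reason,
            mode=mode,
        )
    if mode not in ("otgpd", "gpdimer"):
        raise ValueError(f"unknown mode {mode!r}")

    legacy = mode == "gpdimer"
    metric = _metric_for_mode(mode)
    pairmap = PairTypeMap.from_elements(initial.elements)
    params = KernelParams(
        sigma_c2=config.sigma_c2,
        sigma_f2=config.sigma_f2_init,
        length_scales=np.full(pairmap.n_types, config.length_scale_init),
    )
    model = SurrogateModel(
        params, pairmap, config.energy_nugget, config.gradient_nugget
    )

    x = initial.copy()
    tau = np.asarray(initial_direction, dtype=float).reshape(-1)
    energy0, grad = counter.evaluate(x)
    model.add_observation(Observation(x.copy(), energy0, grad))
    energy = energy0
    n_atoms_mov = int(x.movable.sum())

    msub = config.hyperopt.msub_init
    trace: list[OuterIteration] = []
    n_surrogate_steps = 0
    converged = False
    stop_reason = "max_outer_iterations"
    stalls = 0

    for outer in range(config.max_outer_iterations):
        true_rms = rms_force(grad, x)
        if true_rms < config.force_tol:
            converged = True
            stop_reason = "converged"
            break
        if counter.count >= config.max_pes_calls:
            stop_reason = "pes_budget_exhausted"
            break

        subset_size = model.n_data
        if model.n_data >= 2 and outer % config.reoptimize_every == 0:
            new_params, _opt_trace, msub = optimize_hyperparameters(
                model, config.hyperopt, msub=msub, legacy_full_history=legacy
            )
            model.params = new_params
            subset_size = len(model.subset)

        try:
            model.fit()
            surrogate_ok = True
        except IllConditionedModelError:
            surrogate_ok = False

        theta = trust_threshold(model.n_data, n_atoms_mov, config.trust)

        if not surrogate_ok or stalls >= 3:
            # surrogate unusable: fall back to one true-PES dimer cycle
            cycle = run_dimer(
                counter,
                x,
                tau,
                DimerSettings(
                    max_translations=1,
                    force_tol=config.force_tol,
                    max_step=config.inner_dimer.max_step,
                    ratio_at_limit=config.inner_dimer.ratio_at_limit,
                    separation=config.inner_dimer.separation,
                ),
            )
            x, tau = cycle.configuration, cycle.orientation
            energy, grad = counter.evaluate(x)
            model.add_observation(Observation(x.copy(), energy, grad))
            stalls = 0
            trace.append(
                OuterIteration(
                    model.n_data, theta, model.params.to_log_vector(), subset_size,
                    "true_pes_fallback", cycle.n_translations,
                    rms_force(grad, x), energy, x.copy(),
                )
            )
            continue

        training = model.configurations

        def hook(candidate: AtomicConfiguration) -> bool:
            return accept_candidate(candidate, training, theta, metric)

        inner = run_dimer(
            SurrogateCalculator(model),
            x,
            tau,
            config.inner_dimer,
            step_hook=hook,
        )
        n_surrogate_steps += inner.n_translations
        stalls = stalls + 1 if (inner.stop_reason == "rejected" and inner.n_translations == 0) else 0

        x, tau = inner.configuration, inner.orientation
        try:
            energy, grad = counter.evaluate(x)
        except (ValueError, FloatingPointError):
            stop_reason = "pes_error"
            break
        model.add_observation(Observation(x.copy(), energy, grad))
        trace.append(
            OuterIteration(
                model.n_data, theta, model.params.to_log_vector(), subset_size,
                inner.stop_reason, inner.n_translations,
                rms_force(grad, x), energy, x.copy(),
            )
        )
    else:
        stop_reason = "max_outer_iterations"

    final_rms = rms_force(grad, x)
    if final_rms < config.force_tol:
        converged = True
        stop_reason = "converged"

    return SearchResult(
        configuration=x,
        converged=converged,
        n_pes_calls=counter.count,
        n_surrogate_steps=n_surrogate_steps,
        saddle_energy=energy,
        barrier_energy=energy - energy0,
        final_rms_force=final_rms,
        orientation=tau,
        trace=trace,
        stop_reason=stop_reason,
        mode=mode,
    )
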