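"""Minimum-mode-following dimer engine on any calculator.

The dimer estimates the lowest Hessian eigenvector tau from finite
differences between a displaced replica R1 = R0 + dR * tau and the midpoint,
then inverts the force component along tau:

    F_eff = F_perp - F_par,   F_par = (F . tau) tau,

so the walker climbs the softest mode while relaxing all orthogonal
directions, converging on a first-order saddle.  When the local curvature
along tau is still positive (no negative mode found yet), only the reversed
parallel force is followed, which drives the system uphill out of the
convex basin.

Rotation uses the two-point Fourier method: the curvature C(phi) along a
great circle through tau and the rotational-force direction is a harmonic
in 2*phi, fixed by C(0), C'(0) and one trial rotation, giving the angle of
minimum curvature per iteration at two gradient calls.

Every translation step is purified of net rigid-body motion and clipped so
that no atom moves more than half the gap to its nearest neighbour
(modulated by ratio_at_limit) nor more than a configured absolute cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AtomicConfiguration, project_internal, rigid_body_basis
from .surfaces import Calculator

__all__ = [
    "DimerSettings",
    "DimerState",
    "DimerResult",
    "effective_force",
    "rotate_to_minimum_mode",
    "max_step_length",
    "run_dimer",
    "rms_force",
]


@dataclass
class DimerSettings:
    """All tunables of the rotation/translation loop (lengths in Angstrom)."""

    separation: float = 1e-2  # dimer offset dR
    rotation_force_tol: float = 1.0  # eV/A, rotational force convergence
    max_rotations: int = 10  # per translation cycle
    max_step: float = 0.1  # absolute per-cycle cap on any atom's move
    ratio_at_limit: float = 0.5  # Eq.-of-step-limit interpolation knob
    force_tol: float = 0.01  # eV/A, RMS atomic force convergence
    max_translations: int = 1000
    lbfgs_memory: int = 8
    lbfgs_reset_angle: float = 30.0  # degrees of tau change that reset memory
    initial_step: float = 0.02  # scale of the first (no-history) step
    project_rotations: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio_at_limit <= 1.0:
            raise ValueError("ratio_at_limit must lie in [0, 1]")
        if self.separation <= 0 or self.max_step <= 0:
            raise ValueError("separation and max_step must be positive")


@dataclass
class DimerState:
    """Midpoint, unit orientation, and current curvature estimate."""

    midpoint: AtomicConfiguration
    orientation: np.ndarray
    curvature: float = np.nan

    def __post_init__(self) -> None:
        tau = np.asarray(self.orientation, dtype=float).reshape(-1)
        n = np.linalg.norm(tau)
        if n < 1e-12:
            raise ValueError("orientation vector must be nonzero")
        self.orientation = tau / n


@dataclass
class DimerResult:
    """Outcome of a dimer search on one calculator."""

    configuration: AtomicConfiguration
    converged: bool
    energy: float
    gradient: np.ndarray
    curvature: float
    orientation: np.ndarray
    n_translations: int
    n_rotation_evals: int
    n_force_calls: int
    trajectory: list[AtomicConfiguration] = field(default_factory=list)
    stop_reason: str = ""


def rms_force(gradient: np.ndarray, x: AtomicConfiguration) -> float:
    """Root-mean-square atomic force over the movable atoms, eV/A."""
    g = np.asarray(gradient, dtype=float).reshape(-1)[x.dof_mask]
    n_mov = int(x.movable.sum())
    return float(np.sqrt(np.sum(g**2) / n_mov))


def effective_force(gradient: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Dimer force inversion: -grad V + 2 (tau . grad V) tau."""
    gradient = np.asarray(gradient, dtype=float).reshape(-1)
    tau = np.asarray(tau, dtype=float).reshape(-1)
    return -gradient + 2.0 * np.dot(tau, gradient) * tau


def max_step_length(x: AtomicConfiguration, ratio_at_limit: float) -> float:
    """Per-atom step cap 0.5 * (1 - ratio_at_limit) * d_min."""
    if x.n_atoms < 2:
        raise ValueError("step limiting needs at least two atoms")
    dmin = float(np.min(x.pair_distances()))
    return 0.5 * (1.0 - ratio_at_limit) * dmin


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def rotate_to_minimum_mode(
    pes: Calculator,
    state: DimerState,
    settings: DimerSettings,
    midpoint_gradient: np.ndarray | None = None,
) -> tuple[np.ndarray, float, int]:
    """Rotate the dimer into the lowest-curvature direction.

    Returns (tau, curvature, number of gradient calls made here).  The
    midpoint gradient is reused if supplied; each rotation iteration costs
    two extra gradient evaluations (one at the current orientation, one at
    the Fourier trial angle), except the final convergence check which
    costs one.
    """
    x0 = state.midpoint
    dr = settings.separation
    calls = 0
    if midpoint_gradient is None:
        _, midpoint_gradient = pes.evaluate(x0)
        calls += 1
    g0 = np.asarray(midpoint_gradient).reshape(-1)
    tau = state.orientation.copy()
    tau[~x0.dof_mask] = 0.0
    if settings.project_rotations:
        tau = project_internal(tau, x0)
    tau = _normalize(tau)

    curvature = np.nan
    for _ in range(settings.max_rotations):
        _, g1 = pes.evaluate(x0.displaced(dr * tau))
        calls += 1
        dg = g1 - g0
        curvature = float(np.dot(dg, tau) / dr)
        # rotational force: perpendicular component of the gradient difference
        f_rot = -(dg - np.dot(dg, tau) * tau) * 2.0 / dr
        f_rot[~x0.dof_mask] = 0.0
        if settings.project_rotations:
            f_rot = project_internal(f_rot, x0)
            f_rot -= np.dot(f_rot, tau) * tau
        f_rot_norm = np.linalg.norm(f_rot)
        if f_rot_norm < settings.rotation_force_tol:
            break
        theta = f_rot / f_rot_norm

        dcdphi = float(2.0 * np.dot(dg, theta) / dr)
        phi_trial = -0.5 * np.arctan2(dcdphi, 2.0 * abs(curvature))
        if abs(phi_trial) < 1e-8:
            break
        tau_trial = _normalize(tau * np.cos(phi_trial) + theta * np.sin(phi_trial))
        _, g1t = pes.evaluate(x0.displaced(dr * tau_trial))
        calls += 1
        c_trial = float(np.dot(g1t - g0, tau_trial) / dr)

        # C(phi) = a0/2 + a1 cos(2 phi) + b1 sin(2 phi)
        b1 = 0.5 * dcdphi
        a1 = (curvature - c_trial + b1 * np.sin(2 * phi_trial)) / (
            1.0 - np.cos(2 * phi_trial)
        )
        a0 = 2.0 * (curvature - a1)
        phi_min = 0.5 * np.arctan2(b1, a1)
        c_min = a0 / 2.0 + a1 * np.cos(2 * phi_min) + b1 * np.sin(2 * phi_min)
        if c_min > curvature:
            phi_min += 0.5 * np.pi
            c_min = a0 / 2.0 + a1 * np.cos(2 * phi_min) + b1 * np.sin(2 * phi_min)
        tau = _normalize(tau * np.cos(phi_min) + theta * np.sin(phi_min))
        curvature = float(c_min)

    state.orientation = tau
    state.curvature = curvature
    return tau, curvature, calls


class _ForceLBFGS:
    """Two-loop L-BFGS on an effective force field (no energy available)."""

    def __init__(self, memory: int, initial_step: float):
        self.memory = memory
        self.initial_step = initial_step
        self.s: list[np.ndarray] = []
        self.y: list[np.ndarray] = []
        self.prev_x: np.ndarray | None = None
        self.prev_g: np.ndarray | None = None

    def reset(self) -> None:
        self.s.clear()
        self.y.clear()
        self.prev_x = None
        self.prev_g = None

    def step(self, x: np.ndarray, force: np.ndarray) -> np.ndarray:
        g = -force  # treat the effective force as a descent direction source
        if self.prev_x is not None:
            s = x - self.prev_x
            y = g - self.prev_g
            ys = float(np.dot(y, s))
            if ys > 1e-12:
                self.s.append(s)
                self.y.append(y)
                if len(self.s) > self.memory:
                    self.s.pop(0)
                    self.y.pop(0)
        self.prev_x = x.copy()
        self.prev_g = g.copy()
        if not self.s:
            gn = np.linalg.norm(g)
            return -g * (self.initial_step / gn) if gn > 0 else np.zeros_like(g)
        q = g.copy()
        alphas = []
        rhos = [1.0 / np.dot(y, s) for s, y in zip(self.s, self.y)]
        for s, y, rho in zip(reversed(self.s), reversed(self.y), reversed(rhos)):
            a = rho * np.dot(s, q)
            alphas.append(a)
            q -= a * y
        gamma = np.dot(self.s[-1], self.y[-1]) / np.dot(self.y[-1], self.y[-1])
        z = gamma * q
        for (s, y, rho), a in zip(zip(self.s, self.y, rhos), reversed(alphas)):
            b = rho * np.dot(y, z)
            z += s * (a - b)
        return -z


def _clip_step(step: np.ndarray, x: AtomicConfiguration, settings: DimerSettings) -> np.ndarray:
    """Scale the step so no atom exceeds the per-atom and absolute caps."""
    limit = min(max_step_length(x, settings.ratio_at_limit), settings.max_step)
    per_atom = np.linalg.norm(step.reshape(-1, 3), axis=1)
    biggest = float(per_atom.max())
    if biggest > limit > 0:
        step = step * (limit / biggest)
    return step


def run_dimer(
    pes: Calculator,
    initial: AtomicConfiguration,
    initial_direction: np.ndarray,
    settings: DimerSettings | None = None,
    step_hook=None,
    record_trajectory: bool = False,
) -> DimerResult:
    """Alternate dimer rotation and translation until the RMS force converges.

    ``step_hook(candidate) -> bool`` is consulted before each translation is
    committed; a False verdict aborts the search with stop_reason
    "rejected" (the surrogate controller uses this for its trust radius).
    Budget exhaustion returns a non-converged result, never an exception.
    """
    settings = settings or DimerSettings()
    x = initial.copy()
    state = DimerState(midpoint=x, orientation=initial_direction)
    optimizer = _ForceLBFGS(settings.lbfgs_memory, settings.initial_step)
    trajectory: list[AtomicConfiguration] = []

    energy, grad = pes.evaluate(x)
    n_calls = 1
    n_rot_evals = 0
    n_trans = 0
    prev_tau = None
    stop = "max_translations"

    for _ in range(settings.max_translations):
        if record_trajectory:
            trajectory.append(x.copy())
        if rms_force(grad, x) < settings.force_tol:
            stop = "converged"
            break
        state.midpoint = x
        try:
            tau, curvature, rot_calls = rotate_to_minimum_mode(
                pes, state, settings, midpoint_gradient=grad
            )
        except (ValueError, FloatingPointError):
            stop = "pes_error"
            break
        n_rot_evals += rot_calls
        n_calls += rot_calls

        if prev_tau is not None:
            cosang = np.clip(abs(np.dot(tau, prev_tau)), 0.0, 1.0)
            if np.degrees(np.arccos(cosang)) > settings.lbfgs_reset_angle:
                optimizer.reset()
        prev_tau = tau

        if curvature < 0.0:
            f_eff = effective_force(grad, tau)
        else:
            # still in a convex region: climb straight up the softest mode
            f_eff = np.dot(tau, grad) * tau
        f_eff[~x.dof_mask] = 0.0
        step = optimizer.step(x.coords, f_eff)
        step[~x.dof_mask] = 0.0
        if settings.project_rotations:
            step = project_internal(step, x, rigid_body_basis(x))
        step = _clip_step(step, x, settings)

        candidate = x.displaced(step)
        if step_hook is not None and not step_hook(candidate):
            stop = "rejected"
            break
        try:
            energy_new, grad_new = pes.evaluate(candidate)
        except (ValueError, FloatingPointError):
            stop = "pes_error"
            break
        x, energy, grad = candidate, energy_new, grad_new
        n_calls += 1
        n_trans += 1

    if stop == "max_translations" and rms_force(grad, x) < settings.force_tol:
        stop = "converged"

    if record_trajectory and (not trajectory or trajectory[-1].positions is not x.positions):
        trajectory.append(x.copy())

    return DimerResult(
        configuration=x,
        converged=(stop == "converged"),
        energy=energy,
        gradient=grad,
        curvature=state.curvature,
        orientation=state.orientation,
        n_translations=n_trans,
        n_rotation_evals=n_rot_evals,
        n_force_calls=n_calls,
        trajectory=trajectory,
        stop_reason=stop,
    )
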