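"""Hyperparameter control for the surrogate.

Three mechanisms keep the marginal-likelihood optimization cheap and stable:

* **Farthest-point sampling (FPS)** under the intensive EMD selects a
  fixed-size, geometrically diverse subset of the observation history; only
  this subset enters the likelihood, bounding the covariance at
  (Msub * (3N+1))^2 regardless of how long the search runs.  The two most
  recent observations are always retained for continuity of the dimer path.
* **A logarithmic barrier** on w0 = log(sigma_f^2) prevents the signal
  variance from running away along the likelihood's shallow ridge: the
  objective gains -mu * log(lambda_max - w0), whose gradient diverges at the
  bound, and the barrier strength mu grows linearly with the amount of data.
* **Hyperparameter oscillation detection (HOD)** measures the fraction of
  sign-alternating consecutive updates over a trailing window of optimizer
  iterates; sustained alternation flags an unstable fit and triggers subset
  growth with a rerun, up to three retries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize
from scipy.stats import t as student_t

from .geometry import AtomicConfiguration, intensive_emd
from .gp import SurrogateModel
from .kernel import KernelParams

__all__ = [
    "BarrierConfig",
    "HODConfig",
    "PriorConfig",
    "HyperoptConfig",
    "OptimizationTrace",
    "BarrierDomainError",
    "fps_select",
    "student_t_log_prior",
    "barrier_strength",
    "barrier_term",
    "barrier_gradient_w0",
    "effective_objective",
    "oscillation_fraction",
    "optimize_hyperparameters",
]


@dataclass
class BarrierConfig:
    """Log-barrier on the signal variance: bound and strength schedule."""

    lambda_max: float = float(np.log(2.0))  # hard bound on log sigma_f^2
    mu0: float = 1e-4  # seed strength
    alpha: float = 1e-3  # growth per data point
    mu_max: float = 0.5  # strength ceiling

    def __post_init__(self) -> None:
        if self.mu0 < 0 or self.alpha < 0 or self.mu_max < self.mu0:
            raise ValueError("require mu0, alpha >= 0 and mu_max >= mu0")


@dataclass
class HODConfig:
    """Oscillation-detection window, threshold, and retry policy."""

    window: int = 6
    threshold: float = 0.5
    max_retries: int = 3
    subset_increment: int = 5

    def __post_init__(self) -> None:
        if self.window < 3:
            raise ValueError("window must be at least 3")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class PriorConfig:
    """Student-t prior on the log hyperparameters.

    The degrees of freedom never drop below a floor of 28 (near-Gaussian
    shape) and grow proportionally with the number of interaction types so
    that chemically complex systems are regularized more strongly.
    """

    dof_floor: int = 28
    dof_per_interaction_type: float = 1.0
    location: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.dof_floor < 28:
            raise ValueError("degrees-of-freedom floor is 28")

    def dof(self, n_interaction_types: int) -> float:
        return max(self.dof_floor, self.dof_per_interaction_type * n_interaction_types)


@dataclass
class HyperoptConfig:
    """Knobs of the subset-based likelihood optimization."""

    msub_init: int = 10
    msub_cap: int = 30
    energy_filter_kappa: float = 3.0
    maxiter: int = 60
    n_random_starts: int = 2  # extra seeded restarts (the MLL is multimodal)
    barrier: BarrierConfig = field(default_factory=BarrierConfig)
    hod: HODConfig = field(default_factory=HODConfig)
    prior: PriorConfig = field(default_factory=PriorConfig)


@dataclass
class OptimizationTrace:
    """Per-iteration record of one (possibly retried) optimization."""

    iterates: list[np.ndarray] = field(default_factory=list)
    objectives: list[float] = field(default_factory=list)
    subset_sizes: list[int] = field(default_factory=list)
    oscillation_fractions: list[float] = field(default_factory=list)
    retries: int = 0
    unstable: bool = False


class BarrierDomainError(ValueError):
    """log sigma_f^2 reached or exceeded the barrier bound."""


# ---------------------------------------------------------------------------
# farthest-point sampling
# ---------------------------------------------------------------------------


def fps_select(
    configurations: list[AtomicConfiguration],
    msub: int,
    metric: Callable[[AtomicConfiguration, AtomicConfiguration], float] = intensive_emd,
    energies: np.ndarray | None = None,
    energy_filter_kappa: float | None = 3.0,
) -> list[int]:
    """Greedy max-min subset of the history under a configuration metric.

    The two most recent observations seed the subset (path continuity), then
    the candidate whose minimum distance to the subset is maximal is added
    until ``min(msub, len(X))`` members are reached; ties break to the
    smallest index.  When energies are given, candidates far above the
    subset's energy spread (median + kappa * IQR) are deferred: they enter
    only if the target size cannot otherwise be reached.
    """
    m = len(configurations)
    if m == 0:
        raise ValueError("empty observation history")
    target = min(msub, m)
    selected = [m - 1] if m == 1 else [m - 2, m - 1]
    target = max(target, len(selected)) if m > 1 else target
    remaining = [i for i in range(m) if i not in selected]

    mindist = {
        i: min(metric(configurations[i], configurations[j]) for j in selected)
        for i in remaining
    }

    use_filter = energies is not None and energy_filter_kappa is not None
    if use_filter:
        energies = np.asarray(energies, dtype=float)
    while len(selected) < target and remaining:
        if use_filter:
            sub_e = energies[selected]
            q1, q3 = np.percentile(sub_e, [25, 75])
            cutoff = float(np.median(sub_e)) + energy_filter_kappa * (q3 - q1)
            pool = [i for i in remaining if energies[i] <= cutoff]
            if not pool:
                pool = list(remaining)  # filter would starve the subset
        else:
            pool = remaining
        best = max(pool, key=lambda i: (mindist[i], -i))
        selected.append(best)
        remaining.remove(best)
        for i in remaining:
            dnew = metric(configurations[i], configurations[best])
            if dnew < mindist[i]:
                mindist[i] = dnew

    return sorted(selected)


# ---------------------------------------------------------------------------
# prior, barrier, objective
# ---------------------------------------------------------------------------


def student_t_log_prior(
    params: KernelParams, prior: PriorConfig, n_interaction_types: int
) -> float:
    """Sum of independent Student-t log densities on the log hyperparameters."""
    w = params.to_log_vector()
    dof = prior.dof(n_interaction_types)
    return float(np.sum(student_t.logpdf(w, dof, loc=prior.location, scale=prior.scale)))


def barrier_strength(n_data: int, cfg: BarrierConfig) -> float:
    """mu(N) = min(mu0 + alpha * N, mu_max): weak early, strict late."""
    if n_data < 0:
        raise ValueError("data count cannot be negative")
    return min(cfg.mu0 + cfg.alpha * n_data, cfg.mu_max)


def barrier_term(w0: float, mu: float, cfg: BarrierConfig) -> float:
    """Interior-point barrier mu * log(lambda_max - w0) on the maximized objective.

    Diverges to -inf as w0 -> lambda_max from below, so the optimizer can
    never cross the signal-variance bound; for the equivalent minimized
    objective this is the textbook -mu log(C - w0) penalty whose w0-gradient
    mu / (C - w0) blows up at the wall.
    """
    if w0 >= cfg.lambda_max:
        raise BarrierDomainError(
            f"log sigma_f^2 = {w0:.6f} >= lambda_max = {cfg.lambda_max:.6f}"
        )
    return mu * np.log(cfg.lambda_max - w0)


def barrier_gradient_w0(w0: float, mu: float, cfg: BarrierConfig) -> float:
    """d/dw0 of the barrier term: -mu / (lambda_max - w0)."""
    if w0 >= cfg.lambda_max:
        raise BarrierDomainError("gradient undefined at or beyond the bound")
    return -mu / (cfg.lambda_max - w0)


def effective_objective(
    params: KernelParams,
    model: SurrogateModel,
    subset: list[int],
    cfg: HyperoptConfig,
    n_data: int,
) -> float:
    """Barrier-augmented objective to maximize: MLL + log-prior + barrier."""
    mu = barrier_strength(n_data, cfg.barrier)
    w0 = float(np.log(params.sigma_f2))
    bar = barrier_term(w0, mu, cfg.barrier)
    mll = model.log_marginal_likelihood(params, subset)
    prior = student_t_log_prior(params, cfg.prior, model.pairmap.n_types)
    return mll + prior + bar


# ---------------------------------------------------------------------------
# oscillation detection
# ---------------------------------------------------------------------------


def oscillation_fraction(trace: np.ndarray | list[np.ndarray], window: int) -> float:
    """Fraction of sign-alternating consecutive updates in a trailing window.

    With window iterates theta(0..W-1) and updates Delta(t) = theta(t) -
    theta(t-1), a cell (j, t) oscillates when Delta_j(t) and Delta_j(t-1)
    have strictly opposite signs; the count is normalized by D * (W - 2).
    Fewer than three iterates in the window give 0 by convention.
    """
    arr = np.asarray(trace, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    arr = arr[-window:]
    if arr.shape[0] < 3:
        return 0.0
    deltas = np.diff(arr, axis=0)
    signs = np.sign(deltas)
    flips = (signs[1:] * signs[:-1]) < 0
    w_eff, dim = arr.shape
    return float(flips.sum() / (dim * (w_eff - 2)))


# ---------------------------------------------------------------------------
# the optimization driver
# ---------------------------------------------------------------------------


def optimize_hyperparameters(
    model: SurrogateModel,
    cfg: HyperoptConfig,
    msub: int | None = None,
    legacy_full_history: bool = False,
) -> tuple[KernelParams, OptimizationTrace, int]:
    """Fit kernel hyperparameters on an FPS subset with HOD retries.

    Bounded L-BFGS-B descent on the negative barrier-augmented objective in
    log space, warm-started from the model's current parameters.  If the
    update trace oscillates beyond the HOD threshold, the subset grows by
    the configured increment (capped) and the optimization reruns, at most
    three times.  Returns the best parameters seen, the trace, and the
    (possibly grown) subset size to persist for the next outer iteration.

    ``legacy_full_history`` reproduces the predecessor behaviour: no FPS
    (the whole history enters the likelihood), no barrier, no HOD.
    """
    if model.n_data < 2:
        raise ValueError("need at least two observations to fit hyperparameters")
    msub = cfg.msub_init if msub is None else msub
    n_data = model.n_data
    energies = np.array([o.energy for o in model.observations])

    trace = OptimizationTrace()
    best_obj = -np.inf
    best_params = model.params
    best_subset: list[int] = list(range(n_data))

    attempts = 1 if legacy_full_history else cfg.hod.max_retries + 1
    for attempt in range(attempts):
        if legacy_full_history:
            subset = list(range(n_data))
        else:
            subset = fps_select(
                model.configurations,
                msub,
                energies=energies,
                energy_filter_kappa=cfg.energy_filter_kappa,
            )
        mu = 0.0 if legacy_full_history else barrier_strength(n_data, cfg.barrier)
        lam = cfg.barrier.lambda_max

        def negative_objective(w: np.ndarray) -> float:
            params = model.params.with_log_vector(w)
            if not legacy_full_history and w[0] >= lam:
                return 1e12
            mll = model.log_marginal_likelihood(params, subset)
            if not np.isfinite(mll):
                return 1e12
            val = mll + student_t_log_prior(params, cfg.prior, model.pairmap.n_types)
            if not legacy_full_history:
                val += barrier_term(float(w[0]), mu, cfg.barrier)
            return -val

        w_warm = model.params.to_log_vector()
        if not legacy_full_history:
            w_warm[0] = min(w_warm[0], lam - 1e-3)
        upper0 = 5.0 if legacy_full_history else lam - 1e-6
        bounds = [(-5.0, upper0)] + [(-5.0, 5.0)] * (len(w_warm) - 1)
        w_prior = np.full_like(w_warm, cfg.prior.location)
        w_prior[0] = min(w_prior[0], upper0 - 1e-3)

        # warm start, a restart from the prior location, and a few seeded
        # random restarts: the likelihood surface is multimodal and a
        # collapsed length scale is a sticky local optimum that fresh data
        # cannot undo from inside
        starts = [w_warm]
        if np.linalg.norm(w_prior - w_warm) > 1e-6:
            starts.append(w_prior)
        rng = np.random.default_rng(100_003 * n_data + 17 * attempt)
        for _ in range(cfg.n_random_starts):
            w_rand = rng.uniform(-2.0, 1.5, size=w_warm.shape)
            w_rand[0] = rng.uniform(-2.0, min(upper0, lam) - 0.1)
            starts.append(w_rand)
        res = None
        run_iterates: list[np.ndarray] = []
        for w0_start in starts:
            iterates: list[np.ndarray] = [w0_start.copy()]
            cand = minimize(
                negative_objective,
                w0_start,
                method="L-BFGS-B",
                jac="3-point",  # the MLL ridge is too flat for forward differences
                bounds=bounds,
                callback=lambda w: iterates.append(np.array(w)),
                options={"maxiter": cfg.maxiter, "ftol": 1e-13, "gtol": 1e-7, "eps": 1e-5},
            )
            if res is None or cand.fun < res.fun:
                res = cand
                run_iterates = iterates

        obj = -float(res.fun)
        trace.iterates.extend(run_iterates)
        trace.objectives.append(obj)
        trace.subset_sizes.append(len(subset))
        fosc = oscillation_fraction(np.array(run_iterates), cfg.hod.window)
        trace.oscillation_fractions.append(fosc)

        if obj > best_obj:
            best_obj = obj
            best_params = model.params.with_log_vector(res.x)
            best_subset = subset

        if legacy_full_history or fosc <= cfg.hod.threshold:
            break
        if attempt < attempts - 1:
            msub = min(msub + cfg.hod.subset_increment, cfg.msub_cap)
            trace.retries += 1
    else:
        trace.unstable = True

    model.subset = best_subset
    return best_params, trace, msub
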