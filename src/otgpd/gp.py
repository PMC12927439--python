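"""Energy+gradient Gaussian-process surrogate over atomic configurations.

Observations are exact (energy, gradient) pairs from a deterministic
calculator, so the noise model is a fixed small diagonal nugget per channel
rather than a fitted likelihood variance.  Training energies are centered on
their mean before fitting (prior mean = data mean), which keeps the signal
variance in the O(1) regime that the log-barrier bound assumes.

Hyperparameters are fitted on a diverse subset of the history (see
``hyperopt``), but prediction always conditions on the *full* observation
history: every expensive PES evaluation contributes to the surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .geometry import AtomicConfiguration
from .kernel import ConfigurationFeatures, KernelParams, PairTypeMap, kernel_blocks

__all__ = ["Observation", "SurrogateModel", "SurrogateCalculator", "IllConditionedModelError"]


@dataclass
class Observation:
    """One evaluated configuration: V(x) in eV, grad V(x) in eV/A (3N)."""

    configuration: AtomicConfiguration
    energy: float
    gradient: np.ndarray

    def __post_init__(self) -> None:
        self.gradient = np.asarray(self.gradient, dtype=float).reshape(-1)
        if self.gradient.shape[0] != self.configuration.n_dof:
            raise ValueError("gradient length must be 3N")
        if not np.isfinite(self.energy):
            raise ValueError("energy must be finite")

    @property
    def movable_gradient(self) -> np.ndarray:
        return self.gradient[self.configuration.dof_mask]


class IllConditionedModelError(RuntimeError):
    """Covariance factorization failed even at the maximum jitter."""


class SurrogateModel:
    """GP over a growing observation history.

    Parameters
    ----------
    params : KernelParams
        Current kernel hyperparameters.
    pairmap : PairTypeMap
        Element-pair -> length-scale index map (fixed along a search).
    energy_nugget, gradient_nugget : float
        Diagonal regularization per observation channel, eV^2 and (eV/A)^2.
    """

    #: jitter escalation, relative to the mean covariance diagonal
    JITTER_START = 1e-8
    JITTER_MAX = 1e-4
    JITTER_GROWTH = 10.0

    def __init__(
        self,
        params: KernelParams,
        pairmap: PairTypeMap,
        energy_nugget: float = 1e-8,
        gradient_nugget: float = 1e-8,
    ):
        self.params = params
        self.pairmap = pairmap
        self.energy_nugget = float(energy_nugget)
        self.gradient_nugget = float(gradient_nugget)
        self.observations: list[Observation] = []
        self._features: list[ConfigurationFeatures] = []
        self.subset: list[int] = []
        self._cho = None
        self._alpha = None
        self._prior_mean = 0.0
        self.jitter_used: float | None = None

    # -- data management ----------------------------------------------------

    def add_observation(self, obs: Observation) -> None:
        if self.observations and obs.configuration.elements != self.observations[0].configuration.elements:
            raise ValueError("all observations must share one element list")
        self.observations.append(obs)
        self._features.append(ConfigurationFeatures(obs.configuration))
        self._cho = None

    @property
    def n_data(self) -> int:
        return len(self.observations)

    @property
    def configurations(self) -> list[AtomicConfiguration]:
        return [o.configuration for o in self.observations]

    @property
    def is_fitted(self) -> bool:
        return self._cho is not None

    # -- covariance assembly -------------------------------------------------

    def _assemble(
        self, indices: list[int], params: KernelParams
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Return (K + nuggets, centered y, energy mean) over observations."""
        obs = [self.observations[i] for i in indices]
        feats = [self._features[i] for i in indices]
        X = [o.configuration for o in obs]
        kff, kfg, kgf, kgg = kernel_blocks(
            X, X, params, self.pairmap, features1=feats, features2=feats
        )
        m = len(obs)
        d = kgg.shape[0] // m
        K = np.block([[kff, kfg], [kgf, kgg]])
        K[np.arange(m), np.arange(m)] += self.energy_nugget
        K[np.arange(m, m + m * d), np.arange(m, m + m * d)] += self.gradient_nugget
        energies = np.array([o.energy for o in obs])
        mean = float(energies.mean())
        y = np.concatenate([energies - mean, np.concatenate([o.movable_gradient for o in obs])])
        return K, y, mean

    def _factorize(self, K: np.ndarray):
        """Cholesky with geometric jitter escalation; raises when exhausted."""
        scale = float(np.mean(np.diag(K)))
        jitter = 0.0
        rel = self.JITTER_START
        while True:
            try:
                cho = cho_factor(K + jitter * np.eye(K.shape[0]), lower=True)
                return cho, jitter
            except LinAlgError:
                if rel > self.JITTER_MAX:
                    raise IllConditionedModelError(
                        f"covariance not positive definite at jitter {jitter:.3e}"
                    )
                jitter = rel * scale
                rel *= self.JITTER_GROWTH

    # -- fitting and prediction ----------------------------------------------

    def fit(self) -> "SurrogateModel":
        """Factorize the block covariance over the full history."""
        if self.n_data < 1:
            raise ValueError("cannot fit with no observations")
        K, y, mean = self._assemble(list(range(self.n_data)), self.params)
        self._cho, self.jitter_used = self._factorize(K)
        self._alpha = cho_solve(self._cho, y)
        self._prior_mean = mean
        return self

    def predict(self, x: AtomicConfiguration) -> tuple[float, np.ndarray, float]:
        """Posterior mean energy, mean gradient (3N), and energy variance."""
        if not self.is_fitted:
            raise RuntimeError("model must be fitted before prediction")
        X = self.configurations
        kff, kfg, kgf, kgg = kernel_blocks(
            [x], X, self.params, self.pairmap, features2=self._features
        )
        # cross-covariance rows: energy row, then one row per movable DOF
        k_energy = np.concatenate([kff[0], kfg[0]])
        k_grad = np.hstack([kgf, kgg])  # (d, M(1+d))
        energy = self._prior_mean + float(k_energy @ self._alpha)
        grad = np.zeros(x.n_dof)
        grad[x.dof_mask] = k_grad @ self._alpha
        prior_var = self.params.sigma_c2 + self.params.sigma_f2 + self.energy_nugget
        var = prior_var - float(k_energy @ cho_solve(self._cho, k_energy))
        return energy, grad, max(var, 0.0)

    # -- marginal likelihood ---------------------------------------------------

    def log_marginal_likelihood(
        self, params: KernelParams, indices: list[int] | None = None
    ) -> float:
        """MLL of the (centered) observations at ``indices`` under ``params``.

        Returns -inf when the covariance cannot be factorized, so an
        optimizer simply avoids that region.
        """
        idx = list(range(self.n_data)) if indices is None else list(indices)
        if not idx:
            raise ValueError("need at least one observation for the likelihood")
        K, y, _ = self._assemble(idx, params)
        try:
            cho, _ = self._factorize(K)
        except IllConditionedModelError:
            return -np.inf
        alpha = cho_solve(cho, y)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        n = y.shape[0]
        return -0.5 * float(y @ alpha) - 0.5 * logdet - 0.5 * n * np.log(2.0 * np.pi)


class SurrogateCalculator:
    """Expose a fitted surrogate through the calculator contract."""

    def __init__(self, model: SurrogateModel):
        self.model = model

    def evaluate(self, x: AtomicConfiguration) -> tuple[float, np.ndarray]:
        energy, grad, _ = self.model.predict(x)
        return energy, grad
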