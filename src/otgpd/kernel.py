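"""Inverse-distance squared-exponential kernel with derivative blocks.

The covariance between two configurations x and x' is

    k(x, x') = sigma_c^2
             + sigma_f^2 * exp(-1/2 * sum_{i<j} ((1/r_ij(x) - 1/r_ij(x'))
                                                 / l_phi(i,j))^2)

with one length scale per unordered element-pair type phi(i,j).  The 1/r
features give a strong physical prior: the kernel saturates smoothly as
atoms approach, where the energy varies violently.

Joint energy+gradient modelling needs the analytic derivatives of k with
respect to the Cartesian coordinates of either argument.  With

    q(x)   = vector of inverse pair distances,          (P,)
    J(x)   = dq/dx, the pair Jacobian,                  (P, d)
    u      = (q(x) - q(x')) / l,                        (P,)
    E      = exp(-1/2 u.u)

the blocks are

    dk/dx          = -sigma_f^2 E J(x)^T (u/l)
    dk/dx'         = +sigma_f^2 E J(x')^T (u/l)
    d2k/dx dx'^T   =  sigma_f^2 E [ J(x)^T diag(1/l^2) J(x')
                                    - (J(x)^T u/l)(J(x')^T u/l)^T ]

The constant offset sigma_c^2 contributes to no derivative block.  Only
movable degrees of freedom enter the derivative blocks (frozen fixture
anchors carry no gradient observations), while *all* pair distances,
including those to frozen atoms, enter the kernel exponent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import AtomicConfiguration

__all__ = ["PairTypeMap", "KernelParams", "ConfigurationFeatures", "kernel_energy", "kernel_blocks"]


@dataclass(frozen=True)
class PairTypeMap:
    """Unordered element pair {A, B} -> length-scale index."""

    index: dict[tuple[str, str], int]

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    @classmethod
    def from_elements(cls, elements: tuple[str, ...]) -> "PairTypeMap":
        keys = sorted({cls._key(a, b) for i, a in enumerate(elements) for b in elements[i + 1 :]})
        return cls({k: i for i, k in enumerate(keys)})

    @property
    def n_types(self) -> int:
        return len(self.index)

    def pair_type_indices(self, elements: tuple[str, ...]) -> np.ndarray:
        """Length-scale index per pair, in condensed (pdist) pair order."""
        n = len(elements)
        out = []
        for i in range(n):
            for j in range(i + 1, n):
                out.append(self.index[self._key(elements[i], elements[j])])
        return np.array(out, dtype=int)


@dataclass
class KernelParams:
    """Kernel hyperparameters; the optimizer works on the log-space view.

    sigma_c2 : eV^2   constant energy offset variance (fixed by default)
    sigma_f2 : eV^2   signal variance; w0 = log(sigma_f2) is barrier-bounded
    length_scales :   one per pair type, on the inverse-distance (1/A) scale
    """

    sigma_c2: float
    sigma_f2: float
    length_scales: np.ndarray

    def __post_init__(self) -> None:
        self.length_scales = np.asarray(self.length_scales, dtype=float)
        if self.sigma_c2 < 0 or self.sigma_f2 <= 0 or np.any(self.length_scales <= 0):
            raise ValueError(
                "signal variance and length scales must be positive, offset nonnegative"
            )

    @property
    def n_free(self) -> int:
        return 1 + len(self.length_scales)

    def to_log_vector(self) -> np.ndarray:
        """w = [log sigma_f2, log l_1, ..., log l_T]; sigma_c2 stays fixed."""
        return np.concatenate(([np.log(self.sigma_f2)], np.log(self.length_scales)))

    def with_log_vector(self, w: np.ndarray) -> "KernelParams":
        w = np.asarray(w, dtype=float)
        return replace(
            self, sigma_f2=float(np.exp(w[0])), length_scales=np.exp(w[1:]).copy()
        )


class ConfigurationFeatures:
    """Cached inverse-distance features and Jacobian for one configuration."""

    def __init__(self, x: AtomicConfiguration):
        self.x = x
        pos = x.positions
        n = x.n_atoms
        iu = np.triu_indices(n, 1)
        diff = pos[iu[0]] - pos[iu[1]]  # (P, 3)
        r = np.linalg.norm(diff, axis=1)
        if r.size == 0:
            raise ValueError("at least two atoms are required by the kernel")
        if r.min() <= 1e-12:
            raise ValueError("degenerate geometry: coincident atoms")
        self.q = 1.0 / r  # (P,)
        # d(1/r)/dp_i = -(p_i - p_j)/r^3 ; opposite sign for atom j
        scaled = -diff / (r**3)[:, None]  # (P, 3) contribution to atom i
        jac = np.zeros((len(r), 3 * n))
        p_idx = np.arange(len(r))
        for axis in range(3):
            jac[p_idx, 3 * iu[0] + axis] = scaled[:, axis]
            jac[p_idx, 3 * iu[1] + axis] = -scaled[:, axis]
        self.jacobian = jac[:, x.dof_mask]  # (P, d) movable DOFs only
        self.n_movable_dof = int(x.dof_mask.sum())


def _pair_scales(params: KernelParams, pairmap: PairTypeMap, elements) -> np.ndarray:
    return params.length_scales[pairmap.pair_type_indices(tuple(elements))]


def _exponent_terms(
    f1: ConfigurationFeatures, f2: ConfigurationFeatures, ell: np.ndarray
) -> tuple[np.ndarray, float]:
    u = (f1.q - f2.q) / ell
    return u, float(np.exp(-0.5 * np.dot(u, u)))


def kernel_energy(
    x1: AtomicConfiguration,
    x2: AtomicConfiguration,
    params: KernelParams,
    pairmap: PairTypeMap,
) -> float:
    """Energy-energy covariance k(x1, x2)."""
    if x1.elements != x2.elements:
        raise ValueError("configurations must share the same ordered element list")
    f1, f2 = ConfigurationFeatures(x1), ConfigurationFeatures(x2)
    ell = _pair_scales(params, pairmap, x1.elements)
    _, ex = _exponent_terms(f1, f2, ell)
    return params.sigma_c2 + params.sigma_f2 * ex


def kernel_blocks(
    X1: list[AtomicConfiguration],
    X2: list[AtomicConfiguration],
    params: KernelParams,
    pairmap: PairTypeMap,
    features1: list[ConfigurationFeatures] | None = None,
    features2: list[ConfigurationFeatures] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Block covariance between two configuration lists.

    Returns (Kff, Kfg, Kgf, Kgg) with shapes (M1, M2), (M1, M2*d),
    (M1*d, M2), (M1*d, M2*d), where d is the movable-DOF count.  Gradient
    blocks are ordered configuration-major.
    """
    f1s = features1 if features1 is not None else [ConfigurationFeatures(x) for x in X1]
    f2s = features2 if features2 is not None else [ConfigurationFeatures(x) for x in X2]
    ell = _pair_scales(params, pairmap, X1[0].elements)
    m1, m2 = len(f1s), len(f2s)
    d = f1s[0].n_movable_dof
    q2 = np.stack([f.q for f in f2s])  # (m2, P)
    j2 = np.stack([f.jacobian for f in f2s])  # (m2, P, d)
    j2_scaled = j2 / (ell**2)[None, :, None]
    kff = np.zeros((m1, m2))
    kfg = np.zeros((m1, m2 * d))
    kgf = np.zeros((m1 * d, m2))
    kgg = np.zeros((m1 * d, m2 * d))
    for a, fa in enumerate(f1s):
        u = (fa.q[None, :] - q2) / ell[None, :]  # (m2, P)
        amp = params.sigma_f2 * np.exp(-0.5 * (u**2).sum(axis=1))  # (m2,)
        w = u / ell[None, :]
        g1 = w @ fa.jacobian  # (m2, d)
        g2 = np.einsum("mp,mpd->md", w, j2)  # (m2, d)
        cross = np.einsum("pa,mpb->mab", fa.jacobian, j2_scaled)  # (m2, d, d)
        kff[a] = params.sigma_c2 + amp
        kfg[a] = (amp[:, None] * g2).reshape(-1)
        kgf[a * d : (a + 1) * d] = -(amp[:, None] * g1).T
        blocks = amp[:, None, None] * (cross - g1[:, :, None] * g2[:, None, :])
        kgg[a * d : (a + 1) * d] = blocks.transpose(1, 0, 2).reshape(d, m2 * d)
    return kff, kfg, kgf, kgg
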