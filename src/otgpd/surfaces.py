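"""Analytic potential-energy surfaces and synthetic configuration generators.

These fixtures make the whole search stack testable without any external
electronic-structure engine.  Every surface implements the calculator
contract ``evaluate(AtomicConfiguration) -> (energy [eV], gradient [eV/A])``
with a closed-form gradient; a finite-difference self-test in the test suite
guards every fixture.

Sign convention: the calculator returns the *gradient* of the energy; the
force on the atoms is its negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from scipy.optimize import fsolve

from .geometry import AtomicConfiguration, typed_partition

__all__ = [
    "Calculator",
    "CountingCalculator",
    "AnalyticPES",
    "MorseClusterPES",
    "GaussianWellsPES",
    "QuadraticPES",
    "make_morse_cluster",
    "make_2d_gaussian_wells",
    "make_morse_trimer_start",
    "perturb_configuration",
    "permute_within_types",
    "rigid_transform",
    "random_internal_direction",
    "relax_to_minimum",
    "newton_stationary_point",
    "finite_difference_hessian",
]


class Calculator(Protocol):
    """The PES evaluator contract used by every engine in the package."""

    def evaluate(self, x: AtomicConfiguration) -> tuple[float, np.ndarray]:
        """Return (energy in eV, gradient as a flattened 3N vector in eV/A)."""
        ...


class CountingCalculator:
    """Wrap a calculator and count evaluations (the paper's cost currency)."""

    def __init__(self, inner: Calculator):
        self.inner = inner
        self.count = 0

    def evaluate(self, x: AtomicConfiguration) -> tuple[float, np.ndarray]:
        self.count += 1
        return self.inner.evaluate(x)

    def reset(self) -> None:
        self.count = 0


@dataclass
class AnalyticPES:
    """A named closed-form PES with optional pre-solved stationary points."""

    name: str
    _energy: Callable[[AtomicConfiguration], float]
    _gradient: Callable[[AtomicConfiguration], np.ndarray]
    known_minima: list[AtomicConfiguration] = field(default_factory=list)
    known_saddles: list[AtomicConfiguration] = field(default_factory=list)

    def evaluate(self, x: AtomicConfiguration) -> tuple[float, np.ndarray]:
        grad = np.asarray(self._gradient(x), dtype=float).reshape(-1)
        grad[~x.dof_mask] = 0.0
        return float(self._energy(x)), grad


class MorseClusterPES:
    """Pairwise Morse potential over all movable-and-frozen atom pairs.

    V = sum_{i<j} De * [(1 - exp(-a (r_ij - r0)))^2 - 1].  A single (De, a,
    r0) parameter set applies to every pair; element labels only tag atom
    types for the kernel's pair-type map and the per-type metric, they do
    not change the physics.
    """

    def __init__(self, well_depth: float = 1.0, width: float = 1.5, r0: float = 1.5):
        self.well_depth = float(well_depth)
        self.width = float(width)
        self.r0 = float(r0)
        self.name = "morse-cluster"

    def evaluate(self, x: AtomicConfiguration) -> tuple[float, np.ndarray]:
        pos = x.positions
        n = x.n_atoms
        diff = pos[:, None, :] - pos[None, :, :]
        r = np.sqrt((diff**2).sum(axis=-1))
        iu = np.triu_indices(n, 1)
        rij = r[iu]
        if rij.size and rij.min() <= 1e-10:
            raise ValueError("coincident atoms in Morse evaluation")
        ex = np.exp(-self.width * (rij - self.r0))
        energy = float(self.well_depth * ((1.0 - ex) ** 2 - 1.0).sum())
        # dV/dr = 2 De a ex (1 - ex)
        dvdr = 2.0 * self.well_depth * self.width * ex * (1.0 - ex)
        grad = np.zeros((n, 3))
        unit = diff[iu] / rij[:, None]
        contrib = dvdr[:, None] * unit
        np.add.at(grad, iu[0], contrib)
        np.add.at(grad, iu[1], -contrib)
        g = grad.reshape(-1)
        g[~x.dof_mask] = 0.0
        return energy, g

    def pair_energy(self, r: float) -> float:
        """Closed-form Morse energy of a single pair at separation r."""
        ex = np.exp(-self.width * (r - self.r0))
        return float(self.well_depth * ((1.0 - ex) ** 2 - 1.0))


def make_morse_cluster(
    n_atoms: int,
    element_labels: tuple[str, ...] | None = None,
    well_depth: float = 1.0,
    width: float = 1.5,
    r0: float = 1.5,
) -> tuple[MorseClusterPES, AtomicConfiguration]:
    """A Morse pair-potential cluster and a reasonable starting geometry.

    The default labels alternate two element types so pair-type machinery
    and the per-type metric are exercised.  The starting geometry places the
    atoms on a loose helix near the pair minimum distance.
    """
    if n_atoms < 2:
        raise ValueError("a cluster needs at least two atoms")
    if element_labels is None:
        element_labels = tuple("A" if i % 2 == 0 else "B" for i in range(n_atoms))
    if len(element_labels) != n_atoms:
        raise ValueError("label count must equal atom count")
    pes = MorseClusterPES(well_depth, width, r0)
    t = np.arange(n_atoms)
    pos = np.stack(
        [
            r0 * np.cos(0.9 * t),
            r0 * np.sin(0.9 * t),
            0.45 * r0 * t,
        ],
        axis=1,
    )
    return pes, AtomicConfiguration(element_labels, pos)


def make_morse_trimer_start(r0: float = 1.5) -> AtomicConfiguration:
    """Near-equilateral Morse trimer, slightly squeezed toward linear."""
    h = 0.75 * r0 * np.sqrt(3.0) / 2.0 * 2.0  # flattened triangle height
    pos = np.array(
        [
            [-r0 / 2.0, 0.0, 0.0],
            [r0 / 2.0, 0.0, 0.0],
            [0.0, h / 2.0, 0.0],
        ]
    )
    return AtomicConfiguration(("A", "A", "A"), pos)


class GaussianWellsPES:
    """A 2D sum-of-Gaussian-wells surface carried by one movable pseudo-atom.

    The surface lives in the xy-plane of atom 0; two distant frozen anchor
    atoms give the configuration enough pairs for the inverse-distance
    kernel.  The z-coordinate of the movable atom does not enter the energy,
    so planar starts stay planar.
    """

    def __init__(
        self,
        wells: list[tuple[float, float, float, float]],
        confinement: float = 0.05,
    ):
        """wells: list of (depth eV, x0, y0, width); confinement in eV/A^2.

        The weak harmonic confinement about the origin keeps far-field
        forces finite, as in a bound molecule: without it the Gaussian tails
        create a zero-force plateau where any walker would satisfy a
        force-based convergence test.
        """
        if len(wells) < 2:
            raise ValueError("need at least two wells for a saddle")
        self.wells = [tuple(map(float, w)) for w in wells]
        self.confinement = float(confinement)
        self.name = "gaussian-wells-2d"

    def plane_energy(self, p: np.ndarray) -> float:
        x, y = p[0], p[1]
        e = 0.5 * self.confinement * (x * x + y * y)
        for depth, x0, y0, w in self.wells:
            e -= depth * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * w * w))
        return float(e)

    def plane_gradient(self, p: np.ndarray) -> np.ndarray:
        x, y = p[0], p[1]
        g = self.confinement * np.array([x, y])
        for depth, x0, y0, w in self.wells:
            e = depth * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * w * w))
            g[0] += e * (x - x0) / (w * w)
            g[1] += e * (y - y0) / (w * w)
        return g

    def evaluate(self, x: AtomicConfiguration) -> tuple[float, np.ndarray]:
        p = x.positions[0, :2]
        grad = np.zeros(x.n_dof)
        grad[0:2] = self.plane_gradient(p)
        grad[~x.dof_mask] = 0.0
        return self.plane_energy(p), grad

    def embed(self, xy: np.ndarray) -> AtomicConfiguration:
        """Embed a 2D point as movable atom 0 plus two frozen anchors."""
        pos = np.array(
            [
                [xy[0], xy[1], 0.0],
                [8.0, 0.0, 0.0],
                [0.0, 8.0, 0.0],
            ]
        )
        return AtomicConfiguration(
            ("X", "Y", "Y"), pos, frozen=np.array([False, True, True])
        )

    def solve_saddle(self, guess: np.ndarray) -> np.ndarray:
        """Newton's method on the analytic in-plane gradient (the oracle)."""
        sol = fsolve(self.plane_gradient, np.asarray(guess, float), full_output=False, xtol=1e-13)
        return np.asarray(sol, dtype=float)


def make_2d_gaussian_wells(
    wells: list[tuple[float, float, float, float]],
    saddle_guesses: list[np.ndarray] | None = None,
    confinement: float = 0.05,
) -> tuple[GaussianWellsPES, list[np.ndarray]]:
    """Build a 2D Gaussian-wells surface and numerically pre-solve saddles.

    Each guess is polished by Newton's method on the analytic gradient and
    kept if it is a genuine index-1 stationary point of the in-plane
    Hessian.
    """
    pes = GaussianWellsPES(wells, confinement=confinement)
    saddles: list[np.ndarray] = []
    if saddle_guesses is None:
        # midpoints between consecutive wells are natural ridge guesses
        saddle_guesses = [
            np.array([(wells[i][1] + wells[i + 1][1]) / 2.0, (wells[i][2] + wells[i + 1][2]) / 2.0])
            for i in range(len(wells) - 1)
        ]
    for guess in saddle_guesses:
        p = pes.solve_saddle(guess)
        if np.linalg.norm(pes.plane_gradient(p)) > 1e-8:
            continue
        h = _plane_hessian(pes, p)
        evals = np.linalg.eigvalsh(h)
        if evals[0] < -1e-10 and evals[1] > 1e-10:
            saddles.append(p)
    return pes, saddles


def _plane_hessian(pes: GaussianWellsPES, p: np.ndarray, h: float = 1e-6) -> np.ndarray:
    hess = np.zeros((2, 2))
    for k in range(2):
        dp = np.zeros(2)
        dp[k] = h
        hess[:, k] = (pes.plane_gradient(p + dp) - pes.plane_gradient(p - dp)) / (2 * h)
    return 0.5 * (hess + hess.T)


class QuadraticPES:
    """V(x) = 1/2 (x-x0)^T H (x-x0); exact testbed for mode following."""

    def __init__(self, hessian: np.ndarray, x0: np.ndarray):
        self.hessian = np.asarray(hessian, dtype=float)
        self.x0 = np.asarray(x0, dtype=float).reshape(-1)
        self.name = "quadratic"

    def evaluate(self, x: AtomicConfiguration) -> tuple[float, np.ndarray]:
        d = x.coords - self.x0
        g = self.hessian @ d
        g = g.copy()
        g[~x.dof_mask] = 0.0
        return float(0.5 * d @ self.hessian @ d), g


# ---------------------------------------------------------------------------
# synthetic configuration generators (seed-deterministic)
# ---------------------------------------------------------------------------


def perturb_configuration(
    x: AtomicConfiguration, magnitude: float, seed: int
) -> AtomicConfiguration:
    """Displace every movable atom by an isotropic Gaussian of given RMS size."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=magnitude, size=x.positions.shape) if magnitude > 0 else 0.0
    out = x.positions + noise
    if magnitude > 0:
        out[x.frozen] = x.positions[x.frozen]
    return x.with_positions(out)


def permute_within_types(x: AtomicConfiguration, seed: int) -> AtomicConfiguration:
    """Shuffle atom positions within each element type (labels unchanged)."""
    rng = np.random.default_rng(seed)
    pos = x.positions.copy()
    for el, idx in typed_partition(x, movable_only=False).items():
        perm = rng.permutation(len(idx))
        pos[idx] = x.positions[idx[perm]]
    return x.with_positions(pos)


def rigid_transform(
    x: AtomicConfiguration,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> AtomicConfiguration:
    """Apply a proper rotation about the centroid and then a translation."""
    pos = x.positions
    if rotation is not None:
        rotation = np.asarray(rotation, dtype=float)
        if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation matrix must be orthogonal")
        c = pos.mean(axis=0)
        pos = (pos - c) @ rotation.T + c
    if translation is not None:
        pos = pos + np.asarray(translation, dtype=float).reshape(1, 3)
    return x.with_positions(pos)


def random_rotation_matrix(seed: int) -> np.ndarray:
    """Haar-ish random proper rotation via QR of a Gaussian matrix."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_internal_direction(x: AtomicConfiguration, seed: int) -> np.ndarray:
    """A random unit 3N vector in the internal (purified, movable) subspace."""
    from .geometry import project_internal

    rng = np.random.default_rng(seed)
    v = rng.normal(size=x.n_dof)
    v[~x.dof_mask] = 0.0
    v = project_internal(v, x)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("degenerate internal direction; try another seed")
    return v / n


def relax_to_minimum(pes: Calculator, x: AtomicConfiguration, tol: float = 1e-8) -> AtomicConfiguration:
    """L-BFGS energy minimization respecting the frozen mask."""
    from scipy.optimize import minimize

    mask = x.dof_mask
    base = x.coords.copy()

    def unpack(z: np.ndarray) -> AtomicConfiguration:
        c = base.copy()
        c[mask] = z
        return x.with_positions(c.reshape(-1, 3))

    def fun(z: np.ndarray):
        e, g = pes.evaluate(unpack(z))
        return e, g[mask]

    res = minimize(fun, base[mask], jac=True, method="L-BFGS-B", tol=tol)
    return unpack(res.x)


def newton_stationary_point(
    pes: Calculator, x: AtomicConfiguration, max_iter: int = 60, tol: float = 1e-10
) -> AtomicConfiguration:
    """Newton's method on the gradient (the saddle oracle), movable DOFs only.

    Rigid-body zero modes are regularized by pseudo-inverting the Hessian
    with the near-null space cut off, so the iteration converges to the
    stationary point nearest the start without drifting the frame.
    """
    mask = x.dof_mask
    current = x.copy()
    for _ in range(max_iter):
        _, g = pes.evaluate(current)
        gm = g[mask]
        if np.linalg.norm(gm, ord=np.inf) < tol:
            break
        h = finite_difference_hessian(pes, current)[np.ix_(mask, mask)]
        step = -np.linalg.pinv(h, rcond=1e-8) @ gm
        full = np.zeros(x.n_dof)
        full[mask] = step
        current = current.displaced(full)
    return current


def finite_difference_hessian(
    pes: Calculator, x: AtomicConfiguration, step: float = 1e-4
) -> np.ndarray:
    """Central-difference Hessian of the PES over the movable 3N coordinates."""
    n = x.n_dof
    hess = np.zeros((n, n))
    mask = x.dof_mask
    coords = x.coords
    for k in np.flatnonzero(mask):
        dp = np.zeros(n)
        dp[k] = step
        _, gp = pes.evaluate(x.with_positions((coords + dp).reshape(-1, 3)))
        _, gm = pes.evaluate(x.with_positions((coords - dp).reshape(-1, 3)))
        hess[:, k] = (gp - gm) / (2 * step)
    return 0.5 * (hess + hess.T)
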