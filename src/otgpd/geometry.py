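"""Configuration-space geometry: distances, rigid-body modes, step purification.

The two trust metrics used by the surrogate-accelerated saddle search live
here.  The legacy metric is the maximum absolute log-ratio of interatomic
distances between two configurations of the same indexing; it is invariant
under rigid rotation and translation but *not* under permutation of
identical atoms.  The permutation-invariant replacement is an intensive
Earth Mover's distance: for each element type the atoms of the two
configurations are matched by an exact optimal assignment (Hungarian
algorithm), the mean matched displacement is taken per type, and the overall
distance is the maximum over types.  Averaging within a type makes the
measure intensive -- adding spectator atoms of a type does not dilute it.

Rigid-body machinery: an orthonormal basis of the external (translation +
infinitesimal-rotation) subspace is built by Gram-Schmidt, and proposed
translation steps are purified by projecting that subspace out, so the
surrogate only ever sees genuine internal deformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "AtomicConfiguration",
    "RigidBodyBasis",
    "typed_partition",
    "one_d_max_log",
    "per_type_mean_displacement",
    "intensive_emd",
    "rigid_body_basis",
    "project_internal",
]

#: Gram-Schmidt residual-norm tolerance below which a rotation generator is
#: considered linearly dependent (collinear geometries) and dropped.
GS_DROP_TOL = 1e-8


@dataclass
class AtomicConfiguration:
    """An element-typed Cartesian point set.

    Parameters
    ----------
    elements : sequence of str
        Element symbol per atom.
    positions : (N, 3) array
        Cartesian coordinates in Angstrom.
    frozen : (N,) bool array, optional
        Atoms excluded from the search degrees of freedom (fixture anchors).
        Frozen atoms are ignored by the configuration metrics and by the
        rigid-body basis.
    """

    elements: tuple[str, ...]
    positions: np.ndarray
    frozen: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.elements = tuple(self.elements)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.elements) != self.positions.shape[0]:
            raise ValueError(
                f"{len(self.elements)} element symbols for "
                f"{self.positions.shape[0]} position rows"
            )
        if self.frozen is None:
            self.frozen = np.zeros(len(self.elements), dtype=bool)
        else:
            self.frozen = np.asarray(self.frozen, dtype=bool)
            if self.frozen.shape != (len(self.elements),):
                raise ValueError("frozen mask length does not match atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_dof(self) -> int:
        return 3 * self.n_atoms

    @property
    def coords(self) -> np.ndarray:
        """Flattened 3N coordinate vector."""
        return self.positions.reshape(-1)

    @property
    def movable(self) -> np.ndarray:
        return ~self.frozen

    @property
    def dof_mask(self) -> np.ndarray:
        """Boolean mask of length 3N selecting movable degrees of freedom."""
        return np.repeat(self.movable, 3)

    def copy(self) -> "AtomicConfiguration":
        return AtomicConfiguration(
            self.elements, self.positions.copy(), self.frozen.copy()
        )

    def with_positions(self, positions: np.ndarray) -> "AtomicConfiguration":
        return AtomicConfiguration(
            self.elements,
            np.asarray(positions, dtype=float).reshape(-1, 3),
            self.frozen.copy(),
        )

    def displaced(self, step: np.ndarray) -> "AtomicConfiguration":
        """Return a copy displaced by a flattened 3N step vector."""
        step = np.asarray(step, dtype=float).reshape(self.n_atoms, 3)
        return self.with_positions(self.positions + step)

    def pair_distances(self) -> np.ndarray:
        """Condensed upper-triangle interatomic distances (pdist order)."""
        return pdist(self.positions)


@dataclass(frozen=True)
class RigidBodyBasis:
    """Orthonormal basis of the external (rigid-body) subspace.

    ``vectors`` has shape (rank, 3N): three exact translations plus up to
    three orthonormalized infinitesimal rotations about the centroid.  Rank
    is 5 for collinear geometries, 6 otherwise, 3 for a single atom, and 0
    when constraints (frozen atoms) break the rigid-body symmetry entirely.
    """

    vectors: np.ndarray
    rank: int


def _check_same_indexing(x1: AtomicConfiguration, x2: AtomicConfiguration) -> None:
    if x1.elements != x2.elements:
        raise ValueError("configurations must share the same ordered element list")


def _check_positive_distances(r: np.ndarray, who: str) -> None:
    if r.size and np.min(r) <= 0.0:
        raise ValueError(f"degenerate geometry: coincident atoms in {who}")


def typed_partition(x: AtomicConfiguration, movable_only: bool = True) -> dict[str, np.ndarray]:
    """Map element type -> array of atom indices of that type.

    Frozen atoms are excluded by default; the metrics operate on the search
    degrees of freedom only.
    """
    part: dict[str, list[int]] = {}
    for i, (el, mov) in enumerate(zip(x.elements, x.movable)):
        if movable_only and not mov:
            continue
        part.setdefault(el, []).append(i)
    return {el: np.array(idx, dtype=int) for el, idx in part.items()}


def one_d_max_log(x1: AtomicConfiguration, x2: AtomicConfiguration) -> float:
    """Maximum absolute log-ratio of interatomic distances.

    The legacy fixed-index trust metric: ``max_{i<j} |log(r_ij(x2)/r_ij(x1))|``.
    Rotation/translation invariant, but a swap of two identical atoms
    registers as a large distance.
    """
    _check_same_indexing(x1, x2)
    if x1.n_atoms < 2:
        raise ValueError("at least two atoms required for a distance metric")
    r1 = x1.pair_distances()
    r2 = x2.pair_distances()
    _check_positive_distances(r1, "first configuration")
    _check_positive_distances(r2, "second configuration")
    return float(np.max(np.abs(np.log(r2 / r1))))


def per_type_mean_displacement(
    x1: AtomicConfiguration, x2: AtomicConfiguration, element: str
) -> float:
    """Mean optimal-assignment displacement of the atoms of one element type.

    Solves the linear assignment problem between the type-``element`` atoms
    of the two configurations exactly and returns the matched Euclidean
    distances averaged over the type count.
    """
    p1 = typed_partition(x1)
    p2 = typed_partition(x2)
    if element not in p1 or element not in p2:
        raise ValueError(f"element type {element!r} absent from a configuration")
    i1, i2 = p1[element], p2[element]
    if len(i1) != len(i2):
        raise ValueError(
            f"unequal counts of element {element!r}: {len(i1)} vs {len(i2)}"
        )
    cost = cdist(x1.positions[i1], x2.positions[i2])
    row, col = linear_sum_assignment(cost)
    return float(cost[row, col].sum() / len(i1))


def intensive_emd(x1: AtomicConfiguration, x2: AtomicConfiguration) -> float:
    """Intensive Earth Mover's distance between two configurations.

    The maximum over element types of the per-type mean optimal-assignment
    displacement.  Permutation invariant within each type, symmetric, zero
    iff the configurations coincide up to within-type permutation.  Raw
    coordinates are compared (no rotational pre-alignment): along a search
    trajectory rigid motion has already been projected out of every step.
    """
    p1 = typed_partition(x1)
    p2 = typed_partition(x2)
    if {el: len(ix) for el, ix in p1.items()} != {el: len(ix) for el, ix in p2.items()}:
        raise ValueError("configurations must share the same element multiset")
    return max(per_type_mean_displacement(x1, x2, el) for el in p1)


def rigid_body_basis(x: AtomicConfiguration) -> RigidBodyBasis:
    """Orthonormal basis spanning overall translation and rotation.

    Three exact translation vectors, then the three infinitesimal-rotation
    generators about the geometric centroid (unit masses), Gram-Schmidt
    orthonormalized against the translations and each other.  Generators
    whose residual falls below ``GS_DROP_TOL`` (relative) are dropped, so a
    collinear geometry yields rank 5 and a single atom rank 3.  If any atom
    is frozen the rigid-body symmetry is broken by the constraint and the
    basis is empty (rank 0).
    """
    n = x.n_atoms
    if np.any(x.frozen):
        return RigidBodyBasis(np.zeros((0, 3 * n)), 0)

    basis: list[np.ndarray] = []
    for axis in range(3):
        u = np.zeros((n, 3))
        u[:, axis] = 1.0 / np.sqrt(n)
        basis.append(u.reshape(-1))

    centroid = x.positions.mean(axis=0)
    rel = x.positions - centroid
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        gen = np.cross(np.broadcast_to(e, rel.shape), rel).reshape(-1)
        norm0 = np.linalg.norm(gen)
        if norm0 < GS_DROP_TOL:
            continue  # e.g. single atom, or all atoms on this axis
        v = gen.copy()
        for u in basis:
            v -= np.dot(u, v) * u
        # second pass for numerical orthogonality
        for u in basis:
            v -= np.dot(u, v) * u
        res = np.linalg.norm(v)
        if res < GS_DROP_TOL * norm0:
            continue  # generator lies in the span already (collinear axis)
        basis.append(v / res)

    vecs = np.array(basis)
    return RigidBodyBasis(vecs, vecs.shape[0])


def project_internal(
    step: np.ndarray,
    x: AtomicConfiguration,
    basis: RigidBodyBasis | None = None,
) -> np.ndarray:
    """Remove the rigid-body component from a flattened 3N step vector.

    Returns ``s - sum_k (s . u_k) u_k`` over the external-mode basis of
    ``x``.  Idempotent and linear; the purified step has zero overlap with
    every basis vector.
    """
    step = np.asarray(step, dtype=float).reshape(-1)
    if step.shape[0] != x.n_dof:
        raise ValueError(f"step length {step.shape[0]} != 3N = {x.n_dof}")
    if basis is None:
        basis = rigid_body_basis(x)
    if basis.rank == 0:
        return step.copy()
    overlaps = basis.vectors @ step
    return step - basis.vectors.T @ overlaps
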