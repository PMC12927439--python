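"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from otgpd import AtomicConfiguration, KernelParams, PairTypeMap
from otgpd.geometry import typed_partition
from otgpd.surfaces import (
    GaussianWellsPES,
    MorseClusterPES,
    make_2d_gaussian_wells,
    make_morse_cluster,
    relax_to_minimum,
)

# -- independent brute-force oracles ----------------------------------------


def brute_force_per_type(x1, x2, element: str) -> float:
    """Mean matched displacement by exhaustive enumeration of permutations."""
    p1 = typed_partition(x1)[element]
    p2 = typed_partition(x2)[element]
    best = np.inf
    for perm in itertools.permutations(range(len(p2))):
        tot = sum(
            np.linalg.norm(x1.positions[p1[k]] - x2.positions[p2[perm[k]]])
            for k in range(len(p1))
        )
        best = min(best, tot)
    return best / len(p1)


def brute_force_emd(x1, x2) -> float:
    return max(brute_force_per_type(x1, x2, el) for el in typed_partition(x1))


def brute_force_max_log(x1, x2) -> float:
    """Direct pair enumeration of the fixed-index log-ratio metric."""
    n = x1.n_atoms
    worst = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            r1 = np.linalg.norm(x1.positions[i] - x1.positions[j])
            r2 = np.linalg.norm(x2.positions[i] - x2.positions[j])
            worst = max(worst, abs(np.log(r2 / r1)))
    return worst


def fd_gradient(pes, x, step: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a calculator's energy."""
    g = np.zeros(x.n_dof)
    c = x.coords
    for k in range(x.n_dof):
        d = np.zeros(x.n_dof)
        d[k] = step
        ep = pes.evaluate(x.with_positions((c + d).reshape(-1, 3)))[0]
        em = pes.evaluate(x.with_positions((c - d).reshape(-1, 3)))[0]
        g[k] = (ep - em) / (2 * step)
    return g


# -- geometries ---------------------------------------------------------------


@pytest.fixture
def water_like() -> AtomicConfiguration:
    """Asymmetric bent triatomic with two like atoms (H) and one O."""
    return AtomicConfiguration(
        ("O", "H", "H"),
        np.array([[0.0, 0.0, 0.0], [0.96, 0.05, 0.0], [-0.42, 1.33, 0.15]]),
    )


@pytest.fixture
def mixed_cluster() -> AtomicConfiguration:
    """Five atoms, two element types, generic positions."""
    rng = np.random.default_rng(7)
    return AtomicConfiguration(
        ("A", "A", "A", "B", "B"), 1.8 * rng.normal(size=(5, 3))
    )


@pytest.fixture(scope="session")
def soft_morse():
    """Soft Morse 4-atom cluster relaxed to its tetrahedral minimum."""
    pes, start = make_morse_cluster(4)
    return pes, relax_to_minimum(pes, start)


@pytest.fixture(scope="session")
def stiff_wells():
    """Asymmetric 2D double well with molecular-scale curvatures."""
    pes, saddles = make_2d_gaussian_wells(
        [(4.0, -0.6, 0.0, 0.45), (3.0, 0.7, 0.25, 0.4)]
    )
    assert len(saddles) == 1
    return pes, saddles


@pytest.fixture(scope="session")
def symmetric_wells():
    """Mirror-symmetric 2D double well; the saddle sits on the midplane."""
    pes, saddles = make_2d_gaussian_wells(
        [(3.5, -0.8, 0.0, 0.42), (3.5, 0.8, 0.0, 0.42)]
    )
    assert len(saddles) == 1
    return pes, saddles


@pytest.fixture
def small_kernel_setup():
    """Diatomic + params with a single pair type, for kernel arithmetic."""
    x = AtomicConfiguration(("A", "B"), [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    pm = PairTypeMap.from_elements(x.elements)
    params = KernelParams(sigma_c2=0.0, sigma_f2=1.0, length_scales=np.ones(1))
    return x, pm, params
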