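"""Configuration metrics, rigid-body basis, and step purification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otgpd import (
    AtomicConfiguration,
    intensive_emd,
    one_d_max_log,
    per_type_mean_displacement,
    project_internal,
    rigid_body_basis,
)
from otgpd.surfaces import (
    permute_within_types,
    perturb_configuration,
    random_rotation_matrix,
    rigid_transform,
)

from conftest import brute_force_emd, brute_force_max_log, brute_force_per_type


class TestOneDMaxLog:
    def test_identity_is_zero(self, water_like):
        assert one_d_max_log(water_like, water_like) == 0.0

    def test_uniform_scaling_gives_log_factor(self, water_like):
        scaled = water_like.with_positions(2.0 * water_like.positions)
        assert one_d_max_log(water_like, scaled) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_like_atom_swap_registers_large_distance(self, water_like):
        """Swapping the two H atoms of a bent asymmetric triatomic is a pure
        relabeling, yet the fixed-index metric sees a nonzero distance."""
        pos = water_like.positions.copy()
        pos[[1, 2]] = pos[[2, 1]]
        swapped = water_like.with_positions(pos)
        d = one_d_max_log(water_like, swapped)
        assert d > 0.1
        assert d == pytest.approx(brute_force_max_log(water_like, swapped), abs=1e-12)
        # the assignment-based metric correctly sees the same structure
        assert intensive_emd(water_like, swapped) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_arguments(self, water_like):
        other = perturb_configuration(water_like, 0.2, 5)
        assert one_d_max_log(water_like, other) == pytest.approx(
            one_d_max_log(other, water_like), abs=1e-14
        )

    def test_rigid_motion_invariance(self, mixed_cluster):
        moved = rigid_transform(
            mixed_cluster, rotation=random_rotation_matrix(3), translation=[1.0, -2.0, 0.5]
        )
        ref = perturb_configuration(mixed_cluster, 0.3, 11)
        assert one_d_max_log(moved, ref) == pytest.approx(
            one_d_max_log(mixed_cluster, ref), abs=1e-10
        )

    def test_mismatched_elements_rejected(self, water_like):
        other = AtomicConfiguration(("O", "H", "D"), water_like.positions)
        with pytest.raises(ValueError):
            one_d_max_log(water_like, other)


class TestPerTypeDisplacement:
    def test_identity_zero(self, mixed_cluster):
        assert per_type_mean_displacement(mixed_cluster, mixed_cluster, "A") == 0.0

    def test_uniform_translation(self, mixed_cluster):
        moved = mixed_cluster.with_positions(mixed_cluster.positions + [0.5, 0.0, 0.0])
        assert per_type_mean_displacement(mixed_cluster, moved, "A") == pytest.approx(0.5)
        assert per_type_mean_displacement(mixed_cluster, moved, "B") == pytest.approx(0.5)

    def test_label_exchange_is_free(self, mixed_cluster):
        pos = mixed_cluster.positions.copy()
        pos[[0, 1]] = pos[[1, 0]]  # both type A
        swapped = mixed_cluster.with_positions(pos)
        assert per_type_mean_displacement(mixed_cluster, swapped, "A") == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_brute_force(self, mixed_cluster):
        for seed in range(8):
            other = perturb_configuration(
                permute_within_types(mixed_cluster, seed), 0.4, seed
            )
            for el in ("A", "B"):
                assert per_type_mean_displacement(
                    mixed_cluster, other, el
                ) == pytest.approx(brute_force_per_type(mixed_cluster, other, el), abs=1e-12)

    def test_absent_type_rejected(self, mixed_cluster):
        with pytest.raises(ValueError):
            per_type_mean_displacement(mixed_cluster, mixed_cluster, "Q")


class TestIntensiveEMD:
    def test_within_type_relabeling_is_identity(self, mixed_cluster):
        for seed in range(5):
            relabeled = permute_within_types(mixed_cluster, seed)
            assert intensive_emd(mixed_cluster, relabeled) == pytest.approx(0.0, abs=1e-12)

    def test_max_over_types(self, mixed_cluster):
        pos = mixed_cluster.positions.copy()
        part = {"A": [0, 1, 2], "B": [3, 4]}
        pos[part["A"]] += [0.2, 0.0, 0.0]
        pos[part["B"]] += [0.0, 0.5, 0.0]
        moved = mixed_cluster.with_positions(pos)
        assert intensive_emd(mixed_cluster, moved) == pytest.approx(0.5, abs=1e-12)

    def test_spectator_atoms_do_not_dilute(self, mixed_cluster):
        moved = mixed_cluster.with_positions(
            mixed_cluster.positions + np.array([0.3, 0.0, 0.0])
        )
        d0 = intensive_emd(mixed_cluster, moved)
        # duplicate a resting spectator pair far away, same in both frames
        extra = np.array([[9.0, 9.0, 9.0], [9.0, 9.0, 11.0]])
        big1 = AtomicConfiguration(
            mixed_cluster.elements + ("A", "B"), np.vstack([mixed_cluster.positions, extra])
        )
        big2 = AtomicConfiguration(
            mixed_cluster.elements + ("A", "B"), np.vstack([moved.positions, extra])
        )
        d1 = intensive_emd(big1, big2)
        # spectators at rest lower the per-type mean only through averaging;
        # the brute-force oracle confirms the exact value either way
        assert d1 == pytest.approx(brute_force_emd(big1, big2), abs=1e-12)
        assert d0 == pytest.approx(0.3, abs=1e-12)

    def test_element_multiset_mismatch_rejected(self, mixed_cluster):
        other = AtomicConfiguration(
            ("A", "A", "B", "B", "B"), mixed_cluster.positions
        )
        with pytest.raises(ValueError):
            intensive_emd(mixed_cluster, other)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), mag=st.floats(0.0, 1.0))
    def test_symmetric_nonnegative(self, seed, mag):
        rng = np.random.default_rng(7)
        base = AtomicConfiguration(
            ("A", "A", "A", "B", "B"), 1.8 * rng.normal(size=(5, 3))
        )
        other = perturb_configuration(base, mag, seed)
        d12 = intensive_emd(base, other)
        assert d12 >= 0.0
        assert d12 == pytest.approx(intensive_emd(other, base), abs=1e-12)

    def test_hungarian_equals_brute_force_on_random_pairs(self, mixed_cluster):
        rng = np.random.default_rng(0)
        for seed in range(20):
            a = permute_within_types(perturb_configuration(mixed_cluster, 0.6, seed), seed)
            b = perturb_configuration(mixed_cluster, float(rng.uniform(0, 0.8)), 500 + seed)
            assert intensive_emd(a, b) == pytest.approx(brute_force_emd(a, b), abs=1e-12)


class TestRigidBodyBasis:
    def test_orthonormality(self, mixed_cluster):
        b = rigid_body_basis(mixed_cluster)
        gram = b.vectors @ b.vectors.T
        assert np.abs(gram - np.eye(b.rank)).max() < 1e-10

    def test_collinear_rank_five(self):
        x = AtomicConfiguration(
            ("A", "A", "A"), [[0.0, 0.0, 0.0], [0.0, 0.0, 1.1], [0.0, 0.0, 2.5]]
        )
        assert rigid_body_basis(x).rank == 5

    def test_nonplanar_rank_six(self, mixed_cluster):
        assert rigid_body_basis(mixed_cluster).rank == 6

    def test_single_atom_rank_three(self):
        x = AtomicConfiguration(("A",), [[0.0, 0.0, 0.0]])
        assert rigid_body_basis(x).rank == 3

    def test_spans_translations_exactly(self, mixed_cluster):
        b = rigid_body_basis(mixed_cluster)
        t = np.tile([1.0, 0.0, 0.0], mixed_cluster.n_atoms)
        residual = t - b.vectors.T @ (b.vectors @ t)
        assert np.linalg.norm(residual) < 1e-12

    def test_axis_rotation_generator_in_span(self):
        """An infinitesimal rotation about the centroid must be annihilated."""
        x = AtomicConfiguration(
            ("A", "A", "A", "A"),
            [[0, 0, 0], [1.5, 0, 0], [0.2, 1.4, 0], [0.4, 0.5, 1.3]],
        )
        b = rigid_body_basis(x)
        rel = x.positions - x.positions.mean(axis=0)
        gen = np.cross(np.broadcast_to([0.0, 0.0, 1.0], rel.shape), rel).reshape(-1)
        assert np.linalg.norm(project_internal(gen, x, b)) < 1e-9 * np.linalg.norm(gen)


class TestProjectInternal:
    def test_translation_annihilated(self, mixed_cluster):
        s = np.tile([0.3, -0.2, 0.7], mixed_cluster.n_atoms)
        assert np.linalg.norm(project_internal(s, mixed_cluster)) < 1e-9

    def test_pythagoras(self, mixed_cluster):
        b = rigid_body_basis(mixed_cluster)
        rng = np.random.default_rng(42)
        for _ in range(50):
            s = rng.normal(size=mixed_cluster.n_dof)
            si = project_internal(s, mixed_cluster, b)
            ext = np.sum((b.vectors @ s) ** 2)
            assert np.dot(s, s) == pytest.approx(np.dot(si, si) + ext, rel=1e-9)
            assert np.abs(b.vectors @ si).max() < 1e-9

    def test_idempotent_and_linear(self, mixed_cluster):
        rng = np.random.default_rng(1)
        s1 = rng.normal(size=mixed_cluster.n_dof)
        s2 = rng.normal(size=mixed_cluster.n_dof)
        p1 = project_internal(s1, mixed_cluster)
        assert np.allclose(project_internal(p1, mixed_cluster), p1, atol=1e-12)
        lhs = project_internal(2.0 * s1 - 0.5 * s2, mixed_cluster)
        assert np.allclose(lhs, 2.0 * p1 - 0.5 * project_internal(s2, mixed_cluster), atol=1e-12)

    def test_frozen_atoms_disable_external_modes(self, stiff_wells):
        pes, _ = stiff_wells
        x = pes.embed(np.array([0.0, 0.0]))
        s = np.arange(x.n_dof, dtype=float)
        assert np.allclose(project_internal(s, x), s)
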