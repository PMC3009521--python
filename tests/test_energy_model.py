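"""Closed-form checks and oracle tests for the pairwise energy model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from penkit import (COULOMB_CONSTANT, ForceFieldParams, compute_energy_matrix,
                    coulomb_pair, generate_toy_ensemble, lj_pair,
                    residue_pair_energy)
from penkit.residues import StructureEnsemble


class TestLJPair:
    def test_zero_crossing_at_sigma(self):
        assert lj_pair(0.35, 0.35, 1.2, 0.35, 1.2) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_is_minus_epsilon(self):
        r = 2 ** (1 / 6) * 0.35
        assert lj_pair(r, 0.35, 0.9, 0.35, 0.9) == pytest.approx(-0.9, rel=1e-12)

    def test_asymptotic_decay(self):
        assert abs(lj_pair(3.5, 0.35, 1.0, 0.35, 1.0)) < 1e-4

    def test_combining_rules(self):
        # Lorentz-Berthelot: arithmetic sigma; geometric: geometric sigma
        si, sj = 0.3, 0.4
        lb = lj_pair((si + sj) / 2, si, 1.0, sj, 1.0, "lorentz-berthelot")
        geo = lj_pair(math.sqrt(si * sj), si, 1.0, sj, 1.0, "geometric")
        assert lb == pytest.approx(0.0, abs=1e-12)
        assert geo == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            lj_pair(0.0, 0.3, 1.0, 0.3, 1.0)


class TestCoulombPair:
    def test_unit_charges_at_one_nm(self):
        assert coulomb_pair(1.0, 1.0, 1.0) == pytest.approx(138.935485, rel=1e-12)

    def test_zero_charge_gives_zero(self):
        assert coulomb_pair(0.7, 0.0, 1.0) == 0.0

    def test_opposite_charges_half_nm(self):
        # k * (+1)(-1) / 0.5 computed by hand from the constant
        assert coulomb_pair(0.5, 1.0, -1.0) == pytest.approx(-277.87097, rel=1e-6)

    def test_dielectric_scales_inversely(self):
        params = ForceFieldParams(atom_params={}, relative_dielectric=4.0)
        assert coulomb_pair(1.0, 1.0, 1.0, params) == pytest.approx(
            COULOMB_CONSTANT / 4.0, rel=1e-12)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            coulomb_pair(-0.1, 1.0, 1.0)


def _two_residue_ensemble(coords_i, coords_j, names_i, names_j):
    n_i = len(names_i)
    frames = [np.vstack([coords_i, coords_j]).astype(float)]
    from penkit import ResidueID
    return StructureEnsemble(
        residues=[ResidueID("A", 1, None, "GLY"), ResidueID("A", 3, None, "GLY")],
        atom_names=[list(names_i), list(names_j)],
        frames=frames)


class TestResiduePairEnergy:
    def _params(self, table):
        return ForceFieldParams(atom_params=table)

    def test_brute_force_atom_pair_sum(self):
        """3-atom vs 2-atom residues equal an explicit double loop."""
        rng = np.random.default_rng(5)
        xyz_i = rng.random((3, 3))
        xyz_j = rng.random((2, 3)) + 2.0
        table = {("GLY", "N"): (-0.5, 0.325, 0.711),
                 ("GLY", "CA"): (0.2, 0.35, 0.276),
                 ("GLY", "C"): (0.3, 0.375, 0.439)}
        names_i, names_j = ["N", "CA", "C"], ["N", "CA"]
        ens = _two_residue_ensemble(xyz_i, xyz_j, names_i, names_j)
        params = self._params(table)
        lj, coul = residue_pair_energy(ens, 0, 0, 1, params)
        exp_lj = exp_c = 0.0
        for a, na in enumerate(names_i):
            for b, nb in enumerate(names_j):
                qa, sa, ea = table[("GLY", na)]
                qb, sb, eb = table[("GLY", nb)]
                r = float(np.linalg.norm(xyz_i[a] - xyz_j[b]))
                exp_lj += lj_pair(r, sa, ea, sb, eb)
                exp_c += coulomb_pair(r, qa, qb)
        assert lj == pytest.approx(exp_lj, rel=1e-12)
        assert coul == pytest.approx(exp_c, rel=1e-12)

    def test_neutral_atoms_at_sigma_give_zero(self):
        table = {("GLY", "CA"): (0.0, 0.35, 0.276)}
        ens = _two_residue_ensemble([[0, 0, 0]], [[0.35, 0, 0]], ["CA"], ["CA"])
        lj, coul = residue_pair_energy(ens, 0, 0, 1, self._params(table))
        assert lj == pytest.approx(0.0, abs=1e-12)
        assert coul == 0.0

    def test_pure_coulomb_when_epsilon_zero(self):
        table = {("GLY", "CA"): (1.0, 0.35, 0.0)}
        ens = _two_residue_ensemble([[0, 0, 0]], [[1.0, 0, 0]], ["CA"], ["CA"])
        lj, coul = residue_pair_energy(ens, 0, 0, 1, self._params(table))
        assert lj == 0.0
        assert coul == pytest.approx(138.935485, rel=1e-12)

    def test_unparameterized_atoms_contribute_zero(self):
        table = {("GLY", "CA"): (1.0, 0.35, 0.0)}
        ens = _two_residue_ensemble([[0, 0, 0]], [[1.0, 0, 0]], ["CA"], ["XX"])
        lj, coul = residue_pair_energy(ens, 0, 0, 1, self._params(table))
        assert (lj, coul) == (0.0, 0.0)

    def test_self_interaction_rejected(self):
        ens = generate_toy_ensemble(4, 1, 0.0, seed=0)
        with pytest.raises(ValueError):
            residue_pair_energy(ens, 0, 2, 2)

    def test_distance_cutoff_drops_far_pairs(self):
        table = {("GLY", "CA"): (1.0, 0.35, 0.0)}
        ens = _two_residue_ensemble([[0, 0, 0]], [[1.0, 0, 0]], ["CA"], ["CA"])
        params = ForceFieldParams(atom_params=table, distance_cutoff=0.5)
        assert residue_pair_energy(ens, 0, 0, 1, params) == (0.0, 0.0)


class TestEnergyMatrixContracts:
    def test_single_frame_equals_pair_energy(self, toy_ensemble):
        one = toy_ensemble.select_frames([0])
        m = compute_energy_matrix(one, exclude_adjacent=False)
        lj, coul = residue_pair_energy(one, 0, 0, 5)
        assert m.lj[0, 5] == pytest.approx(lj, rel=1e-12)
        assert m.coulomb[0, 5] == pytest.approx(coul, rel=1e-12)

    def test_frame_averaging(self, toy_ensemble):
        """Ensemble mean equals the mean of single-frame matrices."""
        m = compute_energy_matrix(toy_ensemble)
        singles = [compute_energy_matrix(toy_ensemble.select_frames([f])).total
                   for f in range(toy_ensemble.n_frames)]
        np.testing.assert_allclose(m.total, np.mean(singles, axis=0), atol=1e-9)

    def test_total_is_lj_plus_coulomb_bitwise(self, toy_ensemble):
        m = compute_energy_matrix(toy_ensemble)
        assert np.array_equal(m.total, m.lj + m.coulomb)

    def test_frame_order_invariance(self, toy_ensemble):
        m1 = compute_energy_matrix(toy_ensemble)
        m2 = compute_energy_matrix(toy_ensemble.select_frames([2, 0, 1]))
        np.testing.assert_allclose(m1.total, m2.total, atol=1e-9)

    def test_rigid_motion_invariance(self, toy_ensemble):
        theta = 0.83
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0],
                        [0, 0, 1.0]])
        moved = StructureEnsemble(
            residues=toy_ensemble.residues,
            atom_names=toy_ensemble.atom_names,
            frames=[f @ rot.T + np.array([1.0, -2.0, 0.5])
                    for f in toy_ensemble.frames])
        m1 = compute_energy_matrix(toy_ensemble)
        m2 = compute_energy_matrix(moved)
        np.testing.assert_allclose(m1.total, m2.total, atol=1e-9)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=0.1, max_value=3.0))
    def test_charge_scaling_is_quadratic(self, c):
        ens = generate_toy_ensemble(5, 1, 0.0, seed=3)
        base = ForceFieldParams.default()
        scaled = ForceFieldParams(
            atom_params={k: (q * c, s, e)
                         for k, (q, s, e) in base.atom_params.items()},
            combining_rule=base.combining_rule)
        m1 = compute_energy_matrix(ens, base)
        m2 = compute_energy_matrix(ens, scaled)
        np.testing.assert_allclose(m2.coulomb, m1.coulomb * c * c, atol=1e-9)
        np.testing.assert_allclose(m2.lj, m1.lj, atol=1e-12)

    def test_symmetry_and_zero_diagonal(self, toy_ensemble):
        m = compute_energy_matrix(toy_ensemble)
        np.testing.assert_array_equal(m.total, m.total.T)
        np.testing.assert_array_equal(np.diag(m.total), 0.0)

    def test_adjacent_exclusion_masks_neighbours(self, toy_ensemble):
        m = compute_energy_matrix(toy_ensemble, exclude_adjacent=True)
        assert m.excluded[0, 1] and m.excluded[1, 0]
        assert m.total[0, 1] == 0.0
        m2 = compute_energy_matrix(toy_ensemble, exclude_adjacent=False)
        assert m2.total[0, 1] != 0.0


class TestForceFieldTable:
    def test_bundled_table_loads_all_standard_residues(self):
        params = ForceFieldParams.default()
        residues = {r for r, _ in params.atom_params}
        assert len(residues) == 20
        assert params.lookup("ALA", "CA") is not None

    def test_protonation_variants_resolve(self):
        params = ForceFieldParams.default()
        assert params.lookup("HSD", "CA") == params.lookup("HIS", "CA")

    def test_charges_sum_to_formal_charge(self):
        params = ForceFieldParams.default()
        formal = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}
        sums = {}
        for (res, _), (q, _, _) in params.atom_params.items():
            sums[res] = sums.get(res, 0.0) + q
        for res, total in sums.items():
            assert total == pytest.approx(formal.get(res, 0), abs=1e-9), res
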