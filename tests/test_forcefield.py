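import numpy as np
import pytest

import flexref.forcefield as ff
from flexref.geometry import rotation_about_axis
from flexref.synthetic import ToySystemSpec, make_target, _build_chain, HELIX


def _dipeptide():
    spec = ToySystemSpec(n_residues=5, seed=0, architecture="extended")
    model = make_target(spec)
    keep = model.res_num <= 2
    idx = np.flatnonzero(keep)
    model.serial = model.serial[idx]
    model.name = [model.name[i] for i in idx]
    model.element = [model.element[i] for i in idx]
    model.res_name = [model.res_name[i] for i in idx]
    model.res_num = model.res_num[idx]
    model.chain = [model.chain[i] for i in idx]
    model.icode = [model.icode[i] for i in idx]
    model.altloc = [model.altloc[i] for i in idx]
    model.xyz = model.xyz[idx]
    model.occ = model.occ[idx]
    model.b_iso = model.b_iso[idx]
    return model


class TestTopology:
    def test_dipeptide_bond_count(self):
        """Two ALA (N, CA, C, O, CB) -> 4 template bonds each + 1 peptide bond."""
        model = _dipeptide()
        topo = ff.build_topology(model)
        assert len(topo.bonds) == 4 + 4 + 1

    def test_glycine_has_no_chirality_improper(self):
        model = _dipeptide()
        # strip CB from residue 2 and rename it GLY
        keep = ~((model.res_num == 2) & (np.array(model.name) == "CB"))
        idx = np.flatnonzero(keep)
        model.name = [model.name[i] for i in idx]
        model.element = [model.element[i] for i in idx]
        model.res_name = ["GLY" if model.res_num[i] == 2 else "ALA" for i in idx]
        model.res_num = model.res_num[idx]
        model.chain = [model.chain[i] for i in idx]
        model.icode = [model.icode[i] for i in idx]
        model.altloc = [model.altloc[i] for i in idx]
        model.serial = model.serial[idx]
        model.xyz = model.xyz[idx]
        model.occ = model.occ[idx]
        model.b_iso = model.b_iso[idx]
        topo = ff.build_topology(model)
        # only residue 1 contributes a CA chirality improper
        chirality = [q for q in topo.impropers if model.name[q[0]] == "CA"]
        assert len(chirality) == 1

    def test_template_geometry_near_zero_energy(self):
        model = _dipeptide()
        topo = ff.build_topology(model)
        e, _ = ff.compute_energy_forces(model.xyz, topo)
        assert e < 2.0   # residual is nonbonded noise only

    def test_unknown_residue_restrained_rigid(self):
        model = _dipeptide()
        model.res_name = ["ZZZZ"] * model.n_atoms
        with pytest.warns(UserWarning, match="unknown residue"):
            topo = ff.build_topology(model)
        e0, _ = ff.compute_energy_forces(model.xyz, topo)
        assert e0 < 1.0
        stretched = model.xyz.copy()
        stretched[0] += [1.0, 0, 0]
        e1, _ = ff.compute_energy_forces(stretched, topo)
        assert e1 > 10.0


class TestSecondaryStructure:
    def test_ideal_helix_assigned_and_relaxed(self, toy_target):
        rs = ff.assign_secondary_structure(toy_target, mode="geometric")
        helix_res = [k for k, v in rs.assignments.items() if v == "H"]
        # both 15-residue arms assigned (terminal residues lack phi or psi)
        assert len(helix_res) >= 24
        topo = ff.build_topology(toy_target)
        _, _, comps = ff.compute_energy_forces(toy_target.xyz, topo, rs, detail=True)
        assert comps["ss_dihedral"] < 2.0
        assert comps["hbond"] < 1.0

    def test_loop_residues_unrestrained(self, toy_target, toy_spec):
        rs = ff.assign_secondary_structure(toy_target, mode="geometric")
        _, hinge = toy_spec.phi_psi_sequence()
        hinge_key = ("A", hinge + 1, "")
        assert hinge_key not in rs.assignments

    def test_annotation_mode_validates_residues(self, mini_target):
        with pytest.raises(ValueError, match="absent"):
            ff.assign_secondary_structure(mini_target, mode="from-annotation",
                                          annotation={("Z", 99, ""): "H"})
        rs = ff.assign_secondary_structure(mini_target, mode="from-annotation",
                                           annotation={("A", 3, ""): "H"})
        assert rs.assignments == {("A", 3, ""): "H"}


class TestEnergyForces:
    def test_stretched_bond_harmonic_law(self):
        model = _dipeptide()
        topo = ff.build_topology(model)
        # stretch the first bond along its axis by moving one terminal atom
        i, j = topo.bonds[0]
        delta = 0.2
        xyz = model.xyz.copy()
        direction = (xyz[j] - xyz[i]) / np.linalg.norm(xyz[j] - xyz[i])
        only = ff.Topology(
            n_atoms=topo.n_atoms,
            bonds=topo.bonds[:1], bond_r0=topo.bond_r0[:1], bond_k=topo.bond_k[:1],
            angles=np.zeros((0, 3), int), angle_theta0=np.zeros(0), angle_k=np.zeros(0),
            torsions=np.zeros((0, 4), int), torsion_target=np.zeros(0), torsion_k=np.zeros(0),
            impropers=np.zeros((0, 4), int), improper_target=np.zeros(0), improper_k=np.zeros(0),
            radii=topo.radii, eps=np.zeros(topo.n_atoms), masses=topo.masses)
        xyz[j] += direction * delta
        e, f = ff.compute_energy_forces(xyz, only)
        k = topo.bond_k[0]
        assert e == pytest.approx(k * delta**2, rel=1e-9)
        assert np.linalg.norm(f[j]) == pytest.approx(2 * k * delta, rel=1e-9)

    def test_zero_force_at_equilibrium(self, toy_target):
        topo = ff.build_topology(toy_target)
        # bonded terms only: equilibrium is the built geometry
        topo.eps = np.zeros(toy_target.n_atoms)
        _, f = ff.compute_energy_forces(toy_target.xyz, topo)
        # residual reflects sub-millidegree rounding of the link-angle
        # constants, i.e. zero for practical purposes
        assert np.abs(f).max() < 1e-3

    def test_analytic_forces_match_finite_difference(self, mini_target):
        topo = ff.build_topology(mini_target)
        rs = ff.assign_secondary_structure(mini_target, mode="geometric")
        rng = np.random.default_rng(0)
        xyz = mini_target.xyz + rng.normal(0, 0.15, mini_target.xyz.shape)
        _, f = ff.compute_energy_forces(xyz, topo, rs)
        h = 1e-5
        num = np.zeros_like(f)
        for i in range(len(xyz)):
            for d in range(3):
                xp, xm = xyz.copy(), xyz.copy()
                xp[i, d] += h
                xm[i, d] -= h
                ep, _ = ff.compute_energy_forces(xp, topo, rs)
                em, _ = ff.compute_energy_forces(xm, topo, rs)
                num[i, d] = -(ep - em) / (2 * h)
        assert np.abs(f - num).max() / np.abs(num).max() < 1e-4

    def test_newtons_third_law(self, mini_target):
        topo = ff.build_topology(mini_target)
        rs = ff.assign_secondary_structure(mini_target, mode="geometric")
        rng = np.random.default_rng(1)
        xyz = mini_target.xyz + rng.normal(0, 0.3, mini_target.xyz.shape)
        _, f = ff.compute_energy_forces(xyz, topo, rs)
        assert np.abs(f.sum(axis=0)).max() < 1e-8

    def test_rigid_motion_invariance(self, mini_target):
        topo = ff.build_topology(mini_target)
        rs = ff.assign_secondary_structure(mini_target, mode="geometric")
        rng = np.random.default_rng(2)
        xyz = mini_target.xyz + rng.normal(0, 0.2, mini_target.xyz.shape)
        e0, _ = ff.compute_energy_forces(xyz, topo, rs)
        R = rotation_about_axis([1.0, -2.0, 0.5], 1.1)
        e1, _ = ff.compute_energy_forces(xyz @ R.T + np.array([3.0, -7.0, 2.0]), topo, rs)
        assert e1 == pytest.approx(e0, abs=1e-8)

    def test_overlapping_atoms_capped(self):
        model = _dipeptide()
        topo = ff.build_topology(model)
        xyz = model.xyz.copy()
        # move a nonbonded pair on top of each other
        xyz[-1] = xyz[0] + 1e-4
        e, f = ff.compute_energy_forces(xyz, topo)
        assert np.all(np.isfinite(f))
        assert np.all(np.isfinite(e))


class TestNCS:
    def _two_copy_model(self):
        seq = [HELIX] * 6
        res = _build_chain(seq)
        xyz = np.array([a[nm] for a in res for nm in ("N", "CA", "C", "O", "CB")])
        return xyz

    def test_identical_copies_zero(self):
        xyz1 = self._two_copy_model()
        coords = np.vstack([xyz1, xyz1 + np.array([20.0, 0, 0])])
        n = len(xyz1)
        groups = [[np.arange(n), np.arange(n, 2 * n)]]
        e, f = ff.ncs_restraint_forces(coords, groups, k_ncs=5.0)
        assert e == pytest.approx(0.0, abs=1e-10)
        assert np.abs(f).max() < 1e-8

    def test_rigid_rotation_costs_nothing(self):
        xyz1 = self._two_copy_model()
        R = rotation_about_axis([0.0, 0.0, 1.0], 0.9)
        coords = np.vstack([xyz1, xyz1 @ R.T + np.array([15.0, 5.0, 0.0])])
        n = len(xyz1)
        e, _ = ff.ncs_restraint_forces(coords, [[np.arange(n), np.arange(n, 2 * n)]], 5.0)
        assert e == pytest.approx(0.0, abs=1e-8)

    def test_displaced_atom_restoring_force(self):
        xyz1 = self._two_copy_model()
        coords = np.vstack([xyz1, xyz1 + np.array([20.0, 0, 0])])
        n = len(xyz1)
        coords[n + 3] += np.array([0.8, 0.0, 0.0])
        groups = [[np.arange(n), np.arange(n, 2 * n)]]
        e, f = ff.ncs_restraint_forces(coords, groups, k_ncs=5.0)
        assert e > 0
        assert f[n + 3, 0] < 0      # pushes back toward consensus
        # finite-difference check at the displaced atom
        h = 1e-5
        for d in range(3):
            cp, cm = coords.copy(), coords.copy()
            cp[n + 3, d] += h
            cm[n + 3, d] -= h
            ep, _ = ff.ncs_restraint_forces(cp, groups, 5.0)
            em, _ = ff.ncs_restraint_forces(cm, groups, 5.0)
            num = -(ep - em) / (2 * h)
            assert f[n + 3, d] == pytest.approx(num, rel=1e-3, abs=1e-6)

    def test_single_copy_noop(self):
        xyz1 = self._two_copy_model()
        e, f = ff.ncs_restraint_forces(xyz1, [[np.arange(len(xyz1))]], 5.0)
        assert e == 0.0 and np.all(f == 0)

    def test_unequal_copies_rejected(self):
        xyz1 = self._two_copy_model()
        with pytest.raises(ValueError, match="equal"):
            ff.ncs_restraint_forces(xyz1, [[np.arange(5), np.arange(5, 12)]], 1.0)
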