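import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromocg import constants
from chromocg import energetics as en
from chromocg import model_build as mb
from chromocg.geometry import random_quaternion

from conftest import random_dilute_system


class TestDebyeLength:
    def test_physiological_salt(self):
        lam = en.debye_length_from_salt(0.15, 300.0, 80.0)
        assert lam == pytest.approx(8.0, abs=0.3)

    def test_low_salt_closed_form(self):
        # lambda_D[nm] ~ 0.304/sqrt(I) at 298 K in water (eps_r ~ 78.5)
        lam = en.debye_length_from_salt(0.01, 298.0, 78.5)
        assert lam == pytest.approx(30.4, abs=0.4)

    def test_vanishes_at_high_concentration(self):
        assert en.debye_length_from_salt(1e6) < 0.1

    def test_monotone_decreasing(self):
        lams = [en.debye_length_from_salt(c) for c in (0.01, 0.05, 0.15, 0.5)]
        assert np.all(np.diff(lams) < 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(en.EnergeticsError):
            en.debye_length_from_salt(0.0)

    def test_inverse_roundtrip(self):
        lam = en.debye_length_from_salt(0.15)
        assert en.salt_from_debye_length(lam) == pytest.approx(0.15, rel=1e-9)


class TestDHPairEnergy:
    def setup_method(self):
        self.params = en.DebyeHuckelParams(debye_length=8.0)

    def test_zero_beyond_cutoff(self):
        assert en.dh_pair_energy(1, 1, self.params.cutoff, self.params) == 0.0
        assert en.dh_pair_energy(1, 1, self.params.cutoff + 50, self.params) == 0.0

    def test_like_charges_repulsive_everywhere(self):
        for r in np.linspace(1.0, self.params.cutoff - 1e-6, 50):
            assert en.dh_pair_energy(1, 1, r, self.params) > 0

    def test_unshifted_value_at_debye_length(self):
        # 332.06/(80*8) e^-1, checked against the shifted form plus the shift
        p = self.params
        shift = 332.06 / 80.0 * math.exp(-p.cutoff / 8.0) / p.cutoff
        got = en.dh_pair_energy(1, 1, 8.0, p) + shift
        assert got == pytest.approx(332.06 / (80 * 8) * math.exp(-1), rel=1e-9)

    def test_zero_distance_rejected(self):
        with pytest.raises(en.EnergeticsError):
            en.dh_pair_energy(1, 1, 0.0, self.params)

    def test_cutoff_floor_enforced(self):
        with pytest.raises(en.EnergeticsError):
            en.DebyeHuckelParams(debye_length=20.0, cutoff=35.0)

    def test_default_cutoff_grows_at_low_salt(self):
        assert en.DebyeHuckelParams(debye_length=30.0).cutoff == pytest.approx(120.0)
        assert en.DebyeHuckelParams(debye_length=5.0).cutoff == pytest.approx(35.0)


class TestKHPairEnergy:
    def setup_method(self):
        self.table = en.KHPairTable()

    def test_attractive_minimum(self):
        eps, sigma, _ = self.table.pair("F", "L")
        assert eps < 0
        r = 2 ** (1 / 6) * sigma
        got = en.kh_pair_energy("F", "L", r, self.table)
        shift = en._kh_unshifted(eps, sigma, np.array(3.0 * sigma))
        assert got == pytest.approx(-abs(eps) - float(shift), rel=1e-9)

    def test_zero_beyond_cutoff(self):
        _, sigma, rc = self.table.pair("A", "G")
        assert en.kh_pair_energy("A", "G", rc, self.table) == 0.0
        assert en.kh_pair_energy("A", "G", rc * 2, self.table) == 0.0

    def test_repulsive_pair_never_negative(self):
        eps, sigma, rc = self.table.pair("K", "K")
        assert eps > 0
        for r in np.linspace(0.5 * sigma, rc - 1e-9, 200):
            assert en.kh_pair_energy("K", "K", r, self.table) >= -1e-9

    def test_repulsive_pair_monotone_decreasing(self):
        _, sigma, rc = self.table.pair("K", "K")
        rs = np.linspace(0.6 * sigma, rc - 1e-9, 200)
        es = [en.kh_pair_energy("K", "K", r, self.table) for r in rs]
        assert np.all(np.diff(es) <= 1e-12)

    def test_continuity_at_form_boundary(self):
        eps, sigma, _ = self.table.pair("K", "K")
        rmin = 2 ** (1 / 6) * sigma
        lo = en.kh_pair_energy("K", "K", rmin - 1e-9, self.table)
        hi = en.kh_pair_energy("K", "K", rmin + 1e-9, self.table)
        assert abs(lo - hi) < 1e-6

    def test_symmetry(self):
        assert en.kh_pair_energy("A", "W", 7.0, self.table) == en.kh_pair_energy("W", "A", 7.0, self.table)

    def test_unknown_code_rejected(self):
        with pytest.raises(en.EnergeticsError):
            en.kh_pair_energy("Z", "A", 5.0, self.table)

    def test_dna_entries_repulsive(self):
        eps, _, _ = self.table.pair("bp", "K")
        assert eps > 0


class TestStepParams:
    def test_constructed_rise_twist(self, rng):
        from chromocg.geometry import quat_from_rotvec, quat_multiply, quat_rotate

        q1 = random_quaternion(rng)
        r1 = rng.normal(size=3)
        up = mb.BasePairFrame(0, r1, q1)
        dz = quat_rotate(q1, [0, 0, 3.4])
        q2 = quat_multiply(q1, quat_from_rotvec([0, 0, math.radians(36)]))
        down = mb.BasePairFrame(1, r1 + dz, q2)
        xi = en.step_params_from_frames(up, down)
        assert xi.as_vector() == pytest.approx([0, 0, 3.4, 0, 0, 36], abs=1e-9)

    def test_identical_frames_zero(self, rng):
        q = random_quaternion(rng)
        r = rng.normal(size=3)
        xi = en.step_params_from_frames(mb.BasePairFrame(0, r, q), mb.BasePairFrame(1, r, q))
        assert np.abs(xi.as_vector()).max() < 1e-9

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_roundtrip_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        f1 = mb.BasePairFrame(0, rng.normal(size=3), random_quaternion(rng))
        f2 = mb.BasePairFrame(1, rng.normal(scale=4, size=3), random_quaternion(rng))
        xi = en.step_params_from_frames(f1, f2)
        pos2, q2 = en.apply_step_params(f1, xi)
        assert np.abs(pos2 - f2.position).max() < 1e-6
        assert min(np.abs(q2 - f2.orientation).max(), np.abs(q2 + f2.orientation).max()) < 1e-6

    def test_non_unit_quaternion_rejected(self):
        f1 = mb.BasePairFrame(0, np.zeros(3), np.array([1.0, 0, 0, 0]))
        f2 = mb.BasePairFrame(1, np.zeros(3), np.array([2.0, 0, 0, 0]))
        with pytest.raises(en.EnergeticsError):
            en.step_params_from_frames(f1, f2)


class TestRBPStepEnergy:
    def setup_method(self):
        self.st = en.step_stiffness_table()["AVG"]

    def test_zero_at_equilibrium(self):
        xi = en.HelicalStepParams.from_vector(self.st.equilibrium)
        assert en.rbp_step_energy(xi, self.st) == 0.0

    def test_quadratic_scaling(self, rng):
        d = rng.normal(size=6)
        e1 = en.rbp_step_energy(en.HelicalStepParams.from_vector(self.st.equilibrium + d), self.st)
        e2 = en.rbp_step_energy(en.HelicalStepParams.from_vector(self.st.equilibrium + 2 * d), self.st)
        assert e2 == pytest.approx(4 * e1, rel=1e-12)

    def test_brute_force_double_loop(self, rng):
        xi = rng.normal(size=6) + self.st.equilibrium
        d = xi - self.st.equilibrium
        brute = 0.0
        for i in range(6):
            for j in range(6):
                brute += 0.5 * d[i] * self.st.force_constants[i, j] * d[j]
        got = en.rbp_step_energy(en.HelicalStepParams.from_vector(xi), self.st)
        assert got == pytest.approx(brute, abs=1e-12)

    def test_nonnegative_for_psd(self, rng):
        for _ in range(20):
            xi = self.st.equilibrium + rng.normal(scale=3, size=6)
            assert en.rbp_step_energy(en.HelicalStepParams.from_vector(xi), self.st) >= 0

    def test_asymmetric_matrix_rejected(self):
        f = np.eye(6)
        f[0, 1] = 0.5
        with pytest.raises(en.EnergeticsError):
            en.StepStiffness(np.zeros(6), f)

    def test_sequence_rise_averages_to_canonical(self):
        tab = en.step_stiffness_table()
        assert tab["AVG"].equilibrium[2] == pytest.approx(constants.BDNA_RISE, abs=0.01)


class TestTotalEnergy:
    def brute_force(self, system, dh, kh):
        """Independent O(N^2) python-loop oracle over all energy terms."""
        x = system.site_positions()
        species = system.site_species()
        charges = system.site_charges()
        excl = {tuple(p) for p in system.exclusion_pairs()}
        n = system.n_sites
        e_dh = e_kh = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excl:
                    continue
                r = np.linalg.norm(x[i] - x[j])
                if charges[i] != 0 and charges[j] != 0 and r < dh.cutoff:
                    e_dh += en.dh_pair_energy(charges[i], charges[j], r, dh)
                e_kh += en.kh_pair_energy(species[i], species[j], r, kh)
        e_bond = 0.0
        for a, b in np.asarray(system.flexible_bonds).reshape(-1, 2):
            d = np.linalg.norm(x[a] - x[b])
            e_bond += system.bond_spring_constant * (d - system.bond_rest_length) ** 2
        e_gnm = 0.0
        for g in system.gnm:
            for (a, b), r0 in zip(g.pairs, g.rest_lengths):
                d = np.linalg.norm(x[a] - x[b])
                e_gnm += g.spring_constant * (d - r0) ** 2
        e_rbp = 0.0
        table = en.step_stiffness_table()
        for a, b in system._bonded_bp_steps():
            xi = en.step_params_from_frames(system.dna_frames[a], system.dna_frames[b])
            e_rbp += en.rbp_step_energy(xi, table[system.dna_frames[a].step_sequence])
        return e_bond, e_gnm, e_rbp, e_dh, e_kh

    def test_matches_brute_force_random_system(self, rng):
        system = random_dilute_system(rng, n_protein=30, n_bp=6)
        dh = en.DebyeHuckelParams(debye_length=8.0)
        kh = en.KHPairTable()
        got = en.total_energy(system, dh, kh)
        eb, eg, er, ed, ek = self.brute_force(system, dh, kh)
        assert got.bonds == pytest.approx(eb, abs=1e-9)
        assert got.gnm == pytest.approx(eg, abs=1e-9)
        assert got.rbp == pytest.approx(er, abs=1e-9)
        assert got.dh == pytest.approx(ed, abs=1e-9)
        assert got.kh == pytest.approx(ek, abs=1e-9)
        assert got.total == pytest.approx(eb + eg + er + ed + ek, abs=1e-9)

    def test_two_bonded_beads_no_nonbonded(self):
        beads = mb.build_histone_chain("KK", ["tail", "tail"])
        beads[0].position = np.array([0.0, 0, 0])
        beads[1].position = np.array([3.5, 0, 0])
        system = mb.ChromatinSystem(protein_beads=beads, dna_frames=[],
                                    flexible_bonds=np.array([[0, 1]]))
        e = en.total_energy(system, en.DebyeHuckelParams(debye_length=8.0))
        assert e.dh == 0.0
        assert e.kh == 0.0
        assert e.bonds == pytest.approx(0.0, abs=1e-12)

    def test_isolated_bead_zero(self):
        beads = mb.build_histone_chain("K", ["tail"])
        system = mb.ChromatinSystem(protein_beads=beads, dna_frames=[])
        assert en.total_energy(system, en.DebyeHuckelParams(debye_length=8.0)).total == 0.0

    def test_dangling_bond_rejected(self, rng):
        system = random_dilute_system(rng, n_protein=5, n_bp=0)
        system.flexible_bonds = np.array([[0, 99]])
        with pytest.raises(en.EnergeticsError, match="dangling"):
            en.total_energy(system, en.DebyeHuckelParams(debye_length=8.0))

    def test_translation_rotation_invariance(self, mini_model, rng):
        from scipy.spatial.transform import Rotation

        prot, bpos, bquat = mini_model.coords_from_system()
        e0 = mini_model.energy(prot, bpos, bquat).total
        rot = Rotation.random(random_state=7)
        shift = rng.normal(scale=50, size=3)
        prot2 = rot.apply(prot) + shift
        bpos2 = rot.apply(bpos) + shift
        qrot = np.roll(rot.as_quat(), 1)
        from chromocg.geometry import quat_multiply

        bquat2 = quat_multiply(qrot, bquat)
        e1 = mini_model.energy(prot2, bpos2, bquat2).total
        assert e1 == pytest.approx(e0, abs=1e-9 * max(abs(e0), 1.0))


class TestForces:
    def test_gradient_consistency(self, mini_model):
        prot, bpos, bquat = mini_model.coords_from_system()
        fp, fb, tb = mini_model.forces(prot, bpos, bquat)
        h = 1e-5
        rng = np.random.default_rng(3)
        for i in rng.integers(0, len(prot), size=4):
            for ax in range(3):
                pp = prot.copy(); pp[i, ax] += h
                pm = prot.copy(); pm[i, ax] -= h
                num = -(mini_model.energy(pp, bpos, bquat).total -
                        mini_model.energy(pm, bpos, bquat).total) / (2 * h)
                assert fp[i, ax] == pytest.approx(num, rel=1e-5, abs=1e-5)
        for j in rng.integers(0, len(bpos), size=3):
            for ax in range(3):
                bp2 = bpos.copy(); bp2[j, ax] += h
                bm = bpos.copy(); bm[j, ax] -= h
                num = -(mini_model.energy(prot, bp2, bquat).total -
                        mini_model.energy(prot, bm, bquat).total) / (2 * h)
                assert fb[j, ax] == pytest.approx(num, rel=1e-4, abs=1e-4)

    def test_torque_consistency(self, mini_model):
        prot, bpos, bquat = mini_model.coords_from_system()
        _, _, tb = mini_model.forces(prot, bpos, bquat)
        hr = 1e-6
        for j in (0, 11, 23):
            for ax in range(3):
                qp = bquat.copy(); qp[j] = en._rotate_quats(bquat[j], ax, hr)
                qm = bquat.copy(); qm[j] = en._rotate_quats(bquat[j], ax, -hr)
                num = -(mini_model.energy(prot, bpos, qp).total -
                        mini_model.energy(prot, bpos, qm).total) / (2 * hr)
                assert tb[j, ax] == pytest.approx(num, rel=1e-3, abs=1e-3)

    def test_momentum_conservation(self, mini_model):
        """Internal forces sum to zero over the whole system."""
        prot, bpos, bquat = mini_model.coords_from_system()
        fp, fb, _ = mini_model.forces(prot, bpos, bquat)
        net = fp.sum(axis=0) + fb.sum(axis=0)
        scale = max(np.abs(fp).max(), np.abs(fb).max(), 1.0)
        assert np.abs(net).max() < 1e-7 * scale
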