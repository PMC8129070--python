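import numpy as np
import pytest

from chromocg import constants
from chromocg import minimal_model as mm
from chromocg import model_build as mb

KBT = constants.KB * 300.0


class TestMapping:
    def test_straight_200bp_strand(self):
        system = mb.build_straight_dna(200)
        msys = mm.map_cs_to_minimal(system)
        assert msys.n_beads == 40
        pos = np.array([b.position for b in msys.dna_beads])
        # centroids sit on the straight axis, ~17 A apart
        assert np.allclose(np.linalg.norm(np.diff(pos, axis=0), axis=1), 17.0, atol=1e-9)
        # centroid arithmetic: first bead = mean of bp 0..4
        bp = np.array([f.position for f in system.dna_frames[:5]])
        assert np.allclose(pos[0], bp.mean(axis=0), atol=1e-12)

    def test_trailing_block_merged(self):
        system = mb.build_straight_dna(203)
        msys = mm.map_cs_to_minimal(system)
        assert msys.n_beads == 40
        assert msys.dna_beads[-1].span_bp == 8
        assert msys.dna_beads[-1].charge == pytest.approx(-16.0)

    def test_unwrapped_end_becomes_linker(self, full_nucleosome):
        disp = full_nucleosome.copy()
        for j in range(20):  # displace 20 bp (4 blocks) far from the core
            disp.dna_frames[j].position = disp.dna_frames[j].position + np.array([300.0, 0, 0])
        msys = mm.map_cs_to_minimal(disp)
        nuc = msys.nucleosomes[0]
        assert 0 not in nuc.attached_beads
        assert all(b not in nuc.attached_beads for b in range(4))
        assert not msys.dna_beads[0].is_nucleosomal

    def test_non_breathing_keeps_full_span(self, full_nucleosome):
        nb = mb.apply_non_breathing(full_nucleosome)
        disp = nb.copy()
        # even with displaced coordinates the span definition is retained
        for j in range(10):
            disp.dna_frames[j].position = disp.dna_frames[j].position + np.array([300.0, 0, 0])
        msys = mm.map_cs_to_minimal(disp)
        assert set(msys.nucleosomes[0].attached_beads) == set(range(29))

    def test_fully_wrapped_breathing_keeps_span(self, full_nucleosome):
        # 147 bp -> 29 blocks (the 2-bp remainder merges into the last bead)
        msys = mm.map_cs_to_minimal(full_nucleosome)
        assert set(msys.nucleosomes[0].attached_beads) == set(range(29))


class TestHelixFit:
    def test_gaussian_recovery(self, rng):
        mean = np.array([0.0, -0.5, 17.0, 0.0, 3.0, 171.5])
        cov = np.diag([0.5, 0.4, 0.3, 4.0, 9.0, 16.0])
        fit = mm.fit_minimal_helix_params(rng.multivariate_normal(mean, cov, 100000))
        assert np.abs(fit.equilibrium - mean).max() < 0.1
        expected = KBT / np.diag(cov)
        got = np.diag(fit.force_constants)
        assert np.abs(got - expected).max() < 0.03 * expected.max()

    def test_zero_variance_rejected(self):
        samples = np.tile(np.arange(6.0), (100, 1))
        with pytest.raises(mm.MinimalModelError, match="condition|singular"):
            mm.fit_minimal_helix_params(samples)

    def test_wrong_shape_rejected(self):
        with pytest.raises(mm.MinimalModelError):
            mm.fit_minimal_helix_params(np.zeros((10, 5)))

    def test_default_rise_is_five_single_bp_rises(self):
        st = mm.default_minimal_stiffness()
        assert st.equilibrium[2] == pytest.approx(5 * constants.BDNA_RISE, abs=1e-9)

    def test_fitted_rise_consistent_with_level2_tables(self, rng):
        """Composing 5 independent AVG steps reproduces ~5x the single-bp
        equilibrium rise (consistency between resolutions)."""
        from chromocg.energetics import step_stiffness_table

        avg = step_stiffness_table()["AVG"]
        cov1 = KBT * np.linalg.inv(avg.force_constants)
        samples = sum(rng.multivariate_normal(avg.equilibrium, cov1, 30000) for _ in range(5))
        fit = mm.fit_minimal_helix_params(samples)
        assert fit.equilibrium[2] == pytest.approx(5 * avg.equilibrium[2], rel=0.02)


class TestAnisoFit:
    def table_from(self, pars, rs=None):
        rs = rs if rs is not None else np.linspace(35, 130, 40)
        rows = []
        for r in rs:
            for ci, cj in [(1, 1), (0, 0), (1, 0), (0.6, 0.6), (0.1, 0.9)]:
                rows.append([r, ci, cj, float(pars.evaluate(r, ci, cj))])
        return np.array(rows)

    def test_self_consistency(self):
        true = mm.AnisoParams(1.5, 0.5, 40.0, 56.0)
        pars, rms = mm.fit_aniso_nucleosome_potential(self.table_from(true))
        assert rms < 1e-6
        assert pars.eps_face == pytest.approx(1.5, abs=1e-4)
        assert pars.sigma_side == pytest.approx(56.0, abs=1e-3)

    def test_purely_repulsive_gives_zero_depth(self):
        rows = []
        for r in np.linspace(30, 130, 50):
            for ci, cj in [(1, 1), (0, 0), (0.5, 0.5)]:
                rows.append([r, ci, cj, 5.0 * np.exp(-r / 12.0)])
        pars, _ = mm.fit_aniso_nucleosome_potential(np.array(rows))
        # well depth ~ 0 (< 0.1 kBT)
        assert pars.eps_face * 1.0 < 0.1 * KBT + 0.06
        assert pars.eps_side < 0.1

    def test_face_side_ordering_preserved(self):
        true = mm.AnisoParams(2.0, 0.3, 40.0, 56.0)
        pars, _ = mm.fit_aniso_nucleosome_potential(self.table_from(true))
        assert pars.eps_face > pars.eps_side

    def test_missing_orientation_coverage_rejected(self):
        rows = [[r, 1.0, 1.0, 0.0] for r in np.linspace(30, 100, 20)]
        with pytest.raises(mm.MinimalModelError, match="side-to-side"):
            mm.fit_aniso_nucleosome_potential(np.array(rows))


class TestMinimalEnergy:
    def test_distant_cores_no_interaction(self):
        nucs = [
            mm.MinimalNucleosome(np.zeros(3), np.array([1.0, 0, 0, 0])),
            mm.MinimalNucleosome(np.array([5000.0, 0, 0]), np.array([1.0, 0, 0, 0])),
        ]
        sys_ = mm.MinimalSystem([], nucs, mm.default_minimal_stiffness(),
                                mm.default_aniso_params(), breathing=False)
        e = mm.minimal_total_energy(sys_)
        assert e.total == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracle_small_system(self, rng):
        import math

        from chromocg.energetics import DebyeHuckelParams, step_params_batch

        msys = mm.build_minimal_array(2, 165, breathing=True, unwrapped_blocks=2, seed=3)
        dh = DebyeHuckelParams(debye_length=8.0)
        got = mm.minimal_total_energy(msys, dh)
        # independent recomputation with explicit loops
        beads, cores = msys.dna_beads, msys.nucleosomes
        e_bond = sum(
            mm.BOND_K * (np.linalg.norm(cores[c].position - beads[b].position) - r0) ** 2
            for c, b, r0 in msys.bonds
        )
        e_rbp = 0.0
        for i in range(len(beads) - 1):
            xi = step_params_batch(beads[i].position, beads[i].orientation,
                                   beads[i + 1].position, beads[i + 1].orientation)[0]
            d = xi - msys.stiffness.equilibrium
            e_rbp += 0.5 * d @ msys.stiffness.force_constants @ d
        assert got.bonds == pytest.approx(e_bond, abs=1e-9)
        assert got.rbp == pytest.approx(e_rbp, abs=1e-9)
        assert got.total == pytest.approx(
            got.bonds + got.rbp + got.dh + got.aniso + got.exposure, abs=1e-12)

    def test_non_breathing_has_no_exposure_term(self):
        msys = mm.build_minimal_array(3, 165, breathing=False)
        assert mm.minimal_total_energy(msys).exposure == 0.0

    def test_dangling_bond_rejected(self):
        msys = mm.build_minimal_array(1, 165)
        msys.bonds.append((0, 9999, 10.0))
        with pytest.raises(mm.MinimalModelError, match="dangling"):
            mm.minimal_total_energy(msys)


class TestPersistenceLength:
    def test_tangent_decay_matches_wlc_closed_form(self, rng):
        """Chains grown from the fitted Gaussian steps decay their
        tangent-tangent correlation as the worm-like-chain closed form
        implied by the bending stiffness (within 10%)."""
        st = mm.default_minimal_stiffness()
        cov = KBT * np.linalg.inv(st.force_constants)
        n_steps, n_chains = 60, 400
        samples = rng.multivariate_normal(st.equilibrium, cov, (n_chains, n_steps))
        corr = np.zeros(n_steps)
        counts = np.zeros(n_steps)
        from chromocg.geometry import quat_multiply, quat_rotate_vec, rotvec_to_quat

        for c in range(n_chains):
            q = np.array([1.0, 0, 0, 0])
            tangents = []
            for s in range(n_steps):
                tangents.append(quat_rotate_vec(q[None], np.array([0.0, 0, 1]))[0])
                rot = rotvec_to_quat(np.radians(samples[c, s, 3:]))
                q = quat_multiply(q, rot)
                q /= np.linalg.norm(q)
            t = np.array(tangents)
            for lag in range(1, min(30, n_steps)):
                corr[lag] += (t[:-lag] * t[lag:]).sum()
                counts[lag] += len(t) - lag
        corr[1:30] /= counts[1:30]
        # closed form: for a rotation vector with dominant twist phi, the
        # tangent deflection carries a factor (1 - cos phi)/phi^2 relative to
        # the small-twist (var_tilt + var_roll)/2 law
        var_bend = np.radians(np.sqrt(cov[3, 3])) ** 2 + np.radians(np.sqrt(cov[4, 4])) ** 2
        phi = np.radians(st.equilibrium[5])
        expected_rate = var_bend * (1.0 - np.cos(phi)) / phi**2
        lags = np.arange(1, 20)
        measured_rate = -np.polyfit(lags, np.log(corr[1:20]), 1)[0]
        assert measured_rate == pytest.approx(expected_rate, rel=0.10)

    def test_rg_of_mapping_matches_source_dna(self, full_nucleosome):
        """Cross-resolution fidelity: the mapped minimal beads reproduce the
        radius of gyration of the underlying DNA path."""
        msys = mm.map_cs_to_minimal(full_nucleosome)
        bp = np.array([f.position for f in full_nucleosome.dna_frames])
        beads = np.array([b.position for b in msys.dna_beads])
        rg = lambda x: np.sqrt(((x - x.mean(axis=0)) ** 2).sum(axis=1).mean())
        assert rg(beads) == pytest.approx(rg(bp), rel=0.05)
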