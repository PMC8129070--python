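import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chromocg import model_build as mb
from chromocg import structure_analysis as sa


def make_axes(origin, normal, dyad):
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    d = np.asarray(dyad, dtype=float)
    d = d / np.linalg.norm(d)
    return sa.NucleosomeAxes(np.asarray(origin, dtype=float), n, d)


class TestUnwrappedBp:
    def test_ideal_fixture_zero(self, full_nucleosome):
        assert sa.count_unwrapped_bp(full_nucleosome) == 0.0

    def test_ten_displaced_terminal_bp(self, full_nucleosome):
        disp = full_nucleosome.copy()
        for j in range(10):
            disp.dna_frames[j].position = disp.dna_frames[j].position + np.array([80.0, 0, 0])
        assert sa.count_unwrapped_bp(disp) == 10.0

    def test_both_ends_counted(self, full_nucleosome):
        disp = full_nucleosome.copy()
        for j in list(range(4)) + list(range(147 - 6, 147)):
            disp.dna_frames[j].position = disp.dna_frames[j].position + np.array([0, 0, 90.0])
        assert sa.count_unwrapped_bp(disp) == 10.0

    def test_interior_gap_not_counted(self, full_nucleosome):
        """Counting is contiguous from the ends only."""
        disp = full_nucleosome.copy()
        for j in range(70, 75):
            disp.dna_frames[j].position = disp.dna_frames[j].position + np.array([90.0, 0, 0])
        assert sa.count_unwrapped_bp(disp) == 0.0

    def test_fully_detached_counts_all(self, full_nucleosome):
        disp = full_nucleosome.copy()
        for f in disp.dna_frames:
            f.position = f.position + np.array([500.0, 0, 0])
        assert sa.count_unwrapped_bp(disp) == 147.0

    def test_brute_force_recount(self, full_nucleosome, rng):
        """Oracle: direct per-bp threshold scan + end-contiguity logic."""
        from scipy.spatial import cKDTree

        disp = full_nucleosome.copy()
        for j in rng.choice(147, size=30, replace=False):
            disp.dna_frames[j].position = disp.dna_frames[j].position + rng.normal(0, 30, 3)
        got = sa.count_unwrapped_bp(disp)
        glob = np.array([b.position for b in disp.protein_beads if b.region == "globular"])
        tree = cKDTree(glob)
        pos = disp.site_positions()
        p = disp.n_protein
        flags = []
        for j in range(147):
            d, _ = tree.query(pos[p + 3 * j : p + 3 * j + 3])
            flags.append(d.min() > sa.DETACH_THRESHOLD)
        lead = 0
        for f in flags:
            if not f:
                break
            lead += 1
        trail = 0
        if lead < len(flags):
            for f in reversed(flags):
                if not f:
                    break
                trail += 1
        expected = min(lead + trail, 147)
        assert got == expected


class TestNucleosomeAxes:
    def test_flat_ring_normal_along_z(self):
        s = mb.build_ideal_nucleosome(superhelix_pitch=0.0)
        axes = sa.axes_for_system(s)[0]
        assert abs(axes.face_normal @ [0, 0, 1]) > 0.999

    def test_axes_orthonormal(self, full_nucleosome):
        axes = sa.axes_for_system(full_nucleosome)[0]
        assert np.linalg.norm(axes.face_normal) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(axes.dyad_axis) == pytest.approx(1.0, abs=1e-9)
        assert abs(axes.face_normal @ axes.dyad_axis) < 1e-9

    def test_rotational_equivariance(self, full_nucleosome):
        pos = full_nucleosome.site_positions()
        axes0 = sa.axes_for_system(full_nucleosome, pos)[0]
        rot = Rotation.random(random_state=11)
        axes1 = sa.axes_for_system(full_nucleosome, rot.apply(pos))[0]
        assert np.allclose(axes1.face_normal, rot.apply(axes0.face_normal), atol=1e-9)
        assert np.allclose(axes1.dyad_axis, rot.apply(axes0.dyad_axis), atol=1e-9)

    def test_noisy_fixture_normal_within_2deg(self, rng):
        s = mb.build_ideal_nucleosome(superhelix_pitch=0.0)
        dna = np.array([f.position for f in s.dna_frames])
        noisy = dna + rng.normal(0, 1.0, dna.shape)
        axes = sa.nucleosome_axes(noisy)
        angle = np.degrees(np.arccos(abs(axes.face_normal @ [0, 0, 1])))
        assert angle < 2.0

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(25.0), np.zeros(25), np.zeros(25)])
        with pytest.raises(sa.AnalysisError):
            sa.nucleosome_axes(line)

    def test_too_few_sites_rejected(self):
        with pytest.raises(sa.AnalysisError):
            sa.nucleosome_axes(np.random.default_rng(0).normal(size=(10, 3)))

    def test_winding_sign_convention(self, full_nucleosome):
        """Left-handed wrap fixes the normal sign deterministically."""
        a1 = sa.axes_for_system(full_nucleosome)[0]
        a2 = sa.axes_for_system(full_nucleosome)[0]
        assert np.allclose(a1.face_normal, a2.face_normal)


class TestOrientationClasses:
    def test_coaxial_stack_ff(self):
        a = make_axes([0, 0, 0], [0, 0, 1], [1, 0, 0])
        b = make_axes([0, 0, 60], [0, 0, 1], [1, 0, 0])
        assert sa.classify_pair_orientation(a, b) == "FF"

    def test_perpendicular_t_fs(self):
        a = make_axes([0, 0, 0], [0, 0, 1], [1, 0, 0])
        b = make_axes([0, 0, 60], [1, 0, 0], [0, 0, 1])
        assert sa.classify_pair_orientation(a, b) == "FS"

    def test_side_by_side_ss(self):
        a = make_axes([0, 0, 0], [0, 0, 1], [1, 0, 0])
        b = make_axes([60, 0, 0], [0, 0, 1], [1, 0, 0])
        assert sa.classify_pair_orientation(a, b) == "SS"

    def test_antiparallel_normal_still_ff(self):
        a = make_axes([0, 0, 0], [0, 0, 1], [1, 0, 0])
        b = make_axes([0, 0, 60], [0, 0, -1], [1, 0, 0])
        assert sa.classify_pair_orientation(a, b) == "FF"


class TestValency:
    def test_isolated_zero(self):
        assert sa.valency(np.zeros((1, 3))) == 0.0

    def test_six_clique(self, rng):
        pts = rng.normal(0, 20, (6, 3))
        assert sa.valency(pts, cutoff=1e6) == 5.0

    def test_brute_force_recount(self, rng):
        pts = rng.uniform(0, 400, (20, 3))
        got = sa.valency(pts, cutoff=150.0)
        expected = np.mean([
            sum(1 for j in range(20)
                if j != i and np.linalg.norm(pts[i] - pts[j]) <= 150.0)
            for i in range(20)
        ])
        assert got == pytest.approx(expected)

    def test_translation_invariance(self, rng):
        pts = rng.uniform(0, 300, (10, 3))
        assert sa.valency(pts) == sa.valency(pts + 123.4)


class TestNeighborHistogram:
    def test_zigzag_fiber_k2_ff(self):
        """An ideal zigzag stack: i and i+2 coaxially stacked discs."""
        s = mb.build_array(6, 165, histones={})
        # construct synthetic positions: two stacks side by side
        pos = s.site_positions().copy()
        p = s.n_protein
        for k, rec in enumerate(s.nucleosome_records):
            lo, hi = rec.dna_span
            template = mb.build_ideal_nucleosome(superhelix_pitch=0.0, histones={})
            tpos = np.array([f.position for f in template.dna_frames])
            offset = np.array([0.0 if k % 2 == 0 else 120.0, 0.0, (k // 2) * 60.0])
            pos[p + 3 * lo : p + 3 * hi : 3] = tpos[: hi - lo] + offset
        counts, fractions = sa.neighbor_interaction_histogram(s, [pos], cutoff=80.0)
        assert set(counts) == {2}
        assert fractions[2]["FF"] == pytest.approx(1.0)

    def test_all_far_empty(self):
        s = mb.build_array(3, 165, histones={})
        pos = s.site_positions().copy()
        p = s.n_protein
        for k, rec in enumerate(s.nucleosome_records):
            lo, hi = rec.dna_span
            pos[p + 3 * lo : p + 3 * hi] += np.array([0.0, 0.0, 5000.0 * k])
        counts, _ = sa.neighbor_interaction_histogram(s, [pos], cutoff=80.0)
        assert counts == {}

    def test_class_fractions_sum_to_one(self, rng):
        s = mb.build_array(4, 165, histones={})
        pos = s.site_positions()
        counts, fractions = sa.neighbor_interaction_histogram(s, [pos], cutoff=500.0)
        for k, fr in fractions.items():
            assert sum(fr.values()) == pytest.approx(1.0)


class TestSedimentation:
    def test_single_nucleosome_s1(self):
        assert sa.sedimentation_coefficient(np.zeros((1, 3))) == sa.S1_SVEDBERG

    def test_two_nucleosome_closed_form(self):
        two = np.array([[0, 0, 0], [100.0, 0, 0]])
        expected = 11.1 * (1 + (2 * 5.5 / 4) * (1 / 10.0))
        assert sa.sedimentation_coefficient(two) == pytest.approx(expected, rel=1e-12)

    def test_compaction_monotonicity(self, rng):
        pts = rng.uniform(0, 300, (12, 3))
        assert sa.sedimentation_coefficient(0.5 * pts) > sa.sedimentation_coefficient(pts)

    def test_dilation_strictly_decreases(self, rng):
        pts = rng.uniform(0, 300, (12, 3))
        assert sa.sedimentation_coefficient(1.5 * pts) < sa.sedimentation_coefficient(pts)

    def test_rotation_invariance(self, rng):
        pts = rng.uniform(0, 300, (8, 3))
        rot = Rotation.random(random_state=5)
        assert sa.sedimentation_coefficient(rot.apply(pts)) == pytest.approx(
            sa.sedimentation_coefficient(pts), rel=1e-12)


class TestRgAutocorrelation:
    def test_white_noise_uncorrelated(self, rng):
        acf, _ = sa.rg_autocorrelation(rng.normal(size=5000))
        assert np.abs(acf[1:10]).max() < 0.05

    def test_ar1_rate_recovered(self, rng):
        tau = 20.0
        phi = np.exp(-1 / tau)
        x = np.zeros(10000)
        for i in range(1, len(x)):
            x[i] = phi * x[i - 1] + rng.normal()
        _, rate = sa.rg_autocorrelation(x)
        assert rate == pytest.approx(1 / tau, rel=0.10)

    def test_constant_series_rejected(self):
        with pytest.raises(sa.AnalysisError):
            sa.rg_autocorrelation(np.full(500, 3.0))

    def test_short_series_rejected(self):
        with pytest.raises(sa.AnalysisError):
            sa.rg_autocorrelation(np.arange(50.0))


class TestBindingSeries:
    def test_always_close_all_ones(self):
        series, lt = sa.binding_timeseries(np.full(30, 50.0))
        assert series.all()
        assert lt == 30.0

    def test_always_far_all_zero(self):
        series, lt = sa.binding_timeseries(np.full(30, 500.0))
        assert not series.any()
        assert lt == 0.0

    def test_alternating_no_hysteresis(self):
        d = np.array([90.0, 130.0] * 10)
        series, lt = sa.binding_timeseries(d, bind_cutoff=100.0, unbind_cutoff=100.0)
        assert list(series[:4]) == [1, 0, 1, 0]
        assert lt == 1.0

    def test_hysteresis_suppresses_chatter(self):
        # oscillation within the hysteresis band keeps the bound state
        d = np.array([90.0, 110.0] * 10)
        series, lt = sa.binding_timeseries(d, bind_cutoff=100.0, unbind_cutoff=120.0)
        assert series.all()


class TestPerResidueContacts:
    def test_zero_contact_trajectory_all_zero(self):
        s = mb.build_array(2, 165, histones={})
        pos = s.site_positions().copy()
        p = s.n_protein
        lo, hi = s.nucleosome_records[1].dna_span
        pos[p + 3 * lo :] += np.array([0.0, 0.0, 10000.0])
        total, by_cat = sa.per_residue_contact_fractions(s, [pos])
        assert total.max() == 0.0

    def test_constructed_single_contact(self, mini_nucleosome):
        """Two copies of the mini nucleosome with exactly one close site pair."""
        import copy

        s = mini_nucleosome
        # duplicate system: second nucleosome far away except one DNA site
        pos = s.site_positions()
        double = _duplicate_system(s)
        pos2 = double.site_positions().copy()
        n1 = s.n_sites
        pos2[n1:] += np.array([0.0, 0.0, 3000.0])
        # bring one protein site of copy 2 next to a DNA site of copy 1
        target = pos2[s.bp_center_site(0)]
        pos2[n1] = target + np.array([0.0, 0.0, 1.0])
        total, by_cat = sa.per_residue_contact_fractions(double, [pos2])
        assert total[n1] == pytest.approx(1.0)
        assert total.sum() > 0
        # decomposition: per-site category fractions sum to the total
        stacked = sum(by_cat.values())
        assert np.allclose(stacked, total, atol=1e-12)

    def test_category_decomposition_identity(self, mini_nucleosome, rng):
        double = _duplicate_system(mini_nucleosome)
        pos = double.site_positions() + rng.normal(0, 0.1, (double.n_sites, 3))
        total, by_cat = sa.per_residue_contact_fractions(double, [pos])
        assert np.allclose(sum(by_cat.values()), total, atol=1e-12)


def _duplicate_system(s):
    """Two disconnected copies of a system as independent nucleosomes."""
    import dataclasses

    beads = [dataclasses.replace(b, position=np.array(b.position)) for b in s.protein_beads]
    beads += [dataclasses.replace(b, chain_id=b.chain_id + "'", position=np.array(b.position))
              for b in s.protein_beads]
    frames = [dataclasses.replace(f, position=np.array(f.position),
                                  orientation=np.array(f.orientation),
                                  phosphate_offsets=np.array(f.phosphate_offsets))
              for f in s.dna_frames]
    frames += [dataclasses.replace(f, index=f.index + s.n_bp,
                                   position=np.array(f.position),
                                   orientation=np.array(f.orientation),
                                   phosphate_offsets=np.array(f.phosphate_offsets))
               for f in s.dna_frames]
    n_p, n_bp = s.n_protein, s.n_bp
    recs = [dataclasses.replace(r) for r in s.nucleosome_records]
    recs += [
        mb.NucleosomeRecord(
            histone_range=(r.histone_range[0] + n_p, r.histone_range[1] + n_p),
            dna_span=(r.dna_span[0] + n_bp, r.dna_span[1] + n_bp),
            dyad_bp=r.dyad_bp + n_bp, breathing=r.breathing)
        for r in s.nucleosome_records
    ]
    return mb.ChromatinSystem(protein_beads=beads, dna_frames=frames,
                              nucleosome_records=recs)
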