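"""Structural analyses against brute-force and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibremetrics.fiber_structure import (
    GofR,
    HBond,
    HBondTable,
    amide_dihedrals,
    classify_helicity,
    contraction,
    count_flipped,
    detect_hbonds,
    detect_stable_domains,
    fiber_dimensions,
    first_peak,
    hbond_occupancy,
    helicity_fractions,
    intercore_distances,
    order_increase,
    persistent_hbonds,
    radial_distribution,
    sasa,
)
from fibremetrics.synthetic_data import GeneratorConfig, build_ideal_fiber
from fibremetrics.topology import FiberFrame, dihedral_angles


class TestIntercoreDistances:
    def test_two_cores_symmetric_wrap(self):
        cfg = GeneratorConfig(n_monomers=2, intercore_distance=3.4)
        topo, frame = build_ideal_fiber(cfg)
        assert np.allclose(intercore_distances(frame, topo), [3.4, 3.4])

    def test_matches_bruteforce_minimum_image(self, jittered_fiber):
        _, topo, _, traj = jittered_fiber
        frame = traj[3]
        got = intercore_distances(frame, topo)
        cent = topo.core_centroids(frame.coords)
        n = len(cent)
        for i in range(n):
            a, b = cent[i], cent[(i + 1) % n]
            delta = b - a
            dz = delta[2] - frame.box_z * round(delta[2] / frame.box_z)
            expected = np.sqrt(delta[0] ** 2 + delta[1] ** 2 + dz**2)
            assert got[i] == pytest.approx(expected, abs=1e-9)


class TestRadialDistribution:
    def test_ideal_stack_concentrates_at_spacing(self, ideal_48mer):
        topo, frame = ideal_48mer
        g = radial_distribution(frame, topo, r_max=5.0, bin_width=0.1)
        occupied = np.flatnonzero(g.g > 0)
        assert len(occupied) == 1
        assert g.r[occupied[0]] == pytest.approx(3.4)

    def test_uniform_points_give_unit_g(self, rng):
        pts = rng.uniform(0, 50, size=(30, 200, 3))
        g = radial_distribution(
            None, points=pts, box=(50, 50, 50), r_max=10, bin_width=0.5
        )
        body = g.g[g.r > 2]
        assert abs(body.mean() - 1.0) < 0.05
        assert np.abs(body - 1.0).max() < 0.2

    def test_small_frame_matches_exhaustive_enumeration(self, rng):
        pts = rng.uniform(0, 20, size=(1, 5, 3))
        box = (20.0, 20.0, 20.0)
        r_max, w = 15.0, 0.5
        g = radial_distribution(None, points=pts, box=box, r_max=r_max, bin_width=w)
        # exhaustive ordered-pair histogram
        edges = (np.arange(len(g.r) + 1) - 0.5) * w
        edges[0] = 0.0
        counts = np.zeros(len(g.r))
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                d = pts[0, i] - pts[0, j]
                d -= np.array(box) * np.round(d / np.array(box))
                r = np.linalg.norm(d)
                if r <= edges[-1]:
                    counts[np.searchsorted(edges, r, side="right") - 1] += 1
        density = 5 / np.prod(box)
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        assert np.allclose(g.g, counts / (5 * density * shell))

    def test_fewer_than_two_cores_rejected(self):
        with pytest.raises(ValueError):
            radial_distribution(None, points=np.zeros((1, 1, 3)), box=(10, 10, 10))


class TestPeaks:
    def test_tie_breaks_toward_smaller_r(self):
        r = np.arange(0, 50) * 0.1
        g = np.zeros(50)
        g[34] = g[36] = 5.0
        got_r, got_h = first_peak(GofR(r=r, g=g, bin_width=0.1))
        assert got_r == pytest.approx(3.4) and got_h == 5.0

    def test_matches_direct_argmax_scan(self, rng):
        r = np.arange(0, 100) * 0.1
        g = rng.random(100)
        gofr = GofR(r=r, g=g, bin_width=0.1)
        got_r, got_h = first_peak(gofr, (1.0, 8.0))
        mask = (r >= 1.0) & (r <= 8.0)
        assert got_h == g[mask].max()
        assert got_r == r[mask][np.argmax(g[mask])]

    def test_empty_window_rejected(self):
        g = GofR(r=np.arange(10) * 0.1, g=np.ones(10), bin_width=0.1)
        with pytest.raises(ValueError):
            first_peak(g, (5.0, 6.0))

    @pytest.mark.parametrize(
        "h_ref,h_test,expected", [(1.0, 1.52, 52.0), (1.0, 1.0, 0.0), (2.0, 1.0, -50.0)]
    )
    def test_order_increase_arithmetic(self, h_ref, h_test, expected):
        r = np.arange(10) * 0.1
        make = lambda h: GofR(r=r, g=np.eye(10)[3] * h, bin_width=0.1)
        assert order_increase(make(h_ref), make(h_test)) == pytest.approx(expected)


class TestDihedrals:
    def test_planar_cis_quadruplet_is_zero(self):
        p = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
        assert dihedral_angles(*p) == pytest.approx(0.0)

    def test_random_quadruplets_match_mdanalysis(self, rng):
        from MDAnalysis.lib.distances import calc_dihedrals

        p = rng.normal(size=(50, 4, 3))
        ours = dihedral_angles(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
        theirs = np.degrees(
            calc_dihedrals(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
        )
        assert np.allclose(ours, theirs, atol=1e-5)

    def test_collinear_triple_flagged_nan(self):
        p = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], dtype=float)
        assert np.isnan(dihedral_angles(*p))


class TestHelicity:
    @pytest.mark.parametrize(
        "angle,label",
        [(-140.0, "P"), (30.0, "flipped"), (-90.0, "P"), (0.0, "M"), (-45.0, "M"),
         (180.0, "flipped")],
    )
    def test_classification_and_boundaries(self, angle, label):
        assert classify_helicity(angle) == label

    def test_constructed_mixture_counted_exactly(self):
        angles = np.concatenate(
            [np.full(76, -140.0), np.full(19, -45.0), np.full(5, 30.0)]
        )
        labels = classify_helicity(angles)
        assert np.count_nonzero(labels == "P") == 76
        assert np.count_nonzero(labels == "M") == 19
        assert np.count_nonzero(labels == "flipped") == 5

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-180, 180, allow_nan=False), min_size=1, max_size=50))
    def test_classification_is_a_partition(self, angles):
        labels = classify_helicity(np.asarray(angles))
        assert np.all(np.isin(labels, ["P", "M", "flipped"]))

    def test_fractions_sum_to_100_on_trajectory(self, jittered_fiber):
        _, topo, _, traj = jittered_fiber
        hel = helicity_fractions(traj, topo)
        total = hel.fraction_p + hel.fraction_m + hel.fraction_flipped
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_circular_and_arithmetic_means_agree_away_from_wrap(self, ideal_48mer):
        topo, frame = ideal_48mer
        a = helicity_fractions(frame, topo, circular_mean=False).mean_dihedral
        c = helicity_fractions(frame, topo, circular_mean=True).mean_dihedral
        assert a == pytest.approx(-140.0) and c == pytest.approx(-140.0)


class TestCountFlipped:
    def test_paper_scale_percentages(self):
        # 7 of 144 -> 5%, 23 of 144 -> 16% at the 48-monomer scale
        assert round(100 * 7 / 144) == 5
        assert round(100 * 23 / 144) == 16

    def test_ideal_fiber_has_none(self, ideal_48mer):
        topo, frame = ideal_48mer
        assert count_flipped(frame, topo) == (0.0, 0.0)

    def test_counts_positive_dihedrals(self, jittered_fiber):
        _, topo, _, traj = jittered_fiber
        count, pct = count_flipped(traj[0], topo)
        ang = amide_dihedrals(traj[0], topo)
        assert count == np.count_nonzero(ang > 0)
        assert pct == pytest.approx(100 * count / (3 * topo.n_monomers))


class TestHBonds:
    def test_ideal_fiber_has_three_bonds_per_interface(self, ideal_48mer):
        topo, frame = ideal_48mer
        present = detect_hbonds(frame, topo)
        assert len(present) == 3 * topo.n_monomers
        for b in present:
            gap = (b.donor_monomer - b.acceptor_monomer) % topo.n_monomers
            assert gap == 1

    def test_distant_pair_absent(self, ideal_48mer):
        topo, frame = ideal_48mer
        moved = frame.coords.copy()
        # push monomer 1's donors far off axis
        for am in topo.monomers[1].amides:
            moved[am.n] += np.array([50.0, 0, 0])
            moved[am.h] += np.array([50.0, 0, 0])
        present = detect_hbonds(FiberFrame(moved, frame.box_z), topo)
        donors_of_1 = {am.n for am in topo.monomers[1].amides}
        assert not any(b.donor_atom in donors_of_1 for b in present)

    def test_randomised_frame_matches_exhaustive_check(self, jittered_fiber, rng):
        _, topo, _, traj = jittered_fiber
        frame = traj[1]
        noisy = FiberFrame(
            frame.coords + rng.normal(0, 0.3, frame.coords.shape), frame.box_z
        )
        present = {
            (b.donor_atom, b.acceptor_atom)
            for b in detect_hbonds(noisy, topo, d_cut=3.5, angle_cut=120.0)
        }
        # brute force over every donor/acceptor pairing, same slot
        expected = set()
        c = noisy.coords
        for mi in topo.monomers:
            for mj in topo.monomers:
                if mi.index == mj.index:
                    continue
                for ai, aj in zip(mi.amides, mj.amides):
                    d = c[ai.n] - c[aj.o]
                    d[2] -= noisy.box_z * round(d[2] / noisy.box_z)
                    if np.linalg.norm(d) >= 3.5:
                        continue
                    v1 = c[ai.n] - c[ai.h]
                    v2 = c[aj.o] - c[ai.h]
                    v2[2] -= noisy.box_z * round(v2[2] / noisy.box_z)
                    cosang = v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 120.0:
                        expected.add((ai.n, aj.o))
        assert present == expected

    def test_occupancy_is_one_on_stable_trajectory(self, jittered_fiber):
        _, topo, _, traj = jittered_fiber
        table = hbond_occupancy(traj, topo)
        assert len(table.bonds) == 3 * topo.n_monomers
        assert np.allclose(table.occupancy, 1.0)


class TestPersistence:
    def test_strict_threshold(self):
        table = HBondTable(
            bonds=[HBond(0, 1, 0, 1, 2)] * 3,
            occupancy=[1.0, 0.96, 0.94],
            d_cut=3.5,
            angle_cut=120,
        )
        assert persistent_hbonds(table)[0] == 2

    def test_exactly_095_excluded(self):
        table = HBondTable(
            bonds=[HBond(0, 1, 0, 1, 2)], occupancy=[0.95], d_cut=3.5, angle_cut=120
        )
        assert persistent_hbonds(table, 0.95)[0] == 0

    def test_constructed_39_of_144(self, rng):
        occ = np.concatenate([rng.uniform(0.99, 1.0, 39), rng.uniform(0, 0.5, 105)])
        table = HBondTable(
            bonds=[HBond(0, 1, 0, 1, 2)] * 144, occupancy=occ, d_cut=3.5, angle_cut=120
        )
        assert persistent_hbonds(table)[0] == 39

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=30),
        st.floats(0.1, 0.99),
        st.floats(0.1, 0.99),
    )
    def test_monotone_in_threshold(self, occ, t1, t2):
        table = HBondTable(
            bonds=[HBond(0, 1, 0, 1, 2)] * len(occ),
            occupancy=occ,
            d_cut=3.5,
            angle_cut=120,
        )
        lo, hi = sorted((t1, t2))
        assert persistent_hbonds(table, hi)[0] <= persistent_hbonds(table, lo)[0]


class TestDimensionsAndContraction:
    def test_ideal_length_and_envelope(self, ideal_48mer):
        topo, frame = ideal_48mer
        length, (t_lo, t_hi) = fiber_dimensions(frame, topo)
        assert length == pytest.approx(16.32)
        assert t_lo == pytest.approx(6.8) and t_hi == pytest.approx(6.8)

    def test_compressed_frame_length(self, ideal_48mer):
        topo, frame = ideal_48mer
        short = FiberFrame(frame.coords, 95.0)
        assert fiber_dimensions(short, topo)[0] == pytest.approx(9.5)

    @pytest.mark.parametrize(
        "l0,leq,expected", [(16.3, 9.5, 42), (16.3, 7.1, 56), (10.0, 10.0, 0)]
    )
    def test_contraction_reference_values(self, l0, leq, expected):
        assert round(contraction(l0, leq)) == expected

    def test_elongation_gives_negative_percent(self):
        assert contraction(10.0, 12.0) < 0

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.01, 1.0), st.floats(1.0, 1e3))
    def test_fold_factor_identity(self, fold, l0):
        assert contraction(l0, fold * l0) == pytest.approx(100 * (1 - fold), abs=1e-9)


class TestSASA:
    def test_single_atom_closed_form(self):
        total, per = sasa(np.zeros((1, 3)), np.array([1.6]))
        assert total == pytest.approx(4 * np.pi * 3.0**2)
        assert per[0] == total

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        total, per = sasa(coords, np.array([1.6, 2.0]))
        assert total == pytest.approx(4 * np.pi * (3.0**2 + 3.4**2))
        assert per.sum() == pytest.approx(total)

    def test_overlapping_pair_matches_spherical_cap_formula(self):
        """Two overlapping spheres have an exact accessible area via the
        spherical-cap construction."""
        r1, r2, probe, d = 1.6, 1.4, 1.4, 2.5
        R1, R2 = r1 + probe, r2 + probe
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        total, per = sasa(coords, np.array([r1, r2]), probe=probe, n_points=2000)
        h1 = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
        h2 = R2 - (d**2 + R2**2 - R1**2) / (2 * d)
        exact1 = 4 * np.pi * R1**2 - 2 * np.pi * R1 * h1
        exact2 = 4 * np.pi * R2**2 - 2 * np.pi * R2 * h2
        assert per[0] == pytest.approx(exact1, rel=0.02)
        assert per[1] == pytest.approx(exact2, rel=0.02)

    def test_deterministic(self, rng):
        coords = rng.normal(size=(10, 3)) * 2
        radii = rng.uniform(1.2, 2.0, 10)
        a = sasa(coords, radii)
        b = sasa(coords, radii)
        assert a[0] == b[0] and np.array_equal(a[1], b[1])


class TestStableDomains:
    def test_constructed_run_recovered(self):
        vals = np.full(48, -3.0)
        vals[24:31] = -5.5
        assert detect_stable_domains(vals, min_run=5) == [(25, 31)]

    def test_all_equal_gives_no_runs(self):
        assert detect_stable_domains(np.full(10, -3.0), min_run=5) == []

    def test_alternating_profile_has_no_long_runs(self):
        vals = np.tile([-4.0, -2.0], 24)
        assert detect_stable_domains(vals, min_run=5) == []

    def test_periodic_wrap_merges_boundary_run(self):
        vals = np.full(20, 0.0)
        vals[:3] = -2.0
        vals[17:] = -2.0
        assert detect_stable_domains(vals, min_run=5, periodic=True) == [(18, 3)]
        assert detect_stable_domains(vals, min_run=5, periodic=False) == []
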