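"""H-bond detection, edge classification, distances, RMSD and time courses.

Detection is checked against an independent brute-force double loop over
all donor/acceptor pairs, against sharp synthetic threshold probes, and
against the scripted ground truth of generator trajectories.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.optimize import brentq

from ribocar import chemistry as chem
from ribocar import geometry as geom
from ribocar import synthetic as syn
from ribocar import templates as tpl
from ribocar.structure import Atom, AtomicStructure, Trajectory


# -- independent oracle ----------------------------------------------------

def brute_force_hbonds(frame, donors, acceptors, dist_cutoff=3.0,
                       angle_cutoff=135.0):
    """Plain double loop over all donor/acceptor combinations."""
    found = set()
    for don in donors:
        if not don.hydrogens:
            continue
        res = frame.residue(*don.residue)
        d = res.coord(don.heavy)
        for acc in acceptors:
            if acc.residue == don.residue:
                continue
            a = frame.residue(*acc.residue).coord(acc.atom)
            if not np.linalg.norm(a - d) < dist_cutoff:
                continue
            for h in don.hydrogens:
                hx = res.coord(h)
                u, v = d - hx, a - hx
                cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                if np.degrees(np.arccos(np.clip(cos, -1, 1))) >= angle_cutoff:
                    found.add((don.residue, don.heavy, acc.residue, acc.atom))
                    break
    return found


def event_keys(events):
    return {(e.donor_residue, e.donor_atom, e.acceptor_residue,
             e.acceptor_atom) for e in events}


def collinear_probe(distance, angle_deg):
    """Minimal donor/H/acceptor triplet with exact distance and angle.

    Donor N at the origin, acceptor O at (distance, 0, 0); the hydrogen sits
    at unit length from N, swung off axis until the N-H-O angle (vertex H)
    equals ``angle_deg``.
    """
    acc = np.array([distance, 0.0, 0.0])

    def ang(alpha):
        h = np.array([np.cos(alpha), np.sin(alpha), 0.0])
        return geom._angle_deg(np.zeros(3), h, acc)

    if angle_deg >= ang(0.0) - 1e-12:
        alpha = 0.0
    else:
        alpha = brentq(lambda a: ang(a) - angle_deg, 0.0, 0.9 * np.pi,
                       xtol=1e-14)
    h = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    atoms = [Atom("A", 1, "UNK", "N", "N"), Atom("A", 1, "UNK", "H", "H"),
             Atom("A", 2, "UNK", "O", "O")]
    s = AtomicStructure(atoms, np.array([np.zeros(3), h, acc]))
    donors = [geom.Donor(("A", 1), "UNK", "N", ("H",))]
    acceptors = [geom.Acceptor(("A", 2), "UNK", "O")]
    return s, donors, acceptors


# -- detection -------------------------------------------------------------

class TestDetectHBonds:
    def test_reverse_hoogsteen_ac_pair_two_named_bonds(self, ac_pair):
        # adenine N6 donates to cytosine N3; cytosine N4 donates to N7
        keys = event_keys(geom.detect_hbonds(ac_pair))
        assert keys == {
            (("A", 1), "N6", ("B", 1), "N3"),
            (("B", 1), "N4", ("A", 1), "N7"),
        }

    def test_wc_gc_pair_three_bonds(self, gc_pair):
        keys = event_keys(geom.detect_hbonds(gc_pair))
        assert keys == {
            (("B", 1), "N4", ("A", 1), "O6"),
            (("A", 1), "N1", ("B", 1), "N3"),
            (("A", 1), "N2", ("B", 1), "O2"),
        }

    def test_translated_pair_has_no_bonds(self, ac_pair):
        coords = ac_pair.coords.copy()
        idx = ac_pair.residue_index[("B", 1)]
        coords[idx] += np.array([10.0, 0.0, 0.0])
        assert geom.detect_hbonds(ac_pair.with_coords(coords)) == []

    def test_missing_hydrogens_diagnostic(self, ac_pair):
        bare = syn.strip_hydrogens(ac_pair)
        with pytest.raises(geom.MissingHydrogenError):
            geom.detect_hbonds(bare)

    def test_empty_structure_empty_list(self):
        s = AtomicStructure([Atom("A", 1, "GLY", "CA", "C")],
                            np.zeros((1, 3)))
        assert geom.detect_hbonds(s) == []

    @pytest.mark.parametrize("distance,expected", [
        (2.999, True), (3.001, False)])
    def test_distance_threshold_sharp(self, distance, expected):
        s, d, a = collinear_probe(distance, 180.0)
        assert bool(geom.detect_hbonds(s, d, a)) is expected

    @pytest.mark.parametrize("angle,expected", [
        (135.1, True), (134.9, False)])
    def test_angle_threshold_sharp(self, angle, expected):
        s, d, a = collinear_probe(2.8, angle)
        assert bool(geom.detect_hbonds(s, d, a)) is expected

    def test_oracle_equivalence_on_noisy_fixtures(self, ac_pair):
        traj = syn.make_trajectory(
            ac_pair, syn.TrajectorySpec(20, noise_sigma_A=0.3, seed=42))
        for f in range(traj.n_frames):
            frame = traj.frame(f)
            donors = geom.enumerate_donors(frame)
            acceptors = geom.enumerate_acceptors(frame)
            got = event_keys(geom.detect_hbonds(frame, donors, acceptors))
            want = brute_force_hbonds(frame, donors, acceptors)
            assert got == want

    def test_mean_count_non_increasing_with_noise(self, ac_pair):
        spec = geom.PairSpec(("A", 1), ("B", 1), "Hoogsteen", "WC",
                             ("hbond_count",))
        means = []
        for sigma in (0.0, 0.1, 0.3, 0.6):
            traj = syn.make_trajectory(
                ac_pair, syn.TrajectorySpec(200, noise_sigma_A=sigma,
                                            seed=11))
            (series,) = geom.series_extract(traj, [spec])
            means.append(series.mean())
        assert all(a >= b for a, b in zip(means, means[1:]))
        assert means[0] == pytest.approx(2.0)


# -- classification --------------------------------------------------------

class TestClassifyEdge:
    def test_reverse_hoogsteen_assignment(self, ac_pair):
        classified = geom.classify_edge(geom.detect_hbonds(ac_pair))
        by_donor = {c.event.donor_atom: c for c in classified}
        # A side engages its Hoogsteen face, C side its WC face
        assert by_donor["N6"].donor_edge == "Hoogsteen"
        assert by_donor["N6"].acceptor_edge == "WC"
        assert by_donor["N4"].donor_edge == "WC"
        assert by_donor["N4"].acceptor_edge == "Hoogsteen"

    def test_wc_pair_assignment(self, gc_pair):
        classified = geom.classify_edge(geom.detect_hbonds(gc_pair))
        assert all(c.donor_edge == "WC" and c.acceptor_edge == "WC"
                   for c in classified)

    def test_sugar_donor_is_off_edge(self, car_fixture):
        classified = geom.classify_edge(geom.detect_hbonds(car_fixture))
        sugar = [c for c in classified if c.event.donor_atom == "O2'"]
        assert sugar  # the stacked anticodon sugars touch
        assert all(c.donor_edge == "off-edge" for c in sugar)

    def test_guanidinium_edge_label(self):
        ev = geom.HBondEvent(0, ("P", 146), "ARG", "NH1", "HH11",
                             ("M", 8), "C", "O2", 2.9, 160.0)
        (c,) = geom.classify_edge([ev])
        assert c.donor_edge == "guanidinium"
        assert c.acceptor_edge == "WC"

    def test_unknown_residue_retained_unclassified(self):
        ev = geom.HBondEvent(0, ("A", 1), "XYZ", "N1", "H1",
                             ("B", 1), "C", "N3", 2.8, 150.0)
        (c,) = geom.classify_edge([ev])
        assert c.donor_edge == "unclassified"

    def test_empty_events_zero_counts(self):
        df = geom.edge_pair_counts(geom.classify_edge([]))
        assert len(df) == 0

    def test_counts_table(self, gc_pair):
        df = geom.edge_pair_counts(
            geom.classify_edge(geom.detect_hbonds(gc_pair)))
        assert df["n_bonds"].sum() == 3


# -- distances -------------------------------------------------------------

class TestDistances:
    def test_superposed_edges_zero(self):
        a = tpl.oriented_residue("C", "A", 1)
        b = tpl.oriented_residue("C", "B", 1)
        s = syn.merge_structures(a, b)
        assert geom.edge_distance(s, ("A", 1), "WC",
                                  ("B", 1), "WC") == pytest.approx(0.0)

    def test_rigid_translation_is_exact(self):
        a = tpl.oriented_residue("C", "A", 1)
        b = tpl.apply_rigid(tpl.oriented_residue("C", "B", 1), np.eye(3),
                            np.array([3.0, 0.0, 0.0]))
        s = syn.merge_structures(a, b)
        assert geom.edge_distance(s, ("A", 1), "WC", ("B", 1), "WC") == \
            pytest.approx(3.0, abs=1e-12)

    def test_com_matches_independent_oracle(self, ac_pair):
        def com(res, names):
            xyz = np.array([res.coord(n) for n in names])
            mass = np.array([chem.ATOMIC_MASS[n[0]] for n in names])
            return (xyz * mass[:, None]).sum(0) / mass.sum()

        res_a = ac_pair.residue("A", 1)
        res_b = ac_pair.residue("B", 1)
        want = np.linalg.norm(com(res_a, ["N6", "N7"])
                              - com(res_b, ["N4", "N3", "O2"]))
        got = geom.edge_distance(ac_pair, ("A", 1), "Hoogsteen",
                                 ("B", 1), "WC")
        assert got == pytest.approx(want, abs=1e-9)

    def test_missing_edge_atoms_reported(self, ac_pair):
        bare = syn.strip_hydrogens(ac_pair)
        coords_keep = [i for i, a in enumerate(bare.atoms)
                       if not (a.chain_id == "B" and a.atom_name == "N3")]
        cut = AtomicStructure([bare.atoms[i] for i in coords_keep],
                              bare.coords[coords_keep])
        with pytest.raises(geom.GeometryError, match="N3"):
            geom.edge_distance(cut, ("A", 1), "WC", ("B", 1), "WC")


class TestGuanidinium:
    @staticmethod
    def _arg_and_partner(target_point):
        arg = tpl.oriented_residue("ARG", "P", 146)
        c = tpl.oriented_residue("C", "M", 8)
        s0 = syn.merge_structures(arg, c)
        shift = target_point - geom.edge_com(s0, ("M", 8), "WC")
        c = tpl.apply_rigid(c, np.eye(3), shift)
        return syn.merge_structures(arg, c)

    @staticmethod
    def _branch_coms(s):
        res = s.residue("P", 146)
        m = {n: res.coord(n) for n in ("NE", "NH1", "NH2")}
        w = chem.ATOMIC_MASS["N"]
        com1 = (m["NE"] + m["NH1"]) / 2
        com2 = (m["NE"] + m["NH2"]) / 2
        return com1, com2

    def test_partner_at_ne_nh1_com_gives_zero(self):
        arg = tpl.oriented_residue("ARG", "P", 146)
        com1, _ = self._branch_coms(arg)
        s = self._arg_and_partner(com1)
        d = geom.guanidinium_edge_distance(s, ("P", 146), ("M", 8))
        assert d.distance_A == pytest.approx(0.0, abs=1e-9)
        assert d.branch == "NE,NH1"

    def test_closer_nh2_branch_wins(self):
        arg = tpl.oriented_residue("ARG", "P", 146)
        _, com2 = self._branch_coms(arg)
        s = self._arg_and_partner(com2 + np.array([0.0, 0.0, 1.0]))
        d = geom.guanidinium_edge_distance(s, ("P", 146), ("M", 8))
        # both branch values computed explicitly
        com1, com2b = self._branch_coms(s)
        target = geom.edge_com(s, ("M", 8), "WC")
        d1 = np.linalg.norm(com1 - target)
        d2 = np.linalg.norm(com2b - target)
        assert d2 < d1
        assert d.branch == "NE,NH2"
        assert d.distance_A == pytest.approx(d2, abs=1e-9)

    def test_exact_tie_resolves_to_ne_nh1(self):
        arg = tpl.oriented_residue("ARG", "P", 146)
        com1, com2 = self._branch_coms(arg)
        s = self._arg_and_partner((com1 + com2) / 2.0)
        d = geom.guanidinium_edge_distance(s, ("P", 146), ("M", 8))
        assert d.branch == "NE,NH1"
        assert d.distance_A == pytest.approx(
            np.linalg.norm((com2 - com1) / 2), abs=1e-9)


class TestStacking:
    def test_generator_rise_recovered_exactly(self):
        s = syn.make_stack("C", "A", rise=3.9)
        assert geom.stacking_distance(s, ("A", 1), ("B", 1)) == \
            pytest.approx(3.9, abs=1e-6)

    def test_parallel_rings_at_normal_offset(self):
        s = syn.make_stack("C", "C", rise=3.5, twist_deg=0.0)
        assert geom.stacking_distance(s, ("A", 1), ("B", 1)) == \
            pytest.approx(3.5, abs=1e-9)

    def test_ring_with_itself_zero(self):
        s = tpl.oriented_residue("A", "A", 1)
        assert geom.stacking_distance(s, ("A", 1), ("A", 1)) == 0.0

    def test_guanidinium_group_as_ring(self, car_fixture):
        d = geom.stacking_distance(car_fixture, ("R", 1196), ("P", 146))
        assert 3.5 <= d <= 4.0


class TestBackboneRMSD:
    def test_identical_frames_zero(self, strand10):
        traj = Trajectory(strand10, np.repeat(strand10.coords[None], 3,
                                              axis=0))
        series = geom.backbone_rmsd(traj, strand10)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_rigid_motion_removed(self, strand10):
        rot = tpl.rot_z(0.7) @ tpl.rot_x(0.3)
        frames = np.stack([
            strand10.coords,
            strand10.coords @ rot.T + np.array([5.0, -2.0, 1.0]),
        ])
        series = geom.backbone_rmsd(Trajectory(strand10, frames), strand10)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_single_atom_displacement_closed_form(self, strand10):
        from ribocar.geometry import _backbone_indices
        idx = _backbone_indices(strand10, None)
        n = len(idx)
        d = 0.8
        coords = strand10.coords.copy()
        coords[idx[3]] += np.array([0.0, 0.0, d])
        traj = Trajectory(strand10, coords[None])
        raw = geom.backbone_rmsd(traj, strand10, superpose=False)
        assert raw.values[0] == pytest.approx(d / np.sqrt(n), abs=1e-12)
        fitted = geom.backbone_rmsd(traj, strand10, superpose=True)
        assert fitted.values[0] <= d / np.sqrt(n) + 1e-12

    def test_selection_mismatch_raises(self, strand10, ac_pair):
        traj = Trajectory(strand10, strand10.coords[None])
        with pytest.raises(geom.GeometryError):
            geom.backbone_rmsd(traj, ac_pair)


# -- time courses ----------------------------------------------------------

class TestSeriesExtract:
    def test_scripted_schedule_recovered(self, ac_pair):
        pair = (("A", 1), ("B", 1))
        spec = syn.TrajectorySpec(200, noise_sigma_A=0.0, seed=0,
                                  schedule={pair: ((0, 100),)})
        traj = syn.make_trajectory(ac_pair, spec)
        (series,) = geom.series_extract(
            traj, [geom.PairSpec(*pair, "Hoogsteen", "WC",
                                 ("hbond_count",))])
        np.testing.assert_array_equal(series.values[:100] > 0, True)
        np.testing.assert_array_equal(series.values[100:] > 0, False)

    def test_stride_rescales_time_axis(self, ac_pair):
        traj = syn.make_trajectory(ac_pair, syn.TrajectorySpec(
            200, frames_per_ns=100.0))
        (series,) = geom.series_extract(
            traj, [geom.PairSpec(("A", 1), ("B", 1), "Hoogsteen", "WC",
                                 ("hbond_count",))], stride=10)
        assert series.frames_per_ns == pytest.approx(10.0)
        assert len(series) == 20

    def test_single_frame_length_one(self, ac_pair):
        traj = syn.make_trajectory(ac_pair, syn.TrajectorySpec(1))
        series = geom.series_extract(
            traj, [geom.PairSpec(("A", 1), ("B", 1), "Hoogsteen", "WC")])
        assert all(len(s) == 1 for s in series)

    def test_empty_pair_spec_rejected(self, ac_pair):
        traj = syn.make_trajectory(ac_pair, syn.TrajectorySpec(1))
        with pytest.raises(ValueError):
            geom.series_extract(traj, [])

    def test_distance_metric_uses_guanidinium_rule(self, car_fixture):
        traj = Trajectory(car_fixture, car_fixture.coords[None])
        (series,) = geom.series_extract(
            traj, [geom.PairSpec(("P", 146), ("M", 8), None, "WC",
                                 ("distance",))])
        want = geom.guanidinium_edge_distance(
            car_fixture, ("P", 146), ("M", 8), "WC").distance_A
        assert series.values[0] == pytest.approx(want)


class TestBinSeries:
    def test_constant_series(self):
        s = geom.MetricSeries("m", "p", np.full(250, 1.7), 100.0)
        binned = geom.bin_series(s, 1.0)
        np.testing.assert_allclose(binned.bin_means, 1.7)
        assert binned.last_bin_partial

    def test_two_full_bins_from_200_frames(self):
        s = geom.MetricSeries("m", "p", np.arange(200.0), 100.0)
        binned = geom.bin_series(s, 1.0)
        assert list(binned.bin_counts) == [100, 100]
        assert not binned.last_bin_partial

    def test_weighted_bin_means_conserve_global_mean(self):
        rng = np.random.default_rng(5)
        s = geom.MetricSeries("m", "p", rng.normal(0, 2, 173), 100.0)
        binned = geom.bin_series(s, 0.37)
        pooled = np.average(binned.bin_means, weights=binned.bin_counts)
        assert pooled == pytest.approx(s.values.mean(), abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(n=hst.integers(1, 400),
           rate=hst.sampled_from([10.0, 100.0]),
           bin_ns=hst.floats(0.05, 3.0))
    def test_conservation_property(self, n, rate, bin_ns):
        rng = np.random.default_rng(n)
        s = geom.MetricSeries("m", "p", rng.normal(size=n), rate)
        binned = geom.bin_series(s, bin_ns)
        assert int(binned.bin_counts.sum()) == n
        pooled = np.average(binned.bin_means, weights=binned.bin_counts)
        assert pooled == pytest.approx(s.values.mean(), abs=1e-9)
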