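"""Contact maps, separation maps, distance series and salt bridges."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ppstab import interface, synthetic as syn
from ppstab.io import ComplexDefinition, Selection, Structure, Trajectory

from conftest import make_structure, translated_copy_complex


def _two_ca_structure(distance):
    return make_structure([
        ("A", 1, "ALA", {"CA": (0.0, 0.0, 0.0)}),
        ("B", 1, "ALA", {"CA": (distance, 0.0, 0.0)}),
    ])


def _cdef():
    return ComplexDefinition(Selection("A"), (Selection("B"),))


class TestContactMap:
    @pytest.mark.parametrize("d, expected", [(4.9, True), (5.1, False)])
    def test_cutoff_boundary(self, d, expected):
        cmap = interface.contact_map(_two_ca_structure(d), _cdef(), 5.0, "calpha")
        assert bool(cmap.matrix[0, 0]) is expected

    def test_counts_match_brute_force(self, toy_complex):
        cplx, cdef = toy_complex
        cmap = interface.contact_map(cplx, cdef, 5.0, "heavy")
        atoms = cplx.atoms
        heavy = atoms.element != "H"
        brute = 0
        for rk in cmap.receptor_residues:
            for pk in cmap.partner_residues:
                ra = atoms.coord[(atoms.chain_id == rk[0]) & (atoms.res_id == rk[1]) & heavy]
                pb = atoms.coord[(atoms.chain_id == pk[0]) & (atoms.res_id == pk[1]) & heavy]
                dmin = min(
                    float(np.linalg.norm(a - b)) for a in ra for b in pb
                )
                if dmin < 5.0:
                    brute += 1
        assert cmap.n_contacts == brute

    def test_monotone_in_cutoff(self, toy_complex):
        cplx, cdef = toy_complex
        small = interface.contact_map(cplx, cdef, 4.0)
        large = interface.contact_map(cplx, cdef, 6.0)
        assert (~small.matrix | large.matrix).all()  # small subset of large

    def test_bad_cutoff(self, toy_complex):
        cplx, cdef = toy_complex
        with pytest.raises(ValueError):
            interface.contact_map(cplx, cdef, 0.0)


class TestSeparationChange:
    def test_identical_frames_zero(self, toy_complex):
        cplx, cdef = toy_complex
        traj = syn.trajectory_bound(cplx, 0.0, 5, seed=1)
        smap = interface.separation_change(traj, cdef)
        assert np.abs(smap.delta).max() == 0.0

    def test_pure_drift_on_axis_pairs_is_exact(self):
        """A rigid +5 A partner translation gives delta d = -5 exactly for
        Calpha pairs parallel to the drift axis."""
        cplx, cdef = translated_copy_complex(offset=8.0)
        coords = np.stack([cplx.atoms.coord.astype(float)] * 2)
        partner = cdef.partner_mask(cplx.atoms)
        coords[1][partner] += [5.0, 0.0, 0.0]
        traj = Trajectory(cplx.atoms, coords)
        smap = interface.separation_change(traj, cdef)
        assert np.abs(np.diag(smap.delta) + 5.0).max() < 1e-9

    def test_swap_negates(self, dissociating_trajectory):
        traj, cdef = dissociating_trajectory
        fwd = interface.separation_change(traj, cdef, 0, -1)
        rev = interface.separation_change(traj, cdef, -1, 0)
        assert np.allclose(fwd.delta, -rev.delta)

    def test_rigid_whole_frame_motion_invariant(self, dissociating_trajectory):
        traj, cdef = dissociating_trajectory
        ref = interface.separation_change(traj, cdef)
        rot = Rotation.from_euler("xyz", [1.0, 0.5, -0.7]).as_matrix()
        moved = Trajectory(traj.topology, traj.coords @ rot.T + 3.0)
        alt = interface.separation_change(moved, cdef)
        assert np.allclose(ref.delta, alt.delta, atol=1e-9)

    def test_same_frame_errors(self, dissociating_trajectory):
        traj, cdef = dissociating_trajectory
        with pytest.raises(ValueError):
            interface.separation_change(traj, cdef, 0, 0)


class TestDistanceSeries:
    def test_constant_geometry_zero_spread(self, toy_complex):
        cplx, cdef = toy_complex
        traj = syn.trajectory_bound(cplx, 0.0, 10, seed=2)
        series = interface.cb_distance_series(traj, ("A", 5), ("B", 3))
        assert np.std(series.distances) == 0.0
        summary = interface.distribution_summary(series)
        assert summary.iqr == 0.0

    def test_jitter_spread_matches_generator(self, toy_complex):
        """With per-atom jitter sigma the CB-CB distance spread must match
        a direct Monte-Carlo resampling of the same generator model."""
        cplx, cdef = toy_complex
        sigma = 0.3
        traj = syn.trajectory_bound(cplx, sigma, 1000, seed=3)
        series = interface.cb_distance_series(traj, ("A", 5), ("B", 3))
        atoms = cplx.atoms
        a = atoms.coord[(atoms.chain_id == "A") & (atoms.res_id == 5)
                        & (atoms.atom_name == "CB")][0].astype(float)
        b = atoms.coord[(atoms.chain_id == "B") & (atoms.res_id == 3)
                        & (atoms.atom_name == "CB")][0].astype(float)
        rng = np.random.default_rng(99)
        mc = np.linalg.norm(
            (a + rng.normal(0, sigma, (20000, 3)))
            - (b + rng.normal(0, sigma, (20000, 3))), axis=1)
        assert np.std(series.distances) == pytest.approx(np.std(mc), rel=0.15)

    def test_glycine_flagged_as_surrogate(self):
        s = make_structure([
            ("A", 1, "GLY", {"CA": (0.0, 0.0, 0.0)}),
            ("B", 1, "ALA", {"CA": (6.0, 0.0, 0.0), "CB": (5.0, 0.0, 0.0)}),
        ])
        traj = Trajectory(s.atoms, s.atoms.coord[None])
        series = interface.cb_distance_series(traj, ("A", 1), ("B", 1))
        assert series.surrogate
        assert series.distances[0] == pytest.approx(5.0)

    def test_missing_residue_errors(self, toy_complex):
        cplx, cdef = toy_complex
        traj = syn.trajectory_bound(cplx, 0.0, 2, seed=4)
        with pytest.raises(KeyError):
            interface.cb_distance_series(traj, ("A", 999), ("B", 1))


class TestDistributionSummary:
    def test_fraction_below_threshold(self):
        series = interface.DistanceSeries(("A", 1), ("B", 1), "CB",
                                          np.array([3.0, 3.0, 3.0, 9.0]))
        summary = interface.distribution_summary(series, threshold=5.0)
        assert summary.fraction_below == pytest.approx(0.75)

    def test_median_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(2, 12, size=301)
        series = interface.DistanceSeries(("A", 1), ("B", 1), "CB", d)
        summary = interface.distribution_summary(series)
        assert summary.median == pytest.approx(np.sort(d)[150])

    def test_histogram_grid_deterministic(self):
        series = interface.DistanceSeries(("A", 1), ("B", 1), "CB",
                                          np.array([3.1, 3.4, 4.9]))
        summary = interface.distribution_summary(series)
        assert np.allclose(summary.bin_edges % 0.25, 0, atol=1e-9)
        assert summary.counts.sum() == 3


def _salt_bridge_frames(distances_nz_oe1, d_oe2_extra=0.7):
    """Frames of a LYS/GLU pair whose NZ-OE1 distance follows the series."""
    frames = []
    for d in distances_nz_oe1:
        frames.append([
            ("A", 1, "LYS", {"CA": (0.0, 0.0, 0.0), "CB": (1.5, 0.0, 0.0),
                             "NZ": (3.0, 0.0, 0.0)}),
            ("B", 2, "GLU", {"CA": (10.0, 0.0, 0.0), "CB": (8.5, 0.0, 0.0),
                             "OE1": (3.0 + d, 0.0, 0.0),
                             "OE2": (3.0 + d + d_oe2_extra, 0.0, 0.0)}),
        ])
    base = make_structure(frames[0])
    coords = np.stack([
        make_structure(f).atoms.coord.astype(float) for f in frames
    ])
    return Trajectory(base.atoms, coords)


class TestSaltBridge:
    def test_minimum_over_group_atoms(self):
        traj = _salt_bridge_frames([2.8])
        series = interface.salt_bridge_series(traj, ("B", 2), ("A", 1))
        assert series.distances[0] == pytest.approx(2.8, abs=1e-6)
        assert not series.surrogate

    def test_non_acidic_first_argument_errors(self):
        traj = _salt_bridge_frames([2.8])
        with pytest.raises(ValueError, match="acidic"):
            interface.salt_bridge_series(traj, ("A", 1), ("B", 2))

    def test_crossing_series_matches_hand_enumeration(self):
        """10 constructed frames crossing the 4 A cutoff in 6 frames."""
        dists = [2.5, 3.0, 3.5, 3.9, 3.2, 2.8, 4.5, 5.0, 6.0, 7.0]
        traj = _salt_bridge_frames(dists)
        series = interface.salt_bridge_series(traj, ("B", 2), ("A", 1))
        frac, persistent = interface.persistence(series, cutoff=4.0)
        assert frac == pytest.approx(6 / 10)
        assert persistent

    def test_cbeta_only_model_is_surrogate(self):
        s = make_structure([
            ("A", 1, "LYS", {"CA": (0.0, 0.0, 0.0), "CB": (1.5, 0.0, 0.0)}),
            ("B", 2, "GLU", {"CA": (8.0, 0.0, 0.0), "CB": (6.5, 0.0, 0.0)}),
        ])
        traj = Trajectory(s.atoms, s.atoms.coord[None])
        series = interface.salt_bridge_series(traj, ("B", 2), ("A", 1))
        assert series.surrogate
        assert series.distances[0] == pytest.approx(5.0)


class TestPersistence:
    def test_simple_fraction(self):
        series = interface.DistanceSeries(("A", 1), ("B", 1), "CB",
                                          np.array([3.0, 3, 5, 5, 3]))
        frac, persistent = interface.persistence(series, cutoff=4.0)
        assert frac == pytest.approx(0.6)
        assert persistent

    def test_all_below(self):
        series = interface.DistanceSeries(("A", 1), ("B", 1), "CB",
                                          np.full(7, 2.0))
        assert interface.persistence(series)[0] == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.5, 10.0), min_size=1, max_size=60),
           st.floats(1.0, 8.0))
    def test_matches_counting_oracle_and_reorder_invariance(self, values, cutoff):
        d = np.array(values)
        series = interface.DistanceSeries(("A", 1), ("B", 1), "CB", d)
        frac, _ = interface.persistence(series, cutoff=cutoff)
        assert frac == pytest.approx(sum(v < cutoff for v in values) / len(values))
        shuffled = interface.DistanceSeries(
            ("A", 1), ("B", 1), "CB", d[np.argsort(np.sin(d))])
        assert interface.persistence(shuffled, cutoff=cutoff)[0] == pytest.approx(frac)
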