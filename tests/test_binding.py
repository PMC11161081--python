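"""Occupancy rules: nearest-peptide ranking, strict cutoffs, blocks, events."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_system, random_rotation, standard_anchors

from discbind.binding import (
    block_stats,
    frame_occupied,
    helix_occupancy,
    longest_event,
    nearest_peptide,
    occupancy,
)
from discbind.trajectory import (
    AnalysisWindow,
    BeadMeta,
    FULLLENGTH_SITE,
    MolType,
    NANODISC_SITE,
)

W = AnalysisWindow(t_start_ns=0.0, n_blocks=3)
W1 = AnalysisWindow(t_start_ns=0.0, n_blocks=1)

# anchor points implied by standard_anchors(): G226 at origin,
# midpoint(W48, I237) at (10, 1, 0), W48 at (10, 0, 0)
A1 = np.array([0.0, 0.0, 0.0])
A2 = np.array([10.0, 1.0, 0.0])
A3 = np.array([10.0, 0.0, 0.0])


def system_with_constraint_distances(*pep_dists, times=(0.0,)):
    """Peptides whose residues 2/11/20 sit at given distances from the anchors."""
    peptides = {}
    for k, (d1, d2, d3) in enumerate(pep_dists, start=1):
        peptides[k] = {
            2: A1 + [0.0, 0.0, d1],
            11: A2 + [0.0, 0.0, d2],
            20: A3 + [0.0, 0.0, d3],
        }
    return build_system(times, lcat=standard_anchors(), peptides=peptides)


class TestNearestPeptide:
    def test_coincident_peptide_has_zero_distances(self):
        traj = system_with_constraint_distances((0.0, 0.0, 0.0))
        pid, d, comb = nearest_peptide(traj, 0, NANODISC_SITE)
        assert pid == 1
        np.testing.assert_allclose(d, [0, 0, 0], atol=1e-12)
        assert comb == 0.0

    def test_smallest_combined_distance_wins(self):
        # A: (0.9, 0.9, 1.9) sum 3.7 -- B: (0.5, 1.2, 1.5) sum 3.2
        traj = system_with_constraint_distances((0.9, 0.9, 1.9), (0.5, 1.2, 1.5))
        pid, d, comb = nearest_peptide(traj, 0, NANODISC_SITE)
        assert pid == 2
        np.testing.assert_allclose(d, [0.5, 1.2, 1.5], atol=1e-12)
        assert comb == pytest.approx(3.2, abs=1e-12)

    def test_nearest_failing_a_cutoff_leaves_frame_unoccupied(self):
        # B is nearest but violates the 1 nm second cutoff even though A
        # satisfies every cutoff: occupancy follows the nearest peptide only
        traj = system_with_constraint_distances((0.9, 0.9, 1.9), (0.5, 1.2, 1.5))
        assert not frame_occupied(traj, 0, NANODISC_SITE)

    def test_tie_broken_by_lowest_mol_id(self):
        traj = system_with_constraint_distances((0.7, 0.7, 0.7), (0.7, 0.7, 0.7))
        pid, _, _ = nearest_peptide(traj, 0, NANODISC_SITE)
        assert pid == 1

    def test_no_peptides_is_an_error(self):
        traj = build_system([0.0], lcat=standard_anchors(),
                            peptides={1: {(1, "SC1"): (0, 0, 0)}})
        # a bead exists but not the required BB residue-2 bead
        with pytest.raises(KeyError, match="residue 2"):
            nearest_peptide(traj, 0, NANODISC_SITE)


class TestFrameOccupied:
    def test_all_distances_just_under_cutoffs(self):
        traj = system_with_constraint_distances((0.99, 0.99, 1.99))
        assert frame_occupied(traj, 0, NANODISC_SITE)

    def test_boundary_distance_is_not_occupied(self):
        # "less than" is strict: 1.00 on the first cutoff fails
        traj = system_with_constraint_distances((1.0, 0.5, 0.5))
        assert not frame_occupied(traj, 0, NANODISC_SITE)


class TestBlockStats:
    def test_constant_series_has_zero_std(self):
        bs = block_stats([5.0] * 30, 3)
        assert bs.std == 0.0 and bs.mean == 5.0

    def test_closed_form_three_blocks(self):
        series = [1.0] * 10 + [2.0] * 10 + [3.0] * 10
        bs = block_stats(series, 3)
        assert bs.block_means == (1.0, 2.0, 3.0)
        assert bs.mean == pytest.approx(2.0)
        assert bs.std == pytest.approx(1.0)  # sample std, n-1 denominator

    def test_single_block_flags_and_reports_zero(self):
        with pytest.warns(UserWarning, match="single block"):
            bs = block_stats([1.0, 2.0], 1)
        assert bs.std == 0.0 and bs.single_block

    def test_remainder_goes_to_last_block(self):
        bs = block_stats([0.0, 0.0, 3.0, 3.0, 3.0], 2)
        assert bs.block_means == (0.0, 3.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            block_stats([1.0], 2)
        with pytest.raises(ValueError):
            block_stats([1.0], 0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=60))
    def test_mean_of_block_means_matches_series_mean_when_even(self, series):
        n = 3 * (len(series) // 3)
        bs = block_stats(series[:n], 3)
        assert bs.mean == pytest.approx(np.mean(bs.block_means), abs=1e-9)


class TestOccupancy:
    def test_window_excludes_early_occupied_frames(self):
        far = (5.0, 5.0, 5.0)
        near = (0.5, 0.5, 0.5)
        # occupied only in the first half; analysis starts afterwards
        pep = {
            2: np.array([A1 + [0, 0, (near if t < 3 else far)[0]] for t in range(6)]),
            11: np.array([A2 + [0, 0, (near if t < 3 else far)[1]] for t in range(6)]),
            20: np.array([A3 + [0, 0, (near if t < 3 else far)[2]] for t in range(6)]),
        }
        traj = build_system(np.arange(6.0), lcat=standard_anchors(),
                            peptides={1: pep})
        occ = occupancy(traj, NANODISC_SITE, AnalysisWindow(3.0, 3))
        assert occ.occupancy_pct == 0.0 and occ.events == []

    def test_all_far_peptides_give_zero_and_no_events(self):
        traj = system_with_constraint_distances(
            (5.0, 5.0, 5.0), (6.0, 6.0, 6.0), times=np.arange(9.0))
        occ = occupancy(traj, NANODISC_SITE, W)
        assert occ.occupancy_pct == 0.0 and occ.events == []

    def test_zero_analyzed_frames_is_error_not_zero(self):
        traj = system_with_constraint_distances((0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="no frames"):
            occupancy(traj, NANODISC_SITE, AnalysisWindow(1000.0, 1))

    def test_rigid_motion_invariance(self, rng):
        traj = system_with_constraint_distances(
            (0.8, 0.9, 1.5), (2.0, 0.3, 0.4), times=np.arange(6.0))
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, 3)
        moved = traj.transformed(R, t)
        a = occupancy(traj, NANODISC_SITE, W)
        b = occupancy(moved, NANODISC_SITE, W)
        assert np.array_equal(a.occupied, b.occupied)
        assert np.array_equal(a.occupant, b.occupant)
        np.testing.assert_allclose(a.distances, b.distances, atol=1e-9)

    def test_matches_bruteforce_on_random_instances(self, rng):
        site = NANODISC_SITE
        for _ in range(30):
            F = int(rng.integers(2, 12))
            P = int(rng.integers(1, 6))
            peptides = {
                pid: {r: rng.uniform(0, 5, (F, 3)) for r in (2, 11, 20)}
                for pid in range(1, P + 1)
            }
            lcat = {r: rng.uniform(0, 5, (F, 3)) for r in (48, 226, 237)}
            lcat.update({229: (0, 0, 0), 239: (0, 0, 0)})
            traj = build_system(np.arange(float(F)), lcat=lcat, peptides=peptides)
            occ = occupancy(traj, site, W1)
            # independent re-evaluation: loop every peptide every frame
            for f in range(F):
                anchors = [
                    lcat[226] if np.ndim(lcat[226]) == 2 else np.asarray(lcat[226]),
                    0.5 * (np.asarray(lcat[48]) + np.asarray(lcat[237])),
                    np.asarray(lcat[48]),
                ]
                best, best_sum, best_d = None, np.inf, None
                for pid in range(1, P + 1):
                    ds = []
                    for (r, a) in zip((2, 11, 20), anchors):
                        apos = a[f] if a.ndim == 2 else a
                        ds.append(np.linalg.norm(peptides[pid][r][f] - apos))
                    if sum(ds) < best_sum:
                        best, best_sum, best_d = pid, sum(ds), ds
                expect = all(d < c for d, c in zip(best_d, (1.0, 1.0, 2.0)))
                assert occ.occupant[f] == best
                assert bool(occ.occupied[f]) == expect


class TestEvents:
    def test_no_events_longest_zero(self):
        traj = system_with_constraint_distances((5, 5, 5), times=np.arange(3.0))
        assert longest_event(occupancy(traj, NANODISC_SITE, W1)) == 0.0

    def test_event_duration_includes_one_frame_spacing(self):
        # occupied runs of 3 then 5 frames at 0.1 ns spacing -> longest 0.5 ns
        on = [1, 1, 1, 0, 1, 1, 1, 1, 1, 0]
        z = np.array([[0, 0, 0.5 if o else 5.0] for o in on])
        pep = {2: A1 + z, 11: A2 + z, 20: A3 + z}
        traj = build_system(np.arange(10) * 0.1, lcat=standard_anchors(),
                            peptides={1: pep})
        occ = occupancy(traj, NANODISC_SITE, W1)
        assert len(occ.events) == 2
        assert longest_event(occ) == pytest.approx(0.5)

    def test_occupant_switch_splits_event(self):
        F = 4
        near = np.array([0, 0, 0.5])
        far = np.array([0, 0, 5.0])
        # peptide 1 occupies frames 0-1, peptide 2 frames 2-3 (no gap)
        p1 = {r: np.array([a + (near if f < 2 else far) for f in range(F)])
              for r, a in ((2, A1), (11, A2), (20, A3))}
        p2 = {r: np.array([a + (far if f < 2 else near) for f in range(F)])
              for r, a in ((2, A1), (11, A2), (20, A3))}
        traj = build_system(np.arange(float(F)), lcat=standard_anchors(),
                            peptides={1: p1, 2: p2})
        occ = occupancy(traj, NANODISC_SITE, W1)
        assert occ.occupancy_pct == 100.0
        assert [e.occupant for e in occ.events] == [1, 2]


class TestHelixOccupancy:
    def anchors(self):
        a = standard_anchors()
        return a

    def test_coincident_helix_is_occupied_others_not(self):
        a = self.anchors()
        q229, l239 = np.asarray(a[229]), np.asarray(a[239])
        chain = {}
        # helix A at residues 10-31: residue 11 and 29 on the anchors
        chain[11] = q229 + [0.0, 0.0, 0.3]
        chain[29] = l239 + [0.0, 0.0, 0.3]
        # helix B at residues 40-61: far away
        chain[41] = (50.0, 0.0, 0.0)
        chain[59] = (50.0, 1.0, 0.0)
        traj = build_system([0.0], lcat=a, peptides={1: chain})
        tab = helix_occupancy(traj, [("A", 10, 31), ("B", 40, 61)])
        assert bool(tab["A"].iloc[0]) and not bool(tab["B"].iloc[0])

    def test_short_helix_range_is_error(self):
        traj = build_system([0.0], lcat=self.anchors(),
                            peptides={1: {11: (0, 0, 0), 29: (0, 0, 0)}})
        with pytest.raises(ValueError, match="at least 20"):
            helix_occupancy(traj, [("short", 10, 25)])

    def test_planted_alternation_recovered_exactly(self):
        a = self.anchors()
        q229, l239 = np.asarray(a[229]), np.asarray(a[239])
        F = 6
        near = np.array([0.0, 0.0, 0.5])
        far = np.array([0.0, 0.0, 30.0])
        chain = {
            11: np.array([q229 + (near if f % 2 == 0 else far) for f in range(F)]),
            29: np.array([l239 + (near if f % 2 == 0 else far) for f in range(F)]),
            41: np.array([q229 + (near if f % 2 == 1 else far) for f in range(F)]),
            59: np.array([l239 + (near if f % 2 == 1 else far) for f in range(F)]),
        }
        traj = build_system(np.arange(float(F)), lcat=a, peptides={1: chain})
        tab = helix_occupancy(traj, [("even", 10, 31), ("odd", 40, 61)])
        assert list(tab["even"]) == [True, False] * 3
        assert list(tab["odd"]) == [False, True] * 3
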