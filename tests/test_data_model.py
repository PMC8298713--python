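"""Observation-table IO, trajectory assembly, triplet and pairing rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chemodetect import (ConsistencyError, FormatError, ObservationTable,
                         Trajectory, build_trajectories, extract_triplets,
                         filter_min_triplets, load_observations,
                         pair_with_targets, write_observations)
from chemodetect.data_model import count_triplet_candidates


def _table(rows, **kw):
    return ObservationTable(
        pd.DataFrame(rows, columns=["t", "x", "y", "z", "id", "class"]), **kw)


def _walk_trajectory(length, step=2.0, cell_id=0, missing=()):
    """Deterministic zig-zag trajectory with strictly positive step widths."""
    ts = [t for t in range(length) if t not in missing]
    xyz = np.array([[step * t, 1.0 * (t % 2), 0.0] for t in ts])
    return Trajectory(cell_id, 0, np.array(ts), xyz)


class TestTableIO:
    def test_round_trip_is_lossless(self, tmp_path):
        rows = [(t, 1.5 * t + 0.123456789, -2.0 * t, 0.5, cid, cid % 2)
                for cid in (3, 7) for t in range(3)]
        table = _table(rows, frame_interval=0.25)
        path = tmp_path / "obs.csv"
        write_observations(table, path)
        back = load_observations(path, frame_interval=0.25)
        pd.testing.assert_frame_equal(table.data, back.data)
        assert len(back) == 6
        assert len(build_trajectories(back)) == 2

    def test_duplicate_detection_is_rejected_with_location(self):
        rows = [(3, 0.0, 0.0, 0.0, 7, 0), (3, 1.0, 0.0, 0.0, 7, 0)]
        with pytest.raises(ConsistencyError, match="id 7.*t=3"):
            _table(rows)

    def test_missing_column_and_bad_coordinate_are_format_errors(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t,x,y,id,class\n0,1,2,0,0\n")
        with pytest.raises(FormatError, match="z"):
            load_observations(path)
        path.write_text("t,x,y,z,id,class\n0,1,2,0,0,0\n1,oops,2,0,0,0\n")
        with pytest.raises(FormatError, match="row 1"):
            load_observations(path)

    def test_unknown_class_label_rejected(self):
        with pytest.raises(FormatError, match="class"):
            _table([(0, 0.0, 0.0, 0.0, 1, 2)])


class TestTrajectories:
    def test_gap_is_recorded(self):
        rows = [(t, 1.0 * t, 0.0, 0.0, 0, 0) for t in (0, 1, 2, 4)]
        (traj,) = build_trajectories(_table(rows))
        assert list(traj.missing_frames) == [3]
        assert list(traj.t) == [0, 1, 2, 4]

    def test_empty_table_gives_empty_list(self):
        assert build_trajectories(_table([])) == []

    def test_class_change_within_cell_is_inconsistent(self):
        rows = [(0, 0.0, 0.0, 0.0, 5, 0), (1, 1.0, 0.0, 0.0, 5, 1)]
        with pytest.raises(ConsistencyError, match="id 5"):
            build_trajectories(_table(rows))

    def test_simulator_output_yields_one_trajectory_per_cell(self, scenario_table):
        table = scenario_table("BLS", seed=3, n_immune=10, n_targets=5,
                               n_steps=30, field_size=1000.0)
        trajs = build_trajectories(table)
        immune = [tr for tr in trajs if tr.cell_class == 0]
        assert len(immune) == 10
        assert all(len(tr) == 31 for tr in immune)  # immune cells never die


class TestTriplets:
    @pytest.mark.parametrize("length,n,expected", [(5, 1, 3), (5, 2, 1),
                                                   (5, 3, 0), (2, 1, 0)])
    def test_gap_free_counts(self, length, n, expected):
        assert len(extract_triplets(_walk_trajectory(length), n)) == expected

    def test_gap_suppresses_affected_centers(self):
        traj = _walk_trajectory(7, missing=(3,))   # frames 0,1,2,4,5,6
        trips = extract_triplets(traj, 1)
        assert [tp.t for tp in trips] == [1, 5]

    def test_zero_length_step_drops_triplet(self):
        xyz = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                       dtype=float)
        traj = Trajectory(0, 0, np.arange(5), xyz)
        # steps 1->2 has zero width: centers 1 and 2 lose a step, 3 survives
        assert [tp.t for tp in extract_triplets(traj, 1)] == [3]

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(length=st.integers(3, 40), n=st.integers(1, 5))
    def test_count_matches_combinatorics(self, length, n):
        traj = _walk_trajectory(length)
        assert len(extract_triplets(traj, n)) == max(0, length - 2 * n)
        assert count_triplet_candidates(traj, n) == max(0, length - 2 * n)

    def test_min_triplet_filter(self):
        groups = {1: [object()] * 4, 2: [object()] * 5, 3: [object()] * 21}
        assert set(filter_min_triplets(groups, 5)) == {2, 3}
        assert set(filter_min_triplets(groups, 1)) == {1, 2, 3}
        assert set(filter_min_triplets(groups, 20)) == {3}


class TestPairing:
    def _one_triplet_table(self, target_xyz):
        rows = [(t, 2.0 * t, 0.1 * (t % 2), 0.0, 0, 0) for t in range(3)]
        rows.append((1, *target_xyz, 9, 1))
        return _table(rows)

    def test_distance_gate_is_three_dimensional_and_exact(self):
        # target at 3-D distance 99 µm (60, 60, 48.75...) from (2, 0.1, 0)
        inside = self._one_triplet_table((2.0, 0.1 + 99.0, 0.0))
        outside = self._one_triplet_table((2.0, 0.1 + 101.0, 0.0))
        vertical = self._one_triplet_table((2.0, 0.1, 99.0))
        for table, n_expected in [(inside, 1), (outside, 0), (vertical, 1)]:
            trajs = build_trajectories(table)
            trips = extract_triplets([t for t in trajs if t.cell_class == 0][0])
            pairs = pair_with_targets(trips, table, r_max=100.0)
            assert len(pairs) == n_expected
        for pr in pair_with_targets(
                extract_triplets(build_trajectories(inside)[0]), inside, 100.0):
            assert pr.distance <= 100.0

    def test_planar_mode_ignores_z(self):
        table = self._one_triplet_table((2.0, 0.1, 99.0))
        trips = extract_triplets(build_trajectories(table)[0])
        pairs = pair_with_targets(trips, table, 50.0, use_z=False)
        assert len(pairs) == 1 and pairs[0].distance == pytest.approx(0.0)

    def test_within_class_mode_never_pairs_cell_with_itself(self):
        rows = []
        for cid in (0, 1):
            for t in range(4):
                rows.append((t, 3.0 * t + 10.0 * cid, 1.0 * (t % 2), 0.0, cid, 0))
        table = _table(rows)
        trips = [tp for tr in build_trajectories(table)
                 for tp in extract_triplets(tr)]
        pairs = pair_with_targets(trips, table, r_max=1000.0,
                                  immune_class=0, target_class=0)
        assert pairs  # the two cells do see each other
        assert all(pr.target_id != pr.triplet.cell_id for pr in pairs)
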