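"""Event ingestion, the win-cooldown filter, windowing and matrices."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rankloop.events import (
    apply_win_cooldown,
    build_matrix,
    event_log_from_frame,
    exclude_individuals,
    network_density,
    read_event_log,
    split_windows,
)

from conftest import make_log


class TestReadEventLog:
    def test_parses_and_infers_roster(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text("time,actor,target\n5,A,B\n1,B,C\n3,C,A\n")
        log = read_event_log(p)
        assert log.n_events == 3
        assert log.roster == ("A", "B", "C")
        assert list(log.events["time"]) == [1.0, 3.0, 5.0]  # sorted ascending

    def test_iso_timestamps_become_seconds(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(
            "time,actor,target\n"
            "2021-06-01T08:00:00,A,B\n2021-06-01T08:01:30,B,A\n"
        )
        log = read_event_log(p)
        assert list(log.events["time"]) == [0.0, 90.0]

    def test_self_aggression_rejected_with_row(self):
        with pytest.raises(ValueError, match="actor == target"):
            make_log([1, 2], ["A", "B"], ["B", "B"], roster=("A", "B"))

    def test_unknown_id_rejected_when_roster_supplied(self):
        with pytest.raises(ValueError, match="unknown ids"):
            make_log([1.0], ["A"], ["Z"], roster=("A", "B"))

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing required columns"):
            event_log_from_frame(pd.DataFrame({"time": [1], "actor": ["A"]}))


class TestWinCooldown:
    def test_ten_second_barrage_collapses_to_one_win(self):
        # six attacks in 10 s on the same target score a single win
        log = make_log(np.linspace(0, 10, 6), ["A"] * 6, ["B"] * 6)
        assert apply_win_cooldown(log, 60.0).n_events == 1

    def test_gap_beyond_cooldown_retains_both(self):
        log = make_log([0.0, 61.0], ["A", "A"], ["B", "B"])
        assert apply_win_cooldown(log, 60.0).n_events == 2

    def test_distinct_pairs_do_not_interact(self):
        log = make_log([5.0, 5.0], ["A", "A"], ["B", "C"])
        assert apply_win_cooldown(log, 60.0).n_events == 2

    def test_clock_resets_from_retained_event(self):
        # sustained barrage every 30 s: wins at t=0, 60, 120, ...
        times = np.arange(0, 300, 30.0)
        log = make_log(times, ["A"] * len(times), ["B"] * len(times))
        kept = apply_win_cooldown(log, 60.0)
        assert list(kept.events["time"]) == [0.0, 60.0, 120.0, 180.0, 240.0]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        times=st.lists(
            st.floats(0, 5000, allow_nan=False), min_size=1, max_size=40
        ),
        pair_ids=st.lists(st.integers(0, 2), min_size=1, max_size=40),
    )
    def test_idempotent_and_conservative(self, times, pair_ids):
        k = min(len(times), len(pair_ids))
        pairs = [("A", "B"), ("B", "C"), ("C", "A")]
        log = make_log(
            sorted(times[:k]),
            [pairs[i][0] for i in pair_ids[:k]],
            [pairs[i][1] for i in pair_ids[:k]],
            roster=("A", "B", "C"),
        )
        once = apply_win_cooldown(log, 60.0)
        twice = apply_win_cooldown(once, 60.0)
        assert once.n_events <= log.n_events  # nothing invented
        pd.testing.assert_frame_equal(once.events, twice.events)


class TestWindows:
    def test_24_days_split_into_four_quarters(self):
        log = make_log(
            [0.0, 6 * 86400.0, 13 * 86400.0, 23.9 * 86400.0],
            ["A"] * 4,
            ["B"] * 4,
            t_obs_minutes=24 * 1440.0,
        )
        ws = split_windows(log, 6.0)
        assert [w.label for w in ws] == ["Q1", "Q2", "Q3", "Q4"]
        assert [w.n_events for w in ws] == [1, 1, 1, 1]  # boundary -> later window
        assert all(w.t_obs_minutes == 6 * 1440.0 for w in ws)

    def test_whole_study_window_is_identity(self):
        log = make_log([50.0, 90.0], ["A", "B"], ["B", "A"], t_obs_minutes=24 * 1440.0)
        (w,) = split_windows(log, 24.0)
        assert w.n_events == 2

    def test_non_multiple_duration_errors_without_force(self):
        log = make_log([1.0], ["A"], ["B"], t_obs_minutes=24 * 1440.0)
        with pytest.raises(ValueError, match="not a multiple"):
            split_windows(log, 7.0)
        assert len(split_windows(log, 7.0, force=True)) == 4

    def test_window_matrices_sum_to_whole(self):
        rng = np.random.default_rng(0)
        n = 60
        roster = ("A", "B", "C")
        a = rng.integers(0, 3, n)
        t = (a + 1 + rng.integers(0, 2, n)) % 3
        log = make_log(
            np.sort(rng.uniform(0, 24 * 86400.0, n)),
            [roster[i] for i in a],
            [roster[i] for i in t],
            roster=roster,
            t_obs_minutes=24 * 1440.0,
        )
        total = sum(build_matrix(w).counts for w in split_windows(log, 6.0))
        np.testing.assert_array_equal(total, build_matrix(log).counts)


class TestExclusions:
    def test_drop_one_of_19_leaves_18(self):
        roster = tuple(f"P{i}" for i in range(19))
        log = make_log([1.0, 2.0], ["P0", "P18"], ["P18", "P1"], roster=roster)
        out = exclude_individuals(log, ["P18"])
        assert len(out.roster) == 18
        assert out.n_events == 0  # both events touched P18
        assert out.t_obs_minutes == log.t_obs_minutes

    def test_empty_exclusion_is_identity(self, toy_log):
        assert exclude_individuals(toy_log, []) is toy_log

    def test_unknown_id_errors(self, toy_log):
        with pytest.raises(ValueError, match="unknown"):
            exclude_individuals(toy_log, ["Z"])


class TestMatrixAndDensity:
    def test_tally(self, toy_log):
        m = build_matrix(toy_log)
        assert m.counts[0, 1] == 2  # A->B twice
        assert m.counts[1, 0] == 1
        assert m.total_events == toy_log.n_events
        assert np.all(np.diag(m.counts) == 0)

    def test_empty_log_gives_zero_matrix(self):
        log = make_log([], [], [], roster=("A", "B"))
        assert build_matrix(log).total_events == 0

    def test_density_conventions(self):
        from rankloop.events import AggressionMatrix

        c = np.array([[0, 2, 1], [0, 0, 1], [0, 0, 0]])
        m = AggressionMatrix(c, ("A", "B", "C"))
        assert network_density(m) == pytest.approx(0.5)  # 3 of 6 ordered pairs
        assert network_density(m, directed=False) == pytest.approx(1.0)
        full = AggressionMatrix(np.ones((3, 3), int) - np.eye(3, dtype=int), ("A", "B", "C"))
        assert network_density(full) == 1.0
        empty = AggressionMatrix(np.zeros((3, 3), int), ("A", "B", "C"))
        assert network_density(empty) == 0.0

    def test_order_independence_for_equal_times(self):
        a = make_log([5.0, 5.0, 5.0], ["A", "B", "C"], ["B", "C", "A"], roster=("A", "B", "C"))
        b = make_log([5.0, 5.0, 5.0], ["C", "A", "B"], ["A", "B", "C"], roster=("A", "B", "C"))
        np.testing.assert_array_equal(build_matrix(a).counts, build_matrix(b).counts)
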