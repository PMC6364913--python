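import datetime as dt
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from pitmove.events import (
    build_movements,
    classify_order_direction,
    collapse_scans,
    detection_efficiency,
    drift_time,
    filter_rate,
    filter_transit_time,
    laps_from_meters,
    meters_from_laps,
    movement_speed,
    remove_overlaps,
    run_cleaning,
    total_distance_per_fish,
)
from pitmove.model import Direction, FilterLedger, MovementEvent
from pitmove.simulate import SimulationConfig, simulate_raceway

from conftest import at, ev, rec, noise_free_config


class TestCollapseScans:
    def test_single_scan_becomes_single_event(self):
        events = collapse_scans([rec("F1", "A1", 0)], max_gap_s=2)
        assert len(events) == 1
        assert events[0].n_scans == 1
        assert events[0].t_start == events[0].t_end

    def test_contiguous_scans_merge(self):
        events = collapse_scans(
            [rec("F1", "A1", 0), rec("F1", "A1", 1), rec("F1", "A1", 2)], max_gap_s=2
        )
        assert len(events) == 1
        assert events[0].n_scans == 3
        assert (events[0].t_end - events[0].t_start).total_seconds() == 2

    def test_gap_beyond_threshold_splits(self):
        events = collapse_scans([rec("F1", "A1", 0), rec("F1", "A1", 10)], max_gap_s=2)
        assert len(events) == 2

    def test_different_antennas_never_merge(self):
        events = collapse_scans([rec("F1", "A1", 0), rec("F1", "A2", 1)], max_gap_s=5)
        assert len(events) == 2

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            collapse_scans([rec("F1", "A1", 0)], max_gap_s=-1)


def brute_force_overlap_removal(events):
    """Oracle: union-find over all interval-intersecting pairs per tag."""
    removed = set()
    by_tag = {}
    for e in events:
        by_tag.setdefault(e.tag_id, []).append(e)
    for tag, evs in by_tag.items():
        parent = list(range(len(evs)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(evs)), 2):
            a, b = evs[i], evs[j]
            if a.t_start <= b.t_end and b.t_start <= a.t_end:
                parent[find(i)] = find(j)
        groups = {}
        for i in range(len(evs)):
            groups.setdefault(find(i), []).append(evs[i])
        for members in groups.values():
            if len({m.antenna_id for m in members}) > 1:
                removed.update(id(m) for m in members)
    kept = [e for e in events if id(e) not in removed]
    return kept, [e for e in events if id(e) in removed]


class TestRemoveOverlaps:
    def test_cross_antenna_overlap_removes_both(self):
        events = [ev("F1", "A1", 0, 5), ev("F1", "A2", 3, 8)]
        kept, removed = remove_overlaps(events)
        assert kept == []
        assert len(removed) == 2

    def test_same_antenna_overlap_is_kept(self):
        events = [ev("F1", "A1", 0, 5), ev("F1", "A1", 3, 8)]
        kept, removed = remove_overlaps(events)
        assert len(kept) == 2
        assert removed == []

    def test_transitive_chain_removed_in_full(self):
        # A1[0,5] ~ A1[4,9] ~ A2[8,12]: all three in one cross-antenna group
        events = [ev("F1", "A1", 0, 5), ev("F1", "A1", 4, 9), ev("F1", "A2", 8, 12)]
        kept, removed = remove_overlaps(events)
        assert kept == []
        assert len(removed) == 3

    def test_partition_example(self):
        events = [
            ev("F1", "A1", 0, 2),
            ev("F1", "A2", 10, 12),
            ev("F1", "A3", 11, 13),  # overlaps previous at another antenna
            ev("F1", "A4", 20, 22),
            ev("F1", "A1", 30, 32),
        ]
        kept, removed = remove_overlaps(events)
        assert len(kept) == 3 and len(removed) == 2

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["F1", "F2"]),
                st.sampled_from(["A1", "A2", "A3"]),
                st.integers(0, 50),
                st.integers(0, 10),
            ),
            max_size=12,
        )
    )
    def test_matches_brute_force_oracle(self, raw):
        events = [ev(t, a, s, s + d) for t, a, s, d in raw]
        kept, removed = remove_overlaps(events)
        oracle_kept, oracle_removed = brute_force_overlap_removal(events)
        key = lambda e: (e.tag_id, e.antenna_id, e.t_start, e.t_end)
        assert sorted(kept, key=key) == sorted(oracle_kept, key=key)
        assert sorted(removed, key=key) == sorted(oracle_removed, key=key)
        assert len(kept) + len(removed) == len(events)


class TestBuildMovements:
    def test_simple_transition(self, raceway):
        movements = build_movements([ev("F1", "A1", 0, 1), ev("F1", "A2", 100, 101)], raceway)
        assert len(movements) == 1
        assert movements[0].duration_s == 100

    def test_repeat_detection_at_origin_bounds_by_last_event(self, raceway):
        movements = build_movements(
            [ev("F1", "A1", 0, 1), ev("F1", "A1", 50, 51), ev("F1", "A2", 100, 101)],
            raceway,
        )
        assert len(movements) == 1
        assert movements[0].t_start == at(50)
        assert movements[0].t_end == at(100)

    def test_same_antenna_pairs_yield_no_movement(self, raceway):
        movements = build_movements([ev("F1", "A1", 0, 1), ev("F1", "A1", 100, 101)], raceway)
        assert movements == []

    def test_identical_start_tie_breaks_with_warning(self, raceway):
        with pytest.warns(UserWarning, match="identical t_start"):
            build_movements(
                [ev("F1", "A2", 0, 1), ev("F1", "A1", 0, 2), ev("F1", "A3", 60, 61)],
                raceway,
            )


class TestClassifyOrderDirection:
    def test_circular_wrap_is_first_order_downstream(self, raceway):
        mv = MovementEvent("F1", "A4", "A1", at(0), at(40))
        (out,) = classify_order_direction([mv], raceway)
        assert out.first_order and out.direction is Direction.DOWNSTREAM
        assert out.distance_m == pytest.approx(3.75)
        assert out.rate_m_s == pytest.approx(3.75 / 40)

    def test_skip_transition_is_unknown(self, raceway):
        mv = MovementEvent("F1", "A1", "A3", at(0), at(40))
        (out,) = classify_order_direction([mv], raceway)
        assert not out.first_order
        assert out.direction is Direction.UNKNOWN
        assert out.distance_m is None and out.rate_m_s is None

    def test_upstream_on_circle(self, raceway):
        mv = MovementEvent("F1", "A2", "A1", at(0), at(40))
        (out,) = classify_order_direction([mv], raceway)
        assert out.first_order and out.direction is Direction.UPSTREAM

    def test_stream_array3_to_array2_downstream_200m(self, stream):
        mv = MovementEvent("F1", "array3", "array2", at(0), at(240))
        (out,) = classify_order_direction([mv], stream)
        assert out.first_order and out.direction is Direction.DOWNSTREAM
        assert out.distance_m == 200.0

    def test_unknown_antenna_raises(self, raceway):
        mv = MovementEvent("F1", "A1", "A9", at(0), at(40))
        with pytest.raises(KeyError):
            classify_order_direction([mv], raceway)


class TestEfficiencyAndFilters:
    def make(self, raceway, dur_s, origin="A1", dest="A2"):
        mv = MovementEvent("F1", origin, dest, at(0), at(dur_s))
        return classify_order_direction([mv], raceway)[0]

    def test_detection_efficiency_fraction(self, raceway):
        movements = [self.make(raceway, 40), self.make(raceway, 50, "A1", "A3")]
        assert detection_efficiency(movements) == 0.5
        with pytest.raises(ValueError):
            detection_efficiency([])

    def test_rate_filter_strict_inequality(self, raceway):
        fast = self.make(raceway, 3.0)  # 1.25 m/s
        boundary = self.make(raceway, 3.75)  # exactly 1.0 m/s
        slow = self.make(raceway, 40)
        unknown = self.make(raceway, 2, "A1", "A3")  # no rate defined
        kept, removed = filter_rate([fast, boundary, slow, unknown])
        assert removed == [fast]
        assert set(id(m) for m in kept) == {id(boundary), id(slow), id(unknown)}

    def test_transit_filter_strict_inequality(self, raceway):
        kept_mv = self.make(raceway, 179)
        boundary = self.make(raceway, 180)
        long_mv = self.make(raceway, 181)
        kept, removed = filter_transit_time([kept_mv, boundary, long_mv])
        assert removed == [long_mv]
        assert kept == [kept_mv, boundary]

    def test_filter_order_is_immaterial(self, raceway):
        cfg = noise_free_config(seed=21, rest_prob=0.05, crosstalk_per_1000=5.0,
                                detection_prob=0.9)
        records, _ = simulate_raceway(cfg, raceway)
        _, _, stages = run_cleaning(records, raceway)
        movements = stages["movements_all"]
        a, _ = filter_transit_time(filter_rate(movements)[0])
        b, _ = filter_rate(filter_transit_time(movements)[0])
        assert a == b

    def test_ledger_conservation_on_simulated_log(self, raceway):
        cfg = noise_free_config(seed=22, rest_prob=0.05, crosstalk_per_1000=5.0,
                                detection_prob=0.9)
        records, _ = simulate_raceway(cfg, raceway)
        movements, ledger, stages = run_cleaning(records, raceway)
        ledger.validate()
        assert ledger.n_overlap_removed == len(stages["overlap_removed"])
        assert ledger.n_movement_events == len(stages["movements_all"])
        assert ledger.n_final == len(movements)
        assert (
            len(movements)
            == ledger.n_movement_events - ledger.n_rate_removed - ledger.n_transit_removed
        )
        for mv in movements:
            assert mv.duration_s <= 180.0
            if mv.first_order:
                assert mv.rate_m_s <= 1.0


class TestArithmetic:
    @pytest.mark.parametrize(
        "distance,duration,expected",
        [(200.0, 300.0, 0.67), (200.0, 240.0, 0.83), (15.0, 15.0, 1.00)],
    )
    def test_movement_speed(self, distance, duration, expected):
        assert round(movement_speed(distance, duration), 2) == expected

    @pytest.mark.parametrize(
        "distance,speed,expected",
        [(4800.0, 0.83, 1.6), (5200.0, 0.67, 2.2), (3600.0, 1.0, 1.0)],
    )
    def test_drift_time_hours(self, distance, speed, expected):
        assert round(drift_time(distance, speed), 1) == expected

    @pytest.mark.parametrize(
        "meters,laps", [(28292.0, 1886.1), (20.5, 1.4), (15.0, 1.0)]
    )
    def test_laps_conversion(self, meters, laps):
        assert round(laps_from_meters(meters, 15.0), 1) == laps
        assert meters_from_laps(laps_from_meters(meters, 15.0), 15.0) == pytest.approx(meters)

    def test_invalid_inputs_raise(self):
        for fn in (movement_speed, drift_time):
            with pytest.raises(ValueError):
                fn(0, 10)
            with pytest.raises(ValueError):
                fn(10, 0)
        with pytest.raises(ValueError):
            laps_from_meters(10, 0)


class TestTotalDistance:
    def test_sums_first_order_only(self, raceway):
        a = MovementEvent("F1", "A1", "A2", at(0), at(40))
        b = MovementEvent("F1", "A2", "A4", at(100), at(200))  # non-first-order
        movements = classify_order_direction([a, b], raceway)
        totals = total_distance_per_fish(movements, raceway)
        assert totals == {"F1": pytest.approx(3.75)}

    def test_empty_is_empty(self, raceway):
        assert total_distance_per_fish([], raceway) == {}

    def test_known_laps_recovered_at_perfect_detection(self, raceway):
        cfg = noise_free_config(seed=23, n_fish=3, study_days=8)
        records, truth = simulate_raceway(cfg, raceway)
        movements, _, stages = run_cleaning(records, raceway)
        # distance over *all* first-order movements equals total true passages
        totals = total_distance_per_fish(stages["movements_all"], raceway)
        for tag in totals:
            n_true = sum(t.tag_id == tag for t in truth.transitions)
            assert totals[tag] == pytest.approx(n_true * 3.75)
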