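"""Movement-event construction and false-detection filtering.

The cleaning cascade mirrors standard PIT-telemetry practice:

1. collapse contiguous same-tag same-antenna scans into detection events;
2. remove, per tag, every group of detection events whose time intervals
   overlap across *different* antennas (a tag cannot be in two places at
   once — antenna cross-talk or tag-collision artefacts);
3. pair consecutive detection events at different antennas into movement
   events bounded by the first detection at each antenna;
4. classify each movement as a first-order transition (adjacent antennas,
   direction knowable from flow order) or not;
5. drop first-order movements faster than a physical speed ceiling
   (default 1 m/s, beyond juvenile lamprey swimming ability);
6. drop movements slower than a transit-time ceiling (default 3 min,
   indicating the animal rested mid-transit rather than swam through).

Every stage reports kept and removed so the :class:`~pitmove.model.FilterLedger`
conserves counts end to end.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from typing import Iterable, Sequence

from .model import (
    DetectionEvent,
    DetectionRecord,
    Direction,
    FilterLedger,
    MovementEvent,
    SiteGeometry,
)

__all__ = [
    "collapse_scans",
    "remove_overlaps",
    "build_movements",
    "classify_order_direction",
    "detection_efficiency",
    "filter_rate",
    "filter_transit_time",
    "movement_speed",
    "drift_time",
    "laps_from_meters",
    "meters_from_laps",
    "total_distance_per_fish",
    "run_cleaning",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP_S = 10.0
DEFAULT_MAX_RATE_M_S = 1.0
DEFAULT_MAX_TRANSIT_S = 180.0


def collapse_scans(
    records: Iterable[DetectionRecord], max_gap_s: float = DEFAULT_MAX_GAP_S
) -> list[DetectionEvent]:
    """Merge contiguous same-tag same-antenna scans into detection events.

    Consecutive records of one tag at one antenna whose inter-scan gap is at
    most ``max_gap_s`` seconds become a single event whose interval spans the
    merged scans and whose ``n_scans`` counts them.  Records that already
    carry an interval (pre-collapsed reader output) pass through unchanged
    unless they chain with neighbours.
    """
    if max_gap_s < 0:
        raise ValueError("max_gap_s must be non-negative")
    by_key: dict[tuple[str, str], list[DetectionRecord]] = defaultdict(list)
    for rec in records:
        by_key[(rec.tag_id, rec.antenna_id)].append(rec)
    events: list[DetectionEvent] = []
    for (tag, antenna), recs in by_key.items():
        recs.sort(key=lambda r: (r.t_start, r.t_end))
        cur_start, cur_end, cur_n = recs[0].t_start, recs[0].t_end, 1
        for rec in recs[1:]:
            gap = (rec.t_start - cur_end).total_seconds()
            if gap <= max_gap_s:
                cur_end = max(cur_end, rec.t_end)
                cur_n += 1
            else:
                events.append(DetectionEvent(tag, antenna, cur_start, cur_end, cur_n))
                cur_start, cur_end, cur_n = rec.t_start, rec.t_end, 1
        events.append(DetectionEvent(tag, antenna, cur_start, cur_end, cur_n))
    events.sort(key=lambda e: (e.t_start, e.tag_id, e.antenna_id))
    return events


def remove_overlaps(
    events: Sequence[DetectionEvent], ledger: FilterLedger | None = None
) -> tuple[list[DetectionEvent], list[DetectionEvent]]:
    """Remove per-tag groups of events overlapping across multiple antennas.

    For each tag, events whose closed intervals intersect pairwise or
    transitively form a group; any group spanning two or more distinct
    antennas is removed *in full* (the tag appeared to be in two places at
    once).  Groups confined to a single antenna are kept — re-detection at
    one antenna is not physically impossible.  Returns ``(kept, removed)``,
    a partition of the input.
    """
    by_tag: dict[str, list[DetectionEvent]] = defaultdict(list)
    for ev in events:
        by_tag[ev.tag_id].append(ev)
    kept: list[DetectionEvent] = []
    removed: list[DetectionEvent] = []
    for tag, evs in by_tag.items():
        evs.sort(key=lambda e: (e.t_start, e.t_end))
        # sweep: a new group starts when the next event begins after the
        # running max end of the current group (closed intervals)
        group = [evs[0]]
        group_end = evs[0].t_end
        for ev in evs[1:]:
            if ev.t_start > group_end:
                _flush_overlap_group(group, kept, removed)
                group = [ev]
                group_end = ev.t_end
            else:
                group.append(ev)
                group_end = max(group_end, ev.t_end)
        _flush_overlap_group(group, kept, removed)
    kept.sort(key=lambda e: (e.t_start, e.tag_id, e.antenna_id))
    removed.sort(key=lambda e: (e.t_start, e.tag_id, e.antenna_id))
    if ledger is not None:
        ledger.n_overlap_removed += len(removed)
    return kept, removed


def _flush_overlap_group(
    group: list[DetectionEvent],
    kept: list[DetectionEvent],
    removed: list[DetectionEvent],
) -> None:
    antennas = {e.antenna_id for e in group}
    (removed if len(antennas) > 1 else kept).extend(group)


def build_movements(
    events: Sequence[DetectionEvent],
    geometry: SiteGeometry,
    ledger: FilterLedger | None = None,
) -> list[MovementEvent]:
    """Pair consecutive detection events at different antennas into movements.

    Each per-tag consecutive pair of detection events at different antennas
    yields one movement bounded by the first detection of each event
    (``t_start`` of the origin event to ``t_start`` of the destination
    event); consecutive events at the same antenna yield no movement.  Events
    with identical ``t_start`` at different antennas (possible only for
    degenerate input that survived overlap removal) are ordered by antenna
    position in the geometry, with a warning.
    """
    by_tag: dict[str, list[DetectionEvent]] = defaultdict(list)
    for ev in events:
        by_tag[ev.tag_id].append(ev)
    movements: list[MovementEvent] = []
    for tag, evs in by_tag.items():
        starts = {e.t_start for e in evs}
        if len(starts) < len(evs):
            warnings.warn(
                f"tag {tag}: detection events with identical t_start; "
                "breaking ties by antenna order",
                stacklevel=2,
            )
        evs.sort(key=lambda e: (e.t_start, geometry.index(e.antenna_id)))
        for prev, nxt in zip(evs, evs[1:]):
            if prev.antenna_id == nxt.antenna_id:
                continue
            if nxt.t_start <= prev.t_start:
                continue  # degenerate tie; cannot form a positive-duration movement
            movements.append(
                MovementEvent(
                    tag_id=tag,
                    origin_antenna=prev.antenna_id,
                    dest_antenna=nxt.antenna_id,
                    t_start=prev.t_start,
                    t_end=nxt.t_start,
                )
            )
    movements.sort(key=lambda m: (m.t_start, m.tag_id))
    if ledger is not None:
        ledger.n_movement_events += len(movements)
    return movements


def classify_order_direction(
    movements: Iterable[MovementEvent],
    geometry: SiteGeometry,
    ledger: FilterLedger | None = None,
) -> list[MovementEvent]:
    """Set first-order flag, direction, distance and rate on each movement.

    A movement is first-order iff origin and destination are adjacent in the
    geometry (including the circular wrap); only then are direction, distance
    and rate defined.
    """
    out: list[MovementEvent] = []
    n_first = 0
    for mv in movements:
        first_order, direction = geometry.classify_pair(
            mv.origin_antenna, mv.dest_antenna
        )
        mv.first_order = first_order
        mv.direction = direction
        if first_order:
            n_first += 1
            mv.distance_m = geometry.adjacent_distance(mv.origin_antenna, mv.dest_antenna)
            mv.rate_m_s = mv.distance_m / mv.duration_s
        else:
            mv.distance_m = None
            mv.rate_m_s = None
        out.append(mv)
    if ledger is not None:
        ledger.n_first_order += n_first
    return out


def detection_efficiency(movements: Sequence[MovementEvent]) -> float:
    """Fraction of movements that are first-order transitions.

    Missed antenna passages turn adjacent transitions into non-adjacent
    ones, so this fraction is a coarse proxy for per-antenna read
    probability.
    """
    if not movements:
        raise ValueError("detection efficiency undefined for zero movements")
    return sum(m.first_order for m in movements) / len(movements)


def filter_rate(
    movements: Sequence[MovementEvent],
    max_rate_m_s: float = DEFAULT_MAX_RATE_M_S,
    ledger: FilterLedger | None = None,
) -> tuple[list[MovementEvent], list[MovementEvent]]:
    """Remove first-order movements whose rate strictly exceeds the ceiling.

    Non-first-order movements carry no defined rate and are never removed
    here.  The boundary value is kept (strict "exceeded").
    """
    if max_rate_m_s <= 0:
        raise ValueError("max_rate_m_s must be positive")
    kept, removed = [], []
    for mv in movements:
        if mv.rate_m_s is not None and mv.rate_m_s > max_rate_m_s:
            removed.append(mv)
        else:
            kept.append(mv)
    if ledger is not None:
        ledger.n_rate_removed += len(removed)
    return kept, removed


def filter_transit_time(
    movements: Sequence[MovementEvent],
    max_transit_s: float = DEFAULT_MAX_TRANSIT_S,
    ledger: FilterLedger | None = None,
) -> tuple[list[MovementEvent], list[MovementEvent]]:
    """Remove movements taking strictly more than the transit-time ceiling.

    Long transits indicate the animal stopped and rested between antennas;
    the boundary value is kept (strict "more than").
    """
    kept, removed = [], []
    for mv in movements:
        if mv.duration_s > max_transit_s:
            removed.append(mv)
        else:
            kept.append(mv)
    if ledger is not None:
        ledger.n_transit_removed += len(removed)
    return kept, removed


def movement_speed(distance_m: float, duration_s: float) -> float:
    """Speed in m/s from a centerline distance and a transit duration."""
    if distance_m <= 0 or duration_s <= 0:
        raise ValueError("distance and duration must be positive")
    return distance_m / duration_s


def drift_time(distance_m: float, speed_m_s: float) -> float:
    """Hours needed to cover ``distance_m`` at a constant ``speed_m_s``."""
    if distance_m <= 0 or speed_m_s <= 0:
        raise ValueError("distance and speed must be positive")
    return distance_m / speed_m_s / 3600.0


def laps_from_meters(total_m: float, circumference_m: float) -> float:
    """Longitudinal meters expressed as laps of a circular channel."""
    if circumference_m <= 0:
        raise ValueError("circumference must be positive")
    return total_m / circumference_m


def meters_from_laps(laps: float, circumference_m: float) -> float:
    if circumference_m <= 0:
        raise ValueError("circumference must be positive")
    return laps * circumference_m


def total_distance_per_fish(
    movements: Iterable[MovementEvent], geometry: SiteGeometry
) -> dict[str, float]:
    """Per-tag sum of first-order centerline distance, in meters.

    Non-first-order movements have ambiguous paths and contribute nothing,
    so totals are lower bounds ("at least" distances).
    """
    totals: dict[str, float] = defaultdict(float)
    for mv in movements:
        if mv.first_order and mv.distance_m is not None:
            totals[mv.tag_id] += mv.distance_m
    return dict(totals)


def run_cleaning(
    records: Sequence[DetectionRecord],
    geometry: SiteGeometry,
    *,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    max_rate_m_s: float = DEFAULT_MAX_RATE_M_S,
    max_transit_s: float = DEFAULT_MAX_TRANSIT_S,
    n_rejects: int = 0,
) -> tuple[list[MovementEvent], FilterLedger, dict[str, list]]:
    """Run the full cleaning cascade and return (final movements, ledger, stages).

    ``stages`` maps stage names to the intermediate products for auditing:
    ``detection_events``, ``overlap_removed``, ``movements_all``,
    ``rate_removed``, ``transit_removed``.
    """
    ledger = FilterLedger(n_records=len(records), n_rejects=n_rejects)
    detections = collapse_scans(records, max_gap_s=max_gap_s)
    ledger.n_detection_events = len(detections)
    kept_det, removed_det = remove_overlaps(detections, ledger=ledger)
    movements = build_movements(kept_det, geometry, ledger=ledger)
    movements = classify_order_direction(movements, geometry, ledger=ledger)
    kept_rate, removed_rate = filter_rate(movements, max_rate_m_s, ledger=ledger)
    kept_final, removed_transit = filter_transit_time(
        kept_rate, max_transit_s, ledger=ledger
    )
    ledger.validate()
    stages = {
        "detection_events": detections,
        "overlap_removed": removed_det,
        "movements_all": movements,
        "rate_removed": removed_rate,
        "transit_removed": removed_transit,
    }
    return kept_final, ledger, stages
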