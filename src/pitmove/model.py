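"""Core domain types for multi-antenna PIT-telemetry movement analysis.

The pipeline's unit of raw data is a single tag read (:class:`DetectionRecord`).
Contiguous reads of one tag at one antenna collapse into a
:class:`DetectionEvent`; consecutive detection events at different antennas
define a :class:`MovementEvent`.  A :class:`SiteGeometry` describes the antenna
topology (linear stream reach or circular raceway), inter-antenna centerline
distances, and the site coordinates needed for solar day/night classification.
A :class:`FilterLedger` keeps the bookkeeping of how many events enter and
leave every cleaning stage, so no record is ever silently dropped.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Direction",
    "Diel",
    "DetectionRecord",
    "DetectionEvent",
    "MovementEvent",
    "SiteGeometry",
    "FilterLedger",
    "SolarDay",
]


class Direction(str, Enum):
    """Direction of a movement relative to water flow."""

    DOWNSTREAM = "downstream"
    UPSTREAM = "upstream"
    UNKNOWN = "unknown"


class Diel(str, Enum):
    """Diel period of an instant: day is [sunrise, sunset), night the rest."""

    DAY = "day"
    NIGHT = "night"


def _check_aware(t: dt.datetime, name: str) -> None:
    if t.tzinfo is None or t.utcoffset() is None:
        raise ValueError(f"{name} must carry a fixed UTC offset (aware datetime)")


@dataclass(frozen=True)
class DetectionRecord:
    """One tag read (or one pre-collapsed presence interval) at one antenna.

    ``t_end`` equals ``t_start`` for single scans; readers that emit scan
    durations produce records with ``t_end > t_start``.
    """

    tag_id: str
    antenna_id: str
    t_start: dt.datetime
    t_end: dt.datetime | None = None

    def __post_init__(self) -> None:
        if not self.tag_id:
            raise ValueError("tag_id must be non-empty")
        if not self.antenna_id:
            raise ValueError("antenna_id must be non-empty")
        _check_aware(self.t_start, "t_start")
        if self.t_end is None:
            object.__setattr__(self, "t_end", self.t_start)
        else:
            _check_aware(self.t_end, "t_end")
            if self.t_end < self.t_start:
                raise ValueError("t_end must be >= t_start")

    @property
    def duration_s(self) -> float:
        return (self.t_end - self.t_start).total_seconds()


@dataclass(frozen=True)
class DetectionEvent:
    """One or more contiguous reads of a tag at a single antenna.

    This is the unit the false-detection filters operate on: a presence
    interval ``[t_start, t_end]`` with the number of merged scans.
    """

    tag_id: str
    antenna_id: str
    t_start: dt.datetime
    t_end: dt.datetime
    n_scans: int = 1

    def __post_init__(self) -> None:
        if not self.tag_id:
            raise ValueError("tag_id must be non-empty")
        if not self.antenna_id:
            raise ValueError("antenna_id must be non-empty")
        _check_aware(self.t_start, "t_start")
        _check_aware(self.t_end, "t_end")
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")

    def overlaps(self, other: "DetectionEvent") -> bool:
        """Closed-interval overlap test on [t_start, t_end]."""
        return self.t_start <= other.t_end and other.t_start <= self.t_end


@dataclass
class MovementEvent:
    """A transition of a tag between two antennas.

    Bounded by the first detection at the origin antenna (of the detection
    event immediately preceding the transition) and the first detection at the
    destination.  Distance and rate are defined only for first-order
    transitions (adjacent antennas), because for non-adjacent detections the
    path — and on a circular raceway even the direction — is ambiguous.
    """

    tag_id: str
    origin_antenna: str
    dest_antenna: str
    t_start: dt.datetime
    t_end: dt.datetime
    first_order: bool = False
    direction: Direction = Direction.UNKNOWN
    distance_m: float | None = None
    rate_m_s: float | None = None
    diel: Diel | None = None
    diel_boundary: bool = False

    def __post_init__(self) -> None:
        if self.origin_antenna == self.dest_antenna:
            raise ValueError("origin and destination antennas must differ")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must be > t_start")
        if (self.direction is not Direction.UNKNOWN) != self.first_order:
            raise ValueError("direction is known iff the transition is first-order")
        if self.rate_m_s is not None and self.rate_m_s <= 0:
            raise ValueError("rate_m_s must be positive when defined")

    @property
    def duration_s(self) -> float:
        return (self.t_end - self.t_start).total_seconds()


@dataclass(frozen=True)
class SiteGeometry:
    """Antenna topology plus the solar coordinates of the site.

    ``antennas`` are ordered in downstream-flow order.  For ``circular``
    topology the last antenna wraps to the first (the raceway loop), and the
    adjacent pair distances must sum to ``circumference_m``.
    """

    topology: str  # "linear" | "circular"
    antennas: tuple[str, ...]
    pair_distance_m: Mapping[tuple[str, str], float]
    latitude_deg: float
    longitude_deg: float
    utc_offset_hr: float
    circumference_m: float | None = None
    name: str = "site"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if len(self.antennas) < 2:
            raise ValueError("need at least two antennas")
        if len(set(self.antennas)) != len(self.antennas):
            raise ValueError("antenna ids must be unique")
        object.__setattr__(self, "antennas", tuple(self.antennas))
        object.__setattr__(self, "pair_distance_m", dict(self.pair_distance_m))
        for pair in self.adjacent_pairs():
            d = self.pair_distance_m.get(pair)
            if d is None:
                raise ValueError(f"missing distance for adjacent pair {pair}")
            if d <= 0:
                raise ValueError(f"non-positive distance for {pair}")
        if self.topology == "circular":
            if self.circumference_m is None:
                raise ValueError("circular geometry requires circumference_m")
            total = sum(self.pair_distance_m[p] for p in self.adjacent_pairs())
            if abs(total - self.circumference_m) > 1e-9:
                raise ValueError(
                    f"adjacent distances sum to {total} m, expected "
                    f"circumference {self.circumference_m} m"
                )
        if abs(self.latitude_deg) >= 66.5:
            raise ValueError("polar-circle latitudes are not supported")

    # -- topology ---------------------------------------------------------
    def adjacent_pairs(self) -> list[tuple[str, str]]:
        """Ordered (upstream, downstream) adjacent pairs, incl. circular wrap."""
        pairs = [
            (self.antennas[i], self.antennas[i + 1])
            for i in range(len(self.antennas) - 1)
        ]
        if self.topology == "circular":
            pairs.append((self.antennas[-1], self.antennas[0]))
        return pairs

    def index(self, antenna_id: str) -> int:
        try:
            return self.antennas.index(antenna_id)
        except ValueError:
            raise KeyError(f"antenna {antenna_id!r} not in geometry") from None

    def classify_pair(self, origin: str, dest: str) -> tuple[bool, Direction]:
        """(first_order, direction) for an ordered antenna pair."""
        i, j = self.index(origin), self.index(dest)
        n = len(self.antennas)
        if self.topology == "circular":
            if (i + 1) % n == j:
                return True, Direction.DOWNSTREAM
            if (j + 1) % n == i:
                return True, Direction.UPSTREAM
        else:
            if j == i + 1:
                return True, Direction.DOWNSTREAM
            if j == i - 1:
                return True, Direction.UPSTREAM
        return False, Direction.UNKNOWN

    def adjacent_distance(self, origin: str, dest: str) -> float:
        """Centerline distance between adjacent antennas (either order)."""
        for pair in ((origin, dest), (dest, origin)):
            if pair in self.pair_distance_m:
                return self.pair_distance_m[pair]
        raise KeyError(f"({origin}, {dest}) is not an adjacent pair")

    # -- time -------------------------------------------------------------
    @property
    def tzinfo(self) -> dt.timezone:
        return dt.timezone(dt.timedelta(hours=self.utc_offset_hr))


@dataclass
class FilterLedger:
    """Counts entering and removed at every cleaning stage.

    Guarantees the audit identity
    ``n_final = n_movement_events - n_rate_removed - n_transit_removed``.
    """

    n_records: int = 0
    n_rejects: int = 0
    n_detection_events: int = 0
    n_overlap_removed: int = 0
    n_movement_events: int = 0
    n_first_order: int = 0
    n_rate_removed: int = 0
    n_transit_removed: int = 0

    @property
    def n_final(self) -> int:
        return self.n_movement_events - self.n_rate_removed - self.n_transit_removed

    @property
    def overlap_removed_frac(self) -> float:
        return self.n_overlap_removed / self.n_detection_events

    @property
    def detection_efficiency(self) -> float:
        return self.n_first_order / self.n_movement_events

    @property
    def rate_removed_frac(self) -> float:
        """Rate-filter removals over all movement events."""
        return self.n_rate_removed / self.n_movement_events

    @property
    def transit_removed_frac_of_all(self) -> float:
        """Transit-filter removals over all movement events."""
        return self.n_transit_removed / self.n_movement_events

    @property
    def transit_removed_frac_post_rate(self) -> float:
        """Transit-filter removals over movements surviving the rate filter."""
        return self.n_transit_removed / (self.n_movement_events - self.n_rate_removed)

    def validate(self) -> None:
        for name in (
            "n_records",
            "n_rejects",
            "n_detection_events",
            "n_overlap_removed",
            "n_movement_events",
            "n_first_order",
            "n_rate_removed",
            "n_transit_removed",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_first_order > self.n_movement_events:
            raise ValueError("n_first_order exceeds n_movement_events")
        if self.n_overlap_removed > self.n_detection_events:
            raise ValueError("n_overlap_removed exceeds n_detection_events")
        if self.n_final < 0:
            raise ValueError("filters removed more movements than existed")

    def as_dict(self) -> dict[str, int]:
        return {
            "n_records": self.n_records,
            "n_rejects": self.n_rejects,
            "n_detection_events": self.n_detection_events,
            "n_overlap_removed": self.n_overlap_removed,
            "n_movement_events": self.n_movement_events,
            "n_first_order": self.n_first_order,
            "n_rate_removed": self.n_rate_removed,
            "n_transit_removed": self.n_transit_removed,
            "n_final": self.n_final,
        }


@dataclass(frozen=True)
class SolarDay:
    """Sunrise and sunset for one calendar date at the site's UTC offset."""

    date: dt.date
    sunrise: dt.datetime
    sunset: dt.datetime

    def __post_init__(self) -> None:
        _check_aware(self.sunrise, "sunrise")
        _check_aware(self.sunset, "sunset")
        if not self.sunrise < self.sunset:
            raise ValueError("sunrise must precede sunset")
        if self.sunrise.date() != self.date or self.sunset.date() != self.date:
            raise ValueError("sunrise/sunset must fall on the stated date")

    @property
    def day_length(self) -> dt.timedelta:
        return self.sunset - self.sunrise
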