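"""Synthetic detection-log generator with full ground truth.

Two site presets are emulated:

* a circular raceway (15 m centerline circumference, 4 antennas, flow
  0.10-0.12 m/s) holding a cohort of tagged juvenile lamprey over a
  multi-month observation window.  Behaviour is a two-state (burrowed /
  moving) process: each hour a burrowed fish initiates a downstream bout
  with a diel-dependent probability, swims past consecutive antennas at a
  drawn speed, and burrows again where it stops.  Nocturnal bouts truncate
  at sunrise (negative phototaxis: fish stop at first light).
* a linear stream reach with three antenna arrays 200 m apart, 4.8-5.2 km
  below a release point: each released fish drifts downstream on one night
  (first-night probability 0.81, geometric tail), passing the arrays at a
  drawn drift speed, and may be recaptured at a downstream net.

Each noise channel is independently switchable and maps to exactly one
cleaning filter: antenna cross-talk (spurious simultaneous detections at a
second antenna) is removed by the overlap filter; mid-transit resting by the
3-minute transit filter; missed detections (per-antenna detection
probability < 1) surface as non-first-order transitions.  An optional
teleport channel injects physically impossible fast transitions for the
1 m/s rate filter.

With all noise off the emitted log is exactly identifiable: the cleaning
pipeline recovers the true transition sequence transition-for-transition.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .diel import SolarTable
from .io import raceway_geometry, stream_geometry
from .model import DetectionRecord, Diel, Direction, SiteGeometry

__all__ = [
    "SimulationConfig",
    "TrueTransition",
    "GroundTruth",
    "simulate_raceway",
    "simulate_linear_stream",
    "ground_truth_report",
    "read_ground_truth_report",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario parameters for the synthetic detection-log generator.

    Defaults describe the raceway cohort: 47 tagged fish observed for 91
    days starting 1200 local on 2014-11-06, of which a fraction 25/47 ever
    move; nocturnal hourly bout-initiation probability ``p_night`` far above
    the diurnal ``p_day``; swim speeds near the 0.10-0.12 m/s flow.  Stream
    parameters cover the release-and-drift design: 290 fish, drift speeds
    0.67-0.83 m/s, 81% of transits on the first night after release.
    """

    topology: str = "raceway"
    seed: int = 0
    n_fish: int = 47
    study_days: int = 91
    start: dt.datetime | None = None  # default: 2014-11-06 12:00 at site offset
    mover_fraction: float = 25 / 47
    p_night: float = 0.05
    p_day: float = 0.002
    bout_transits_mean: float = 12.0  # geometric mean number of antenna-to-antenna transits
    speed_mean_m_s: float = 0.11
    speed_sd_m_s: float = 0.015
    speed_min_m_s: float = 0.03
    speed_max_m_s: float = 0.18
    detection_prob: float = 0.95
    crosstalk_per_1000: float = 5.0
    rest_prob: float = 0.02
    rest_extra_median_s: float = 390.0  # added on top of the 180 s floor
    teleport_per_1000: float = 0.0
    # linear-stream parameters
    n_released: int = 290
    first_night_prob: float = 0.81
    drift_speed_range: tuple[float, float] = (0.67, 0.83)
    per_array_detection_prob: float = 0.1335
    recapture_prob: float = 48 / 290
    night_horizon: int = 42
    dark_offset_base_s: float = 3.0 * 3600
    dark_offset_scale_s: float = 3600.0

    def __post_init__(self) -> None:
        if self.topology not in ("raceway", "stream"):
            raise ValueError(f"unknown topology preset {self.topology!r}")
        for name in (
            "mover_fraction",
            "p_night",
            "p_day",
            "detection_prob",
            "first_night_prob",
            "per_array_detection_prob",
            "recapture_prob",
            "rest_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.bout_transits_mean < 1:
            raise ValueError("bout_transits_mean must be >= 1")
        if not 0 < self.speed_min_m_s <= self.speed_mean_m_s <= self.speed_max_m_s:
            raise ValueError("need 0 < speed_min <= speed_mean <= speed_max")
        lo, hi = self.drift_speed_range
        if not 0 < lo <= hi:
            raise ValueError("drift_speed_range must be positive and ordered")


@dataclass(frozen=True)
class TrueTransition:
    """One true antenna-to-antenna transition of a simulated fish."""

    tag_id: str
    origin: str
    dest: str
    t_start: dt.datetime  # true first-detection instant at origin
    t_end: dt.datetime  # true first-detection instant at destination
    direction: str = Direction.DOWNSTREAM.value
    diel: str = Diel.NIGHT.value
    between_bouts: bool = False
    rested: bool = False

    @property
    def duration_s(self) -> float:
        return (self.t_end - self.t_start).total_seconds()


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    transitions: list[TrueTransition]
    movers: list[str]
    n_fish: int
    n_crosstalk_injected: int = 0
    n_rest_injected: int = 0
    n_teleport_injected: int = 0
    recaptured_tags: list[str] = field(default_factory=list)
    detected_tags: list[str] = field(default_factory=list)

    def clean_transitions(self) -> list[TrueTransition]:
        """Transitions the pipeline should keep after all filters."""
        return [
            t for t in self.transitions if not t.between_bouts and not t.rested
        ]

    def activity_days(self) -> dict[str, set[dt.date]]:
        """Per-tag dates with at least one clean downstream transition."""
        out: dict[str, set[dt.date]] = {}
        for t in self.clean_transitions():
            if t.direction == Direction.DOWNSTREAM.value:
                out.setdefault(t.tag_id, set()).add(t.t_start.date())
        return out


def _round_s(t: dt.datetime) -> dt.datetime:
    """Round to whole seconds (detection logs are 1-s resolution)."""
    if t.microsecond >= 500_000:
        t += dt.timedelta(seconds=1)
    return t.replace(microsecond=0)


def _emit_passage(
    records: list[DetectionRecord],
    tag: str,
    antenna: str,
    t: dt.datetime,
    speed: float,
) -> dt.datetime:
    """Append the scan run for one antenna passage; return first-scan time."""
    first = _round_s(t)
    n_scans = int(np.clip(round(0.6 / speed), 2, 6))
    for s in range(n_scans):
        records.append(
            DetectionRecord(tag, antenna, first + dt.timedelta(seconds=s))
        )
    return first


def simulate_raceway(
    config: SimulationConfig,
    geometry: SiteGeometry | None = None,
    solar: SolarTable | None = None,
) -> tuple[list[DetectionRecord], GroundTruth]:
    """Simulate the circular-raceway cohort; return (records, ground truth).

    Identical config (including seed) yields identical output.  Records are
    returned in chronological order, as a reader would log them.
    """
    if config.topology != "raceway":
        raise ValueError("config.topology must be 'raceway'")
    geometry = geometry or raceway_geometry()
    solar = solar or SolarTable(geometry)
    rng = np.random.default_rng(config.seed)
    tz = geometry.tzinfo
    start = config.start or dt.datetime(2014, 11, 6, 12, 0, tzinfo=tz)
    n_hours = config.study_days * 24
    antennas = geometry.antennas
    n_ant = len(antennas)
    spacing = geometry.circumference_m / n_ant if geometry.circumference_m else 3.75

    records: list[DetectionRecord] = []
    transitions: list[TrueTransition] = []
    movers: list[str] = []
    n_crosstalk = n_rest = n_teleport = 0

    for i in range(config.n_fish):
        tag = f"F{i + 1:03d}"
        if rng.random() >= config.mover_fraction:
            continue
        movers.append(tag)
        position = int(rng.integers(n_ant))  # resting just below this antenna
        prev_passage: tuple[str, dt.datetime] | None = None  # antenna, first-scan time
        busy_until = start
        for h in range(n_hours):
            t_hour = start + dt.timedelta(hours=h)
            if t_hour < busy_until:
                continue
            t0 = t_hour + dt.timedelta(seconds=float(rng.uniform(0.0, 3600.0)))
            if t0 < busy_until:
                continue
            diel0 = solar.classify(t0)
            p = config.p_night if diel0 is Diel.NIGHT else config.p_day
            if rng.random() >= p:
                continue
            # --- one downstream bout ---
            n_transits = int(rng.geometric(1.0 / config.bout_transits_mean))
            speed = float(
                np.clip(
                    rng.normal(config.speed_mean_m_s, config.speed_sd_m_s),
                    config.speed_min_m_s,
                    config.speed_max_m_s,
                )
            )
            # passage times through antennas position+1, position+2, ...
            t_pass = t0 + dt.timedelta(seconds=(spacing / 2.0) / speed)
            cutoff = None
            if diel0 is Diel.NIGHT:
                # nocturnal fish stop at first light
                day = solar.day(t0.date())
                cutoff = day.sunrise if t0 < day.sunrise else solar.day(
                    t0.date() + dt.timedelta(days=1)
                ).sunrise
            rest_pending = False
            for k in range(n_transits + 1):
                if cutoff is not None and t_pass >= cutoff:
                    break
                position = (position + 1) % n_ant
                antenna = antennas[position]
                first_scan = _round_s(t_pass)
                rested_here = rest_pending
                if prev_passage is not None:
                    prev_ant, prev_t = prev_passage
                    transitions.append(
                        TrueTransition(
                            tag_id=tag,
                            origin=prev_ant,
                            dest=antenna,
                            t_start=prev_t,
                            t_end=first_scan,
                            diel=solar.classify(prev_t).value,
                            between_bouts=(k == 0),
                            rested=rested_here,
                        )
                    )
                    if rested_here:
                        n_rest += 1
                if rng.random() < config.detection_prob:
                    if rng.random() < config.teleport_per_1000 / 1000.0:
                        # teleport channel: a single scan here plus a spurious
                        # scan at the next antenna 2 s later -- a physically
                        # impossible transition caught by the rate filter
                        records.append(DetectionRecord(tag, antenna, first_scan))
                        nxt = antennas[(position + 1) % n_ant]
                        records.append(
                            DetectionRecord(
                                tag, nxt, first_scan + dt.timedelta(seconds=2)
                            )
                        )
                        n_teleport += 1
                    else:
                        _emit_passage(records, tag, antenna, t_pass, speed)
                        if rng.random() < config.crosstalk_per_1000 / 1000.0:
                            # spurious simultaneous detection at another antenna
                            other = antennas[(position + 2) % n_ant]
                            records.append(DetectionRecord(tag, other, first_scan))
                            n_crosstalk += 1
                prev_passage = (antenna, first_scan)
                # schedule next passage
                dt_next = spacing / speed
                rest_pending = False
                if k < n_transits and rng.random() < config.rest_prob:
                    extra = float(
                        rng.lognormal(math.log(config.rest_extra_median_s), 0.8)
                    )
                    dt_next += 180.0 + extra
                    rest_pending = True
                t_pass = t_pass + dt.timedelta(seconds=dt_next)
            # refractory burrowing: fish stays put >3 min after a bout, so
            # between-bout transitions always trip the transit filter
            busy_until = t_pass + dt.timedelta(seconds=181.0)
    records.sort(key=lambda r: (r.t_start, r.tag_id, r.antenna_id))
    transitions.sort(key=lambda t: (t.t_start, t.tag_id))
    truth = GroundTruth(
        transitions=transitions,
        movers=movers,
        n_fish=config.n_fish,
        n_crosstalk_injected=n_crosstalk,
        n_rest_injected=n_rest,
        n_teleport_injected=n_teleport,
    )
    return records, truth


def simulate_linear_stream(
    config: SimulationConfig,
    geometry: SiteGeometry | None = None,
    solar: SolarTable | None = None,
) -> tuple[list[DetectionRecord], list[dict], GroundTruth]:
    """Simulate the release-and-drift stream design.

    Returns ``(records, recapture_table, ground_truth)``; the recapture table
    has one row per released fish with ``tag_id``, ``transit_night``,
    ``recaptured`` and ``detected`` flags for detection-probability
    estimation.
    """
    if config.topology != "stream":
        raise ValueError("config.topology must be 'stream'")
    geometry = geometry or stream_geometry()
    solar = solar or SolarTable(geometry)
    rng = np.random.default_rng(config.seed)
    tz = geometry.tzinfo
    release = config.start or dt.datetime(2014, 11, 3, 11, 0, tzinfo=tz)
    # cumulative distance from release to each array, downstream order
    array_dist = {}
    d = 4800.0
    array_dist[geometry.antennas[0]] = d
    for a, b in geometry.adjacent_pairs():
        d += geometry.pair_distance_m[(a, b)]
        array_dist[b] = d
    trap_dist = 5600.0

    records: list[DetectionRecord] = []
    table: list[dict] = []
    transitions: list[TrueTransition] = []
    recaptured: list[str] = []
    detected: list[str] = []
    lo, hi = config.drift_speed_range
    for i in range(config.n_released):
        tag = f"S{i + 1:03d}"
        night = int(rng.geometric(config.first_night_prob))
        row = {
            "tag_id": tag,
            "transit_night": night,
            "recaptured": False,
            "detected": False,
            "n_arrays": 0,
        }
        if night > config.night_horizon:
            table.append(row)
            continue
        sunset = solar.day(release.date() + dt.timedelta(days=night - 1)).sunset
        t0 = sunset + dt.timedelta(
            seconds=config.dark_offset_base_s
            + float(rng.exponential(config.dark_offset_scale_s))
        )
        speed = float(rng.uniform(lo, hi))
        pass_times = {}
        for antenna in geometry.antennas:
            t = t0 + dt.timedelta(seconds=array_dist[antenna] / speed)
            pass_times[antenna] = _round_s(t)
            if rng.random() < config.per_array_detection_prob:
                _emit_passage(records, tag, antenna, t, min(speed, 0.3))
                row["n_arrays"] += 1
        for a, b in geometry.adjacent_pairs():
            transitions.append(
                TrueTransition(
                    tag_id=tag,
                    origin=a,
                    dest=b,
                    t_start=pass_times[a],
                    t_end=pass_times[b],
                    diel=solar.classify(pass_times[a]).value,
                )
            )
        row["detected"] = row["n_arrays"] > 0
        if rng.random() < config.recapture_prob:
            row["recaptured"] = True
            recaptured.append(tag)
        if row["detected"]:
            detected.append(tag)
        table.append(row)
    records.sort(key=lambda r: (r.t_start, r.tag_id, r.antenna_id))
    transitions.sort(key=lambda t: (t.t_start, t.tag_id))
    truth = GroundTruth(
        transitions=transitions,
        movers=[r["tag_id"] for r in table if r["transit_night"] <= config.night_horizon],
        n_fish=config.n_released,
        recaptured_tags=recaptured,
        detected_tags=detected,
    )
    return records, table, truth


_TRUTH_COLUMNS = [
    "tag_id",
    "origin",
    "dest",
    "t_start",
    "t_end",
    "direction",
    "diel",
    "between_bouts",
    "rested",
]


def ground_truth_report(
    truth: GroundTruth, path: str | Path, utc_offset_hr: float
) -> Path:
    """Write the true transition table to CSV for pipeline-vs-truth diffing."""
    tz = dt.timezone(dt.timedelta(hours=utc_offset_hr))
    fmt = "%Y-%m-%d %H:%M:%S"
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRUTH_COLUMNS)
        for t in truth.transitions:
            writer.writerow(
                [
                    t.tag_id,
                    t.origin,
                    t.dest,
                    t.t_start.astimezone(tz).strftime(fmt),
                    t.t_end.astimezone(tz).strftime(fmt),
                    t.direction,
                    t.diel,
                    int(t.between_bouts),
                    int(t.rested),
                ]
            )
    return path


def read_ground_truth_report(
    path: str | Path, utc_offset_hr: float
) -> list[TrueTransition]:
    tz = dt.timezone(dt.timedelta(hours=utc_offset_hr))
    fmt = "%Y-%m-%d %H:%M:%S"
    out = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                TrueTransition(
                    tag_id=row["tag_id"],
                    origin=row["origin"],
                    dest=row["dest"],
                    t_start=dt.datetime.strptime(row["t_start"], fmt).replace(tzinfo=tz),
                    t_end=dt.datetime.strptime(row["t_end"], fmt).replace(tzinfo=tz),
                    direction=row["direction"],
                    diel=row["diel"],
                    between_bouts=bool(int(row["between_bouts"])),
                    rested=bool(int(row["rested"])),
                )
            )
    return out
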