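"""Reading and writing detection logs, geometry configs, and reports.

Detection logs are delimited text in the dialect emitted by multi-antenna HDX
readers: one row per scan with tag ID, antenna ID, timestamp and an optional
scan duration.  The default dialect is CSV with header
``tag_id,antenna_id,timestamp[,duration_s]``; :class:`LogDialect` remaps
column names, delimiter and timestamp format for other reader firmwares.

Malformed rows are never silently dropped: the reader quarantines them with a
reason into a rejects list that can be written out as a CSV report, so the
downstream filter ledger accounts for every input record.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .model import DetectionRecord, SiteGeometry

__all__ = [
    "LogDialect",
    "RejectedRow",
    "ReadResult",
    "read_detection_log",
    "write_detection_log",
    "write_rejects_report",
    "load_geometry",
    "save_geometry",
    "raceway_geometry",
    "stream_geometry",
]

DEFAULT_TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M:%S"


@dataclass(frozen=True)
class LogDialect:
    """Column mapping and timestamp convention of a detection-log file."""

    tag_column: str = "tag_id"
    antenna_column: str = "antenna_id"
    timestamp_column: str = "timestamp"
    duration_column: str | None = "duration_s"
    timestamp_format: str = DEFAULT_TIMESTAMP_FORMAT
    utc_offset_hr: float = 0.0
    delimiter: str = ","

    @property
    def tzinfo(self) -> dt.timezone:
        return dt.timezone(dt.timedelta(hours=self.utc_offset_hr))

    def parse_timestamp(self, text: str) -> dt.datetime:
        naive = dt.datetime.strptime(text.strip(), self.timestamp_format)
        return naive.replace(tzinfo=self.tzinfo)

    def format_timestamp(self, t: dt.datetime) -> str:
        return t.astimezone(self.tzinfo).strftime(self.timestamp_format)


@dataclass(frozen=True)
class RejectedRow:
    line_number: int
    reason: str
    raw: str


@dataclass
class ReadResult:
    records: list[DetectionRecord]
    rejects: list[RejectedRow] = field(default_factory=list)

    @property
    def n_rejects(self) -> int:
        return len(self.rejects)


class ConfigurationError(ValueError):
    """A log or geometry config is internally inconsistent."""


def read_detection_log(path: str | Path, dialect: LogDialect | None = None) -> ReadResult:
    """Parse a delimited detection log into records plus quarantined rejects.

    Raises :class:`ConfigurationError` when a mandatory column named by the
    dialect is absent from the header.  Rows with unparseable timestamps or
    empty mandatory fields become :class:`RejectedRow` entries, not records.
    """
    dialect = dialect or LogDialect()
    path = Path(path)
    records: list[DetectionRecord] = []
    rejects: list[RejectedRow] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        for col in (dialect.tag_column, dialect.antenna_column, dialect.timestamp_column):
            if col not in header:
                raise ConfigurationError(
                    f"mandatory column {col!r} missing from header {header}"
                )
        has_duration = (
            dialect.duration_column is not None and dialect.duration_column in header
        )
        for i, row in enumerate(reader, start=2):  # header is line 1
            raw = dialect.delimiter.join(str(v) for v in row.values() if v is not None)
            tag = (row.get(dialect.tag_column) or "").strip()
            antenna = (row.get(dialect.antenna_column) or "").strip()
            ts_text = (row.get(dialect.timestamp_column) or "").strip()
            if not tag or not antenna or not ts_text:
                rejects.append(RejectedRow(i, "empty mandatory field", raw))
                continue
            try:
                t_start = dialect.parse_timestamp(ts_text)
            except ValueError as exc:
                rejects.append(RejectedRow(i, f"bad timestamp: {exc}", raw))
                continue
            t_end = t_start
            if has_duration:
                dur_text = (row.get(dialect.duration_column) or "").strip()
                if dur_text:
                    try:
                        dur = float(dur_text)
                    except ValueError:
                        rejects.append(RejectedRow(i, "bad duration", raw))
                        continue
                    if dur < 0:
                        rejects.append(RejectedRow(i, "negative duration", raw))
                        continue
                    t_end = t_start + dt.timedelta(seconds=dur)
            records.append(DetectionRecord(tag, antenna, t_start, t_end))
    return ReadResult(records=records, rejects=rejects)


def write_detection_log(
    records: Iterable[DetectionRecord],
    path: str | Path,
    dialect: LogDialect | None = None,
) -> Path:
    """Write records in the given dialect; inverse of :func:`read_detection_log`."""
    dialect = dialect or LogDialect()
    path = Path(path)
    columns = [dialect.tag_column, dialect.antenna_column, dialect.timestamp_column]
    if dialect.duration_column is not None:
        columns.append(dialect.duration_column)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(columns)
        for rec in records:
            row = [
                rec.tag_id,
                rec.antenna_id,
                dialect.format_timestamp(rec.t_start),
            ]
            if dialect.duration_column is not None:
                row.append(f"{rec.duration_s:g}")
            writer.writerow(row)
    return path


def write_rejects_report(rejects: Sequence[RejectedRow], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["line_number", "reason", "raw"])
        for r in rejects:
            writer.writerow([r.line_number, r.reason, r.raw])
    return path


# ---------------------------------------------------------------------------
# Geometry configs
# ---------------------------------------------------------------------------

def _geometry_from_mapping(cfg: dict) -> SiteGeometry:
    try:
        antennas = [str(a) for a in cfg["antennas"]]
        distances = {
            (str(k.split("->")[0]), str(k.split("->")[1])): float(v)
            for k, v in cfg["pair_distance_m"].items()
        }
        geom = SiteGeometry(
            topology=cfg["topology"],
            antennas=tuple(antennas),
            pair_distance_m=distances,
            circumference_m=cfg.get("circumference_m"),
            latitude_deg=float(cfg["latitude_deg"]),
            longitude_deg=float(cfg["longitude_deg"]),
            utc_offset_hr=float(cfg["utc_offset_hr"]),
            name=str(cfg.get("name", "site")),
        )
    except KeyError as exc:
        raise ConfigurationError(f"geometry config missing key {exc}") from None
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from None
    return geom


def load_geometry(path: str | Path) -> SiteGeometry:
    """Load a site geometry from a YAML config, enforcing its invariants."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("geometry config must be a mapping")
    return _geometry_from_mapping(cfg)


def save_geometry(geometry: SiteGeometry, path: str | Path) -> Path:
    cfg = {
        "name": geometry.name,
        "topology": geometry.topology,
        "antennas": list(geometry.antennas),
        "pair_distance_m": {
            f"{a}->{b}": d for (a, b), d in geometry.pair_distance_m.items()
        },
        "latitude_deg": geometry.latitude_deg,
        "longitude_deg": geometry.longitude_deg,
        "utc_offset_hr": geometry.utc_offset_hr,
    }
    if geometry.circumference_m is not None:
        cfg["circumference_m"] = geometry.circumference_m
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path


def raceway_geometry() -> SiteGeometry:
    """Bundled preset: 4-antenna circular raceway, 15 m centerline circumference.

    The exact per-pair antenna spacing of the physical channel is not known,
    so spacing defaults to circumference/4 = 3.75 m per adjacent pair.  The
    site is on Lake Huron (Hammond Bay area), fixed UTC offset -5 h.
    """
    antennas = ("A1", "A2", "A3", "A4")
    spacing = 15.0 / 4
    pairs = {("A1", "A2"): spacing, ("A2", "A3"): spacing,
             ("A3", "A4"): spacing, ("A4", "A1"): spacing}
    return SiteGeometry(
        topology="circular",
        antennas=antennas,
        pair_distance_m=pairs,
        circumference_m=15.0,
        latitude_deg=45.497,
        longitude_deg=-84.026,
        utc_offset_hr=-5.0,
        name="raceway",
    )


def stream_geometry() -> SiteGeometry:
    """Bundled preset: three in-stream antenna arrays 4.8/5.0/5.2 km below a
    release point on Morpion Stream (Quebec), i.e. adjacent spacing 200 m,
    fixed UTC offset -5 h.  Arrays are ordered in downstream-flow order."""
    antennas = ("array3", "array2", "array1")  # array3 is upstream-most (4.8 km)
    pairs = {("array3", "array2"): 200.0, ("array2", "array1"): 200.0}
    return SiteGeometry(
        topology="linear",
        antennas=antennas,
        pair_distance_m=pairs,
        latitude_deg=45.1732,
        longitude_deg=-73.0381,
        utc_offset_hr=-5.0,
        name="stream",
    )
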