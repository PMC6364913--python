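"""Solar day/night boundaries and diel classification of movements.

Sunrise and sunset are computed with the NOAA solar-position equations
(Julian-century polynomial series for solar longitude, anomaly, obliquity and
the equation of time) at the standard refraction-corrected zenith of
90.833 deg.  Accuracy is within about a minute of almanac values for
mid-latitudes; polar-circle sites, where the hour-angle equation has no
solution on some dates, are rejected.  A user-supplied sunrise/sunset table
(CSV ``date,sunrise,sunset``) can override computation entirely so analyses
can be pinned to any almanac.

Day is the half-open interval [sunrise, sunset); night spans sunset to the
next sunrise.  Movements are anchored by their start time; movements whose
start and end fall in different diel periods are flagged as boundary
spanners so the anchor choice stays auditable.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import Diel, Direction, MovementEvent, SiteGeometry, SolarDay

__all__ = [
    "solar_events",
    "SolarTable",
    "load_solar_table",
    "classify_diel",
    "assign_diel_to_movements",
    "diel_capture_tally",
    "hourly_histogram",
    "daily_activity",
]

SUN_ZENITH_DEG = 90.833  # official sunrise/sunset: refraction + solar radius


def _julian_day(date: dt.date, utc_offset_hr: float) -> float:
    """Julian day number at local noon of ``date`` for the given UTC offset."""
    # date.toordinal() is days since 0001-01-01; JD of that epoch's midnight
    # is 1721424.5, so local noon UT = ordinal + 1721425.0 - offset/24
    return date.toordinal() + 1721425.0 - utc_offset_hr / 24.0


def _solar_parameters(jd: float) -> tuple[float, float]:
    """(equation_of_time_minutes, solar_declination_deg) for a Julian day."""
    jc = (jd - 2451545.0) / 36525.0
    geom_mean_long = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    m_rad = math.radians(geom_mean_anom)
    eq_of_center = (
        math.sin(m_rad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * m_rad) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * m_rad) * 0.000289
    )
    true_long = geom_mean_long + eq_of_center
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - 0.001813 * jc))) / 60.0) / 60.0
    obliq_corr = mean_obliq + 0.00256 * math.cos(omega)
    obliq_rad = math.radians(obliq_corr)
    decl = math.degrees(math.asin(math.sin(obliq_rad) * math.sin(math.radians(app_long))))
    var_y = math.tan(obliq_rad / 2.0) ** 2
    l_rad = math.radians(geom_mean_long)
    eq_time = 4.0 * math.degrees(
        var_y * math.sin(2 * l_rad)
        - 2.0 * ecc * math.sin(m_rad)
        + 4.0 * ecc * var_y * math.sin(m_rad) * math.cos(2 * l_rad)
        - 0.5 * var_y**2 * math.sin(4 * l_rad)
        - 1.25 * ecc**2 * math.sin(2 * m_rad)
    )
    return eq_time, decl


def solar_events(
    latitude_deg: float,
    longitude_deg: float,
    date: dt.date,
    utc_offset_hr: float,
) -> SolarDay:
    """Sunrise and sunset for one date at a site, in the site's fixed offset.

    Longitude is east-positive decimal degrees.  Raises for latitudes at or
    beyond the polar circles, where the day/night boundary can vanish.
    """
    if abs(latitude_deg) >= 66.5:
        raise ValueError("polar-circle latitudes are not supported")
    jd = _julian_day(date, utc_offset_hr)
    eq_time, decl = _solar_parameters(jd)
    lat_rad = math.radians(latitude_deg)
    decl_rad = math.radians(decl)
    cos_ha = (
        math.cos(math.radians(SUN_ZENITH_DEG)) / (math.cos(lat_rad) * math.cos(decl_rad))
        - math.tan(lat_rad) * math.tan(decl_rad)
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError(f"sun does not rise/set at {latitude_deg} deg on {date}")
    ha_deg = math.degrees(math.acos(cos_ha))
    solar_noon_min = 720.0 - 4.0 * longitude_deg - eq_time + utc_offset_hr * 60.0
    sunrise_min = solar_noon_min - 4.0 * ha_deg
    sunset_min = solar_noon_min + 4.0 * ha_deg
    tz = dt.timezone(dt.timedelta(hours=utc_offset_hr))
    midnight = dt.datetime.combine(date, dt.time(0), tzinfo=tz)
    return SolarDay(
        date=date,
        sunrise=midnight + dt.timedelta(minutes=sunrise_min),
        sunset=midnight + dt.timedelta(minutes=sunset_min),
    )


class SolarTable:
    """Per-date sunrise/sunset lookup for a site.

    Computes days on demand via :func:`solar_events` unless an explicit
    date -> :class:`~pitmove.model.SolarDay` mapping overrides them.
    """

    def __init__(
        self,
        geometry: SiteGeometry | None = None,
        overrides: Mapping[dt.date, SolarDay] | None = None,
    ) -> None:
        if geometry is None and not overrides:
            raise ValueError("need a site geometry or an explicit solar table")
        self._geometry = geometry
        self._cache: dict[dt.date, SolarDay] = dict(overrides or {})

    def day(self, date: dt.date) -> SolarDay:
        if date not in self._cache:
            if self._geometry is None:
                raise KeyError(f"no solar entry for {date} and no site to compute one")
            self._cache[date] = solar_events(
                self._geometry.latitude_deg,
                self._geometry.longitude_deg,
                date,
                self._geometry.utc_offset_hr,
            )
        return self._cache[date]

    def classify(self, t: dt.datetime) -> Diel:
        return classify_diel(t, self.day(t.date()))


def load_solar_table(
    path: str | Path, utc_offset_hr: float, geometry: SiteGeometry | None = None
) -> SolarTable:
    """Read a ``date,sunrise,sunset`` CSV into a :class:`SolarTable`.

    Times are ``HH:MM`` or ``HH:MM:SS`` local clock at the given offset.
    """
    tz = dt.timezone(dt.timedelta(hours=utc_offset_hr))
    overrides: dict[dt.date, SolarDay] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            date = dt.date.fromisoformat(row["date"].strip())
            times = []
            for key in ("sunrise", "sunset"):
                text = row[key].strip()
                fmt = "%H:%M:%S" if text.count(":") == 2 else "%H:%M"
                times.append(
                    dt.datetime.combine(
                        date, dt.datetime.strptime(text, fmt).time(), tzinfo=tz
                    )
                )
            overrides[date] = SolarDay(date=date, sunrise=times[0], sunset=times[1])
    return SolarTable(geometry=geometry, overrides=overrides)


def classify_diel(t: dt.datetime, solar_day: SolarDay) -> Diel:
    """Day iff sunrise <= t < sunset on the timestamp's date; else night."""
    if t.date() != solar_day.date:
        raise ValueError("solar_day does not cover the timestamp's date")
    return Diel.DAY if solar_day.sunrise <= t < solar_day.sunset else Diel.NIGHT


def assign_diel_to_movements(
    movements: Iterable[MovementEvent], solar: SolarTable
) -> list[MovementEvent]:
    """Classify each movement by its start time; flag boundary spanners.

    Transits are short (bounded by the transit filter), so the choice of the
    start as diel anchor rarely matters; the flag records when it would.
    """
    out = []
    for mv in movements:
        start_diel = solar.classify(mv.t_start)
        end_diel = solar.classify(mv.t_end)
        mv.diel = start_diel
        mv.diel_boundary = start_diel != end_diel
        out.append(mv)
    return out


def diel_capture_tally(
    captures: Iterable[dt.datetime | tuple[dt.datetime, str]],
    solar: SolarTable | None = None,
) -> dict:
    """Tally captures per diel bin and per 24-h period.

    Accepts plain timestamps (classified through ``solar``) or
    ``(timestamp, label)`` pairs where label is ``"day"``/``"night"`` for
    captures known only to a net-service interval (sunrise-to-sunset bins).
    Returns ``{"day": int, "night": int, "by_date": {date: {"day": d, "night": n}}}``.
    """
    day = night = 0
    by_date: dict[dt.date, dict[str, int]] = defaultdict(lambda: {"day": 0, "night": 0})
    for item in captures:
        if isinstance(item, tuple):
            t, label = item
            diel = Diel(label)
        else:
            t = item
            if solar is None:
                raise ValueError("plain timestamps require a solar table")
            diel = solar.classify(t)
        if diel is Diel.DAY:
            day += 1
            by_date[t.date()]["day"] += 1
        else:
            night += 1
            by_date[t.date()]["night"] += 1
    return {"day": day, "night": night, "by_date": dict(by_date)}


def hourly_histogram(
    movements: Sequence[MovementEvent],
) -> tuple[dict[str, np.ndarray], dict[str, list[int]]]:
    """Per-tag 24-bin counts of movement starts by local clock hour.

    Returns ``(counts, modes)`` where ``counts[tag]`` is a length-24 integer
    array and ``modes[tag]`` lists every hour attaining the per-tag maximum
    (ties all reported).
    """
    counts: dict[str, np.ndarray] = {}
    for mv in movements:
        arr = counts.setdefault(mv.tag_id, np.zeros(24, dtype=int))
        arr[mv.t_start.hour] += 1
    modes = {
        tag: [h for h in range(24) if arr[h] == arr.max()] for tag, arr in counts.items()
    }
    return counts, modes


def daily_activity(
    movements: Sequence[MovementEvent],
    study_days: Sequence[dt.date],
) -> dict:
    """Daily counts of active tags and per-tag active-day counts.

    A tag is active on a calendar day (site local time, midnight boundary)
    if it has at least one downstream movement starting that day.  Returns
    ``per_day`` (date -> number of distinct active tags over all
    ``study_days``), ``per_tag_days`` (tag -> number of active days), and
    their medians.
    """
    active: dict[dt.date, set[str]] = defaultdict(set)
    for mv in movements:
        if mv.direction is Direction.DOWNSTREAM:
            active[mv.t_start.date()].add(mv.tag_id)
    per_day = {d: len(active.get(d, ())) for d in study_days}
    per_tag_days: dict[str, int] = defaultdict(int)
    for d in study_days:
        for tag in active.get(d, ()):
            per_tag_days[tag] += 1
    counts = np.array(list(per_day.values()), dtype=float)
    tag_counts = np.array(list(per_tag_days.values()), dtype=float)
    return {
        "per_day": per_day,
        "per_tag_days": dict(per_tag_days),
        "median_active_per_day": float(np.median(counts)) if counts.size else 0.0,
        "median_days_active": float(np.median(tag_counts)) if tag_counts.size else 0.0,
    }
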