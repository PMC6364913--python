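"""Independent sunrise/sunset oracle for validating the solar module.

Uses the Astronomical Almanac low-precision solar ephemeris (mean longitude /
mean anomaly linear series, right ascension and declination via the ecliptic)
together with Greenwich mean sidereal time, and finds the instants where the
solar altitude crosses -0.8333 deg by bisection over local time.  This is a
different computation path than the equation-of-time / hour-angle closed form
used by the implementation, so agreement is a genuine cross-check.
"""

import datetime as dt
import math

_J2000 = dt.datetime(2000, 1, 1, 12, 0, tzinfo=dt.timezone.utc)
_ALT_HORIZON = -0.8333  # refraction + solar semidiameter


def _days_since_j2000(t: dt.datetime) -> float:
    return (t.astimezone(dt.timezone.utc) - _J2000).total_seconds() / 86400.0


def solar_altitude_deg(t: dt.datetime, lat_deg: float, lon_deg: float) -> float:
    n = _days_since_j2000(t)
    L = math.radians((280.460 + 0.9856474 * n) % 360.0)
    g = math.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = L + math.radians(1.915 * math.sin(g) + 0.020 * math.sin(2 * g))
    eps = math.radians(23.439 - 0.0000004 * n)
    ra = math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam))
    dec = math.asin(math.sin(eps) * math.sin(lam))
    gmst_deg = (280.46061837 + 360.98564736629 * n) % 360.0
    lst_deg = gmst_deg + lon_deg
    hour_angle = math.radians(lst_deg) - ra
    lat = math.radians(lat_deg)
    sin_alt = math.sin(lat) * math.sin(dec) + math.cos(lat) * math.cos(dec) * math.cos(
        hour_angle
    )
    return math.degrees(math.asin(sin_alt))


def _bisect_crossing(
    t_lo: dt.datetime, t_hi: dt.datetime, lat: float, lon: float, rising: bool
) -> dt.datetime:
    f_lo = solar_altitude_deg(t_lo, lat, lon) - _ALT_HORIZON
    f_hi = solar_altitude_deg(t_hi, lat, lon) - _ALT_HORIZON
    assert f_lo * f_hi < 0, "bracket does not contain a horizon crossing"
    for _ in range(40):
        mid = t_lo + (t_hi - t_lo) / 2
        f_mid = solar_altitude_deg(mid, lat, lon) - _ALT_HORIZON
        if (f_lo < 0) == (f_mid < 0):
            t_lo, f_lo = mid, f_mid
        else:
            t_hi, f_hi = mid, f_mid
    return t_lo + (t_hi - t_lo) / 2


def sunrise_sunset(
    date: dt.date, lat_deg: float, lon_deg: float, utc_offset_hr: float
) -> tuple[dt.datetime, dt.datetime]:
    """Sunrise and sunset instants on ``date`` in the site's fixed offset."""
    tz = dt.timezone(dt.timedelta(hours=utc_offset_hr))
    midnight = dt.datetime.combine(date, dt.time(0), tzinfo=tz)
    noon = midnight + dt.timedelta(hours=12)
    end = midnight + dt.timedelta(hours=24)
    sunrise = _bisect_crossing(midnight, noon, lat_deg, lon_deg, rising=True)
    sunset = _bisect_crossing(noon, end, lat_deg, lon_deg, rising=False)
    return sunrise, sunset
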