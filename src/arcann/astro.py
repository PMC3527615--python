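"""Solar day length from date and geographic position.

Day length — the time from sunrise to sunset, in hours — is one of the five
environmental covariates offered to the abundance models.  At Arctic
latitudes it spans the full 0–24 h range over the year (polar night to
polar day), which makes it a strong seasonal signal.

The computation uses the NOAA low-precision solar-position algorithm:
solar declination from the fractional year, then the sunrise hour angle
from the standard zenith of 90.833 degrees (solar radius plus mean
atmospheric refraction).  Accuracy is a few minutes, which is ample for a
covariate expressed in hours.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

__all__ = ["GeoDate", "day_length", "SUN_ZENITH_DEG"]

#: Effective zenith angle of the sun's upper limb at rise/set, degrees.
#: 90° + 16′ solar semi-diameter + 34′ mean refraction.
SUN_ZENITH_DEG = 90.833


@dataclass(frozen=True)
class GeoDate:
    """A calendar date at a geographic position.

    Parameters
    ----------
    date:
        Calendar date (UTC).
    latitude:
        Degrees north, in [-90, 90].
    longitude:
        Degrees east, in [-180, 180].
    """

    date: _dt.date
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if not isinstance(self.date, _dt.date):
            raise TypeError("date must be a datetime.date")


def _solar_declination_rad(gd: GeoDate) -> float:
    """Solar declination (radians) at local solar noon of the date.

    Fractional-year Fourier expansion (NOAA / Meeus low precision).  The
    fractional year is evaluated at local solar noon, i.e. 12 h minus
    longitude/15 in UTC, so the declination matches the middle of the
    local day.
    """
    year_days = 366 if _is_leap(gd.date.year) else 365
    solar_noon_utc_h = 12.0 - gd.longitude / 15.0
    gamma = (
        2.0
        * math.pi
        / year_days
        * (gd.date.timetuple().tm_yday - 1 + (solar_noon_utc_h - 12.0) / 24.0)
    )
    return (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def day_length(gd: GeoDate) -> float:
    """Hours from sunrise to sunset on the given date and position.

    Returns exactly 24.0 during polar day and exactly 0.0 during polar
    night; otherwise ``2 * H / 15`` hours where ``H`` is the sunrise hour
    angle in degrees from

    .. math::

        \\cos H = \\frac{\\cos z - \\sin\\phi \\sin\\delta}
                        {\\cos\\phi \\cos\\delta}

    with zenith :math:`z` = 90.833°, latitude :math:`\\phi` and solar
    declination :math:`\\delta`.
    """
    decl = _solar_declination_rad(gd)
    phi = math.radians(gd.latitude)
    cos_z = math.cos(math.radians(SUN_ZENITH_DEG))
    denom = math.cos(phi) * math.cos(decl)
    if denom == 0.0:  # exactly at a pole
        cos_h = math.inf if cos_z > math.sin(phi) * math.sin(decl) else -math.inf
    else:
        cos_h = (cos_z - math.sin(phi) * math.sin(decl)) / denom
    if cos_h <= -1.0:
        return 24.0  # sun never sets
    if cos_h >= 1.0:
        return 0.0  # sun never rises
    hour_angle_deg = math.degrees(math.acos(cos_h))
    return 2.0 * hour_angle_deg / 15.0
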