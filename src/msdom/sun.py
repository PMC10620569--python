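"""Sunrise and sunset times from the NOAA sunrise equation.

Good to a couple of minutes at mid-latitudes, which is ample for classifying
camera-trap detections as day or night.  A single study timezone (fixed UTC
offset, no DST arithmetic) is assumed; pass the offset in force during the
survey window.
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd

ZENITH_DEG = 90.833  # official sunrise/sunset zenith (refraction + solar radius)


def sun_times(lat: float, lon: float, day: date, utc_offset: float) -> tuple[float, float]:
    """(sunrise_hour, sunset_hour) as decimal local hours for one date."""
    n = day.toordinal() - date(day.year, 1, 1).toordinal() + 1
    # fractional year (radians), mid-day
    gamma = 2 * np.pi / 365 * (n - 1 + 0.5)
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(gamma) - 0.032077 * np.sin(gamma)
                       - 0.014615 * np.cos(2 * gamma) - 0.040849 * np.sin(2 * gamma))
    decl = (0.006918 - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
            - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
            - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma))
    lat_r = np.radians(lat)
    cos_ha = (np.cos(np.radians(ZENITH_DEG)) / (np.cos(lat_r) * np.cos(decl))
              - np.tan(lat_r) * np.tan(decl))
    if cos_ha > 1 or cos_ha < -1:
        raise ValueError("sun does not rise/set at this latitude and date")
    ha = np.degrees(np.arccos(cos_ha))  # degrees
    # minutes, local standard time
    sunrise = 720 - 4 * (lon + ha) - eqtime + utc_offset * 60
    sunset = 720 - 4 * (lon - ha) - eqtime + utc_offset * 60
    return float(sunrise / 60), float(sunset / 60)


def make_sun_table(start: date, end: date, lat: float, lon: float,
                   utc_offset: float) -> pd.DataFrame:
    """Per-date sunrise/sunset table (decimal hours) for an inclusive range."""
    rows = []
    d = start
    while d <= end:
        rise, set_ = sun_times(lat, lon, d, utc_offset)
        rows.append((d, rise, set_))
        d += timedelta(days=1)
    return pd.DataFrame(rows, columns=["date", "sunrise_hour", "sunset_hour"])
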