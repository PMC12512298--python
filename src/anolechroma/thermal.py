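"""Grid-cell assignment and hourly temperature reconstruction.

Observations are binned to a regular 25-km grid via a local equirectangular
projection, and the ambient temperature at each observation's hour is
reconstructed from that cell's daily minimum/maximum using a sine curve for
daytime warming and a logarithmic decay for nighttime cooling (the Linvill
1990 formulation: sine over ``daylength + 4`` hours; decay from the sunset
temperature to the next morning's minimum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from anolechroma.errors import DegenerateInputError, InvalidInputError

__all__ = [
    "EARTH_RADIUS_M",
    "GridSpec",
    "DielProfile",
    "project_equirectangular",
    "assign_grid_cell",
    "solar_times",
    "hourly_temperature",
    "attach_temperatures",
]

EARTH_RADIUS_M = 6_371_000.0

#: hours added to daylength in the sine divisor of the daytime curve
_SINE_PAD_H = 4.0


@dataclass(frozen=True)
class GridSpec:
    """Regular square grid in a local equirectangular projection.

    ``origin`` is the projected (x, y) of the data bounding-box minimum;
    cells are half-open ``[edge, edge + cell_size)`` so an observation on a
    cell edge belongs to the higher cell.
    """

    origin: tuple[float, float]
    reference_latitude: float
    cell_size: float = 25_000.0

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise InvalidInputError(f"cell_size must be > 0, got {self.cell_size}")

    @classmethod
    def from_points(
        cls, latitudes, longitudes, cell_size: float = 25_000.0
    ) -> "GridSpec":
        """Grid covering the bounding box of the given points; reference
        latitude is the latitude centroid."""
        lats = np.asarray(latitudes, dtype=float)
        lons = np.asarray(longitudes, dtype=float)
        if lats.size == 0:
            raise InvalidInputError("no points given")
        ref = float(lats.mean())
        x, y = project_equirectangular(lats, lons, ref)
        return cls(
            origin=(float(np.min(x)), float(np.min(y))),
            reference_latitude=ref,
            cell_size=cell_size,
        )

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin[0],
            "origin_y": self.origin[1],
            "reference_latitude": self.reference_latitude,
            "cell_size": self.cell_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            origin=(float(d["origin_x"]), float(d["origin_y"])),
            reference_latitude=float(d["reference_latitude"]),
            cell_size=float(d["cell_size"]),
        )


def project_equirectangular(latitude, longitude, reference_latitude: float):
    """(lat, lon) degrees -> (x, y) meters, local equirectangular."""
    lat = np.asarray(latitude, dtype=float)
    lon = np.asarray(longitude, dtype=float)
    x = EARTH_RADIUS_M * np.radians(lon) * math.cos(math.radians(reference_latitude))
    y = EARTH_RADIUS_M * np.radians(lat)
    return x, y


def assign_grid_cell(latitude, longitude, grid: GridSpec):
    """Deterministic (col, row) cell id of a point.

    Accepts scalars (returns a tuple of ints) or arrays (returns two int
    arrays).  Cells are half-open on each axis.
    """
    lat = np.asarray(latitude, dtype=float)
    lon = np.asarray(longitude, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise InvalidInputError("coordinates must be finite")
    x, y = project_equirectangular(lat, lon, grid.reference_latitude)
    col = np.floor((x - grid.origin[0]) / grid.cell_size).astype(int)
    row = np.floor((y - grid.origin[1]) / grid.cell_size).astype(int)
    if lat.ndim == 0:
        return int(col), int(row)
    return col, row


def solar_times(latitude, day_of_year):
    """(sunrise, sunset, daylength) in local solar hours.

    Declination 23.45 deg * sin(2*pi*(284 + doy)/365); the hour-angle
    arccos argument is clamped to [-1, 1] so polar day/night degrade to
    24 h / 0 h daylength instead of erroring.
    """
    lat = np.asarray(latitude, dtype=float)
    doy = np.minimum(np.asarray(day_of_year, dtype=float), 365.0)  # leap-day fold
    decl = np.radians(23.45) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    cos_omega = np.clip(-np.tan(np.radians(lat)) * np.tan(decl), -1.0, 1.0)
    omega = np.arccos(cos_omega)
    daylength = omega * 24.0 / np.pi
    sunrise = 12.0 - daylength / 2.0
    sunset = 12.0 + daylength / 2.0
    if lat.ndim == 0:
        return float(sunrise), float(sunset), float(daylength)
    return sunrise, sunset, daylength


@dataclass(frozen=True)
class DielProfile:
    """Daily min/max temperatures plus the solar times governing one day's
    diel cycle.  ``tmin_next`` is the following morning's minimum, the
    target of the nighttime decay."""

    tmin: float
    tmax: float
    tmin_next: float
    sunrise: float
    sunset: float
    daylength: float

    def __post_init__(self) -> None:
        if self.tmin > self.tmax:
            raise InvalidInputError(f"tmin {self.tmin} > tmax {self.tmax}")
        if not (0.0 < self.daylength <= 24.0):
            raise InvalidInputError(f"daylength {self.daylength} outside (0, 24]")
        if abs((self.sunset - self.sunrise) - self.daylength) > 1e-9:
            raise InvalidInputError("sunset - sunrise must equal daylength")

    @classmethod
    def for_day(
        cls, tmin: float, tmax: float, tmin_next: float,
        latitude: float, day_of_year: int,
    ) -> "DielProfile":
        sunrise, sunset, daylength = solar_times(latitude, day_of_year)
        return cls(tmin, tmax, tmin_next, sunrise, sunset, daylength)


def _hourly_core(tmin, tmax, tmin_next, sunrise, sunset, daylength, hour):
    """Vectorized diel temperature; all args broadcastable float arrays."""
    tmin, tmax, tmin_next, sunrise, sunset, daylength, hour = np.broadcast_arrays(
        *(np.asarray(a, dtype=float)
          for a in (tmin, tmax, tmin_next, sunrise, sunset, daylength, hour))
    )
    is_day = (hour >= sunrise) & (hour <= sunset)
    if np.any(~is_day & (daylength >= 23.0)):
        raise DegenerateInputError(
            "night decay undefined for daylength >= 23 h"
        )
    t_day = tmin + (tmax - tmin) * np.sin(
        np.pi * (hour - sunrise) / (daylength + _SINE_PAD_H)
    )
    t_sunset = tmin + (tmax - tmin) * np.sin(
        np.pi * daylength / (daylength + _SINE_PAD_H)
    )
    # hours since sunset; pre-dawn hours continue the decay begun the
    # previous evening (the profile is the day whose night this is)
    elapsed = np.where(hour > sunset, hour - sunset, hour + 24.0 - sunset)
    elapsed = np.maximum(elapsed, 1.0)  # log floor
    night_len = 24.0 - daylength
    with np.errstate(divide="ignore", invalid="ignore"):
        t_night = t_sunset - (t_sunset - tmin_next) / np.log(night_len) * np.log(elapsed)
    return np.where(is_day, t_day, t_night)


def hourly_temperature(profile: DielProfile, hour: float) -> float:
    """Temperature at a local solar hour from a day's diel profile.

    Daytime (sunrise <= hour <= sunset) follows a sine from ``tmin`` at
    sunrise, peaking at ``tmax`` at sunrise + (daylength + 4)/2.  After
    sunset the temperature decays logarithmically from the sunset value
    toward ``tmin_next`` (reached at the next sunrise); hours before
    sunrise are treated as the tail of the profile's own night, so callers
    should pass the previous day's profile for pre-dawn observations.
    """
    if not (0.0 <= hour < 24.0):
        raise InvalidInputError(f"hour {hour} outside [0, 24)")
    return float(
        _hourly_core(
            profile.tmin, profile.tmax, profile.tmin_next,
            profile.sunrise, profile.sunset, profile.daylength, hour,
        )
    )


def _daily_lookup(daily: pd.DataFrame) -> dict:
    tbl = {}
    for row in daily.itertuples(index=False):
        key = (int(row.cell_col), int(row.cell_row), pd.Timestamp(row.date).normalize())
        tbl[key] = (float(row.tmin), float(row.tmax))
    return tbl


def attach_temperatures(
    records: pd.DataFrame, daily: pd.DataFrame, grid: GridSpec
) -> tuple[pd.DataFrame, dict]:
    """Add an ``hourly_temp`` column to records from a daily-temperature table.

    ``daily`` must have columns cell_col, cell_row, date, tmin, tmax.
    Records whose required daily rows are missing (the observation's
    cell/date, plus next-day tmin for post-sunset hours or the previous
    day for pre-dawn hours) are dropped; the returned log counts them.
    """
    if daily is None or len(daily) == 0:
        raise InvalidInputError("daily temperature table is empty")
    required = {"latitude", "longitude", "date", "hour"}
    missing = required - set(records.columns)
    if missing:
        raise InvalidInputError(f"records missing columns: {sorted(missing)}")

    lookup = _daily_lookup(daily)
    cols, rows = assign_grid_cell(
        records["latitude"].to_numpy(), records["longitude"].to_numpy(), grid
    )
    dates = pd.to_datetime(records["date"]).dt.normalize()
    lats = records["latitude"].to_numpy(dtype=float)
    hours = records["hour"].to_numpy(dtype=float)

    temps = np.full(len(records), np.nan)
    one_day = pd.Timedelta(days=1)
    for i in range(len(records)):
        key = (int(cols[i]), int(rows[i]), dates.iloc[i])
        doy = int(dates.iloc[i].dayofyear)
        sunrise, sunset, daylength = solar_times(lats[i], doy)
        try:
            if hours[i] < sunrise:
                # tail of the previous night: previous day's profile,
                # decaying to this morning's minimum
                prev_key = (key[0], key[1], dates.iloc[i] - one_day)
                if prev_key not in lookup or key not in lookup:
                    continue
                p_tmin, p_tmax = lookup[prev_key]
                profile = DielProfile.for_day(
                    p_tmin, p_tmax, tmin_next=lookup[key][0],
                    latitude=lats[i], day_of_year=max(doy - 1, 1),
                )
            else:
                if key not in lookup:
                    continue
                tmin, tmax = lookup[key]
                if hours[i] > sunset:
                    next_key = (key[0], key[1], dates.iloc[i] + one_day)
                    if next_key not in lookup:
                        continue
                    tmin_next = lookup[next_key][0]
                else:
                    tmin_next = tmin  # unused by the daytime branch
                profile = DielProfile(tmin, tmax, tmin_next, sunrise, sunset, daylength)
            temps[i] = hourly_temperature(profile, float(hours[i]))
        except DegenerateInputError:
            continue

    keep = np.isfinite(temps)
    out = records.loc[keep].copy()
    out["hourly_temp"] = temps[keep]
    log = {
        "input": int(len(records)),
        "dropped_missing_daily": int((~keep).sum()),
        "kept": int(keep.sum()),
    }
    return out, log
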