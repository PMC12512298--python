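"""Synthetic segment images, observation tables and daily temperatures.

Every downstream stage is testable without external data: segment images
plant a known organism color on a differently colored background; observed
green/brown outcomes follow a logistic model with a temperature effect in
the non-breeding season only, plus a cyclic seasonal term whose amplitude
changes linearly with latitude; daily temperatures follow a deterministic
seasonal sinusoid that cools with latitude.  All generators are
deterministic given the configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.special import expit

from anolechroma import thermal
from anolechroma.errors import InvalidInputError
from anolechroma.imagecolor import SegmentSample, classify_color
from anolechroma.models import assign_season, week_of_year, WEEKS_PER_YEAR

__all__ = [
    "SyntheticConfig",
    "gen_segment_image",
    "gen_daily_temps",
    "gen_observation_table",
    "gen_daily_temp_table",
    "make_grid",
    "write_bundle",
]

# defaults of the deterministic daily-temperature sinusoid
TEMP_BASE_C = 33.0  # tmax at latitude 25 on the warmest day
TEMP_LAPSE_PER_DEG = 0.5  # tmax decrease per degree latitude above 25
TEMP_SEASONAL_AMP_C = 10.0  # seasonal half-range of tmax
TEMP_DIURNAL_RANGE_C = 10.0  # tmax - tmin
TEMP_PEAK_DOY = 200.0
TEMP_REF_LAT = 25.0


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic world.  Effect sizes are configuration, not
    claims about the real system; green is coded 1 throughout."""

    n_records: int = 1000
    lat_range: tuple[float, float] = (25.0, 36.0)
    lon_range: tuple[float, float] = (-100.0, -78.0)
    date_range: tuple[Date, Date] = (Date(2022, 1, 1), Date(2023, 12, 31))
    hour_range: tuple[float, float] = (7.0, 19.0)
    beta0: float = -2.4
    beta_temp_nonbreeding: float = 0.12
    beta_breeding: float = 3.4
    beta_temp_breeding: float = 0.0
    season_amp0: float = 0.0
    season_amp_per_lat: float = -0.18
    noise_sd_image: float = 5.0
    organism_color_green: tuple[int, int, int] = (60, 140, 50)
    organism_color_brown: tuple[int, int, int] = (130, 85, 60)
    organism_color_unclear: tuple[int, int, int] = (100, 101, 100)
    background_color: tuple[int, int, int] = (150, 150, 120)
    unclear_fraction: float = 0.0
    missing_temp_fraction: float = 0.0
    image_size: tuple[int, int] = (48, 48)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise InvalidInputError("n_records must be >= 1")
        for name in ("lat_range", "lon_range", "hour_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidInputError(f"{name} must be a non-empty range")
        start, end = self.date_range
        if (pd.Timestamp(end) - pd.Timestamp(start)).days < 364:
            raise InvalidInputError("date_range must span at least one full year")
        if self.noise_sd_image < 0:
            raise InvalidInputError("noise_sd_image must be >= 0")
        if classify_color(self.organism_color_green) != "green":
            raise InvalidInputError("organism_color_green fails the green rule")
        if classify_color(self.organism_color_brown) != "brown":
            raise InvalidInputError("organism_color_brown fails the brown rule")
        if classify_color(self.organism_color_unclear) != "unclear":
            raise InvalidInputError("organism_color_unclear is not unclear")
        if not (0.0 <= self.unclear_fraction < 1.0):
            raise InvalidInputError("unclear_fraction must be in [0, 1)")
        if not (0.0 <= self.missing_temp_fraction < 1.0):
            raise InvalidInputError("missing_temp_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["date_range"] = [str(self.date_range[0]), str(self.date_range[1])]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "date_range" in d:
            d["date_range"] = tuple(
                pd.Timestamp(x).date() for x in d["date_range"]
            )
        for key in (
            "lat_range", "lon_range", "hour_range", "image_size",
            "organism_color_green", "organism_color_brown",
            "organism_color_unclear", "background_color",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def gen_segment_image(
    base_color, background_color, noise_sd: float, size=(48, 48), seed=0
) -> SegmentSample:
    """An elliptical organism blob of ``base_color`` on ``background_color``.

    The axis-aligned ellipse covers 20-60% of the frame; independent
    Gaussian channel noise is added everywhere and clipped to [0, 255].
    Identical arguments produce bit-identical images.
    """
    h, w = int(size[0]), int(size[1])
    if h < 32 or w < 32:
        raise InvalidInputError(f"size must be >= 32x32, got {h}x{w}")
    if noise_sd < 0:
        raise InvalidInputError(f"noise_sd must be >= 0, got {noise_sd}")
    base = np.array(base_color, dtype=float)
    bg = np.array(background_color, dtype=float)
    if base.shape != (3,) or bg.shape != (3,):
        raise InvalidInputError("colors must have 3 channels")
    if (base < 0).any() or (base > 255).any() or (bg < 0).any() or (bg > 255).any():
        raise InvalidInputError("color channels outside [0, 255]")

    rng = np.random.default_rng(seed)
    cy = h * (0.5 + rng.uniform(-0.03, 0.03))
    cx = w * (0.5 + rng.uniform(-0.03, 0.03))
    ay = h * rng.uniform(0.28, 0.38)  # semi-axes; area fraction in ~[0.25, 0.50]
    ax = w * rng.uniform(0.30, 0.42)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    img = np.where(mask[:, :, None], base, bg)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=(h, w, 3))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SegmentSample(
        image=img,
        mask=mask,
        planted_color=tuple(int(c) for c in base),
        planted_label=classify_color(tuple(int(c) for c in base)),
    )


def gen_daily_temps(latitude, day_of_year):
    """Deterministic (tmin, tmax) for a latitude and day of year.

    tmax = 33 - 0.5*(lat - 25) + 10*cos(2*pi*(doy - 200)/365);
    tmin = tmax - 10.
    """
    lat = np.asarray(latitude, dtype=float)
    doy = np.asarray(day_of_year, dtype=float)
    if np.any(np.abs(lat) > 66):
        raise InvalidInputError("latitude outside [-66, 66]")
    tmax = (
        TEMP_BASE_C
        - TEMP_LAPSE_PER_DEG * (lat - TEMP_REF_LAT)
        + TEMP_SEASONAL_AMP_C * np.cos(2.0 * np.pi * (doy - TEMP_PEAK_DOY) / 365.0)
    )
    tmin = tmax - TEMP_DIURNAL_RANGE_C
    if lat.ndim == 0 and doy.ndim == 0:
        return float(tmin), float(tmax)
    return tmin, tmax


def make_grid(config: SyntheticConfig) -> thermal.GridSpec:
    """The 25-km grid spanning the configured coordinate ranges."""
    return thermal.GridSpec.from_points(
        latitudes=list(config.lat_range), longitudes=list(config.lon_range)
    )


def _cell_center_latitude(row: np.ndarray, grid: thermal.GridSpec) -> np.ndarray:
    y = grid.origin[1] + (np.asarray(row, dtype=float) + 0.5) * grid.cell_size
    return np.degrees(y / thermal.EARTH_RADIUS_M)


def gen_daily_temp_table(
    records: pd.DataFrame, grid: thermal.GridSpec
) -> pd.DataFrame:
    """Daily min/max rows for every record's cell and date +/- one day.

    Temperatures come from :func:`gen_daily_temps` at the cell-center
    latitude, so re-attaching them reproduces the generator exactly.
    Deterministic (no randomness).
    """
    cols, rows = thermal.assign_grid_cell(
        records["latitude"].to_numpy(), records["longitude"].to_numpy(), grid
    )
    dates = pd.to_datetime(records["date"]).dt.normalize()
    frames = []
    for shift in (-1, 0, 1):
        frames.append(
            pd.DataFrame(
                {
                    "cell_col": cols,
                    "cell_row": rows,
                    "date": dates + pd.Timedelta(days=shift),
                }
            )
        )
    daily = pd.concat(frames).drop_duplicates().sort_values(
        ["cell_col", "cell_row", "date"], kind="stable"
    ).reset_index(drop=True)
    lat_c = _cell_center_latitude(daily["cell_row"].to_numpy(), grid)
    doy = np.minimum(daily["date"].dt.dayofyear.to_numpy(dtype=float), 365.0)
    tmin, tmax = gen_daily_temps(lat_c, doy)
    daily["tmin"] = tmin
    daily["tmax"] = tmax
    return daily


def gen_observation_table(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observation records plus their ground truth.

    Latitude, longitude, date and hour are uniform over the configured
    ranges.  The hourly temperature T at each record is reconstructed by
    the thermal module from the synthetic daily temperatures of the
    record's grid cell; the linear predictor is

        eta = beta0
            + beta_temp_nonbreeding * T          [non-breeding]
            + beta_breeding + beta_temp_breeding * T   [breeding]
            + (season_amp0 + season_amp_per_lat*(lat - lat_min))
              * cos(2*pi*week/52)

    and the green(1)/brown(0) label is Bernoulli(inv-logit(eta)).
    """
    n = config.n_records
    rng = np.random.default_rng(config.seed)
    lat = rng.uniform(*config.lat_range, size=n)
    lon = rng.uniform(*config.lon_range, size=n)
    start = pd.Timestamp(config.date_range[0])
    n_days = (pd.Timestamp(config.date_range[1]) - start).days + 1
    offsets = rng.integers(0, n_days, size=n)
    hour = rng.uniform(*config.hour_range, size=n)
    label_u = rng.random(size=n)

    dates = start + pd.to_timedelta(offsets, unit="D")
    records = pd.DataFrame(
        {
            "id": [f"rec{i:06d}" for i in range(n)],
            "latitude": lat,
            "longitude": lon,
            "date": dates,
            "hour": hour,
        }
    )
    records["week"] = week_of_year(records["date"])
    records["season"] = records["date"].map(assign_season)

    grid = make_grid(config)
    daily = gen_daily_temp_table(records, grid)
    attached, log = thermal.attach_temperatures(records, daily, grid)
    if log["dropped_missing_daily"]:
        raise AssertionError("internal daily table should cover every record")
    temp = attached["hourly_temp"].to_numpy()

    breeding = (records["season"] == "breeding").to_numpy(dtype=float)
    amp = config.season_amp0 + config.season_amp_per_lat * (
        lat - config.lat_range[0]
    )
    eta = (
        config.beta0
        + config.beta_temp_nonbreeding * temp * (1.0 - breeding)
        + (config.beta_breeding + config.beta_temp_breeding * temp) * breeding
        + amp * np.cos(2.0 * np.pi * records["week"].to_numpy() / WEEKS_PER_YEAR)
    )
    labels = np.where(label_u < expit(eta), "green", "brown")
    records["label"] = labels

    truth = pd.DataFrame(
        {
            "record_id": records["id"],
            "true_label": labels,
            "true_linear_predictor": eta,
            "true_hourly_temp": temp,
        }
    )
    return records, truth


def write_bundle(config: SyntheticConfig, out_dir) -> dict:
    """Write the full fixture bundle to ``out_dir``.

    Contents: ``images/*.png`` and ``masks/*.png`` (one pair per record;
    a configured fraction of organisms are planted with the unclear color),
    ``records.csv``, ``truth.csv``, ``daily_temps.csv`` (with a configured
    fraction of cell/date rows removed), and ``config.yaml`` (which also
    stores the grid so downstream stages reuse it exactly).
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    records, truth = gen_observation_table(config)
    grid = make_grid(config)
    daily = gen_daily_temp_table(records, grid)
    n = len(records)

    rng = np.random.default_rng([config.seed, 1])
    n_unclear = int(math.floor(config.unclear_fraction * n))
    unclear_idx = set(
        rng.choice(n, size=n_unclear, replace=False).tolist() if n_unclear else []
    )

    color_by_label = {
        "green": config.organism_color_green,
        "brown": config.organism_color_brown,
    }
    planted = []
    for i, (rec_id, label) in enumerate(zip(records["id"], records["label"])):
        color = (
            config.organism_color_unclear
            if i in unclear_idx
            else color_by_label[label]
        )
        sample = gen_segment_image(
            color,
            config.background_color,
            config.noise_sd_image,
            size=config.image_size,
            seed=np.random.SeedSequence([config.seed, 2, i]),
        )
        Image.fromarray(sample.image).save(out / "images" / f"{rec_id}.png")
        Image.fromarray((sample.mask * 255).astype(np.uint8)).save(
            out / "masks" / f"{rec_id}.png"
        )
        planted.append(sample.planted_label)
    truth = truth.copy()
    truth["planted_image_label"] = planted

    # remove the primary daily rows of a fraction of records to exercise
    # missing-temperature accounting downstream
    n_missing = int(math.floor(config.missing_temp_fraction * n))
    if n_missing:
        rng2 = np.random.default_rng([config.seed, 3])
        victims = rng2.choice(n, size=n_missing, replace=False)
        cols, rows = thermal.assign_grid_cell(
            records["latitude"].to_numpy(), records["longitude"].to_numpy(), grid
        )
        dates = pd.to_datetime(records["date"]).dt.normalize()
        drop_keys = {
            (int(cols[i]), int(rows[i]), dates.iloc[i]) for i in victims
        }
        keep = [
            (int(r.cell_col), int(r.cell_row), pd.Timestamp(r.date).normalize())
            not in drop_keys
            for r in daily.itertuples(index=False)
        ]
        daily = daily.loc[keep].reset_index(drop=True)

    records_out = records.copy()
    records_out["date"] = pd.to_datetime(records_out["date"]).dt.date
    records_out.to_csv(out / "records.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    daily_out = daily.copy()
    daily_out["date"] = pd.to_datetime(daily_out["date"]).dt.date
    daily_out.to_csv(out / "daily_temps.csv", index=False)

    meta = {"synthetic": config.to_dict(), "grid": grid.to_dict()}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)

    return {
        "bundle_dir": str(out),
        "records_csv": str(out / "records.csv"),
        "truth_csv": str(out / "truth.csv"),
        "daily_temps_csv": str(out / "daily_temps.csv"),
        "images_dir": str(out / "images"),
        "masks_dir": str(out / "masks"),
        "config_yaml": str(out / "config.yaml"),
    }
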