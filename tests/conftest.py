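import numpy as np
import pandas as pd
import pytest

from anolechroma import synthdata


@pytest.fixture(scope="session")
def small_table():
    """A 2000-record observation table with planted temperature effect,
    hourly_temp merged in from the truth table."""
    cfg = synthdata.SyntheticConfig(
        n_records=2000, seed=42, season_amp0=0.0, season_amp_per_lat=0.0
    )
    records, truth = synthdata.gen_observation_table(cfg)
    records = records.assign(hourly_temp=truth["true_hourly_temp"].to_numpy())
    return cfg, records, truth


def make_records_with_temp(n=2000, seed=0, **kwargs):
    cfg = synthdata.SyntheticConfig(n_records=n, seed=seed, **kwargs)
    records, truth = synthdata.gen_observation_table(cfg)
    return cfg, records.assign(hourly_temp=truth["true_hourly_temp"].to_numpy()), truth


def expected_missing_temp_drops(out_dir):
    """Oracle: scan a bundle's daily table for the rows each non-unclear
    record needs, counting records that cannot be temperature-attached."""
    import yaml

    from anolechroma import thermal

    bundle = out_dir / "bundle"
    with open(bundle / "config.yaml") as fh:
        meta = yaml.safe_load(fh)
    grid = thermal.GridSpec.from_dict(meta["grid"])
    records = pd.read_csv(bundle / "records.csv", parse_dates=["date"])
    truth = pd.read_csv(bundle / "truth.csv")
    daily = pd.read_csv(bundle / "daily_temps.csv", parse_dates=["date"])
    keys = {
        (int(r.cell_col), int(r.cell_row), r.date)
        for r in daily.itertuples(index=False)
    }
    clear = records[(truth["planted_image_label"] != "unclear").to_numpy()]
    drops = 0
    for rec in clear.itertuples(index=False):
        col, row = thermal.assign_grid_cell(rec.latitude, rec.longitude, grid)
        sunrise, sunset, _ = thermal.solar_times(rec.latitude, rec.date.dayofyear)
        need = [rec.date]
        if rec.hour < sunrise:
            need.append(rec.date - pd.Timedelta(days=1))
        elif rec.hour > sunset:
            need.append(rec.date + pd.Timedelta(days=1))
        if any((col, row, d) not in keys for d in need):
            drops += 1
    return drops
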