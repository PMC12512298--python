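"""End-to-end orchestration: images -> colors -> temperatures -> models.

Each stage reads and writes plain files inside an output directory, so the
CLI subcommands can be run individually or chained, and ``run_all``
reproduces the chained result exactly.  A retention log accounts for every
record dropped, attributing each drop to exactly one stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from anolechroma import imagecolor, models, synthdata, thermal
from anolechroma.errors import InvalidInputError

__all__ = [
    "RetentionLog",
    "load_config",
    "run_pipeline",
    "stage_simulate",
    "stage_extract_colors",
    "stage_attach_temperature",
    "stage_fit_models",
    "validate_against_truth",
]

log = logging.getLogger("anolechroma.pipeline")

DEFAULT_PARAMS = {"kmeans_k": 4, "ring_width": 20, "gam_knots": 8}


@dataclass
class RetentionLog:
    """Record counts at each pipeline stage; drops are attributed to
    exactly one stage and counts are monotonically nonincreasing."""

    input: int = 0
    segmented: int = 0
    color_labeled: int = 0
    after_unclear_excluded: int = 0
    temperature_attached: int = 0
    modeled: int = 0
    drops: dict = field(default_factory=dict)

    def check(self) -> None:
        seq = [
            self.input, self.segmented, self.color_labeled,
            self.after_unclear_excluded, self.temperature_attached, self.modeled,
        ]
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise InvalidInputError(f"retention counts increased: {seq}")
        if self.input != self.modeled + sum(self.drops.values()):
            raise InvalidInputError(
                f"retention mismatch: input {self.input} != modeled "
                f"{self.modeled} + drops {self.drops}"
            )

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "segmented": self.segmented,
            "color_labeled": self.color_labeled,
            "after_unclear_excluded": self.after_unclear_excluded,
            "temperature_attached": self.temperature_attached,
            "modeled": self.modeled,
            "drops": dict(self.drops),
        }


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InvalidInputError("config must be a YAML mapping")
    return cfg


def _params(cfg: dict) -> dict:
    p = dict(DEFAULT_PARAMS)
    p.update(cfg.get("params") or {})
    return p


def _input_paths(cfg: dict, out: Path) -> dict:
    """Resolve input file locations from the config (or a simulated bundle)."""
    if cfg.get("simulate"):
        bundle = out / "bundle"
        return {
            "images_dir": bundle / "images",
            "masks_dir": bundle / "masks",
            "records_csv": bundle / "records.csv",
            "daily_temps_csv": bundle / "daily_temps.csv",
            "bundle_config": bundle / "config.yaml",
        }
    inputs = cfg.get("inputs") or {}
    needed = ["images_dir", "masks_dir", "records_csv", "daily_temps_csv"]
    missing = [k for k in needed if k not in inputs]
    if missing:
        raise InvalidInputError(f"config inputs missing: {missing}")
    return {k: Path(inputs[k]) for k in inputs}


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: dict, out: Path, seed: int | None = None) -> dict:
    """Write a synthetic fixture bundle under ``out/bundle``."""
    overrides = dict(cfg.get("synthetic") or {})
    if seed is not None:
        overrides["seed"] = int(seed)
    elif "seed" in cfg and "seed" not in overrides:
        overrides["seed"] = int(cfg["seed"])
    syn = synthdata.SyntheticConfig.from_dict(overrides)
    t0 = time.monotonic()
    paths = synthdata.write_bundle(syn, out / "bundle")
    log.info("stage=simulate n_records=%d elapsed=%.1fs", syn.n_records, time.monotonic() - t0)
    return paths


def stage_extract_colors(cfg: dict, out: Path, seed: int | None = None) -> pd.DataFrame:
    """Dominant colors and labels for every record with an image/mask pair.

    Writes ``colors.csv``; records lacking image files are simply absent
    from it (counted as segmentation drops by :func:`run_pipeline`).
    """
    paths = _input_paths(cfg, out)
    params = _params(cfg)
    records = pd.read_csv(paths["records_csv"])
    kseed = int(seed if seed is not None else cfg.get("seed", 0))
    t0 = time.monotonic()

    samples = []
    for rec_id in records["id"]:
        img = Path(paths["images_dir"]) / f"{rec_id}.png"
        msk = Path(paths["masks_dir"]) / f"{rec_id}.png"
        if not (img.exists() and msk.exists()):
            continue
        samples.append(imagecolor.load_segment(img, msk, id=str(rec_id)))
    colors = imagecolor.extract_colors(
        samples, k=params["kmeans_k"], width=params["ring_width"], seed=kseed
    )
    colors.to_csv(out / "colors.csv", index=False)
    log.info(
        "stage=extract_colors records=%d segmented=%d elapsed=%.1fs",
        len(records), len(colors), time.monotonic() - t0,
    )
    return colors


def _load_grid(cfg: dict, out: Path, records: pd.DataFrame) -> thermal.GridSpec:
    paths = _input_paths(cfg, out)
    bundle_cfg = paths.get("bundle_config")
    if bundle_cfg is not None and Path(bundle_cfg).exists():
        with open(bundle_cfg) as fh:
            meta = yaml.safe_load(fh)
        if meta and "grid" in meta:
            return thermal.GridSpec.from_dict(meta["grid"])
    grid_cfg = (cfg.get("inputs") or {}).get("grid")
    if grid_cfg:
        return thermal.GridSpec.from_dict(grid_cfg)
    return thermal.GridSpec.from_points(
        records["latitude"].to_numpy(), records["longitude"].to_numpy()
    )


def stage_attach_temperature(cfg: dict, out: Path) -> tuple[pd.DataFrame, dict]:
    """Join color labels to records and attach hourly temperatures.

    Writes ``records_with_temp.csv`` (unclear-labeled records excluded but
    written to ``excluded.csv`` for audit) and returns the table plus drop
    counts.
    """
    paths = _input_paths(cfg, out)
    records = pd.read_csv(paths["records_csv"], parse_dates=["date"])
    colors = pd.read_csv(out / "colors.csv")
    colors["id"] = colors["id"].astype(records["id"].dtype)
    daily = pd.read_csv(paths["daily_temps_csv"], parse_dates=["date"])

    records = records.drop(columns=[c for c in ("label",) if c in records.columns])
    merged = records.merge(colors, on="id", how="inner")
    n_no_image = len(records) - len(merged)

    excluded = merged[merged["excluded_flag"]]
    excluded.to_csv(out / "excluded.csv", index=False)
    kept = merged[~merged["excluded_flag"]].copy()

    grid = _load_grid(cfg, out, records)
    t0 = time.monotonic()
    with_temp, attach_log = thermal.attach_temperatures(kept, daily, grid)
    with_temp["week"] = models.week_of_year(with_temp["date"])
    with_temp["season"] = with_temp["date"].map(models.assign_season)
    with_temp.to_csv(out / "records_with_temp.csv", index=False)
    log.info(
        "stage=attach_temperature kept=%d dropped_missing_daily=%d elapsed=%.1fs",
        len(with_temp), attach_log["dropped_missing_daily"], time.monotonic() - t0,
    )
    drops = {
        "no_image": int(n_no_image),
        "unclear_excluded": int(len(excluded)),
        "missing_daily_temp": int(attach_log["dropped_missing_daily"]),
    }
    return with_temp, drops


def stage_fit_models(cfg: dict, out: Path) -> dict:
    """Fit all three model families on ``records_with_temp.csv``.

    Writes ``model_report.json``, ``seasonal_curves.csv`` and
    ``temperature_curves.csv``; returns the report dict.
    """
    params = _params(cfg)
    table = pd.read_csv(out / "records_with_temp.csv", parse_dates=["date"])
    t0 = time.monotonic()

    glm_fits = [models.fit_logistic(table, v) for v in models.LOGISTIC_VARIANTS]
    glm_cmp = models.aic_compare(glm_fits)
    gam_fits = [
        models.fit_cyclic_gam(table, v, n_knots=params["gam_knots"])
        for v in models.GAM_VARIANTS
    ]
    gam_cmp = models.aic_compare(gam_fits)
    try:
        background = models.fit_background_lm(table).summary_dict()
    except InvalidInputError as exc:  # e.g. degenerate background variance
        background = {"error": str(exc)}
        log.warning("stage=fit_models background model skipped: %s", exc)

    glm_interaction = next(
        f for f in glm_fits if f.model_name == "temp_by_season_interaction"
    )
    slopes = glm_interaction.extras["season_slopes"]

    # prediction curves: temperature per season (GLM), week x latitude (GAM)
    temp_grid = np.linspace(
        table["hourly_temp"].min(), table["hourly_temp"].max(), 50
    )
    temp_rows = []
    for season in ("nonbreeding", "breeding"):
        nd = pd.DataFrame({"hourly_temp": temp_grid, "season": season})
        ci = models.predict_with_ci(glm_interaction, nd)
        nd = pd.concat([nd, ci], axis=1)
        temp_rows.append(nd)
    pd.concat(temp_rows).to_csv(out / "temperature_curves.csv", index=False)

    gam_interaction = next(
        f for f in gam_fits if f.model_name == "week_by_lat_interaction"
    )
    week_grid = np.linspace(0.0, 52.0, 105)
    lat_pcts = {
        "p10": float(np.percentile(table["latitude"], 10)),
        "p50": float(np.percentile(table["latitude"], 50)),
        "p90": float(np.percentile(table["latitude"], 90)),
    }
    season_rows = []
    for name, lat in lat_pcts.items():
        nd = pd.DataFrame({"week": week_grid, "latitude": lat})
        ci = models.predict_with_ci(gam_interaction, nd)
        nd.insert(0, "latitude_percentile", name)
        season_rows.append(pd.concat([nd, ci], axis=1))
    pd.concat(season_rows).to_csv(out / "seasonal_curves.csv", index=False)

    report = {
        "n_modeled": int(len(table)),
        "logistic": {
            "fits": [f.summary_dict() for f in glm_fits],
            "aic_best": glm_cmp.best,
            "delta_aic": glm_cmp.delta_aic,
            "season_slopes": slopes,
            "nonbreeding_slope_significant": slopes["nonbreeding"]["p_value"] < 0.05,
            "breeding_slope_significant": slopes["breeding"]["p_value"] < 0.05,
        },
        "gam": {
            "fits": [f.summary_dict() for f in gam_fits],
            "aic_best": gam_cmp.best,
            "delta_aic": gam_cmp.delta_aic,
            "latitude_percentiles": lat_pcts,
        },
        "background": background,
    }
    _write_json(out / "model_report.json", report)
    log.info("stage=fit_models n=%d elapsed=%.1fs", len(table), time.monotonic() - t0)
    return report


def run_pipeline(config_path, out_dir, seed: int | None = None) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns the model report dict augmented with the retention log.
    """
    cfg = load_config(config_path) if not isinstance(config_path, dict) else dict(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.get("simulate"):
        stage_simulate(cfg, out, seed=cfg.get("seed"))

    paths = _input_paths(cfg, out)
    for key in ("records_csv", "daily_temps_csv"):
        if not Path(paths[key]).exists():
            raise InvalidInputError(f"stage=inputs missing file: {paths[key]}")

    records = pd.read_csv(paths["records_csv"])
    retention = RetentionLog(input=len(records))

    colors = stage_extract_colors(cfg, out, seed=cfg.get("seed"))
    retention.segmented = len(colors)
    retention.color_labeled = len(colors)

    with_temp, drops = stage_attach_temperature(cfg, out)
    retention.after_unclear_excluded = retention.color_labeled - drops["unclear_excluded"]
    retention.temperature_attached = len(with_temp)
    retention.modeled = len(with_temp)
    retention.drops = drops
    retention.check()
    _write_json(out / "retention.json", retention.to_dict())

    report = stage_fit_models(cfg, out)
    report["retention"] = retention.to_dict()
    _write_json(out / "model_report.json", report)
    return report


# ---------------------------------------------------------------------------
# validation against planted truth


def validate_against_truth(out_dir, bundle_dir=None) -> dict:
    """Per-stage accuracy of a pipeline run against a synthetic bundle.

    Reports color-label recovery (on segments not planted unclear),
    temperature RMSE against the planted hourly temperatures, and the
    interaction-GLM slope errors against the planted coefficients.
    """
    out = Path(out_dir)
    bundle = Path(bundle_dir) if bundle_dir else out / "bundle"
    truth = pd.read_csv(bundle / "truth.csv")
    with open(bundle / "config.yaml") as fh:
        meta = yaml.safe_load(fh)
    syn = meta["synthetic"]

    colors = pd.read_csv(out / "colors.csv")
    merged = colors.merge(truth, left_on="id", right_on="record_id", how="inner")
    if len(merged) != len(colors):
        raise InvalidInputError("colors.csv ids do not match the truth table")
    clear = merged[merged["planted_image_label"] != "unclear"]
    label_recovery = float((clear["label"] == clear["true_label"]).mean())
    unclear_recovered = int((merged["planted_image_label"] == "unclear").sum())
    unclear_flagged = int(merged["excluded_flag"].sum())

    with_temp = pd.read_csv(out / "records_with_temp.csv")
    wt = with_temp.merge(truth, left_on="id", right_on="record_id", how="inner")
    temp_rmse = float(
        np.sqrt(np.mean((wt["hourly_temp"] - wt["true_hourly_temp"]) ** 2))
    )

    with open(out / "model_report.json") as fh:
        report = json.load(fh)
    slopes = report["logistic"]["season_slopes"]
    coef_errors = {
        "nonbreeding_slope_error": slopes["nonbreeding"]["slope"]
        - syn["beta_temp_nonbreeding"],
        "breeding_slope_error": slopes["breeding"]["slope"]
        - syn["beta_temp_breeding"],
    }

    summary = {
        "label_recovery": label_recovery,
        "n_label_checked": int(len(clear)),
        "planted_unclear": unclear_recovered,
        "flagged_unclear": unclear_flagged,
        "temperature_rmse": temp_rmse,
        "coefficient_errors": coef_errors,
    }
    _write_json(out / "validation.json", summary)
    return summary
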