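"""End-to-end pipeline: landscape → telemetry → features → SDM.

Every stage writes its artifact to the output directory and records its
seed and row counts in ``manifest.json``, so the whole run is auditable and
byte-reproducible from the master seed.  Stage seeds are derived from the
master seed with ``numpy.random.SeedSequence`` spawning, so stages are
independently reseedable.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .landscape import LandscapeConfig, default_config, generate_landscape, write_pointcloud
from .metrics import FEATURE_COLUMNS, extract_features
from .sdm import (
    FeatureTable,
    backward_selection,
    bootstrap_ensemble,
    collinearity_filter,
    response_curve,
    variable_importance,
)
from .telemetry import (
    Individual,
    TrackingSchedule,
    UsePreference,
    duration_area_correlation,
    filter_first_fix,
    mcp_area,
    sample_background,
    simulate_fixes,
)

logger = logging.getLogger(__name__)


@dataclass
class SDMConfig:
    runs: int = 100
    train_frac: float = 0.7
    beta: float = 1.0
    collinearity_threshold: float = 0.7
    backward_selection: bool = False
    selection_runs: int = 20
    selection_tolerance: float = 0.01
    response_grid_points: int = 100

    def __post_init__(self):
        if self.runs < 1:
            raise ConfigError("SDM runs must be >= 1")
        if not 0 < self.train_frac < 1:
            raise ConfigError("train_frac must be in (0, 1)")


@dataclass
class TelemetryConfig:
    n_individuals: int = 20
    bouts_per_day: float = 4.0
    duration_days_range: tuple[float, float] = (0.6, 9.0)
    range_radius_m: float = 60.0
    preference: UsePreference = field(
        default_factory=lambda: UsePreference(
            coefficients={"dist_water": -0.01, "veg_height": -0.05},
            lt1_quad_weight=0.004,
            lt1_optimum_pct=30.0,
        )
    )


@dataclass
class RunConfig:
    landscape: LandscapeConfig = field(default_factory=default_config)
    telemetry: TelemetryConfig = field(default_factory=TelemetryConfig)
    sdm: SDMConfig = field(default_factory=SDMConfig)
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a YAML/JSON run configuration (fields default when omitted)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw = raw or {}
        seed = int(raw.get("seed", 0))
        land_raw = dict(raw.get("landscape", {}))
        if "extent_m" in land_raw:
            extent = tuple(land_raw["extent_m"])
        else:
            extent = (300.0, 300.0)
        landscape = default_config(seed=int(land_raw.get("seed", seed)), extent=extent)
        tel_raw = dict(raw.get("telemetry", {}))
        pref_raw = tel_raw.pop("preference", None)
        tel_kwargs = {
            k: tel_raw[k]
            for k in ("n_individuals", "bouts_per_day", "range_radius_m")
            if k in tel_raw
        }
        if "duration_days_range" in tel_raw:
            tel_kwargs["duration_days_range"] = tuple(tel_raw["duration_days_range"])
        telemetry = TelemetryConfig(**tel_kwargs)
        if pref_raw:
            telemetry.preference = UsePreference(**pref_raw)
        sdm = SDMConfig(**raw.get("sdm", {}))
        return cls(landscape=landscape, telemetry=telemetry, sdm=sdm, seed=seed)


def _draw_individuals(
    cfg: TelemetryConfig, truth, rng: np.random.Generator
) -> list[Individual]:
    """Release points and attachment durations for the tracked animals.

    Capture transects in the field are placed in known or suitable habitat,
    so release cells are drawn proportional to the planted habitat-use
    intensity rather than uniformly; durations are spread over the study's
    observed range.
    """
    from .telemetry import _truth_log_intensity

    eta = _truth_log_intensity(truth, cfg.preference)
    land_y, land_x = np.nonzero(~truth.water)
    logits = eta[land_y, land_x]
    w = np.exp(logits - logits.max())
    w /= w.sum()
    lo, hi = cfg.duration_days_range
    durations = np.linspace(lo, hi, cfg.n_individuals)
    rng.shuffle(durations)
    out = []
    for i in range(cfg.n_individuals):
        j = rng.choice(len(land_x), p=w)
        out.append(
            Individual(
                id=f"shrew_{i + 1:02d}",
                release_point=(float(land_x[j] + 0.5), float(land_y[j] + 0.5)),
                attachment_duration_days=float(durations[i]),
                range_radius_m=cfg.range_radius_m,
            )
        )
    return out


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-22s %.1fs", name, t1 - t0)
    return t1


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all stages, persist artifacts, return the manifest dict.

    Artifacts: ``pointcloud.csv``, ``telemetry.csv``, ``positions.csv``,
    ``features.csv``, ``mcp.csv``, ``metrics.json``, ``importance.csv``,
    ``response_curves.csv``, ``removals.log``, ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    ss = np.random.SeedSequence(config.seed)
    seed_land, seed_tel, seed_bg, seed_sdm = (int(s) & 0x7FFFFFFF for s in ss.generate_state(4))
    manifest: dict = {
        "version": __version__,
        "master_seed": config.seed,
        "stage_seeds": {
            "landscape": seed_land,
            "telemetry": seed_tel,
            "background": seed_bg,
            "sdm": seed_sdm,
        },
    }
    t0 = time.perf_counter()

    # --- landscape
    land_cfg = config.landscape
    land_cfg.seed = seed_land
    cloud, truth = generate_landscape(land_cfg)
    write_pointcloud(cloud, outdir / "pointcloud.csv")
    # downstream stages consume the persisted artifact, so a stage-wise run
    # on the same files is byte-identical to this monolithic one
    from .landscape import read_pointcloud

    cloud = read_pointcloud(outdir / "pointcloud.csv")
    manifest["n_points"] = len(cloud)
    manifest["extent_m"] = list(land_cfg.extent_m)
    t0 = _stage("landscape", t0)

    # --- telemetry
    rng_tel = np.random.default_rng(seed_tel)
    individuals = _draw_individuals(config.telemetry, truth, rng_tel)
    schedule = TrackingSchedule(bouts_per_day=config.telemetry.bouts_per_day)
    fixes = simulate_fixes(
        truth, config.telemetry.preference, individuals, schedule, seed=seed_tel
    )
    fixes.to_csv(outdir / "telemetry.csv", index=False, float_format="%.17g")
    fixes = pd.read_csv(outdir / "telemetry.csv")
    manifest["n_fixes"] = len(fixes)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        first = filter_first_fix(fixes)
    manifest["n_first_of_bout"] = len(first)

    # home ranges and the duration-area correlation
    mcp_rows = []
    for ind in individuals:
        sel = first[first["individual"] == ind.id]
        area = mcp_area(sel[["x", "y"]].to_numpy())
        mcp_rows.append(
            {
                "individual": ind.id,
                "n_fixes": len(sel),
                "area_m2": area,
                "duration_days": ind.attachment_duration_days,
            }
        )
    mcp_df = pd.DataFrame(mcp_rows)
    mcp_df.to_csv(outdir / "mcp.csv", index=False)
    ok = np.isfinite(mcp_df["area_m2"])
    if ok.sum() >= 3:
        r, df_, p = duration_area_correlation(
            mcp_df.loc[ok, "duration_days"], mcp_df.loc[ok, "area_m2"]
        )
        manifest["duration_area"] = {"r": r, "df": df_, "p": p}
    t0 = _stage("telemetry", t0)

    # --- positions: presences + matched background
    w, h = land_cfg.extent_m
    background = sample_background((0, 0, w, h), n=len(first), seed=seed_bg)
    positions = pd.DataFrame(
        {
            "x": np.concatenate([first["x"].to_numpy(), background[:, 0]]),
            "y": np.concatenate([first["y"].to_numpy(), background[:, 1]]),
            "label": ["presence"] * len(first) + ["background"] * len(background),
        }
    )
    positions.to_csv(outdir / "positions.csv", index=False, float_format="%.17g")
    positions = pd.read_csv(outdir / "positions.csv")
    manifest["n_presence"] = int(len(first))
    manifest["n_background"] = int(len(background))

    # --- features
    features = extract_features(
        cloud, positions[["x", "y"]].to_numpy(), labels=positions["label"]
    )
    features.to_csv(outdir / "features.csv", index=False, float_format="%.17g")
    features = pd.read_csv(outdir / "features.csv")
    manifest["n_feature_rows"] = len(features)
    t0 = _stage("features", t0)

    # --- SDM
    sdm_out = fit_sdm(features, config.sdm, seed=seed_sdm, outdir=outdir)
    manifest.update(sdm_out)
    _stage("sdm", t0)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def fit_sdm(features: pd.DataFrame, cfg: SDMConfig, seed: int, outdir) -> dict:
    """Collinearity screen + ensemble + importance + response curves.

    Standalone so the ``fit-sdm`` subcommand can run on a features CSV.
    Returns the manifest fragment; writes metrics.json, importance.csv,
    response_curves.csv and removals.log to ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    missing = [c for c in FEATURE_COLUMNS + ["label"] if c not in features.columns]
    if missing:
        raise ConfigError(f"features table lacks columns: {missing}")
    table = FeatureTable.from_dataframe(features)
    retained, removals = collinearity_filter(
        table, threshold=cfg.collinearity_threshold, beta=cfg.beta
    )
    with open(outdir / "removals.log", "w") as fh:
        for entry in removals:
            fh.write(
                f"removed {entry['removed']} (rho={entry['rho']:.3f} with "
                f"{entry['kept']}; AUC {entry['auc_removed']:.3f} < {entry['auc_kept']:.3f})\n"
            )
    table = table.select(retained)

    trail: list[dict] = []
    if cfg.backward_selection:
        final_vars, trail = backward_selection(
            table,
            runs=cfg.selection_runs,
            train_frac=cfg.train_frac,
            seed=seed,
            beta=cfg.beta,
            tolerance=cfg.selection_tolerance,
        )
        table = table.select(final_vars)

    ensemble = bootstrap_ensemble(
        table, runs=cfg.runs, train_frac=cfg.train_frac, seed=seed, beta=cfg.beta
    )
    summary = ensemble.summary()
    per_run = ensemble.metric_frame()
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(
            {
                "aggregate": {
                    m: {"mean": float(summary.loc[m, "mean"]), "sd": float(summary.loc[m, "sd"])}
                    for m in summary.index
                },
                "per_run": per_run.to_dict(orient="list"),
                "backward_selection": trail,
            },
            fh,
            indent=2,
        )
    importance = variable_importance(ensemble)
    importance.rename_axis("variable").to_csv(outdir / "importance.csv")
    curves = []
    for v in table.variables:
        c = response_curve(ensemble, v, grid_points=cfg.response_grid_points)
        c.insert(0, "variable", v)
        curves.append(c)
    pd.concat(curves, ignore_index=True).to_csv(outdir / "response_curves.csv", index=False)

    return {
        "n_model_rows": int(len(table.data)),
        "n_rows_dropped": int(table.n_rows_dropped),
        "variables_retained": list(table.variables),
        "collinearity_removed": [e["removed"] for e in removals],
        "metrics": {
            m: {"mean": float(summary.loc[m, "mean"]), "sd": float(summary.loc[m, "sd"])}
            for m in summary.index
        },
        "importance_top": importance["mean"].head(4).round(6).to_dict(),
    }
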