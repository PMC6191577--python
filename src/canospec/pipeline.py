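"""End-to-end orchestration: simulate or load a season, then analyze it.

The analysis chain mirrors a proximal-sensing field campaign: canopy
photographs → green-pixel fractions; plot spectra → the 12-index battery
and per-trait contour maps with optimized band pairs; simple-regression
summary tables; PLSR evaluations per sampling date and pooled.  A run is
fully determined by its configuration and seed, and every bundle carries
its provenance sidecar.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import contour, pls, regression, spectra as spectra_mod, synthetic
from .imaging import HSBThresholds, batch_green_fraction

__all__ = ["RunConfig", "run_pipeline", "align_observations"]

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = ["fresh_weight", "dry_weight", "n_conc", "n_uptake"]


@dataclass
class RunConfig:
    mode: str = "simulate"                     # "simulate" | "analyze"
    out_dir: str = "canospec_run"
    seed: int = 0
    # simulate mode
    scenario_name: str = "2014"
    n_plots: int = 64
    # analyze mode inputs
    traits_csv: str | None = None
    spectra_csv: str | None = None
    image_dir: str | None = None
    # analysis settings
    thresholds: HSBThresholds = field(default_factory=HSBThresholds)
    contour_range: tuple[float, float] = (302.0, 1048.0)
    plsr_range: tuple[float, float] = (400.0, 1000.0)
    plsr_max_components: int = 10
    plsr_folds: int = 7
    quadratic_green: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate" and self.scenario_name not in synthetic.SCENARIO_PRESETS:
            raise ValueError(f"unknown scenario {self.scenario_name!r}")
        if self.mode == "analyze":
            for p, what in [(self.traits_csv, "traits CSV"), (self.spectra_csv, "spectra CSV")]:
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"analyze mode needs an existing {what}: {p}")
            if self.image_dir is not None and not Path(self.image_dir).is_dir():
                raise FileNotFoundError(f"image dir not found: {self.image_dir}")

    def config_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def align_observations(
    traits_table: pd.DataFrame,
    spectra_table: pd.DataFrame,
    green_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Inner-join the observation tables on (plot_id, date_id).

    Returns the aligned table plus join diagnostics listing orphaned keys
    per source.  Duplicate keys in any table raise; an empty intersection
    raises; orphans are reported but analysis proceeds on the intersection.
    """
    keys = ["plot_id", "date_id"]
    tables = {"traits": traits_table, "spectra": spectra_table}
    if green_table is not None and len(green_table):
        tables["green"] = green_table
    key_sets = {}
    for name, tbl in tables.items():
        if tbl.duplicated(keys).any():
            dups = tbl[tbl.duplicated(keys, keep=False)][keys].drop_duplicates()
            raise ValueError(f"duplicate (plot_id, date_id) keys in {name}: {dups.values.tolist()}")
        key_sets[name] = set(map(tuple, tbl[keys].astype(str).values))
    shared = set.intersection(*key_sets.values())
    if not shared:
        raise ValueError("empty intersection of (plot_id, date_id) keys across inputs")
    diagnostics = {
        f"orphans_{name}": sorted(ks - shared) for name, ks in key_sets.items()
    }
    diagnostics["n_aligned"] = len(shared)
    merged = traits_table.copy()
    merged[keys] = merged[keys].astype(str)
    for name, tbl in list(tables.items())[1:]:
        t = tbl.copy()
        t[keys] = t[keys].astype(str)
        merged = merged.merge(t, on=keys, how="inner", suffixes=("", f"_{name}"))
    return merged, diagnostics


def _traits_to_frame(traits: list[synthetic.TraitRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plot_id": t.plot_id, "date_id": t.date_id, "bbch": t.bbch,
                "fresh_weight": t.fresh_weight, "dry_weight": t.dry_weight,
                "n_conc": t.n_conc, "n_uptake": t.n_uptake,
            }
            for t in traits
        ]
    )


def _simulate(config: RunConfig, out: Path) -> tuple[Path, Path, Path]:
    scenario = synthetic.SCENARIO_PRESETS[config.scenario_name](
        n_plots=config.n_plots, seed=config.seed
    )
    traits, spectra, images = synthetic.simulate_dataset(scenario)
    traits_csv = out / "traits.csv"
    _traits_to_frame(traits).to_csv(traits_csv, index=False)
    spectra_csv = out / "spectra.csv"
    spectra_mod.write_spectra_csv(spectra, spectra_csv)
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    for (plot_id, date_id), (arr, _count) in images.items():
        Image.fromarray(arr).save(img_dir / f"{plot_id}_{date_id}.png")
    (out / "scenario.json").write_text(scenario.to_json())
    logger.info("simulated %d plot-dates into %s", len(traits), out)
    return traits_csv, spectra_csv, img_dir


def _analyze(config: RunConfig, out: Path, traits_csv, spectra_csv, image_dir) -> None:
    traits_df = pd.read_csv(traits_csv)
    spectra_list = spectra_mod.read_spectra_csv(spectra_csv)
    spectra_df = pd.DataFrame(
        {"plot_id": [s.plot_id for s in spectra_list], "date_id": [s.date_id for s in spectra_list]}
    )

    green_df = None
    if image_dir is not None:
        paths = sorted(Path(image_dir).glob("*.png")) + sorted(Path(image_dir).glob("*.jpg"))
        green_df, errors = batch_green_fraction(paths, config.thresholds)
        if errors:
            pd.DataFrame(errors).to_csv(out / "image_errors.csv", index=False)
            logger.warning("%d image(s) failed; see image_errors.csv", len(errors))

    battery = spectra_mod.battery_table(spectra_list)

    aligned, diagnostics = align_observations(
        traits_df, battery, green_df[["plot_id", "date_id", "green_pct"]] if green_df is not None else None
    )
    (out / "join_diagnostics.json").write_text(json.dumps(diagnostics, indent=2, default=str))

    # (1) merged traits + green fraction table, (2) index battery
    aligned.to_csv(out / "observations.csv", index=False)
    battery.to_csv(out / "index_battery.csv", index=False)

    # (3) per-trait aggregated contour maps + best pairs
    spec_by_key = {(s.plot_id, s.date_id): s for s in spectra_list}
    best_rows = []
    for trait in TRAIT_COLUMNS:
        per_date = []
        for date_id, sub in aligned.groupby("date_id", sort=True):
            sp = [spec_by_key[(p, d)] for p, d in zip(sub["plot_id"], sub["date_id"])]
            per_date.append(
                contour.contour_map_for_trait(
                    sp, sub[trait].to_numpy(), config.contour_range, trait_name=trait
                )
            )
        agg = contour.mean_contour_map(per_date)
        contour.write_contour_csv(agg, out / f"contour_{trait}.csv")
        bp = contour.select_best_pair(agg)
        best_rows.append(
            {"trait": trait, "lambda_a": bp.lambda_a, "lambda_b": bp.lambda_b,
             "mean_r2": bp.mean_r2, "n_dates_averaged": agg.n_dates_averaged}
        )
        contour.ranked_pairs(agg).to_csv(out / f"ranked_pairs_{trait}.csv", index=False)
    pd.DataFrame(best_rows).to_csv(out / "best_pairs.csv", index=False)

    # (4) regression tables: indices (and green %) vs traits, per date and pooled
    predictors = [d.name for d in spectra_mod.INDEX_BATTERY]
    if "green_pct" in aligned.columns:
        predictors = ["green_pct"] + predictors
    table = regression.results_table(
        aligned, predictors, TRAIT_COLUMNS, by="date_id",
        quadratic_for=("green_pct",) if config.quadratic_green else (),
    )
    table.to_csv(out / "regression_r2.csv")

    # (5) PLSR evaluations per date subset and pooled
    evals = []
    subsets = [(str(d), sub) for d, sub in aligned.groupby("date_id", sort=True)]
    subsets.append(("All", aligned))
    for label, sub in subsets:
        sp = [spec_by_key[(p, d)] for p, d in zip(sub["plot_id"], sub["date_id"])]
        X, _ = pls.spectra_to_matrix(sp, config.plsr_range)
        for trait in TRAIT_COLUMNS:
            ev = pls.cross_validate_plsr(
                X, sub[trait].to_numpy(), max_components=config.plsr_max_components,
                k_folds=config.plsr_folds, seed=config.seed, trait_name=trait,
                wavelength_range=config.plsr_range,
            )
            evals.append({"subset": label, **asdict(ev)})
    pd.DataFrame(evals).to_csv(out / "plsr_evaluation.csv", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured pipeline and write the result bundle to disk.

    Emits: observations table, index battery, per-trait contour maps and
    best pairs, regression R² tables, PLSR evaluations, and the config +
    provenance sidecar.  Identical config + seed → identical deterministic
    outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "pipeline.log")
    handler.setLevel(config.log_level)
    root = logging.getLogger("canospec")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        if config.mode == "simulate":
            traits_csv, spectra_csv, image_dir = _simulate(config, out)
        else:
            traits_csv, spectra_csv, image_dir = (
                config.traits_csv, config.spectra_csv, config.image_dir
            )
        _analyze(config, out, traits_csv, spectra_csv, image_dir)
        meta = {"config": asdict(config), "config_hash": config.config_hash(), "seed": config.seed}
        (out / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str))
        logger.info("pipeline complete: %s", out)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
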