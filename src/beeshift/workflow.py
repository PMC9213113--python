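"""Configuration-driven pipeline: ingest -> grid -> histories ->
covariates -> fit -> summarize -> counterfactual.

Two modes share the downstream stages.  ``records`` mode starts from a
raw occurrence table plus climate/land-use CSVs; ``synthetic`` mode
starts from the generator in :mod:`beeshift.simulate` (the desk-scale
path used throughout the test-suite).  Every run writes intermediate
artifacts per stage and exactly one ``manifest.json`` recording the
config hash, input checksums, seed, per-stage timings and the
record/site/species counts after each filter — reruns with identical
inputs and seed reproduce identical counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .covariates import EraCovariates, aggregate_climate, derive_category_scores, site_floral_score
from .histories import DetectionData, build_histories, build_visits, filter_sites
from .likelihood import ModelSpec
from .model import MultiSpeciesOccupancyModel, OccupancyResults
from .records import (
    DEFAULT_EXCLUDED_SPECIES,
    deduplicate,
    filter_records,
    load_records,
)
from .simulate import SimConfig, generate_dataset
from .spatiotemporal import (
    ERA_LENGTH,
    SiteGrid,
    assign_era_interval,
    assign_site,
    build_range_mask,
)
from .counterfactual import fig2_scatter_spec, impact_counts, winners_losers_table

logger = logging.getLogger(__name__)

STAGES = ("ingest", "grid", "histories", "covariates", "fit", "summarize",
          "counterfactual")


# ---------------------------------------------------------------------------
# Config schema (unknown keys are fatal)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RecordsConfig(_Strict):
    path: str
    schema_map: dict[str, str]
    delimiter: Optional[str] = None
    min_year: int = 1901
    max_year: int = 2020
    excluded_species: list[str] = list(DEFAULT_EXCLUDED_SPECIES)


class GridConfig(_Strict):
    cell_size: float = 100_000.0  # 50_000 | 100_000 | 250_000
    origin: tuple[float, float] = (-5_000_000.0, -4_000_000.0)


class EraConfig(_Strict):
    start: int = 1901
    n_eras: int = 6


class SiteFilterConfig(_Strict):
    mode: Literal["default", "strict", "none"] = "default"
    min_records_per_era: int = 5


class CovariateFilesConfig(_Strict):
    temperature_csv: str
    precipitation_csv: str
    overlap_csv: str
    crop_scores_csv: str
    composition_csv: str


class FitConfig(_Strict):
    kind: Literal["era", "environmental", "combined"] = "era"
    detection_variant: Literal[
        "site_era_ranef", "site_era_ranef_plus_era_fixed"
    ] = "site_era_ranef"
    n_chains: int = 2
    n_warmup: int = 500
    n_draws: int = 500
    target_accept: float = 0.8
    max_treedepth: int = 10


class CounterfactualConfig(_Strict):
    hold_mode: Literal["site_mean", "global_mean"] = "site_mean"


class PipelineConfig(_Strict):
    mode: Literal["synthetic", "records"] = "synthetic"
    seed: int = 0
    synthetic: dict = {}
    records: Optional[RecordsConfig] = None
    grid: GridConfig = GridConfig()
    eras: EraConfig = EraConfig()
    site_filter: SiteFilterConfig = SiteFilterConfig()
    covariate_files: Optional[CovariateFilesConfig] = None
    fit: FitConfig = FitConfig()
    counterfactual: CounterfactualConfig = CounterfactualConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage implementations


def ingest_stage(config: PipelineConfig, out: Path, manifest: dict) -> pd.DataFrame:
    rc = config.records
    loaded = load_records(rc.path, rc.schema_map, delimiter=rc.delimiter)
    manifest["counts"]["raw_rows"] = len(loaded.records) + len(loaded.rejects)
    manifest["counts"]["parse_rejects"] = len(loaded.rejects)
    loaded.rejects.to_csv(out / "rejects.csv", index=False)
    kept = filter_records(
        loaded.records,
        excluded_species=rc.excluded_species,
        min_year=rc.min_year,
        max_year=rc.max_year,
    )
    manifest["counts"]["after_record_filters"] = len(kept)
    unique = deduplicate(kept)
    manifest["counts"]["after_deduplication"] = len(unique)
    df = pd.DataFrame(
        {
            "species": [r.species for r in unique],
            "longitude": [r.longitude for r in unique],
            "latitude": [r.latitude for r in unique],
            "year": [r.year for r in unique],
            "observer": [r.observer for r in unique],
        }
    )
    df.to_csv(out / "records.csv", index=False)
    return df


def grid_stage(config: PipelineConfig, out: Path, manifest: dict,
               records_df: pd.DataFrame) -> pd.DataFrame:
    grid = SiteGrid(cell_size=config.grid.cell_size, origin=tuple(config.grid.origin))
    cols, rows_ = grid.cell_of_lonlat(
        records_df["longitude"].to_numpy(), records_df["latitude"].to_numpy()
    )
    eras, intervals = [], []
    for y in records_df["year"]:
        ei = assign_era_interval(
            int(y), era_start=config.eras.start, n_eras=config.eras.n_eras
        )
        eras.append(ei.era)
        intervals.append(ei.interval)
    assign = records_df.assign(
        cell_col=cols, cell_row=rows_, era=eras, interval=intervals
    )
    assign["site"] = list(zip(assign["cell_col"], assign["cell_row"]))
    manifest["counts"]["sites_with_records"] = assign["site"].nunique()
    assign.drop(columns="site").to_csv(out / "assignments.csv", index=False)
    return assign


def histories_stage(config: PipelineConfig, out: Path, manifest: dict,
                    assign: pd.DataFrame) -> DetectionData:
    """Site retention, convex-hull ranges, and the 4-D detection array.

    Retention filters run on raw per-site record tallies first, so the
    range hulls are traced over retained sites only.
    """
    K = config.eras.n_eras
    T = ERA_LENGTH // 5
    sites_all = sorted(assign["site"].unique())
    visited, counts = build_visits(assign, sites_all, K, T)
    provisional = DetectionData(
        y=np.zeros((1, len(sites_all), K, T), dtype=np.int8),
        observed=np.zeros((1, len(sites_all), K, T), dtype=bool),
        visited=visited,
        range_mask=np.ones((1, len(sites_all)), dtype=bool),
        record_counts=counts,
        species=["_all"],
        sites=sites_all,
    )
    # the retention rule only consults record_counts, so a one-species
    # shell is enough to reuse filter_sites
    provisional.observed = provisional.visited[None] & provisional.range_mask[:, :, None, None]
    kept = filter_sites(
        provisional, config.site_filter.mode,
        min_records_per_era=config.site_filter.min_records_per_era,
    )
    sites = kept.sites
    manifest["counts"]["sites_retained"] = len(sites)
    assign = assign[assign["site"].isin(set(sites))]
    manifest["counts"]["records_at_retained_sites"] = len(assign)

    grid = SiteGrid(cell_size=config.grid.cell_size, origin=tuple(config.grid.origin))
    grid.cells.update(sites)
    species = sorted(assign["species"].unique())
    manifest["counts"]["n_species"] = len(species)
    masks = {}
    for sp in species:
        occupied = set(assign.loc[assign["species"] == sp, "site"])
        masks[sp] = build_range_mask(sp, occupied, grid, candidate_sites=set(sites))

    visited, counts = build_visits(assign, sites, K, T)
    data = build_histories(assign, visited, counts, masks, species, sites)
    data.validate()
    manifest["counts"].update(data.summary_report())

    pd.DataFrame(
        {
            "cell_col": [c for c, _ in sites],
            "cell_row": [r for _, r in sites],
            "record_count": counts.sum(axis=(1, 2)),
        }
    ).to_csv(out / "sites.csv", index=False)
    np.savez_compressed(
        out / "detection_data.npz",
        y=data.y, observed=data.observed, visited=data.visited,
        range_mask=data.range_mask, record_counts=data.record_counts,
    )
    pd.Series(species).to_csv(out / "species.csv", index=False, header=["species"])
    return data


def covariates_stage(config: PipelineConfig, out: Path, manifest: dict,
                     data: DetectionData) -> EraCovariates:
    cf = config.covariate_files
    if cf is None:
        raise ValueError("records mode requires covariate_files in the config")
    site_labels = [f"{c}_{r}" for c, r in data.sites]
    site_cells = {lab: [lab] for lab in site_labels}
    start, K = config.eras.start, config.eras.n_eras

    def era_of_year(y):
        off = int(y) - start
        return off // ERA_LENGTH if 0 <= off < K * ERA_LENGTH else None

    temp = aggregate_climate(
        pd.read_csv(cf.temperature_csv), site_cells, era_of_year, n_eras=K
    )
    precip = aggregate_climate(
        pd.read_csv(cf.precipitation_csv), site_cells, era_of_year, n_eras=K
    )
    table = derive_category_scores(
        pd.read_csv(cf.overlap_csv),
        pd.read_csv(cf.crop_scores_csv).set_index("crop_class"),
    )
    comp = pd.read_csv(cf.composition_csv)
    floral = np.zeros_like(temp)
    # aggregate_climate returns sites in sorted-label order; build floral
    # in that order too, then permute everything back to data.sites order
    order = {lab: j for j, lab in enumerate(sorted(site_labels))}
    for (site, era), grp in comp.groupby(["site", "era"]):
        if site not in order:
            continue
        fractions = dict(zip(grp["category"], grp["fraction"]))
        floral[order[site], int(era) - 1] = site_floral_score(fractions, table)
    perm = [order[lab] for lab in site_labels]
    cov = EraCovariates(
        temp=temp[perm], precip=precip[perm], floral=floral[perm]
    ).standardized()
    cov.to_frame().to_csv(out / "covariates.csv", index=False)
    with open(out / "standardization.json", "w") as fh:
        json.dump({k: list(v) for k, v in cov.constants.items()}, fh, indent=2)
    return cov


def fit_stage(config: PipelineConfig, out: Path, manifest: dict,
              data: DetectionData, cov: EraCovariates | None) -> OccupancyResults:
    fc = config.fit
    model = MultiSpeciesOccupancyModel(
        data, cov,
        spec=ModelSpec(kind=fc.kind, detection_variant=fc.detection_variant),
    )
    results = model.fit(
        n_chains=fc.n_chains, n_warmup=fc.n_warmup, n_draws=fc.n_draws,
        seed=config.seed, target_accept=fc.target_accept,
        max_treedepth=fc.max_treedepth,
    )
    np.savez_compressed(out / "posterior_draws.npz", draws=results.run.draws)
    manifest["fit"] = {
        "kind": fc.kind,
        "n_divergent": int(results.run.n_divergent),
        "max_rhat": results.max_rhat(),
    }
    return results


def summarize_stage(config: PipelineConfig, out: Path, manifest: dict,
                    results: OccupancyResults) -> None:
    results.summary().to_csv(out / "summary.csv")
    results.species_table().to_csv(out / "species_table.csv")
    if results.spec.has_era:
        labels = results.trend_labels()
        manifest["trend_counts"] = labels.value_counts().to_dict()
    if results.spec.has_env:
        opt = results.thermal_optimum()
        manifest["thermal_optimum_c"] = {
            "mean": opt["community_mean"],
            "bci": list(opt["community_bci"]),
        }


def counterfactual_stage(config: PipelineConfig, out: Path, manifest: dict,
                         results: OccupancyResults) -> pd.DataFrame:
    table = winners_losers_table(results, hold_mode=config.counterfactual.hold_mode)
    table.to_csv(out / "counterfactual.csv", index=False)
    with open(out / "fig2_spec.json", "w") as fh:
        json.dump(fig2_scatter_spec(table), fh, indent=2, default=float)
    manifest["impact_counts"] = {
        v: row.to_dict() for v, row in impact_counts(table).iterrows()
    }
    return table


# ---------------------------------------------------------------------------
# Driver


def run_pipeline(
    config: PipelineConfig | str | Path,
    out_dir: str | Path,
    *,
    stop_after: str | None = None,
) -> dict:
    """Execute the pipeline and return the manifest dict.

    ``stop_after`` names a stage (see ``STAGES``) to halt after, which
    lets callers stage inputs for later stages (e.g. write covariate
    CSVs once the retained site list is known).
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "mode": config.mode,
        "counts": {},
        "timings": {},
        "inputs": {},
    }

    def tick(stage, fn, *args):
        t0 = time.time()
        result = fn(*args)
        manifest["timings"][stage] = round(time.time() - t0, 3)
        return result

    results = None
    if config.mode == "synthetic":
        sim = SimConfig(**{**config.synthetic, "seed": config.seed})
        data, cov, truth = tick("generate", generate_dataset, sim)
        manifest["counts"].update(data.summary_report())
        manifest["counts"]["n_occupied_site_eras_true"] = int(truth.z.sum())
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh)
        if stop_after in ("ingest", "grid", "histories", "covariates"):
            _write_manifest(out, manifest)
            return manifest
    else:
        if config.records is None:
            raise ValueError("records mode requires a records config block")
        manifest["inputs"][config.records.path] = _checksum(config.records.path)
        records_df = tick("ingest", ingest_stage, config, out, manifest)
        if stop_after == "ingest":
            _write_manifest(out, manifest)
            return manifest
        assign = tick("grid", grid_stage, config, out, manifest, records_df)
        if stop_after == "grid":
            _write_manifest(out, manifest)
            return manifest
        data = tick("histories", histories_stage, config, out, manifest, assign)
        if stop_after == "histories":
            _write_manifest(out, manifest)
            return manifest
        cov = tick("covariates", covariates_stage, config, out, manifest, data)
        if stop_after == "covariates":
            _write_manifest(out, manifest)
            return manifest

    results = tick("fit", fit_stage, config, out, manifest, data, cov)
    if stop_after != "fit":
        tick("summarize", summarize_stage, config, out, manifest, results)
        if results.spec.has_env and stop_after != "summarize":
            tick("counterfactual", counterfactual_stage, config, out, manifest,
                 results)
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("manifest written to %s", out / "manifest.json")
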