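"""End-to-end pipeline: characterise, cluster, project, compare, summarise.

``run_pipeline`` binds the stages in order on a (synthetic) tropics:

1. fire characteristics and NLSF assignment;
2. complete-linkage regime definition on focal-region burned cells;
3. MESS projection of the focal regimes onto the full domain;
4. PCA environments and per-regime regional niche overlap;
5. regime-wide and rainfall-decoupled burned-area trends;
6. vegetation classification and degradation summary.

Every stage's table is written under the output directory; all
randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as frio
from .characteristics import (CHARACTERISTIC_COLUMNS, characteristics_table,
                              normalise_characteristics)
from .clustering import assign_nlsf, complete_linkage_cluster, cut_height_diagnostics
from .degradation import classify_vegetation, ndvi_statistics, summarize_degradation
from .grid import make_grid
from .mess import classify_tropics, mess_surface, similarity_coverage
from .overlap import overlap_table, pca_reduce
from .synthetic import (EVENT_FLOOR_KM2, default_archetypes, generate_environment,
                        generate_fire_archive)
from .trends import lagged_precip_features, pixel_decoupled_trends, regime_trend_table

logger = logging.getLogger("fireregimes")


@dataclass
class PipelineConfig:
    """All knobs of the default pipeline, with the study's fixed constants."""

    n_rows: int = 30
    n_cols: int = 30
    cell_area: float = 100.0
    years: int = 14
    K: int = 5
    nlsf_fraction: float = 0.25
    seed: int = 0
    mess_similar_threshold: float = 0.0
    mess_exclusive_threshold: float = 24.0
    ndvi_forest_mean: float = 0.80
    ndvi_forest_annual_cv: float = 0.08
    ndvi_grassy_mean_floor: float = 0.06
    alpha: float = 0.05
    event_floor_km2: float = EVENT_FLOOR_KM2
    overlap_R: int = 100
    overlap_mode: str = "binary"
    normalisation_domain: str = "focal"   # or "all"
    region_fractions: tuple = (0.2, 0.4, 0.4)
    anomaly: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.years < 3:
            raise ValueError("years must be >= 3")
        if not (0 <= self.nlsf_fraction < 1):
            raise ValueError("nlsf_fraction in [0, 1) required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["region_fractions"] = list(self.region_fractions)
        d["anomaly"] = {f"{k[0]}:{k[1]}": v for k, v in self.anomaly.items()}
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute all stages on a synthetic tropics; returns the result bundle."""
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: hash=%s seed=%d", config.config_hash(), config.seed)

    def _stage(name):
        logger.info("stage: %s", name)

    results: dict = {"config": config}

    # --- simulate -------------------------------------------------------
    _stage("simulate")
    grid = make_grid(config.n_rows, config.n_cols, config.cell_area,
                     config.region_fractions)
    archetypes = default_archetypes()
    series, truth = generate_fire_archive(
        grid, archetypes, years=config.years, nlsf_fraction=config.nlsf_fraction,
        seed=config.seed, event_floor=config.event_floor_km2)
    env = generate_environment(grid, truth, n_years=config.years,
                               anomaly=dict(config.anomaly))
    results.update(grid=grid, series=series, truth=truth, env=env)

    # --- characterise ---------------------------------------------------
    _stage("characterize")
    chars = characteristics_table(series)
    nlsf = assign_nlsf(chars["ba_year_mean"].to_numpy())
    focal = grid.region_mask("focal")
    domain = (focal & ~nlsf) if config.normalisation_domain == "focal" else ~nlsf
    normed, params = normalise_characteristics(chars, domain=domain)
    results.update(characteristics=chars, normalised=normed, nlsf=nlsf,
                   norm_params=params)

    # --- cluster (focal region only) -------------------------------------
    _stage("cluster")
    focal_vectors = normed.loc[focal, CHARACTERISTIC_COLUMNS]
    regime_map, Z = complete_linkage_cluster(
        focal_vectors, K=config.K, nlsf_mask=nlsf[focal],
        ba_year_mean=chars.loc[focal, "ba_year_mean"].to_numpy())
    focal_labels = regime_map.labels
    results.update(focal_regimes=regime_map, linkage=Z,
                   cut_diagnostics=cut_height_diagnostics(Z))

    # --- project ----------------------------------------------------------
    _stage("project")
    ref_vectors = focal_vectors.to_numpy()
    surface = mess_surface(ref_vectors, focal_labels,
                           normed[CHARACTERISTIC_COLUMNS].to_numpy())
    tropics_map, exclusive = classify_tropics(
        surface, nlsf, exclusive_threshold=config.mess_exclusive_threshold)
    # focal cells keep their clustered labels
    labels = tropics_map.labels.copy()
    labels[focal] = focal_labels
    coverage = similarity_coverage(labels, chars["ba_year_mean"].to_numpy())
    results.update(surface=surface, labels=labels, exclusive=exclusive,
                   coverage=coverage)

    # --- overlap -----------------------------------------------------------
    _stage("overlap")
    ndvi_stats = ndvi_statistics(env.ndvi)
    veg_table = pd.concat([ndvi_stats, pd.DataFrame({
        "tree_cover": env.tree_cover, "tree_loss": env.tree_loss})], axis=1)
    fire_space = pca_reduce(normed[~nlsf], CHARACTERISTIC_COLUMNS)
    veg_space = pca_reduce(veg_table)
    clim_space = pca_reduce(env.climate)
    burned_labels = labels[~nlsf]
    overlaps = overlap_table(fire_space, burned_labels,
                             grid.region_label[~nlsf],
                             R=config.overlap_R)
    results.update(fire_space=fire_space, veg_space=veg_space,
                   climate_space=clim_space, overlaps=overlaps)

    # --- trends -------------------------------------------------------------
    _stage("trends")
    trend_table = regime_trend_table(series.burned_area, labels,
                                     grid.region_label, alpha=config.alpha)
    if config.years >= 8:
        clim_peak = series.burned_area.mean(axis=1).argmax(axis=1)
        feats = lagged_precip_features(env.precip, clim_peak, config.years,
                                       lead_months=env.lead_months)
        pixel_trends = pixel_decoupled_trends(series.burned_area, feats,
                                              cell_mask=focal & ~nlsf,
                                              alpha=config.alpha)
    else:
        # pixel-wise decoupled trends need >= 8 years; shorter runs keep
        # the regime-wide trends only
        pixel_trends = pd.DataFrame(
            columns=["slope", "t_value", "p_value", "significant"])
        pixel_trends.index.name = "cell_id"
    results.update(trend_table=trend_table, pixel_trends=pixel_trends)

    # --- degrade --------------------------------------------------------------
    _stage("degrade")
    profile = classify_vegetation(ndvi_stats["ndvi_mean"].to_numpy(),
                                  ndvi_stats["ndvi_annual_cv"].to_numpy(),
                                  ndvi_stats["ndvi_monthly_cv"].to_numpy())
    summary = summarize_degradation(labels, grid.region_label, profile.veg_class,
                                    env.tree_cover, env.tree_loss, env.population,
                                    cell_area=grid.cell_area)
    results.update(veg_profile=profile, degradation=summary)

    if out is not None:
        _write_outputs(results, out)
    logger.info("pipeline done")
    return results


def _write_outputs(results: dict, out: Path) -> None:
    config: PipelineConfig = results["config"]
    frio.save_config(config.to_dict(), out / "config.yaml")
    frio.write_fire_series(results["series"], out / "fire_series.nc")
    results["truth"].to_frame().to_csv(out / "truth.csv", index=False)
    results["characteristics"].to_csv(out / "characteristics.csv")
    frio.write_labels_csv(results["labels"], out / "regime_map.csv",
                          extra={"exclusive": results["exclusive"],
                                 "nlsf": results["nlsf"]})
    frio.write_dendrogram_json(results["linkage"], out / "dendrogram.json")
    results["cut_diagnostics"].to_csv(out / "cut_diagnostics.csv", index=False)
    results["surface"].to_frame().to_csv(out / "mess_surface.csv", index=False)
    results["overlaps"].to_csv(out / "overlap.csv", index=False)
    results["trend_table"].to_csv(out / "trend_table.csv", index=False)
    results["pixel_trends"].to_csv(out / "pixel_trends.csv")
    results["degradation"].to_csv(out / "degradation_summary.csv", index=False)
    (out / "run.json").write_text(json.dumps({
        "config_hash": config.config_hash(), "seed": config.seed,
        "coverage": results["coverage"]}))
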