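"""End-to-end driver: synthetic catchment -> terrain -> 2.5D + 3D models ->
stocks -> comparison tables.

``run_pipeline`` executes all stages in memory and writes every result
(rasters, voxel files, CSV tables, a JSON run log with seeds and config
hash) into the output directory. Individual stages are exposed for the CLI,
which communicates through files in the same directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import grids, io, metrics, stocks, synthetic, terrain
from .config import PipelineConfig
from .learners import assign_folds, default_learner_spec
from .mapping import internal_validation, run_25d, run_3d

log = logging.getLogger(__name__)


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    df.to_csv(path, index=False, float_format="%.6g")
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps({"config_hash": cfg.hash(), "seed": cfg.seed}, indent=2))


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage; returns a dict of the headline results."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    incomplete_flag = outdir / "INCOMPLETE"
    incomplete_flag.write_text("run in progress or aborted")
    stage = ["simulate"]
    try:
        result = _run_all_stages(cfg, outdir, stage)
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        incomplete_flag.write_text(f"aborted during stage: {stage[0]}")
        raise RuntimeError(f"pipeline stage {stage[0]!r} failed: {exc}") from exc
    incomplete_flag.unlink()
    return result


def _run_all_stages(cfg: PipelineConfig, outdir: Path, stage: list[str]) -> dict:
    cat = synthetic.reference_catchment_from_config(cfg)
    grids.write_dem(outdir / "dem.tif", cat.dem)
    io.save_profiles(outdir / "soc_profiles.csv", cat.soc, cat.dem)
    io.save_profiles(outdir / "bd_profiles.csv", cat.bd, cat.dem)
    grids.write_stack(outdir / "covariates_std.tif", cat.stack)
    for prop, truth in (("soc", cat.soc_truth), ("bd", cat.bd_truth)):
        arrays = np.stack(list(truth.fields.values()))
        grids.write_raster(outdir / f"truth_{prop}_{truth.family}.tif", arrays,
                           cell_size_cm=cat.dem.cell_size_cm, origin=cat.dem.origin,
                           band_names=list(truth.fields))

    stage[0] = "learn"
    soc_folds = assign_folds(cat.soc.n_plots, cfg.cv_folds, seed=cfg.seed + 10)
    bd_folds = assign_folds(cat.bd.n_plots, cfg.cv_folds, seed=cfg.seed + 11)

    results: dict = {"config_hash": cfg.hash(), "seed": cfg.seed}
    soc_X = cat.stack.design_matrix(cat.soc.plots.rows, cat.soc.plots.cols)
    bd_X = cat.stack.design_matrix(cat.bd.plots.rows, cat.bd.plots.cols)

    for kind in cfg.learners:
        soc_spec = default_learner_spec(kind, soc_X, seed=cfg.seed)
        bd_spec = default_learner_spec(kind, bd_X, seed=cfg.seed)

        # --- 2.5D reference models (per-increment CV table)
        soc_25d = run_25d(cat.soc, cat.stack, soc_spec, soc_folds)
        bd_25d = run_25d(cat.bd, cat.stack, bd_spec, bd_folds)
        cv25 = pd.concat([soc_25d.cv_table().assign(property="SOC", learner=kind),
                          bd_25d.cv_table().assign(property="BD", learner=kind)])
        _write_table(cv25, outdir / f"cv_25d_{kind}.csv", cfg)

        # --- 3D models per family, coefficient CV (with nRMSE), comparison
        compare_tables, internal_tables, coef_tables = [], [], []
        voxels_by_family = {}
        for family in cfg.soc_families:
            fields, voxels = run_3d(cat.soc, cat.stack, family, soc_spec, soc_folds,
                                    cfg.depth_from_cm, cfg.depth_to_cm, cfg.step_cm,
                                    clamp_floor=cfg.soc_clamp_floor)
            voxels_by_family[family] = voxels
            coef_tables.append(fields.cv_table().assign(property="SOC", family=family,
                                                        learner=kind))
            io.save_fits(outdir / f"fits_soc_{family}.csv", fields.fitted_coefficients, family)
            pred3d = fields.evaluate_at_depths(cat.soc.increments.mid_depths_cm)
            compare_tables.append(
                metrics.compare_layers(pred3d, soc_25d.grids)
                .assign(property="SOC", family=family, learner=kind))
            internal_tables.append(internal_validation(fields, cat.soc)
                                   .assign(property="SOC", family=family, learner=kind))
            voxels.to_dataset().to_netcdf(outdir / f"voxels_soc_{family}_{kind}.nc",
                                          engine="scipy")

        bd_fields, bd_voxels = run_3d(cat.bd, cat.stack, cfg.bd_family, bd_spec, bd_folds,
                                      max(cfg.depth_from_cm, cfg.step_cm) if cfg.bd_family == "log"
                                      else cfg.depth_from_cm,
                                      cfg.depth_to_cm, cfg.step_cm, clamp_floor=None)
        coef_tables.append(bd_fields.cv_table().assign(property="BD", family=cfg.bd_family,
                                                       learner=kind))
        io.save_fits(outdir / f"fits_bd_{cfg.bd_family}.csv",
                     bd_fields.fitted_coefficients, cfg.bd_family)
        pred3d_bd = bd_fields.evaluate_at_depths(cat.bd.increments.mid_depths_cm)
        compare_tables.append(metrics.compare_layers(pred3d_bd, bd_25d.grids)
                              .assign(property="BD", family=cfg.bd_family, learner=kind))
        internal_tables.append(internal_validation(bd_fields, cat.bd)
                               .assign(property="BD", family=cfg.bd_family, learner=kind))
        bd_voxels.to_dataset().to_netcdf(outdir / f"voxels_bd_{cfg.bd_family}_{kind}.nc",
                                         engine="scipy")

        _write_table(pd.concat(coef_tables), outdir / f"cv_coefficients_{kind}.csv", cfg)
        _write_table(pd.concat(compare_tables), outdir / f"compare_3d_vs_25d_{kind}.csv", cfg)
        _write_table(pd.concat(internal_tables), outdir / f"internal_validation_{kind}.csv", cfg)

        stage[0] = "stocks"
        # --- stocks from the primary 3D models (first SOC family + BD)
        primary = cfg.soc_families[0]
        soc_vox = voxels_by_family[primary]
        # BD voxel grid may start at step_cm (log family); align SOC to it
        common = np.intersect1d(soc_vox.depths_cm, bd_voxels.depths_cm)
        soc_sel = np.isin(soc_vox.depths_cm, common)
        bd_sel = np.isin(bd_voxels.depths_cm, common)
        from .mapping import VoxelModel
        soc_aligned = VoxelModel(soc_vox.property_name, common, soc_vox.values[soc_sel],
                                 soc_vox.step_cm, soc_vox.clamp_count, soc_vox.cell_size_cm)
        bd_aligned = VoxelModel(bd_voxels.property_name, common, bd_voxels.values[bd_sel],
                                bd_voxels.step_cm, bd_voxels.clamp_count,
                                bd_voxels.cell_size_cm)
        stock = stocks.voxel_stock(soc_aligned, bd_aligned)
        stock.to_dataset().to_netcdf(outdir / f"stock_{kind}.nc", engine="scipy")
        mask = cat.dem.mask
        area_ha = mask.sum() * (cat.dem.cell_size_m**2) / 1e4
        rows = []
        for d_from, d_to in cfg.stock_ranges_cm:
            d_from_eff = max(d_from, float(common.min()) - stock.dz_cm)
            dens = stocks.aggregate_stock(stock, (d_from_eff, d_to), mask=mask)
            rows.append({"depth_from_cm": d_from_eff, "depth_to_cm": d_to,
                         "area_ha": area_ha, "stock_Mg_per_ha": dens, "learner": kind})
        stock_table = pd.DataFrame(rows)
        _write_table(stock_table, outdir / f"stocks_{kind}.csv", cfg)

        results[kind] = {
            "cv_25d_mean_r2_soc": float(soc_25d.cv_table().iloc[-1]["r2"]),
            "internal_validation": pd.concat(internal_tables),
            "compare": pd.concat(compare_tables),
            "stocks": stock_table,
        }

    (outdir / "run_log.json").write_text(json.dumps(
        {"config": cfg.to_dict(), "config_hash": cfg.hash(), "seed": cfg.seed},
        indent=2, default=list))
    cfg.to_yaml(outdir / "config.yaml")
    return results
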