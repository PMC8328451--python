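"""End-to-end driver: landscape -> indices -> snow fraction -> patches ->
selection -> RSPF, with a manifest so any run can be reproduced exactly.

The pipeline runs either on a synthetic bundle (default) or on user-supplied
rasters and tracks.  Every stage's statistics land in one JSON-able report;
per-stage artifacts (grids, patch GeoJSON, tables) are written when an output
directory is configured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as sio
from .grid import Grid
from .patches import (
    DEFAULT_THRESHOLDS,
    apply_exclusions,
    distance_to_snowfree,
    label_patches,
    patch_stats,
    threshold_mask,
)
from .rspf import (
    FULL_MODEL,
    build_design,
    fit_rspf,
    hosmer_lemeshow,
    parse_terms,
    rank_models,
    standardize,
    vif,
)
from .selection import diel_selection, select_against_availability
from .snowfrac import (
    balanced_sample,
    fit_ensemble,
    make_calibration_set,
    predict_fraction,
    transect_coverage,
)
from .synthetic import SyntheticConfig, SyntheticBundle, generate_bundle
from .terrain import block_mean, mean_scene, tpi as tpi_op
from .tracks import Track

log = logging.getLogger("snowsel")

MEDIAN_PATCH_AREA_M2 = 1800.0  # two 30 m cells; floor for the DIST targets


@dataclass
class PipelineConfig:
    """Everything a run needs; recorded verbatim in the manifest."""

    synthetic: SyntheticConfig | None = None
    dem_path: str | None = None
    snow_depth_path: str | None = None
    ndsi_paths: list[str] = field(default_factory=list)
    lichen_path: str | None = None
    tracks_path: str | None = None
    exclusions_path: str | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    selection_threshold: float = 0.3   # mask used for overlay statistics
    connectivity: int = 8
    buffer_m: float = 5.0
    quota_per_bin: int = 30
    avail_per_used: float = 9.0        # available rows per used row
    diel: bool = True
    lat: float = 60.0
    lon: float = 7.5
    seed: int = 0
    n_transects: int = 6
    transect_width_cells: int = 2
    models: list[str] = field(default_factory=list)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None and self.dem_path is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
        if not self.models:
            self.models = default_model_set()


def default_model_set() -> list[str]:
    """The full model and its drop-one-predictor variants.

    Dropping a main effect also drops any interaction containing it; dropping
    DEM removes both DEM and DEM2.
    """
    full = parse_terms(FULL_MODEL)
    specs = [" + ".join(full)]
    groups = {
        "TPI": {"TPI"},
        "SNOW": {"SNOW", "SNOW:LICHEN"},
        "LICHEN": {"LICHEN", "SNOW:LICHEN"},
        "DIST": {"DIST"},
        "DEM": {"DEM", "DEM2"},
        "XCOORD": {"XCOORD"},
    }
    for drop in groups.values():
        specs.append(" + ".join(t for t in full if t not in drop))
    return specs


def _load_inputs(cfg: PipelineConfig) -> SyntheticBundle:
    from .terrain import aggregate_fraction, classify_snow_free_fine

    if cfg.synthetic is not None:
        return generate_bundle(cfg.synthetic)
    dem = sio.read_ascii_grid(cfg.dem_path)
    depth = sio.read_ascii_grid(cfg.snow_depth_path)
    snow_free = classify_snow_free_fine(depth)
    factor = 30
    frac_true = aggregate_fraction(snow_free, factor)
    scenes = [sio.read_ascii_grid(p) for p in cfg.ndsi_paths]
    lichen = sio.read_ascii_grid(cfg.lichen_path) if cfg.lichen_path else None
    trks = sio.read_tracks_csv(cfg.tracks_path) if cfg.tracks_path else []
    return SyntheticBundle(
        dem=dem,
        tpi=tpi_op(dem, window=30.0),
        snow_depth=depth,
        snow_free_fine=snow_free,
        snow_frac_true=frac_true,
        ndsi_scenes=scenes,
        lichen=lichen,
        tracks=trks,
        truth={},
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the combined report.

    Stage failures abort with the stage name attached; partial artifacts
    already written remain on disk, flagged incomplete in the manifest.
    """
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": _manifest_config(cfg),
        "seed": cfg.seed,
        "complete": False,
    }
    report: dict = {"manifest": manifest}
    stage = "ingest"
    try:
        bundle = _load_inputs(cfg)
        factor = round(bundle.snow_frac_true.cell / bundle.dem.cell)

        stage = "indices"
        ndsi_mean = mean_scene(bundle.ndsi_scenes)
        tpi_coarse = block_mean(bundle.tpi, factor)
        report["indices"] = {
            "n_scenes": len(bundle.ndsi_scenes),
            "ndsi_mean_range": [
                float(np.nanmin(ndsi_mean.values)),
                float(np.nanmax(ndsi_mean.values)),
            ],
        }

        stage = "snowfrac"
        coverage = transect_coverage(
            bundle.snow_frac_true, cfg.n_transects, cfg.transect_width_cells
        )
        cal = make_calibration_set(ndsi_mean, tpi_coarse, bundle.snow_frac_true, coverage)
        cal_bal = balanced_sample(cal, cfg.quota_per_bin, seed=cfg.seed)
        ens = fit_ensemble(cal_bal, seed=cfg.seed)
        frac_pred = predict_fraction(ens, ndsi_mean, tpi_coarse)
        report["snowfrac"] = {
            "n_reference_cells": len(cal),
            "n_calibration_rows": len(cal_bal),
            "cv_mean_r2": ens.mean_r2,
            "chosen_learners": [s.name for s in ens.chosen],
            "predictor_correlations": ens.predictor_correlations,
        }

        stage = "patches"
        exclusions = (
            sio.read_exclusion_polygons(cfg.exclusions_path)
            if cfg.exclusions_path
            else []
        )
        patch_report = {}
        masks = {}
        for t in cfg.thresholds:
            mask = threshold_mask(frac_pred, t)
            ps = label_patches(mask, connectivity=cfg.connectivity)
            if exclusions:
                ps = apply_exclusions(ps, exclusions)
                mask = mask.like((ps.labels.values > 0).astype(float))
            masks[t] = mask
            stats = patch_stats(ps)
            stats["excluded_area_pct"] = ps.excluded_area_pct
            patch_report[f"{int(t*100)}pct"] = stats
            if out_dir:
                sio.write_patches_geojson(ps, out_dir / f"patches_{int(t*100)}pct.geojson")
                ps.table.to_csv(out_dir / f"patches_{int(t*100)}pct.csv", index=False)
        report["patches"] = patch_report

        stage = "selection"
        sel_report = {}
        if bundle.tracks:
            for t in cfg.thresholds:
                try:
                    res = select_against_availability(bundle.tracks, masks[t])
                    corrected = False
                except ValueError:
                    # zero cell (e.g. no patch at a strict threshold):
                    # apply the Haldane-Anscombe +0.5 correction, reported
                    res = select_against_availability(
                        bundle.tracks, masks[t], haldane=True
                    )
                    corrected = True
                    log.warning(
                        "zero cell at threshold %.2f; Haldane correction applied", t
                    )
                entry = asdict(res)
                entry["haldane_corrected"] = corrected
                sel_report[f"{int(t*100)}pct"] = entry
            if cfg.diel:
                sel_mask = masks.get(cfg.selection_threshold, next(iter(masks.values())))
                diel = diel_selection(
                    bundle.tracks,
                    sel_mask,
                    sel_report[f"{int(cfg.selection_threshold*100)}pct"][
                        "availability_fraction"
                    ],
                    lat=cfg.lat,
                    lon=cfg.lon,
                )
                sel_report["diel"] = diel
        report["selection"] = sel_report

        stage = "rspf"
        rspf_report = {}
        if bundle.tracks:
            dist_fine = distance_to_snowfree(
                bundle.snow_free_fine,
                min_patch_area=MEDIAN_PATCH_AREA_M2,
                connectivity=cfg.connectivity,
            )
            layers = {
                "SNOW": bundle.snow_depth,
                "DIST": dist_fine,
                "DEM": bundle.dem,
                "TPI": bundle.tpi,
                "LICHEN": bundle.lichen,
            }
            used_xy = np.concatenate(
                [np.column_stack([t.x, t.y]) for t in bundle.tracks]
            )
            have_lichen = bundle.lichen is not None
            if not have_lichen:
                layers["LICHEN"] = bundle.dem.like(np.zeros(bundle.dem.shape))
            n_avail = int(round(cfg.avail_per_used * len(used_xy)))
            design = build_design(
                used_xy, layers, n_available=n_avail, seed=cfg.seed, buffer=cfg.buffer_m
            )
            design_std, means, sds = standardize(
                design, [c for c in design.columns if c != "used" and
                         (have_lichen or c != "LICHEN")]
            )
            models = cfg.models
            if not have_lichen:
                kept = [m for m in models if "LICHEN" not in m]
                skipped = [m for m in models if "LICHEN" in m]
                for m in skipped:
                    log.warning("skipping model with missing LICHEN layer: %s", m)
                models = kept
                rspf_report["skipped_models"] = skipped
            fits = [fit_rspf(design_std, m) for m in models]
            ranking = rank_models(fits)
            best = fits[int(np.argmin([f.aic for f in fits]))]
            x2, dof, p = hosmer_lemeshow(best.fitted, design_std["used"].to_numpy())
            vif_terms = [t for t in best.terms if ":" not in t]
            rspf_report.update(
                {
                    "n_used": best.n_used,
                    "n_available": best.n_avail,
                    "ranking": ranking.reset_index(),
                    "best_model": best.model_spec,
                    "best_coefficients": best.coefficients,
                    "best_std_errors": best.std_errors,
                    "best_p_values": best.p_values,
                    "hosmer_lemeshow": {"x2": x2, "df": dof, "p": p},
                    "vif": vif(design_std, vif_terms),
                }
            )
        report["rspf"] = rspf_report

        manifest["complete"] = True
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        if out_dir:
            sio.write_report(report, out_dir / "report.json")
    return report


def _manifest_config(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    return d
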