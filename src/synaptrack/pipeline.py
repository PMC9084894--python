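"""End-to-end pipeline: simulate → localize → track → diffusion → map → stats.

``run_pipeline`` executes the full analysis chain on a simulated dataset and
writes every intermediate artifact (ground truth, localizations, tracks,
estimates, histogram, density map, masks) plus a JSON run report with
per-stage counts and summary statistics.  All randomness flows from the
single seed in the config, so a fixed config yields byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__, io
from .config import PipelineConfig
from .diffusion import (analyze_tracks, diffusion_distribution, estimates_to_table,
                        summarize_mobility)
from .localize import localize_stack
from .simulate import (degrade_to_localizations, render_movie,
                       render_reference_channel, simulate_ground_truth, _field_shape)
from .srmap import (reconstruct_density_map, synaptic_coverage,
                    synaptic_enrichment, upscale_mask)
from .track import filter_tracks, link_localizations, tracks_to_table

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _rasterize_cell_mask(geometry, pixel_size: float, shape: tuple[int, int]) -> np.ndarray:
    ny, nx = shape
    xc = (np.arange(nx) + 0.5) * pixel_size
    yc = (np.arange(ny) + 0.5) * pixel_size
    X, Y = np.meshgrid(xc, yc)
    x0, y0, w, h = geometry.dendrite_rect
    return (X >= x0) & (X <= x0 + w) & (Y >= y0) & (Y <= y0 + h)


def run_pipeline(config: PipelineConfig, write_movie: bool = False) -> dict:
    """Run the full analysis chain and return the run report (also written).

    In "tables" mode the simulator's ground truth is degraded directly to a
    localization table (fast path, no rendering); in "movie" mode a camera
    stack is rendered and the wavelet detector + Gaussian refinement produce
    the localizations.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)

    logger.info("stage: simulate (%d molecules, %d frames)", sim.n_molecules, sim.n_frames)
    truth = simulate_ground_truth(sim, config.geometry)
    io.write_ground_truth(truth.to_table(), out / "ground_truth.csv")

    shape = _field_shape(config.geometry, config.optics.pixel_size)
    if config.mode == "movie":
        logger.info("stage: render + localize")
        stack = render_movie(truth, config.optics, seed=config.seed + 1, shape=shape)
        if write_movie:
            io.write_stack(stack, out / "movie.tif")
        locs = localize_stack(stack, config.wavelet, pixel_size=config.optics.pixel_size)
    else:
        logger.info("stage: degrade to localizations")
        locs = degrade_to_localizations(truth, seed=config.seed + 1)
    io.write_localizations(locs, out / "localizations.csv")

    logger.info("stage: link + filter")
    tracks = link_localizations(locs, config.tracking)
    kept = filter_tracks(tracks, config.analysis.L_min)
    io.write_tracks(tracks_to_table(kept), out / "tracks.csv")

    logger.info("stage: diffusion analysis")
    params = dataclasses.replace(config.analysis, frame_interval=sim.frame_interval)
    estimates = analyze_tracks(kept, params)
    estimates_to_table(estimates).to_csv(out / "estimates.csv", index=False)
    summary = summarize_mobility(estimates, params) if estimates else None
    edges, mass = diffusion_distribution(estimates, D_floor=params.D_floor) if estimates else (np.array([]), np.array([]))
    if len(edges):
        import pandas as pd
        pd.DataFrame({"bin_left_log10D": edges[:-1], "mass": mass}).to_csv(
            out / "diffusion_histogram.csv", index=False)

    logger.info("stage: density map + synaptic statistics")
    dmap = reconstruct_density_map(locs, config.map, field_shape_px=shape)
    io.write_density_map(dmap.counts, out / "density_map.tif", config.map.map_pixel)
    _, cam_mask = render_reference_channel(config.geometry, config.optics,
                                           seed=config.seed + 2, shape=shape)
    io.write_mask(cam_mask, out / "synapse_mask.tif")
    map_mask = upscale_mask(cam_mask, config.map.zoom).astype(bool)
    cell_mask = upscale_mask(
        _rasterize_cell_mask(config.geometry, config.optics.pixel_size, shape).astype(np.uint8),
        config.map.zoom).astype(bool)
    enr = synaptic_enrichment(locs, map_mask, cell_mask, config.map) if map_mask.any() else None
    cov = synaptic_coverage(dmap, map_mask) if map_mask.any() else None

    report = {
        "software": {"name": "synaptrack", "version": __version__},
        "seed": config.seed,
        "scenario": config.scenario,
        "mode": config.mode,
        "config": _jsonable(config.to_dict()),
        "counts": {
            "n_frames": sim.n_frames,
            "n_molecules": sim.n_molecules,
            "n_localizations": int(len(locs)),
            "n_tracks": len(tracks),
            "n_tracks_filtered": len(kept),
            "n_estimates": len(estimates),
        },
        "mobility": None if summary is None else {
            "n_tracks": summary.n_tracks,
            "immobile_fraction": summary.immobile_fraction,
            "mobile_fraction": summary.mobile_fraction,
            "median_D_um2_s": summary.median_D,
        },
        "enrichment": None if enr is None else {
            "synaptic_density_per_um2": enr.synaptic_density,
            "extrasynaptic_density_per_um2": enr.extrasynaptic_density,
            "enrichment": enr.enrichment if np.isfinite(enr.enrichment) else "inf",
            "flagged": enr.flagged,
        },
        "coverage": None if cov is None else {
            "mean_coverage": cov.mean_coverage,
            "per_synapse": cov.per_synapse.tolist(),
        },
    }
    # timing goes to the log, not the report, so reports are seed-deterministic
    logger.info("pipeline finished in %.2f s", time.time() - t0)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
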