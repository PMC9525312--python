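"""End-to-end pipeline: simulate -> localize -> track -> unwrap ->
segment -> population fits, with a JSON-serializable report.

The pipeline runs the same stages an experimentalist would run on real
localization tables, but sources its input from the synthetic generator,
so every reported quantity can be compared with generator ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import loc3d, popfit, segments as seg, simcell, tracking
from .config import PipelineConfig
from .geometry import CellGeometry, fit_cell_geometry, unwrap_track

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _true_geometry(sim: simcell.SimParams) -> CellGeometry:
    return CellGeometry(axis_point=np.array([0.0, 0.0, sim.radius]),
                        axis_direction=np.array([1.0, 0.0, 0.0]),
                        radius=sim.radius,
                        septum_axial_pos=sim.septum_axial_pos)


def run_pipeline(config: PipelineConfig | None = None,
                 out_dir=None) -> dict:
    """Run the full analysis chain on simulated cells.

    Per cell: simulate septal molecules, attach z via the bead
    calibration lookup (with the 0.75 rescale), band-pass filter the
    widths, link localizations into tracks, select septal tracks,
    unwrap onto the cylinder, segment and classify. Speeds of all
    processive segments are pooled into the log-normal mixture fit with
    bootstrap errors; stationary apparent speeds into the exponential
    decay fit.

    Returns the report dict; with `out_dir` set, also writes the
    intermediate CSVs, the report JSON and an effective-config snapshot.
    Fully deterministic given config.seed.
    """
    config = config or PipelineConfig()
    sim0 = config.sim
    seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_cells + 1) % (2**31)

    bead_table = simcell.simulate_bead_stack(sigma_model=sim0.psf)
    calib = loc3d.calibrate_astigmatism(
        bead_table, rescale_factor=config.rescale_factor)

    all_segments = []
    truth_labels = []
    unwrapped_rows = []
    track_rows = []
    n_tracks_total = 0
    n_locs_total = 0

    for cell in range(config.n_cells):
        sim = replace(sim0, seed=int(seeds[cell]))
        truth, locs = simcell.simulate_septal_molecules(sim)
        if locs.empty:
            continue
        n_locs_total += len(locs)
        locs = loc3d.bandpass_filter(locs, config.band_lo, config.band_hi)
        locs = loc3d.add_z(locs, calib)
        if locs.empty:
            continue
        # lookup z is relative to the focal plane; shift to the coverslip
        # frame the simulation geometry lives in
        locs["z"] = locs["z"] + sim.focal_plane_z

        tracks = tracking.link_localizations(locs, config.max_disp,
                                             config.max_gap)
        if config.geometry_mode == "fit":
            geom = fit_cell_geometry(tracking.tracks_to_frame(tracks))
        else:
            geom = _true_geometry(sim)
        tracks = tracking.select_septal_tracks(tracks, geom,
                                               config.axial_window)
        tracks = [t for t in tracks if len(t) >= config.min_segment_len]
        n_tracks_total += len(tracks)

        mol_pop = truth.groupby("molecule")["population"].first()
        for tr in tracks:
            ut = unwrap_track(tr, geom, frame_interval=sim.frame_interval)
            if len(ut) < config.min_segment_len:
                continue
            segs = seg.analyze_track(
                ut, min_len=config.min_segment_len, B=config.bootstrap_B,
                seed=int(seeds[-1]) + cell * 1000 + tr.track_id,
                r_max=config.r_max, p_min=config.p_min)
            for g in segs:
                g.track_id = cell * 100000 + tr.track_id
            all_segments.extend(segs)
            if "molecule" in tr.data.columns:
                # ground-truth label per classified segment: population of
                # the molecule dominating that stretch of frames (linking
                # can occasionally chain two molecules into one track)
                frames_kept = (ut.data["t"].to_numpy()
                               / sim.frame_interval).round().astype(int)
                by_frame = tr.data.set_index("frame")["molecule"]
                for g in segs:
                    if g.label == "unclassified":
                        continue
                    mols = by_frame.loc[frames_kept[g.start:g.stop]]
                    pop = mol_pop.get(int(mols.mode().iloc[0]), "unknown")
                    truth_labels.append("stationary" if pop == "stationary"
                                        else "processive")
            d = ut.data.copy()
            d.insert(0, "track_id", cell * 100000 + tr.track_id)
            unwrapped_rows.append(d)
            td = tr.data.copy()
            td.insert(0, "track_id", cell * 100000 + tr.track_id)
            td.insert(0, "cell", cell)
            track_rows.append(td)

    summary = seg.population_summary(all_segments)
    report = {
        "config_seed": config.seed,
        "n_cells": config.n_cells,
        "n_localizations": n_locs_total,
        "n_tracks": n_tracks_total,
        "n_segments": summary["n_segments"],
        "pct_stationary": summary["pct_stationary"],
        "pct_processive": summary["pct_processive"],
        "mean_dwell_time_s": float(np.mean(summary["dwell_times"]))
        if summary["dwell_times"] else None,
        "mean_run_time_s": float(np.mean(summary["run_times"]))
        if summary["run_times"] else None,
        "mean_run_length_nm": float(np.mean(summary["run_lengths"]))
        if summary["run_lengths"] else None,
    }

    speeds = np.asarray(summary["speeds"], dtype=float)
    speeds = speeds[speeds > 0]
    if speeds.size >= 20:
        fit = popfit.bootstrap_fit(speeds, config.n_components,
                                   B=config.bootstrap_B,
                                   seed=int(seeds[-1]))
        report["speed_fit"] = {
            "n_components": fit.n_components, "p1": fit.p1,
            "u1": fit.u1, "sigma1": fit.sigma1,
            "u2": fit.u2, "sigma2": fit.sigma2,
            "mean_speeds_nm_s": fit.mean_speeds,
            "se": fit.se, "B": fit.B,
        }
    if speeds.size:
        report["mean_speed_nm_s"] = float(speeds.mean())

    stat_speeds = [abs(g.v) for g in all_segments if g.label == "stationary"]
    if len(stat_speeds) >= 20:
        try:
            sfit = popfit.fit_stationary_exponential(
                stat_speeds, config.stationary_bin_width)
            report["stationary_fit"] = {"A": sfit.A, "lambda": sfit.lam,
                                        "u_nm_s": sfit.u}
        except ValueError:
            pass

    if truth_labels:
        tl = np.asarray(truth_labels)
        report["truth"] = {
            "n_segments_matched": int(tl.size),
            "pct_stationary_truth": float(100.0 * np.mean(tl == "stationary")),
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        if track_rows:
            pd.concat(track_rows, ignore_index=True).to_csv(
                out / "tracks.csv", index=False)
        if unwrapped_rows:
            pd.concat(unwrapped_rows, ignore_index=True).to_csv(
                out / "unwrapped.csv", index=False)
        if all_segments:
            pd.DataFrame([dataclasses.asdict(g) for g in all_segments]).to_csv(
                out / "segments.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        logger.info("pipeline outputs written to %s", out)
    return report
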