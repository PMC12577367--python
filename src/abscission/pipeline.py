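"""Workflow orchestration: simulate, yeast abscission, actin index, midbody, stats.

Each workflow reads its inputs, runs the corresponding analysis modules,
and writes CSV/JSON artifacts into the configured output directory.  All
outputs are deterministic given (config, seed); every table carries the
package version and the effective-config hash, and a structured log
records parameters and dropped frames.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .actin import actin_trace, score_clearance
from .config import config_hash, write_effective_config
from .exceptions import DataError
from .movie import Movie, read_movie, write_movie
from .profiles import classify_profile, detect_ingression, extract_neck_profile, time_to_abscission
from .segmentation import (
    detect_anaphase_onset,
    label_nuclei,
    major_axis_trace,
    threshold_positive,
)
from .simulate import (
    SceneParams,
    generate_division_movie,
    params_from_dict,
)
from .stats import box_summary, cumulative_fraction, fraction_completed_by, mann_whitney

logger = logging.getLogger(__name__)

WORKFLOWS = ("simulate", "yeast_abscission", "actin_index", "midbody", "stats")


def _stamp(df: pd.DataFrame, config: dict) -> pd.DataFrame:
    df = df.copy()
    df["package_version"] = __version__
    df["config_hash"] = config_hash(config)
    return df


def _outdir(config: dict) -> Path:
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _threshold_spec(value):
    return value if isinstance(value, str) else float(value)


def run_pipeline(config: dict, workflow: str) -> dict:
    """Run one workflow; returns a manifest of written artifacts."""
    if workflow not in WORKFLOWS:
        raise DataError(f"unknown workflow {workflow!r}; choose from {WORKFLOWS}")
    out = _outdir(config)
    write_effective_config(config, out)
    handler = {
        "simulate": _run_simulate,
        "yeast_abscission": _run_yeast_abscission,
        "actin_index": _run_actin_index,
        "midbody": _run_midbody,
        "stats": _run_stats,
    }[workflow]
    artifacts = handler(config, out)
    manifest = {
        "workflow": workflow,
        "package_version": __version__,
        "config_hash": config_hash(config),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _scene_params(config: dict) -> SceneParams:
    sim = config["simulate"]
    overrides = dict(sim.get("params") or {})
    overrides.setdefault("seed", config["seed"])
    if sim.get("preset") == "yeast":
        return SceneParams.yeast(**overrides)
    return params_from_dict(overrides)


def _run_simulate(config: dict, out: Path) -> dict:
    params = _scene_params(config)
    movie, truth = generate_division_movie(params)
    movie_path = out / "movie.ome.tif"
    write_movie(movie_path, movie)
    truth_path = out / "ground_truth.json"
    truth_path.write_text(truth.to_json())
    events_path = out / "event_times.csv"
    _stamp(truth.event_table(), config).to_csv(events_path, index=False)
    logger.info("simulated movie %s (%d frames, seed %d)", movie_path, params.n_frames, params.seed)
    return {"movie": movie_path, "ground_truth": truth_path, "events": events_path}


def _load_movie(config: dict) -> Movie:
    if config["input"] is None:
        raise DataError("config key 'input' is required for this workflow")
    return read_movie(
        config["input"],
        role_map=config["channels"],
        pixel_size_um=config["pixel_size_um"],
        frame_interval_min=config["frame_interval_min"],
    )


def _segment_histone(movie: Movie, config: dict):
    seg = config["segmentation"]
    nuclei_sets = []
    for f in range(movie.n_frames):
        frame = movie.frame(f, "histone")
        mask = threshold_positive(frame, _threshold_spec(seg["nucleus_threshold"]))
        nuclei_sets.append(label_nuclei(mask, min_area_px=seg["min_area_px"], frame_index=f))
    return nuclei_sets


def _anaphase_time(movie: Movie, nuclei_sets, config: dict) -> float:
    seg = config["segmentation"]
    masks = [ns.label_image > 0 for ns in nuclei_sets]
    trace = major_axis_trace(masks)
    onset = detect_anaphase_onset(
        trace,
        baseline_frames=seg["baseline_frames"],
        elongation_factor=seg["elongation_factor"],
        persistence_frames=seg["persistence_frames"],
    )
    if onset is None:
        raise DataError("no anaphase onset detected in the chromatin channel")
    return movie.time_min(onset)


def _run_actin_index(config: dict, out: Path) -> dict:
    movie = _load_movie(config)
    nuclei_sets = _segment_histone(movie, config)
    t_anaphase = _anaphase_time(movie, nuclei_sets, config)
    act = config["actin"]
    trace = actin_trace(
        movie,
        nuclei_sets,
        t_anaphase,
        threshold=_threshold_spec(act["threshold"]),
        top_fraction=act["top_fraction"],
        min_positive_px=act["min_positive_px"],
        epsilon=act["epsilon"],
        weighted_com=act["com_weighting"] == "intensity",
    )
    clearance = score_clearance(
        trace, tau_rel=act["tau_rel"], k_frames=act["k_frames"], tau_abs=act["tau_abs"]
    )
    dropped = sorted(
        set(range(movie.n_frames)) - {s.frame_index for s in trace.scores}
    )
    for f in dropped:
        logger.info("actin_index: frame %d dropped (not exactly two interior nuclei)", f)
    trace_df = _stamp(pd.DataFrame([s.as_dict() for s in trace.scores]), config)
    trace_path = out / "actin_trace.csv"
    trace_df.to_csv(trace_path, index=False)
    summary = _stamp(
        pd.DataFrame(
            [
                {
                    "cell_id": trace.cell_id,
                    "t_anaphase_min": t_anaphase,
                    "clearance_time_min": clearance,
                    "censored": clearance is None,
                    "n_frames_scored": len(trace.scores),
                    "n_frames_dropped": len(dropped),
                }
            ]
        ),
        config,
    )
    summary_path = out / "clearance_summary.csv"
    summary.to_csv(summary_path, index=False)
    return {"trace": trace_path, "summary": summary_path}


def _default_axis(movie: Movie):
    h, w = movie.frame_shape
    cy = (h - 1) / 2.0
    return ((cy, 2.0), (cy, w - 3.0))


def _run_yeast_abscission(config: dict, out: Path) -> dict:
    movie = _load_movie(config)
    prof_cfg = config["profile"]
    if config["annotations"]:
        ann = pd.read_csv(config["annotations"])
        row = ann.iloc[0]
        endpoints = ((row["y0"], row["x0"]), (row["y1"], row["x1"]))
    else:
        endpoints = _default_axis(movie)
        logger.info("yeast_abscission: no axis annotation, using horizontal mid-line axis")
    profiles = [
        extract_neck_profile(
            movie.frame(f, "membrane"),
            endpoints,
            pixel_size_um=movie.pixel_size_um,
            half_width_px=prof_cfg["half_width_px"],
            frame_index=f,
            z_aggregate=prof_cfg["z_aggregate"],
        )
        for f in range(movie.n_frames)
    ]
    calls = [
        classify_profile(
            p,
            prominence_rel=prof_cfg["prominence_rel"],
            min_separation_um=prof_cfg["min_separation_um"],
        )
        for p in profiles
    ]
    ingression_frame = detect_ingression(
        profiles,
        ingression_fraction=prof_cfg["ingression_fraction"],
        persistence_frames=prof_cfg["persistence_frames"],
    )
    if ingression_frame is None:
        raise DataError("no membrane ingression detected")
    t_ingression = movie.time_min(ingression_frame)
    t_abscission = time_to_abscission(
        calls,
        t_ingression,
        movie.frame_interval_min,
        persistence_frames=prof_cfg["persistence_frames"],
    )
    call_df = _stamp(
        pd.DataFrame(
            [
                {
                    "frame_index": c.frame_index,
                    "n_peaks": c.n_peaks,
                    "classification": c.classification.value,
                    "peak_separation_um": c.peak_separation_um,
                }
                for c in calls
            ]
        ),
        config,
    )
    calls_path = out / "peak_calls.csv"
    call_df.to_csv(calls_path, index=False)
    summary = _stamp(
        pd.DataFrame(
            [
                {
                    "cell_id": "cell",
                    "ingression_frame": ingression_frame,
                    "t_ingression_min": t_ingression,
                    "time_to_abscission_min": t_abscission,
                    "censored": t_abscission is None,
                }
            ]
        ),
        config,
    )
    summary_path = out / "abscission_summary.csv"
    summary.to_csv(summary_path, index=False)
    return {"calls": calls_path, "summary": summary_path}


def _run_midbody(config: dict, out: Path) -> dict:
    import tifffile

    from .midbody import fit_midbody_ellipse, measure_total_intensity, project_five, select_best_focus

    if config["input"] is None or config["annotations"] is None:
        raise DataError("midbody workflow needs 'input' (stack TIFF) and 'annotations' (ROI CSV)")
    stacks = tifffile.imread(config["input"])
    if stacks.ndim == 3:  # single-channel stack doubles as the measured channel
        tubulin, channel = stacks, stacks
    elif stacks.ndim == 4:  # (C, Z, H, W): tubulin first, channel of interest second
        tubulin, channel = stacks[0], stacks[1]
    else:
        raise DataError(f"unsupported stack shape {stacks.shape}")
    rois = pd.read_csv(config["annotations"])
    rows = []
    mb = config["midbody"]
    for _, roi in rois.iterrows():
        seed = (int(roi["y0"]), int(roi["y1"]), int(roi["x0"]), int(roi["x1"]))
        z_best = select_best_focus(tubulin, seed, criterion=mb["focus_criterion"])
        proj_tub = project_five(tubulin, z_best)
        proj_ch = project_five(channel, z_best)
        ellipse = fit_midbody_ellipse(proj_tub, seed)
        meas = measure_total_intensity(
            proj_ch,
            ellipse,
            pixel_size_um=config["pixel_size_um"],
            background=mb["background"],
            cell_id=str(roi.get("cell_id", "cell")),
            z_best=z_best,
        )
        rows.append(
            {
                "cell_id": meas.cell_id,
                "z_best": meas.z_best,
                "center_y": meas.ellipse.center[0],
                "center_x": meas.ellipse.center[1],
                "semi_major_px": meas.ellipse.semi_major_px,
                "semi_minor_px": meas.ellipse.semi_minor_px,
                "angle_rad": meas.ellipse.angle_rad,
                "area_px": meas.area_px,
                "area_um2": meas.area_um2,
                "mean_intensity": meas.mean_intensity,
                "total_intensity": meas.total_intensity,
            }
        )
    path = out / "midbody_measurements.csv"
    _stamp(pd.DataFrame(rows), config).to_csv(path, index=False)
    return {"measurements": path}


def _run_stats(config: dict, out: Path) -> dict:
    if config["input"] is None:
        raise DataError("stats workflow needs 'input' (event CSV)")
    records = pd.read_csv(config["input"])
    horizon = config["stats"]["horizon_min"]
    artifacts = {}
    summaries = []
    curves = []
    for label, group in records.groupby("condition", sort=False):
        times = group["t_abscission"].tolist() if "t_abscission" in group else []
        if times:
            curve = cumulative_fraction(times, horizon)
            curve["condition"] = label
            curves.append(curve)
            observed = [t for t in times if t == t]
            summaries.append(
                {
                    "condition": label,
                    "n": len(times),
                    "fraction_completed": fraction_completed_by(times, horizon),
                    "median_min": float(np.median(observed)) if observed else np.nan,
                    "box_q1": box_summary(observed).q1 if observed else np.nan,
                    "box_q3": box_summary(observed).q3 if observed else np.nan,
                }
            )
    if curves:
        curves_path = out / "cumulative_curves.csv"
        _stamp(pd.concat(curves, ignore_index=True), config).to_csv(curves_path, index=False)
        artifacts["curves"] = curves_path
    if summaries:
        summary_path = out / "timing_summary.csv"
        _stamp(pd.DataFrame(summaries), config).to_csv(summary_path, index=False)
        artifacts["summary"] = summary_path
    labels = list(records.groupby("condition", sort=False).groups)
    tests = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            xi = records.loc[records["condition"] == labels[i], "t_abscission"].dropna()
            yj = records.loc[records["condition"] == labels[j], "t_abscission"].dropna()
            if len(xi) and len(yj):
                res = mann_whitney(xi, yj)
                tests.append(
                    {"condition_a": labels[i], "condition_b": labels[j], **res}
                )
    if tests:
        tests_path = out / "pairwise_tests.csv"
        _stamp(pd.DataFrame(tests), config).to_csv(tests_path, index=False)
        artifacts["tests"] = tests_path
    if config["stats"]["plots"] and curves:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for label, sub in pd.concat(curves).groupby("condition", sort=False):
            ax.step(sub["t_min"], sub["fraction"], where="post", label=str(label))
        ax.set_xlabel("time from ingression (min)")
        ax.set_ylabel("fraction completed")
        ax.legend()
        fig.tight_layout()
        plot_path = out / "cumulative_curves.png"
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        artifacts["plot"] = plot_path
    return artifacts
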