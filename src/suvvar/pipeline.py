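"""End-to-end orchestration: simulate, measure, estimate, report.

``run_pipeline`` executes the three stages — frame generation (or loading
externally reconstructed frames), SUV metric extraction with fixed ROIs,
and CoV estimation/extrapolation — and writes the tidy CSV tables, the
test report and a reproducibility manifest into a run directory.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, load_config
from .framing import FrameSchedule
from .geometry import ImageVolume, rasterize_activity
from .metrics import SUVRecord, compute_all_metrics, measure_frame, records_to_frame
from .model import SUVVariationModel
from .roi import SphereROI, detect_spheres
from .simulate import frame_rng, simulate_frame

log = logging.getLogger("suvvar")

__all__ = ["simulate_records", "run_pipeline", "recovery_curve", "roi_table"]


def simulate_records(
    config: RunConfig | None = None,
    seed: int = 0,
    keep_frames: bool = False,
):
    """Simulate all subsets and measure them frame-by-frame.

    Frames are generated, measured and discarded one at a time unless
    ``keep_frames`` is set, so default-size runs stay within a modest
    memory footprint.

    Returns ``(records, schedules, context)`` where ``context`` carries the
    truth image, ROIs and (optionally) the simulated frames.
    """
    config = config or RunConfig()
    rng_seed = int(seed if seed is not None else config.seed)
    geom = config.build_geometry()
    grid = config.build_grid()
    noise = config.build_noise()
    schedules = config.build_schedules()

    t0 = time.perf_counter()
    truth = rasterize_activity(geom, grid, supersample=config.supersample)
    if config.detection == "auto":
        rois = detect_spheres(truth, expected_diameters_mm=geom.sphere_diameters_mm)
    else:
        rois = detect_spheres(truth, geom_hint=geom)
    log.info("rasterized truth and detected %d ROIs in %.2f s", len(rois), time.perf_counter() - t0)

    records: list[SUVRecord] = []
    kept: dict[float, list[ImageVolume]] = {}
    for s_idx, sched in enumerate(schedules):
        for f_idx, (start, stop) in enumerate(sched.intervals):
            frame = simulate_frame(truth, start, stop - start, noise, frame_rng(rng_seed, s_idx, f_idx))
            records.extend(measure_frame(frame, rois, rl_s=sched.rl_s, frame_index=f_idx))
            if keep_frames:
                kept.setdefault(sched.rl_s, []).append(frame)
        log.info("simulated and measured %d frames at RL=%g s", sched.n_frames, sched.rl_s)

    context = {"truth": truth, "rois": rois, "geometry": geom, "grid": grid, "noise": noise}
    if keep_frames:
        context["frames"] = kept
    return records_to_frame(records), schedules, context


def roi_table(rois: list[SphereROI]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sphere_id": [r.sphere_id for r in rois],
            "nominal_diameter_mm": [r.nominal_diameter_mm for r in rois],
            "center_x_mm": [r.center_mm[0] for r in rois],
            "center_y_mm": [r.center_mm[1] for r in rois],
            "center_z_mm": [r.center_mm[2] for r in rois],
            "central_plane_index": [r.central_plane_index for r in rois],
        }
    )


def recovery_curve(
    records: pd.DataFrame,
    geom=None,
    rls_s: list[float] | None = None,
) -> pd.DataFrame:
    """Mean metric value ± SD versus sphere diameter, per reconstruction length.

    With a geometry, a ``recovery`` column (mean / true sphere
    concentration) is added.  A single frame per RL yields SD = 0 with a
    warning in the log.
    """
    if rls_s is not None:
        missing = set(rls_s) - set(records["rl_s"].unique())
        if missing:
            raise ValueError(f"no records for reconstruction lengths {sorted(missing)}")
        records = records[records["rl_s"].isin(rls_s)]
    rows = []
    for (metric, rl, sphere), grp in records.groupby(["metric", "rl_s", "sphere_id"], sort=True):
        vals = grp["value_kbq_ml"].to_numpy()
        if vals.size == 1:
            log.warning("single frame for metric %s RL=%g sphere %s; SD reported as 0", metric, rl, sphere)
        rows.append(
            {
                "metric": metric,
                "rl_s": rl,
                "sphere_id": sphere,
                "n_frames": vals.size,
                "mean_value": float(vals.mean()),
                "sd_value": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            }
        )
    out = pd.DataFrame(rows)
    if geom is not None:
        out["recovery"] = out["mean_value"] / geom.sphere_activity_kbq_ml
    return out


def run_pipeline(
    config: RunConfig | str | Path | None = None,
    out_dir: str | Path = "suvvar_run",
    seed: int | None = None,
    frames_dir: str | Path | None = None,
) -> Path:
    """Run all stages and write artifacts; returns the run directory.

    If ``frames_dir`` points at externally reconstructed NIfTI frames they
    are analysed instead of simulating; otherwise the phantom simulator
    supplies the frames.  Identical config and seed produce identical
    outputs.
    """
    if not isinstance(config, RunConfig):
        config = load_config(config)
    seed = config.seed if seed is None else int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if frames_dir is not None or config.io.get("frames_dir"):
            from .io import read_frames

            src = Path(frames_dir or config.io["frames_dir"])
            frames = read_frames(src)
            geom = config.build_geometry()
            # place ROIs from the configured phantom truth on the frames' own
            # grid, so simulator and external-frame paths share one ROI set
            reference = next(iter(frames.values()))[0]
            truth = rasterize_activity(geom, reference.grid, supersample=config.supersample)
            rois = detect_spheres(truth, geom_hint=geom)
            records = compute_all_metrics(frames, rois)
            schedules = config.build_schedules()
            context = {"rois": rois, "geometry": geom}
        else:
            keep = bool(config.io.get("write_frames", False))
            records, schedules, context = simulate_records(config, seed=seed, keep_frames=keep)
            if keep:
                from .io import write_frames

                write_frames(context["frames"], out / "frames")
        stage = "estimate"
        model = SUVVariationModel(
            records, schedules=schedules, target_rl_s=config.target_rl_s, alpha=config.alpha
        )
        results = model.fit()

        stage = "report"
        roi_table(context["rois"]).to_csv(out / "roi_table.csv", index=False)
        records.to_csv(out / "metrics.csv", index=False)
        results.cov_table.to_csv(out / "cov_table.csv", index=False)
        results.estimates.to_csv(out / "estimates.csv", index=False)
        results.cross_estimates().to_csv(out / "cross_estimates.csv", index=False)
        recovery_curve(records, geom=context["geometry"]).to_csv(
            out / "recovery_curve.csv", index=False
        )
        results.estimate_pivot().to_csv(out / "summary_table.csv")
        comparisons = results.comparisons()
        comparisons.to_csv(out / "comparisons.csv", index=False)
        normality = results.normality_report()
        report = {
            "n_welch_significant": int(comparisons["significant"].sum()),
            "n_welch_tests": int(len(comparisons)),
            "n_normality_rejections": int(normality["reject_normality"].sum()),
            "n_normality_tests": int(len(normality)),
        }
        (out / "test_report.json").write_text(json.dumps(report, indent=1))
        (out / "summary.txt").write_text(results.summary() + "\n")

        if config.io.get("write_plots", False):
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            for metric in results.cov_table["metric"].unique():
                ax = results.plot_cov_vs_rl(metric)
                ax.figure.savefig(out / f"cov_vs_rl_{metric}.png", dpi=100)
                plt.close(ax.figure)

        manifest = {
            "package_version": __version__,
            "seed": seed,
            "config": config.to_dict(),
            "n_records": int(len(records)),
            "schedules": [
                {"rl_s": s.rl_s, "n_frames": s.n_frames, "total_s": s.total_s} for s in schedules
            ],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during stage '{stage}': {exc}") from exc
    return out
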