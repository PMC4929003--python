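"""Analysis stages behind the CLI: each takes a RunConfig and an output
directory and writes its artifacts (CSV/TIFF/JSON) to disk."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import counting, events, io, mrna, pcpalm, photophysics, transcription


def _photo(params: dict) -> photophysics.PhotophysicsParams:
    return photophysics.PhotophysicsParams(**params.get("photophysics", {}))


def stage_simulate(cfg: io.RunConfig, out: Path) -> dict:
    """Simulate a cluster scenario; write the per-frame trace CSV."""
    p = _photo(cfg.params)
    scen = photophysics.ClusterScenario(**cfg.params.get("scenario", {}))
    trace = photophysics.simulate_cluster_trace(scen, p, seed=cfg.seed)
    df = pd.DataFrame({"frame": np.arange(trace.n_frames), "count": trace.counts})
    path = out / "trace.csv"
    df.to_csv(path, index=False)
    return {"trace": str(path)}


def stage_fixtures(cfg: io.RunConfig, out: Path) -> dict:
    """Spatial localization field plus an mRNA locus stack for testing."""
    p = _photo(cfg.params)
    fld = cfg.params.get("field", {})
    clusters = [photophysics.SpatialCluster(**c) for c in fld.get("clusters", [])]
    series = photophysics.sample_spatial_field(
        clusters,
        background_density=fld.get("background_density", 1e-6),
        sigma_loc=fld.get("sigma_loc", 30.0),
        n_frames=fld.get("n_frames", 5000),
        extent=tuple(fld.get("extent", (5000.0, 5000.0))),
        frame_time=p.frame_time,
        seed=cfg.seed,
    )
    loc_path = out / "localizations.csv"
    io.write_localizations(series, loc_path)
    st = cfg.params.get("stack", {})
    stack = photophysics.render_locus_stack(
        loci=[tuple(l) for l in st.get("loci", [(32.0, 32.0, 5)])],
        unit_brightness=st.get("unit_brightness", 2000.0),
        psf_sigma_px=st.get("psf_sigma_px", 1.2),
        background_level=st.get("background_level", 100.0),
        shape=tuple(st.get("shape", (64, 64))),
        n_frames=st.get("n_frames", 100),
        seed=cfg.seed + 1,
    )
    tif_path = out / "stack.tif"
    io.write_image_stack(stack, tif_path)
    return {"localizations": str(loc_path), "stack": str(tif_path)}


def stage_tcpalm(cfg: io.RunConfig, out: Path) -> dict:
    """ROI cumulants and detected cluster events from a localization table."""
    p = _photo(cfg.params)
    series = io.read_localizations(cfg.inputs["localizations"], p.frame_time)
    n_frames = int(cfg.params.get("n_frames") or series["frame"].max() + 1)
    rois = cfg.params.get("rois", [])
    econf = events.EventConfig(**cfg.params.get("events", {}))
    rows = []
    for i, roi in enumerate(rois):
        sub = events.extract_roi(series, tuple(roi["center"]), roi["half_width"])
        trace = events.build_cumulant(sub, p.frame_time, n_frames)
        for ev in events.detect_events(trace, econf):
            events.classify_onset(ev, econf.start_tolerance)
            rows.append(
                {
                    "roi_id": roi.get("id", i),
                    "t_onset_s": ev.t_onset,
                    "t_plateau_s": ev.t_plateau,
                    "lifetime_s": ev.lifetime,
                    "burst_size": ev.burst_size,
                    "strength_per_s": ev.strength,
                    "stability": ev.stability,
                }
            )
    path = out / "events.csv"
    pd.DataFrame(
        rows,
        columns=[
            "roi_id",
            "t_onset_s",
            "t_plateau_s",
            "lifetime_s",
            "burst_size",
            "strength_per_s",
            "stability",
        ],
    ).to_csv(path, index=False)
    return {"events": str(path)}


def stage_count(cfg: io.RunConfig, out: Path) -> dict:
    """Simulation-matching molecule counts for detection profiles."""
    p = _photo(cfg.params)
    table = io.read_profile_table(cfg.inputs["profiles"], p.frame_time)
    if table.kind != "traces":
        raise ValueError("counting requires per-frame detection profiles")
    threshold = cfg.params.get("large_threshold", 200)
    labels = counting.classify_cumulants(table.traces, threshold)
    rows = []
    for trace, label in zip(table.traces, labels):
        est = counting.estimate_count(
            trace,
            p,
            n_replicates=cfg.params.get("n_replicates", 100),
            seed=cfg.seed,
        )
        rows.append(
            {
                "cluster_id": trace.label,
                "total_detections": trace.total,
                "class": label,
                "N_hat": est.n_hat,
                "deviation_min": est.deviation_min,
            }
        )
    path = out / "counts.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return {"counts": str(path)}


def stage_pcpalm(cfg: io.RunConfig, out: Path) -> dict:
    """Pair-correlation curve and blinking/protein decomposition."""
    series = io.read_localizations(cfg.inputs["localizations"])
    pts = series[["x_nm", "y_nm"]].to_numpy()
    window = tuple(cfg.params.get("window", (np.ptp(pts[:, 0]), np.ptp(pts[:, 1]))))
    pc = pcpalm.radial_pair_correlation(pts, window)
    pc = pcpalm.fit_correlation_components(
        pc,
        sigma_loc=cfg.params.get("sigma_loc", 30.0),
        protein_model=cfg.params.get("protein_model", "exponential"),
    )
    curve_path = out / "pair_correlation.csv"
    pd.DataFrame(
        {
            "r_nm": pc.r,
            "g_emp": pc.g,
            "g_fit": pc.g_fit,
            "g_stoch": 1.0 + pc.g_stoch,
            "g_prot": 1.0 + pc.g_protein,
        }
    ).to_csv(curve_path, index=False)
    fit_path = out / "pair_correlation_fit.json"
    io.save_report(
        {
            "stoch_amplitude": pc.stoch_amplitude,
            "protein_amplitude": pc.protein_amplitude,
            "correlation_length_nm": pc.correlation_length,
            "protein_model": pc.protein_model,
            "residual": pc.residual,
            "converged": pc.converged,
        },
        fit_path,
    )
    return {"curve": str(curve_path), "fit": str(fit_path)}


def stage_model(cfg: io.RunConfig, out: Path) -> dict:
    """Simulate (and optionally fit) the cluster-gated transcription model."""
    profile = transcription.LifetimeProfile(**cfg.params.get("profile", {}))
    geometry = transcription.GeneGeometry(**cfg.params.get("geometry", {}))
    kinetics = transcription.KineticParams(**cfg.params.get("kinetics", {}))
    n_runs = cfg.params.get("n_runs", 500)
    horizon = cfg.params.get("horizon_min", 60.0)
    report: dict = {}
    if "observed_course" in cfg.inputs:
        obs_df = pd.read_csv(cfg.inputs["observed_course"])
        if not {"t_min", "mean_mrna"} <= set(obs_df.columns):
            raise ValueError("observed course needs columns t_min, mean_mrna")
        obs = transcription.NascentCourse(
            t_min=obs_df["t_min"].to_numpy(), mean=obs_df["mean_mrna"].to_numpy()
        )
        kinetics, course, fit_report = transcription.fit_kinetics(
            obs,
            profile,
            geometry,
            kinetics,
            free=tuple(cfg.params.get("free", ("v",))),
            n_runs=n_runs,
            seed=cfg.seed,
            horizon_min=horizon,
        )
        report.update(fit_report)
    else:
        if "free" in cfg.params:
            raise ValueError(
                "model stage: fitting requested (params.free) but no "
                "observed course was provided"
            )
        course = transcription.simulate_nascent_course(
            profile, geometry, kinetics, horizon_min=horizon, n_runs=n_runs, seed=cfg.seed
        )
    inp = transcription.NascentCourse(
        t_min=course.t_min, mean=transcription.lifetime_input(course.t_min, profile)
    )
    report["peak_lag_min"] = transcription.peak_lag(inp, course)
    course_path = out / "nascent_course.csv"
    pd.DataFrame(
        {"t_min": course.t_min, "mean_mrna": course.mean, "sem": course.sem}
    ).to_csv(course_path, index=False)
    report_path = out / "model_report.json"
    io.save_report(report, report_path)
    return {"course": str(course_path), "report": str(report_path)}


def stage_quant(cfg: io.RunConfig, out: Path) -> dict:
    """Count nascent mRNA at listed loci in an image stack."""
    stack = io.read_image_stack(cfg.inputs["stack"])
    loci_df = pd.read_csv(cfg.inputs["loci"])
    if not {"x_px", "y_px"} <= set(loci_df.columns):
        raise ValueError("locus list needs columns x_px, y_px")
    proj = mrna.max_projection(stack)
    loci = list(zip(loci_df["x_px"], loci_df["y_px"]))
    bg = cfg.params.get("background")
    if bg is None:
        bg = mrna.estimate_background(proj, loci)
    unit = cfg.params.get("unit_intensity")
    if unit is None:
        raise ValueError("quant stage requires params.unit_intensity")
    rows = []
    for i, (x, y) in enumerate(loci):
        m = mrna.measure_locus(proj, (x, y), bg)
        rows.append(
            {
                "locus_id": loci_df.get("locus_id", pd.Series(range(len(loci))))[i],
                "net_intensity": m.net_intensity,
                "unit": unit,
                "count": mrna.count_nascent(m.net_intensity, unit),
            }
        )
    path = out / "mrna_counts.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return {"counts": str(path)}


STAGES = {
    "simulate": stage_simulate,
    "fixtures": stage_fixtures,
    "tcpalm": stage_tcpalm,
    "count": stage_count,
    "pcpalm": stage_pcpalm,
    "model": stage_model,
    "quant": stage_quant,
}
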