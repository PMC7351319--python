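"""File-based pipeline stages: simulate -> process -> coregister ->
discriminate -> visualize.

Each stage reads and writes only documented files under the run directory,
so stages are independently runnable and re-entrant.  All randomness is
derived from the config seed; a fixed seed yields byte-identical tabular
outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import simulate as sim
from .config import RunConfig
from .coregistration import (
    AnnotationMap,
    apply_filters,
    assign_labels,
    exclude_heterogeneous,
    FLIM_PARAMETERS,
)
from .decay import LaguerreDeconvolver, RawRecord, process_scan
from .heatmap import interpolate, overlay
from .instrument import InstrumentModel, generate_irf
from .localization import BeamConfig, segment_aiming_beam, track_scan
from .metrics import (
    DiscriminationReport,
    cohort_summary,
    context_effect_sizes,
    lda_scores,
    patient_report,
)

log = logging.getLogger("flimpipe")

FLOAT_FMT = "%.9g"


def instrument_from_config(cfg: RunConfig) -> InstrumentModel:
    ic = cfg.instrument
    return InstrumentModel(
        sampling_interval=ic.sampling_interval,
        samples_per_channel=ic.samples_per_channel,
        baseline_samples=ic.baseline_samples,
        irf_fwhm=ic.irf_fwhm,
        irf_center=ic.irf_center,
        background_level=ic.background_level,
        frame_size=tuple(ic.frame_size),
    )


def _scan_dir(run_dir: Path, patient_id: int, context: str) -> Path:
    return Path(run_dir) / "patients" / f"p{patient_id:02d}" / context


def _iter_scan_dirs(run_dir: Path):
    base = Path(run_dir) / "patients"
    for pdir in sorted(base.glob("p*")):
        for sdir in sorted(pdir.iterdir()):
            if sdir.is_dir():
                yield int(pdir.name[1:]), sdir.name, sdir


def _require(path: Path, stage: str, hint: str):
    if not path.exists():
        raise FileNotFoundError(f"{stage}: missing {path}; run `{hint}` first")


# ---------------------------------------------------------------------------


def simulate_stage(cfg: RunConfig, run_dir) -> list:
    """Generate the cohort and write waveforms, frames, annotations and
    ground truth under the run directory."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    model = instrument_from_config(cfg)
    cc = cfg.cohort
    class_models = (
        sim.complementary_class_models()
        if cc.complementary
        else sim.default_class_models(cc.contrast)
    )
    patients = sim.generate_cohort(
        cc.n_patients,
        model=model,
        seed=cfg.seed,
        class_models=class_models,
        n_points=cc.n_points,
        snr_mean=cc.snr_mean,
        snr_sd=cc.snr_sd,
        contexts=tuple(cc.contexts),
        spot_radius=cc.spot_radius,
    )
    manifest = {"stages": ["simulate"], "scans": []}
    for patient in patients:
        for context, scan in patient.scans.items():
            sdir = _scan_dir(run_dir, patient.patient_id, context)
            sdir.mkdir(parents=True, exist_ok=True)
            wf = pd.DataFrame(
                np.stack([r.samples for r in scan.records]),
                columns=[f"s{i:04d}" for i in range(model.record_length)],
            )
            wf.insert(0, "point_index", [r.point_index for r in scan.records])
            wf.insert(1, "flags", [";".join(r.flags) for r in scan.records])
            wf.to_csv(sdir / "waveforms.csv", index=False, float_format=FLOAT_FMT)
            scan.ground_truth.to_csv(
                sdir / "ground_truth.csv", index=False, float_format=FLOAT_FMT
            )
            Image.fromarray(scan.annotation, mode="L").save(sdir / "annotation.png")
            Image.fromarray(scan.background).save(sdir / "background.png")
            fdir = sdir / "frames"
            fdir.mkdir(exist_ok=True)
            for idx, frame in scan.frames():
                Image.fromarray(frame).save(fdir / f"frame_{idx:04d}.png")
            manifest["scans"].append(f"p{patient.patient_id:02d}/{context}")
            log.info("simulated p%02d/%s: %d points", patient.patient_id, context, len(scan.records))
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return patients


def process_stage(cfg: RunConfig, run_dir) -> None:
    """Deconvolve every waveform table into a measurement table."""
    run_dir = Path(run_dir)
    model = instrument_from_config(cfg)
    irf = generate_irf(model)
    deconvolver = LaguerreDeconvolver(
        irf,
        model.sampling_interval,
        order=cfg.laguerre.order,
        envelopes=tuple(cfg.laguerre.envelopes),
    )
    for pid, context, sdir in _iter_scan_dirs(run_dir):
        _require(sdir / "waveforms.csv", "process", "flim simulate")
        wf = pd.read_csv(sdir / "waveforms.csv")
        sample_cols = [c for c in wf.columns if c.startswith("s")]
        records = [
            RawRecord(
                samples=row[sample_cols].to_numpy(dtype=float),
                time_base=model.sampling_interval,
                point_index=int(row.point_index),
                flags=tuple(str(row.flags).split(";")) if isinstance(row.flags, str) and row.flags else (),
            )
            for _, row in wf.iterrows()
        ]
        df, dropped = process_scan(records, deconvolver, model)
        df.to_csv(sdir / "measurements.csv", index=False, float_format=FLOAT_FMT)
        (sdir / "process_log.json").write_text(
            json.dumps({"n_records": len(records), "dropped_points": dropped}, sort_keys=True)
        )
        log.info("processed p%02d/%s: %d measurements, %d dropped", pid, context, len(df), len(dropped))


def coregister_stage(cfg: RunConfig, run_dir) -> pd.DataFrame:
    """Localize the aiming beam, attach labels and run the filter chain."""
    run_dir = Path(run_dir)
    lc = cfg.localization
    beam_cfg = BeamConfig(
        hue_range=(lc.hue_min, lc.hue_max),
        saturation_min=lc.saturation_min,
        min_area=lc.min_area,
    )
    accounting_rows = []
    for pid, context, sdir in _iter_scan_dirs(run_dir):
        _require(sdir / "measurements.csv", "coregister", "flim process")
        meas = pd.read_csv(sdir / "measurements.csv")
        frame_paths = sorted((sdir / "frames").glob("frame_*.png"))
        detections = [
            segment_aiming_beam(np.asarray(Image.open(p).convert("RGB")), beam_cfg, i)
            for i, p in enumerate(frame_paths)
        ]
        positions = track_scan(detections, len(frame_paths))
        positions.to_csv(sdir / "positions.csv", index=False, float_format=FLOAT_FMT)
        meas = meas.drop(columns=["x", "y"]).merge(
            positions[["point_index", "x", "y"]], on="point_index", how="left"
        )
        amap = AnnotationMap.from_png(sdir / "annotation.png")
        labeled = assign_labels(meas, amap, radius=cfg.thresholds.radius_px)
        labeled = exclude_heterogeneous(labeled, amap, radius=cfg.thresholds.radius_px)
        labeled, accounting = apply_filters(
            labeled, snr_threshold=cfg.thresholds.snr_db, mad_k=cfg.thresholds.mad_k
        )
        labeled.to_csv(sdir / "labeled.csv", index=False, float_format=FLOAT_FMT)
        (sdir / "filter_log.json").write_text(json.dumps(accounting, sort_keys=True))
        accounting_rows.append({"patient_id": pid, "context": context, **accounting})
        log.info("coregistered p%02d/%s: %s", pid, context, accounting)
    acc = pd.DataFrame(accounting_rows)
    acc.to_csv(run_dir / "filter_accounting.csv", index=False)
    return acc


def discriminate_stage(cfg: RunConfig, run_dir) -> pd.DataFrame:
    """Per-scan discrimination reports, cohort summary and context effect
    sizes."""
    run_dir = Path(run_dir)
    reports = []
    by_context = {}
    for pid, context, sdir in _iter_scan_dirs(run_dir):
        _require(sdir / "labeled.csv", "discriminate", "flim coregister")
        labeled = pd.read_csv(sdir / "labeled.csv").fillna({"condition": "", "binary": ""})
        report = patient_report(labeled, patient_id=pid, context=context)
        (sdir / "report.json").write_text(report.to_json())
        reports.append(report)
        by_context.setdefault(context, []).append(labeled)
    summary = cohort_summary(reports)
    summary.to_csv(run_dir / "summary.csv", index=False, float_format=FLOAT_FMT)
    pooled = {c: pd.concat(dfs, ignore_index=True) for c, dfs in by_context.items()}
    es = context_effect_sizes(pooled)
    es.to_csv(run_dir / "effect_sizes.csv", index=False, float_format=FLOAT_FMT)
    rows = [r.to_dict() for r in reports]
    (run_dir / "reports.json").write_text(json.dumps(rows, sort_keys=True, indent=1))
    return summary


def visualize_stage(cfg: RunConfig, run_dir) -> list:
    """Render per-parameter and LDA heat-map overlays for the first scans."""
    run_dir = Path(run_dir)
    if not cfg.visualization.enabled:
        return []
    out_dir = run_dir / "heatmaps"
    out_dir.mkdir(exist_ok=True)
    written = []
    n_done = 0
    for pid, context, sdir in _iter_scan_dirs(run_dir):
        if n_done >= cfg.visualization.max_scans:
            break
        _require(sdir / "labeled.csv", "visualize", "flim coregister")
        labeled = pd.read_csv(sdir / "labeled.csv")
        ok = labeled[labeled["analysis_ok"] & np.isfinite(labeled["x"])]
        if ok.empty:
            continue
        frame = np.asarray(Image.open(sdir / "background.png").convert("RGB"))
        frame_size = (frame.shape[1], frame.shape[0])
        param_sets = {p: ok[p].to_numpy() for p in FLIM_PARAMETERS}
        report_path = sdir / "report.json"
        if report_path.exists():
            report = DiscriminationReport.from_json(report_path.read_text())
            if report.discriminable and report.lda_weights:
                X = ok[FLIM_PARAMETERS].to_numpy(dtype=float)
                param_sets["lda"] = lda_scores(X, np.asarray(report.lda_weights))
        snr = ok[["snr_ch1", "snr_ch2", "snr_ch3"]].mean(axis=1).to_numpy()
        for name, values in param_sets.items():
            hm = interpolate(
                zip(ok["x"], ok["y"], values, snr),
                frame_size,
                power=cfg.interpolation.power,
                radius=cfg.interpolation.radius,
                snr_weighting=cfg.interpolation.snr_weighting,
            )
            vmin, vmax = (0.0, 1.0) if name == "lda" else (None, None)
            img = overlay(
                frame, hm, colormap=cfg.visualization.colormap,
                alpha=cfg.visualization.alpha, vmin=vmin, vmax=vmax,
            )
            path = out_dir / f"p{pid:02d}_{context}_{name}.png"
            Image.fromarray(img).save(path)
            written.append(path)
        n_done += 1
    return written


def analyze_scan(
    scan,
    deconvolver: LaguerreDeconvolver,
    model: InstrumentModel,
    snr_threshold: float = 30.0,
    mad_k: float = 2.5,
    radius_px: float = 10.0,
):
    """In-memory chain for one simulated scan, using the simulator's true
    beam positions in place of frame segmentation (frame-based localization
    is exercised by the file pipeline and its own tests).

    Returns (labeled table, accounting dict).
    """
    df, _ = process_scan(scan.records, deconvolver, model)
    gt = scan.ground_truth[["point_index", "x", "y"]]
    df = df.drop(columns=["x", "y"]).merge(gt, on="point_index", how="left")
    amap = AnnotationMap(scan.annotation)
    labeled = assign_labels(df, amap, radius=radius_px)
    labeled = exclude_heterogeneous(labeled, amap, radius=radius_px)
    return apply_filters(labeled, snr_threshold=snr_threshold, mad_k=mad_k)


def analyze_cohort(patients, deconvolver, model, **kwargs) -> dict:
    """Run analyze_scan over a simulated cohort.

    Returns {(patient_id, context): labeled DataFrame}.
    """
    out = {}
    for patient in patients:
        for context, scan in patient.scans.items():
            labeled, _ = analyze_scan(scan, deconvolver, model, **kwargs)
            out[(patient.patient_id, context)] = labeled
    return out


def run_pipeline(cfg: RunConfig, run_dir=None):
    """Run every stage in order; returns the run directory."""
    run_dir = Path(run_dir or cfg.output_dir)
    simulate_stage(cfg, run_dir)
    process_stage(cfg, run_dir)
    coregister_stage(cfg, run_dir)
    discriminate_stage(cfg, run_dir)
    visualize_stage(cfg, run_dir)
    return run_dir
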