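"""Stage orchestration: the workflow behind the command-line interface.

The five stages mirror how a screening experiment actually runs:
simulate (or acquire) hourly frames per condition, extract per-cell
features with per-frame quality metrics, train the state classifier on
bootstrap-balanced labeled tables, classify new tables, and condense
kinetic experiments into tracks, rocket tables, and clustered
super-metrics.  Every stage writes its outputs plus the resolved
config + seed, and logs in/out counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import kinetics as kin
from . import synthetic
from .classify import LDAGMMClassifier, balance_bootstrap, macro_accuracy
from .config import PipelineConfig
from .features import FEATURE_NAMES, CalibrationParams, extract_table
from .image import PhaseImage, read_phase_tiff
from .quality import filter_by_bgsd, frame_quality, quality_table
from .segmentation import otsu_threshold, segment_frame

logger = logging.getLogger(__name__)

__all__ = ["cmd_simulate", "cmd_extract", "cmd_train", "cmd_classify", "cmd_kinetics"]


def _load_frames(frames_dir: Path, cfg: PipelineConfig) -> dict[str, list[PhaseImage]]:
    """Read ``{condition}/{well}_{t:03d}.tif`` trees into per-condition lists."""
    by_condition: dict[str, list[PhaseImage]] = {}
    for cond_dir in sorted(p for p in Path(frames_dir).iterdir() if p.is_dir()):
        frames = []
        for k, path in enumerate(sorted(cond_dir.glob("*.tif"))):
            frames.append(
                read_phase_tiff(
                    path,
                    cfg.calibration.pixel_size_um,
                    unit_scale=cfg.calibration.unit_scale,
                    t=float(k),
                    meta={"condition": cond_dir.name, "file": path.name},
                )
            )
        if frames:
            by_condition[cond_dir.name] = frames
    if not by_condition:
        raise FileNotFoundError(f"no condition/*.tif frames under {frames_dir}")
    return by_condition


def _segment(image: PhaseImage, cfg: PipelineConfig):
    if cfg.segmentation.threshold_mode == "fixed":
        if cfg.segmentation.fixed_threshold is None:
            raise ValueError("fixed threshold mode requires segmentation.fixed_threshold")
        thr = cfg.segmentation.fixed_threshold
    else:
        thr = otsu_threshold(image)
    return segment_frame(image, thr, min_size=cfg.segmentation.min_size_px)


def cmd_simulate(
    cfg: PipelineConfig,
    design: synthetic.ExperimentDesign,
    state_models: Mapping[str, synthetic.StateModel],
    drift: synthetic.DriftModel,
    outdir: str | Path,
) -> dict:
    """Simulate a time-lapse experiment and write frames + truth."""
    outdir = Path(outdir)
    results = synthetic.simulate_timelapse(design, state_models, drift)
    for cond, (frames, tracks) in results.items():
        synthetic.write_frames(frames, outdir / "frames", cond)
        synthetic.tracks_to_json(tracks, outdir / "truth" / f"{cond}.json")
        logger.info("simulate: %s -> %d frames, %d tracks", cond, len(frames), len(tracks))
    cfg.write_resolved(outdir)
    return results


def cmd_extract(cfg: PipelineConfig, frames_dir: str | Path, outdir: str | Path) -> pd.DataFrame:
    """Segment every frame, compute quality metrics and the feature table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calib = CalibrationParams(
        pixel_size_um=cfg.calibration.pixel_size_um,
        wavelength_um=cfg.calibration.wavelength_um,
        delta_n=cfg.calibration.delta_n,
    )
    tables, qual_rows = [], []
    for cond, frames in _load_frames(Path(frames_dir), cfg).items():
        objects = [_segment(fr, cfg) for fr in frames]
        qualities = [frame_quality(fr, ob) for fr, ob in zip(frames, objects)]
        qt = quality_table(qualities, [fr.t for fr in frames], cfg.quality.max_bgsd)
        qt.insert(0, "condition", cond)
        qual_rows.append(qt)
        table = extract_table(frames, objects, calib)
        retained = set(qt.loc[qt["retained"], "t"])
        table["frame_retained"] = table["t"].isin(retained)
        tables.append(table)
        logger.info(
            "extract: %s -> %d frames (%d retained), %d cells",
            cond, len(frames), len(retained), len(table),
        )
    features = pd.concat(tables, ignore_index=True)
    quality = pd.concat(qual_rows, ignore_index=True)
    features.to_csv(outdir / "features.csv", index=False)
    quality.to_csv(outdir / "quality.csv", index=False)
    cfg.write_resolved(outdir)
    return features


def cmd_train(
    cfg: PipelineConfig,
    table: pd.DataFrame,
    label_column: str,
    outdir: str | Path,
) -> LDAGMMClassifier:
    """Quality-filter, bootstrap-balance, and fit the LDA+GMM classifier."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "frame_retained" in table.columns:
        n_before = len(table)
        table = table[table["frame_retained"]]
        logger.info("train: BgSD filter kept %d/%d rows", len(table), n_before)
    if len(table) == 0:
        raise ValueError("no frames retained after BgSD filtering")
    boot, labels = balance_bootstrap(
        table, table[label_column], cfg.classifier.n_per_class,
        rng=np.random.default_rng(cfg.seed),
    )
    clf = LDAGMMClassifier(
        n_dims=cfg.classifier.n_dims,
        n_init=cfg.classifier.n_init,
        tol=cfg.classifier.tol,
        random_state=cfg.seed,
        feature_names=list(FEATURE_NAMES),
    ).fit(boot, labels)
    per_class, macro = macro_accuracy(labels, clf.predict(boot))
    clf.to_json(outdir / "classifier.json")
    (outdir / "training_report.json").write_text(
        json.dumps({"macro_accuracy": macro,
                    "per_class": {str(k): v for k, v in per_class.items()}}, indent=1)
    )
    logger.info("train: macro accuracy %.3f on the training bootstrap", macro)
    cfg.write_resolved(outdir)
    return clf


def cmd_classify(cfg: PipelineConfig, classifier, table: pd.DataFrame, outdir: str | Path) -> pd.DataFrame:
    """Apply a trained classifier to a feature table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proba = classifier.predict_proba(table)
    out = pd.DataFrame(
        proba, columns=[f"P({c})" for c in classifier.classes_]
    )
    for col in ("object_id", "t", "condition"):
        if col in table.columns:
            out.insert(0, col, table[col].to_numpy())
    out["predicted"] = classifier.classes_[np.argmax(proba, axis=1)]
    out.to_csv(outdir / "predictions.csv", index=False)
    cfg.write_resolved(outdir)
    return out


def cmd_kinetics(
    cfg: PipelineConfig,
    classifier,
    frames_dir: str | Path,
    outdir: str | Path,
    control_condition: str | None = None,
    st_class: str = "St",
    cdki_class: str = "CDKi",
) -> pd.DataFrame:
    """Track, classify per hour, smooth, and condense into super-metrics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calib = CalibrationParams(
        pixel_size_um=cfg.calibration.pixel_size_um,
        wavelength_um=cfg.calibration.wavelength_um,
        delta_n=cfg.calibration.delta_n,
    )
    summaries = []
    all_rockets = []
    hyper_threshold: float | None = None
    by_condition = _load_frames(Path(frames_dir), cfg)
    order = list(by_condition)
    if control_condition in by_condition:  # control first so its threshold applies
        order = [control_condition] + [c for c in order if c != control_condition]

    for cond in order:
        frames = by_condition[cond]
        objects = [_segment(fr, cfg) for fr in frames]
        qualities = [frame_quality(fr, ob) for fr, ob in zip(frames, objects)]
        kept, removed = filter_by_bgsd(qualities, cfg.quality.max_bgsd)
        logger.info("kinetics: %s %d/%d frames pass BgSD", cond, len(kept), len(frames))
        tracks = kin.link_tracks(
            objects, [fr.t for fr in frames], cfg.kinetics.max_step_um, condition=cond
        )
        kept_set = set(kept)
        for tr in tracks:
            feats = extract_table(
                [frames[int(t)] for t in tr.times],
                [[obj] for obj in tr.objects],
                calib,
            )
            missing = [i for i, t in enumerate(tr.times) if int(t) not in kept_set]
            kin.track_probabilities(classifier, tr, feats[list(FEATURE_NAMES)], missing)
            kin.smooth_track(tr, cfg.kinetics.sg_degree, cfg.kinetics.sg_window)
        if hyper_threshold is None:
            disp = np.concatenate(
                [tr.displacements_um[1:] for tr in tracks if len(tr.times) > 1]
            ) if any(len(tr.times) > 1 for tr in tracks) else np.array([0.0])
            hyper_threshold = cfg.kinetics.hypermotility_factor * float(np.median(disp))
        summaries.append(
            kin.condition_super_metrics(
                tracks, st_class=st_class, cdki_class=cdki_class,
                hypermotility_um=hyper_threshold,
            )
        )
        all_rockets.append(kin.rocket_export(tracks))

    rocket = pd.concat(all_rockets, ignore_index=True)
    rocket.to_csv(outdir / "rocket.csv", index=False)
    metrics = pd.DataFrame([s.as_series() for s in summaries])
    metrics.to_csv(outdir / "super_metrics.csv")
    normalized = kin.normalize_super_metrics(summaries)
    normalized.to_csv(outdir / "super_metrics_normalized.csv")
    if len(normalized) >= 2:
        Z = kin.cluster_conditions(normalized)
        (outdir / "conditions.nwk").write_text(
            kin.linkage_to_newick(Z, list(normalized.index))
        )
    cfg.write_resolved(outdir)
    return normalized
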