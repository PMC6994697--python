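"""End-to-end orchestration: track -> features -> detect -> classify -> report.

A single JSON config drives the run; every acquisition and model constant
(3 min/frame, Gaussian target sigma 50, detection threshold 0.4, 200-frame
pre-death window, ±100-frame evaluation window, wavelength 0.65 um,
alpha 0.18 um^3/pg) is a named, defaulted field.  Each run writes a
manifest (config hash, seed, package versions) sufficient to reproduce it
bit-for-bit at fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .death_classification import (
    classify_deaths,
    summarize_population,
    train_type_classifier,
)
from .death_detection import (
    DeathDetector,
    load_detector,
    save_detector,
    series_from_table,
    survival_curve_and_it50,
)
from .features import DryMassParams, extract_all
from .io_formats import (
    read_annotations,
    read_image_sequence,
    write_annotations,
    write_feature_table,
    write_label_masks,
)
from .synthetic_scenes import SceneConfig, generate_scene
from .tracking import TrackingParams, filter_complete_tracklets, track_sequence

logger = logging.getLogger("qpi_deathwatch")

__all__ = ["PipelineStageError", "run_pipeline", "make_report"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_inputs(config: dict):
    """Either render the configured synthetic scene or read an image dir."""
    seed = int(config.get("seed", 0))
    if "scene" in config:
        scene_cfg = SceneConfig(**{**config["scene"], "seed": seed})
        plan = {int(k): tuple(v) for k, v in scene_cfg.death_plan.items()}
        scene_cfg.death_plan = plan
        seq, gt_masks, gt_centers, annotations = generate_scene(scene_cfg)
        seeds = [tuple(c) for c in gt_centers[0]]
        return seq, seeds, annotations
    seq = read_image_sequence(config["images_dir"], metadata=config.get("metadata"))
    seeds_df = pd.read_csv(config["seeds_csv"])
    seeds = list(zip(seeds_df["row"], seeds_df["col"]))
    annotations = (
        read_annotations(config["annotations_csv"])
        if "annotations_csv" in config
        else None
    )
    return seq, seeds, annotations


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the full pipeline from a config dict (or JSON path).

    Returns a dict of in-memory outputs; artifacts (masks, features.csv,
    predictions.csv, types.csv, survival.csv, manifest.json) are written
    under ``out_dir`` (or config["out"]) when given.
    """
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    out_dir = Path(out_dir or config.get("out", "pipeline_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    logging.basicConfig(level=config.get("log_level", "INFO"))

    try:
        seq, seeds, annotations = _load_inputs(config)
    except Exception as exc:
        raise PipelineStageError("input", exc) from exc

    # ---- tracking ----
    try:
        params = TrackingParams(**config.get("tracking", {}))
        logger.info("tracking %d seeds over %d frames", len(seeds), seq.n_frames)
        trackset, masks, info = track_sequence(seq, seeds, params)
        kept = filter_complete_tracklets(masks, trackset, info)
        logger.info("complete tracklets: %d / %d", len(kept), len(seeds))
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("tracking", exc) from exc

    # ---- feature extraction ----
    try:
        dm = DryMassParams(
            **{**{"pixel_size": seq.pixel_size}, **config.get("dry_mass", {})}
        )
        table = extract_all(seq, masks, dm, cell_ids=kept)
    except Exception as exc:
        raise PipelineStageError("features", exc) from exc

    # ---- death detection ----
    try:
        det_cfg = dict(config.get("detector", {}))
        model_dir = det_cfg.pop("model_dir", None)
        ids, X = series_from_table(table)
        if model_dir:
            detector = load_detector(model_dir)
        else:
            if annotations is None:
                raise ValueError("detector needs a trained model or annotations")
            ann_map = {a.cell_id: a.death_frame for a in annotations}
            y = [ann_map.get(cid) for cid in ids]
            detector = DeathDetector(random_state=seed, **det_cfg)
            detector.fit(X, y)
        pred_frames = detector.predict(X)
        responses = detector.predict_response(X)
        predictions = pd.DataFrame(
            {
                "cell_id": ids,
                "death_frame": pred_frames,
                "confidence": [float(r.max()) for r in responses],
            }
        )
        curve, it50 = survival_curve_and_it50(
            pred_frames, seq.n_frames, seq.frame_interval
        )
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("detection", exc) from exc

    # ---- death-type classification ----
    try:
        cls_cfg = dict(config.get("classifier", {}))
        source = cls_cfg.pop("death_frame_source", "predicted")
        window = cls_cfg.pop("window", 200)
        if annotations is None:
            raise ValueError("classifier training needs annotations")
        ann_map = {a.cell_id: a for a in annotations}
        train_frames = {
            a.cell_id: a.death_frame
            for a in annotations
            if a.death_frame is not None and a.cell_id in ids
        }
        train_summaries = summarize_population(table, train_frames, window=window)
        labels = [ann_map[c].death_type for c in train_summaries["cell_id"]]
        classifier = train_type_classifier(train_summaries, labels, **cls_cfg)
        if source == "manual":
            apply_frames = train_frames
        else:
            apply_frames = {
                cid: int(f)
                for cid, f in zip(ids, pred_frames)
                if not np.isnan(f) and f >= 1
            }
        apply_summaries = summarize_population(
            table, apply_frames, window=window, death_frame_source=source
        )
        if apply_summaries.empty:
            types = pd.DataFrame(columns=["cell_id", "type", "margin"])
        else:
            types = classify_deaths(classifier, apply_summaries)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("classification", exc) from exc

    # ---- artifacts ----
    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "n_seeds": len(seeds),
        "n_complete_tracklets": len(kept),
    }
    write_label_masks(masks, out_dir / "masks.tif")
    write_feature_table(
        table.drop(columns=[c for c in table.columns if c == "fov"]),
        out_dir / "features.csv",
    )
    predictions.to_csv(out_dir / "predictions.csv", index=False)
    types.to_csv(out_dir / "types.csv", index=False)
    pd.DataFrame({"frame": np.arange(seq.n_frames), "dead_fraction": curve}).to_csv(
        out_dir / "survival.csv", index=False
    )
    if annotations is not None:
        write_annotations(annotations, out_dir / "annotations.csv")
    save_detector(detector, out_dir / "detector_model")
    summary = {
        "it50_hours": it50,
        "n_tracked": len(kept),
        "n_dead": int(np.sum(~np.isnan(pred_frames))),
        "n_apoptotic": int((types["type"] == "apoptotic").sum()),
        "n_lytic": int((types["type"] == "lytic").sum()),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "sequence": seq,
        "masks": masks,
        "kept_ids": kept,
        "features": table,
        "detector": detector,
        "predictions": predictions,
        "survival_curve": curve,
        "it50_hours": it50,
        "classifier": classifier,
        "types": types,
        "summary": summary,
        "manifest": manifest,
    }


def make_report(outputs: dict, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Per-FOV summary table; optionally saves the two standard plots
    (aligned average signals; density-vs-CDS scatter) as PNG."""
    seq = outputs["sequence"]
    types = outputs["types"]
    predictions = outputs["predictions"]
    n_dead = int(predictions["death_frame"].notna().sum())
    row = {
        "fov": seq.fov_id,
        "n_tracked": len(outputs["kept_ids"]),
        "n_dead": n_dead,
        "n_apoptotic": int((types["type"] == "apoptotic").sum()),
        "n_lytic": int((types["type"] == "lytic").sum()),
        "it50_hours": outputs["it50_hours"],
    }
    report = pd.DataFrame([row])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        table = outputs["features"]
        # death-aligned average mass/density/CDS curves
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
        aligned = {"mass": [], "density": [], "cds": []}
        for _, p in predictions.dropna(subset=["death_frame"]).iterrows():
            grp = table[table["cell_id"] == p["cell_id"]].sort_values("frame")
            rel = grp["frame"].to_numpy() - p["death_frame"]
            for key in aligned:
                aligned[key].append((rel, grp[key].to_numpy()))
        grid = np.arange(-200, 101)
        for ax, key in zip(axes, aligned):
            stack = []
            for rel, vals in aligned[key]:
                stack.append(np.interp(grid, rel, vals, left=np.nan, right=np.nan))
            if stack:
                arr = np.asarray(stack)
                counts = np.sum(~np.isnan(arr), axis=0)
                mean = np.full(arr.shape[1], np.nan)
                has = counts > 0
                mean[has] = np.nansum(arr[:, has], axis=0) / counts[has]
                ax.plot(grid * seq.frame_interval / 60.0, mean)
            ax.set_xlabel("time from death (h)")
            ax.set_title(key)
        fig.tight_layout()
        fig.savefig(out_dir / "aligned_signals.png", dpi=120)
        plt.close(fig)

        # density vs CDS scatter of pre-death means
        fig, ax = plt.subplots(figsize=(4, 4))
        for label, color in (("apoptotic", "tab:red"), ("lytic", "tab:blue")):
            sel = types[types["type"] == label]
            if not sel.empty:
                sub = table[table["cell_id"].isin(sel["cell_id"])]
                means = sub.groupby("cell_id")[["density", "cds"]].mean()
                ax.scatter(means["density"], means["cds"], s=12, label=label, color=color)
        ax.set_xlabel("density (pg/px)")
        ax.set_ylabel("CDS")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "density_vs_cds.png", dpi=120)
        plt.close(fig)
        report.to_csv(out_dir / "report.csv", index=False)
    return report
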