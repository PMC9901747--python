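"""End-to-end orchestration: stacks in, reports out.

``run_pipeline`` walks an input directory of stacks (``video_*.tif``),
optionally with ground truths (``truth_video_*.tif``) and class labels
(``labels.json``), and writes per-stage artifacts plus CSV/JSON reports to
an output directory.  Stage failures are logged per video and do not abort
the batch.  Given identical configuration and seeds, two runs produce
byte-identical reports.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io as _io
from .classification import benchmark
from .evaluation import MatchReport, metric_sweep
from .features import FeatureImage, build_dataset, extract_traces, split_by_video, to_arrays
from .projection import project
from .segmentation import MLTParams, SegmentationResult, mean_filter, mlt_segment
from .types import LabelImage, RunConfig, VideoStack


def mlt_params(config: RunConfig) -> MLTParams:
    return MLTParams(
        junction=config.junction,
        stopping=config.stopping,
        elimination=config.elimination,
        filter_size=config.filter_size,
        connectivity=config.connectivity,
    )


def process_video(
    stack: VideoStack,
    config: RunConfig,
    truth: LabelImage | None = None,
):
    """Project, segment, optionally evaluate, and extract a feature image.

    The in-memory core of one pipeline iteration: returns ``(projection,
    segmentation, match_reports, feature_image)``; the match reports are
    empty without ground truth and the feature image is None when no ROI
    survives.
    """
    proj = project(stack, config.projection_method)
    seg = mlt_segment(mean_filter(proj.data, config.filter_size), mlt_params(config))
    reports: list[MatchReport] = []
    if truth is not None:
        reports = metric_sweep(seg.label_image, truth, config.iom_thresholds)
    fi = None
    if seg.n_rois > 0:
        traces = extract_traces(stack, seg.label_image)
        fi = FeatureImage(traces.values)
    return proj, seg, reports, fi


def _discover_videos(input_dir: Path) -> list[str]:
    return sorted(
        p.stem for p in input_dir.glob("video_*.tif") if not p.stem.startswith("truth")
    )


def _train_counts(config: RunConfig, labels: dict[str, int]) -> dict[int, int]:
    """Per-class training video counts; fall back to a 2/3 split when the
    configured counts do not fit the study at hand."""
    n_by_class: dict[int, int] = {}
    for lab in labels.values():
        n_by_class[lab] = n_by_class.get(lab, 0) + 1
    wanted = {1: config.train_disease, 0: config.train_control}
    counts = {}
    for label, n in sorted(n_by_class.items()):
        w = wanted.get(label)
        if w is None or not (0 < w < n):
            w = min(n - 1, max(1, round(n * 2 / 3)))
        counts[label] = w
    return counts


def run_pipeline(config: RunConfig, input_dir, output_dir) -> dict:
    """Run projection → segmentation → evaluation → features → classification.

    Returns the summary report (also written as ``report.json``).
    """
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    for sub in ("projections", "segmentations", "traces"):
        (output_dir / sub).mkdir(parents=True, exist_ok=True)

    video_ids = _discover_videos(input_dir)
    if not video_ids:
        raise FileNotFoundError(f"no video_*.tif stacks under {input_dir}")
    labels_path = input_dir / "labels.json"
    class_labels: dict[str, int] = (
        json.loads(labels_path.read_text()) if labels_path.exists() else {}
    )

    per_video: dict[str, dict] = {}
    metric_rows = []
    feature_images: list[FeatureImage] = []
    for vid in video_ids:
        entry: dict = {"status": "ok"}
        try:
            stack = _io.read_stack(input_dir / f"{vid}.tif")
            truth = None
            truth_path = input_dir / f"truth_{vid}.tif"
            if truth_path.exists():
                truth = _io.read_label_image(truth_path, expected_shape=stack.frame_shape)

            proj, seg, reports, fi = process_video(stack, config, truth)
            _io.write_projection(proj, output_dir / "projections" / f"{vid}.tif")
            _io.write_label_image(
                seg.label_image, output_dir / "segmentations" / f"{vid}.tif"
            )
            entry["n_rois"] = seg.n_rois

            for rep in reports:
                metric_rows.append(
                    {
                        "video_id": vid,
                        "iom_threshold": rep.iom_threshold,
                        "tp": rep.tp,
                        "fp": rep.fp,
                        "fn": rep.fn,
                        "precision": rep.precision,
                        "recall": rep.recall,
                        "fscore": rep.fscore,
                    }
                )

            if fi is not None:
                pd.DataFrame(
                    fi.values,
                    index=pd.Index(range(1, fi.values.shape[0] + 1), name="roi_id"),
                ).to_csv(output_dir / "traces" / f"{vid}.csv", float_format="%.6f")
                if vid in class_labels:
                    fi.class_label = int(class_labels[vid])
                    fi.video_id = vid
                    feature_images.append(fi)
            else:
                entry["status"] = "no ROIs detected"
        except Exception as exc:  # contain per-video failures
            entry = {"status": "error", "message": f"{type(exc).__name__}: {exc}"}
            entry["trace"] = traceback.format_exc(limit=3)
        per_video[vid] = entry

    report: dict = {
        "config": asdict(config),
        "n_videos": len(video_ids),
        "videos": per_video,
    }

    if metric_rows:
        metrics = pd.DataFrame(metric_rows)
        metrics.to_csv(output_dir / "metrics.csv", index=False, float_format="%.6f")
        mean_f = metrics.groupby("iom_threshold")["fscore"].mean()
        report["mean_fscore_by_iom"] = {f"{k:g}": round(v, 6) for k, v in mean_f.items()}

    if config.classify and len(feature_images) >= 2:
        present = {fi.class_label for fi in feature_images}
        if len(present) < 2:
            report["classification"] = {"status": "skipped: single-class study"}
        else:
            samples = build_dataset(
                feature_images,
                n_shuffles=config.n_shuffles,
                shuffle_seed=config.shuffle_seed,
                width=config.feature_width,
                height=config.feature_height,
                normalize=config.normalize_features,
            )
            counts = _train_counts(
                config, {fi.video_id: fi.class_label for fi in feature_images}
            )
            train, test = split_by_video(samples, counts, seed=config.split_seed)
            Xtr, ytr, _ = to_arrays(train)
            Xte, yte, _ = to_arrays(test)
            table, best = benchmark(
                config.classifier_names,
                {config.projection_method: (Xtr, ytr, Xte, yte)},
                cv_folds=config.cv_folds,
                seed=config.split_seed,
            )
            table.to_csv(output_dir / "accuracies.csv", index=False, float_format="%.4f")
            report["classification"] = {
                "n_samples": len(samples),
                "n_train": len(train),
                "n_test": len(test),
                "train_videos": counts,
                "best": best,
            }

    (output_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
    )
    return report
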