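"""End-to-end pre-screening pipeline and triage decision.

The two computational steps of the clinical workflow live here: run the
random-forest analysis over a case list, quantify each image's
equivalent-area percentage, and flag a case as *suspected* when that
percentage strictly exceeds the triage threshold (12% by default). The
output is a prioritized worklist — suspected cases first, each group sorted
by descending percentage, ties broken lexicographically by case id — so
the pathologist reviews the most worrying cases first. The tool's contract
is triage priority, never a malignancy call.

A pipeline can be trained once on annotated images and applied to new
cases, or trained on the case image itself (the study protocol); both are
supported — `fit` just takes whichever annotated images you have.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import image_io
from .classifier import PixelForestClassifier, ProbabilityMap
from .features import FilterConfig, build_feature_stack
from .image_io import CalibrationInfo
from .quantify import DEFAULT_RED_THRESHOLD, RedPixelQuantification, quantify_case

__all__ = [
    "TriageConfig",
    "CaseReport",
    "ScreeningPipeline",
    "EmptyBatchError",
    "AllCasesFailedError",
    "run_case",
    "prioritize",
    "run_batch",
]

logger = logging.getLogger("naevoscreen")

PIPELINE_FORMAT = "naevoscreen-pipeline"
PIPELINE_VERSION = 1

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff")

#: free-text follow-up recommended for suspected cases (a human/wet-lab step)
SUSPECTED_FOLLOWUP = (
    "recommend immunohistochemistry work-up (Melan-A, HMB-45, p16, PRAME)"
)


class EmptyBatchError(RuntimeError):
    """The input directory contains no readable case images."""


class AllCasesFailedError(RuntimeError):
    """Every case in the batch failed; the batch produced no reports."""


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds and calibration defaults for a screening run.

    ``triage_threshold`` is a percentage of image area (strictly-greater
    comparison: a case sitting exactly on the threshold is not suspected);
    ``microns_per_pixel`` overrides scale-bar detection when set.
    """

    triage_threshold: float = 12.0
    red_threshold: float = DEFAULT_RED_THRESHOLD
    scale_bar_microns: float = 500.0
    microns_per_pixel: float | None = None
    bar_color: tuple[int, int, int] = (0, 0, 0)
    bar_tolerance: float = 40.0
    min_bar_run: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.triage_threshold < 100:
            raise ValueError("triage_threshold must lie in (0, 100)")
        if not 0 < self.red_threshold < 1:
            raise ValueError("red_threshold must lie in (0, 1)")


@dataclass
class CaseReport:
    """Per-case result: calibration, quantification and the triage flag.

    ``timestamp`` is None unless wall-clock stamping is requested, so that
    identical inputs always produce identical reports.
    """

    case_id: str
    image_path: str
    calibration: CalibrationInfo
    quantification: RedPixelQuantification
    suspected: bool
    model_id: str
    recommended_followup: str = ""
    timestamp: str | None = None

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "image_path": self.image_path,
            "calibration": self.calibration.to_dict(),
            "quantification": self.quantification.to_dict(),
            "suspected": self.suspected,
            "model_id": self.model_id,
            "recommended_followup": self.recommended_followup,
            "timestamp": self.timestamp,
        }


class ScreeningPipeline(BaseEstimator):
    """Filter bank + pixel forest, trainable on annotated images.

    Parameters
    ----------
    filter_config : FilterConfig
        Filter-bank configuration shared by training and prediction.
    n_trees, max_features_per_split, min_samples_leaf, random_state
        Forest hyperparameters (see :class:`PixelForestClassifier`).
    max_pixels_per_class : int
        Cap on labeled pixels sampled per class per training image; dense
        annotation masks are subsampled to keep training tractable.
    """

    def __init__(
        self,
        filter_config: FilterConfig | None = None,
        n_trees: int = 200,
        max_features_per_split: str | int = "sqrt",
        min_samples_leaf: int = 1,
        random_state: int = 0,
        max_pixels_per_class: int = 2000,
    ) -> None:
        self.filter_config = filter_config
        self.n_trees = n_trees
        self.max_features_per_split = max_features_per_split
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state
        self.max_pixels_per_class = max_pixels_per_class

    def _filter_config(self) -> FilterConfig:
        return self.filter_config or FilterConfig()

    def fit(
        self, images: list[np.ndarray], masks: list[np.ndarray]
    ) -> "ScreeningPipeline":
        """Fit the forest on labeled pixels pooled across annotated images."""
        if len(images) != len(masks) or not images:
            raise ValueError("need equally many images and masks, at least one")
        config = self._filter_config()
        rng = np.random.default_rng(self.random_state)
        xs, ys = [], []
        channel_names = None
        for image, mask in zip(images, masks):
            stack = build_feature_stack(image, config)
            channel_names = stack.channel_names
            mask = np.asarray(mask)
            if mask.shape != (stack.height, stack.width):
                raise ValueError("mask dimensions do not match image")
            flat_mask = mask.ravel()
            matrix = stack.as_matrix()
            for label in (image_io.LABEL_REGULAR, image_io.LABEL_ANOMALOUS):
                idx = np.flatnonzero(flat_mask == label)
                if idx.size > self.max_pixels_per_class:
                    idx = np.sort(
                        rng.choice(idx, self.max_pixels_per_class, replace=False)
                    )
                xs.append(matrix[idx])
                ys.append(np.full(idx.size, label, dtype=np.int64))
        X = np.concatenate(xs, axis=0)
        y = np.concatenate(ys, axis=0)
        self.model_ = PixelForestClassifier(
            n_trees=self.n_trees,
            max_features_per_split=self.max_features_per_split,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
        ).fit_samples(X, y, channel_names)
        self.model_id_ = self._digest()
        return self

    def predict_map(self, image: np.ndarray) -> ProbabilityMap:
        """Probability map of a new image under the trained forest."""
        self._check_fitted()
        stack = build_feature_stack(image, self._filter_config())
        return self.model_.predict_proba_map(stack)

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("pipeline is not fitted")

    def _digest(self) -> str:
        payload = json.dumps(self._to_json_dict_inner(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def _to_json_dict_inner(self) -> dict:
        return {
            "filter_config": self._filter_config().to_dict(),
            "forest": self.model_.to_json_dict(),
            "max_pixels_per_class": self.max_pixels_per_class,
        }

    def save(self, path: str | Path) -> None:
        self._check_fitted()
        doc = {
            "format": PIPELINE_FORMAT,
            "version": PIPELINE_VERSION,
            **self._to_json_dict_inner(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "ScreeningPipeline":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != PIPELINE_FORMAT:
            raise ValueError(f"not a {PIPELINE_FORMAT} file")
        if doc.get("version") != PIPELINE_VERSION:
            raise ValueError(f"unsupported pipeline version {doc.get('version')!r}")
        model = PixelForestClassifier.from_json_dict(doc["forest"])
        pipe = cls(
            filter_config=FilterConfig.from_dict(doc["filter_config"]),
            n_trees=model.n_trees,
            max_features_per_split=model.max_features_per_split,
            min_samples_leaf=model.min_samples_leaf,
            random_state=model.random_state,
            max_pixels_per_class=doc.get("max_pixels_per_class", 2000),
        )
        pipe.model_ = model
        pipe.model_id_ = pipe._digest()
        return pipe


def _calibration_for(
    image: np.ndarray, config: TriageConfig
) -> CalibrationInfo:
    height, width = image.shape[:2]
    if config.microns_per_pixel is not None:
        return CalibrationInfo.from_microns_per_pixel(
            width, height, config.microns_per_pixel, config.scale_bar_microns
        )
    bar_px = image_io.detect_scale_bar(
        image,
        bar_color=config.bar_color,
        tolerance=config.bar_tolerance,
        min_run=config.min_bar_run,
    )
    return CalibrationInfo.from_scale_bar(
        width, height, bar_px, config.scale_bar_microns
    )


def run_case(
    image_path: str | Path,
    pipeline: ScreeningPipeline,
    config: TriageConfig | None = None,
    case_id: str | None = None,
    stamp_time: bool = False,
) -> CaseReport:
    """Screen one image: calibrate, classify, quantify, decide."""
    config = config or TriageConfig()
    path = Path(image_path)
    cid = case_id or path.stem
    t0 = time.perf_counter()
    image = image_io.load_image(path)
    calibration = _calibration_for(image, config)
    prob = pipeline.predict_map(image)
    quant = quantify_case(prob, calibration, config.red_threshold)
    suspected = quant.equivalent_area_pct > config.triage_threshold
    logger.info(
        "case=%s pct=%.3f suspected=%s elapsed=%.2fs",
        cid, quant.equivalent_area_pct, suspected, time.perf_counter() - t0,
    )
    return CaseReport(
        case_id=cid,
        image_path=str(path),
        calibration=calibration,
        quantification=quant,
        suspected=suspected,
        model_id=pipeline.model_id_,
        recommended_followup=SUSPECTED_FOLLOWUP if suspected else "",
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
        if stamp_time else None,
    )


def prioritize(reports: list[CaseReport]) -> list[CaseReport]:
    """Worklist order: suspected first, descending percentage, then case id."""
    if not reports:
        raise ValueError("cannot prioritize an empty report list")
    return sorted(
        reports,
        key=lambda r: (
            0 if r.suspected else 1,
            -r.quantification.equivalent_area_pct,
            r.case_id,
        ),
    )


def _discover_images(image_dir: Path) -> list[Path]:
    paths = [
        p for p in sorted(image_dir.iterdir())
        if p.suffix.lower() in IMAGE_EXTENSIONS
        and not p.stem.endswith("_truth")
        and not p.stem.endswith("_labels")
    ]
    return paths


def worklist_frame(ordered: list[CaseReport]) -> pd.DataFrame:
    rows = [
        {
            "case_id": r.case_id,
            "red_pixel_count": r.quantification.red_pixel_count,
            "equivalent_area_mm2": r.quantification.equivalent_area_mm2,
            "equivalent_area_pct": r.quantification.equivalent_area_pct,
            "suspected": r.suspected,
            "priority_rank": rank,
        }
        for rank, r in enumerate(ordered, start=1)
    ]
    return pd.DataFrame(
        rows,
        columns=["case_id", "red_pixel_count", "equivalent_area_mm2",
                 "equivalent_area_pct", "suspected", "priority_rank"],
    )


def run_batch(
    image_dir: str | Path,
    pipeline: ScreeningPipeline,
    config: TriageConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[CaseReport], list[dict]]:
    """Screen every image in a directory and emit the prioritized worklist.

    A failing case is recorded and never aborts the batch. Truth/label
    companion masks (``*_truth``, ``*_labels``) are skipped. When
    ``out_dir`` is given, writes ``worklist.csv`` and ``summary.json``;
    identical inputs yield byte-identical outputs.
    """
    config = config or TriageConfig()
    image_dir = Path(image_dir)
    paths = _discover_images(image_dir)
    if not paths:
        raise EmptyBatchError(f"no case images found in {image_dir}")
    reports: list[CaseReport] = []
    failures: list[dict] = []
    for path in paths:
        try:
            reports.append(run_case(path, pipeline, config))
        except Exception as exc:  # error isolation: record, continue
            logger.warning("case=%s failed: %s", path.stem, exc)
            failures.append({"case_id": path.stem, "error": str(exc)})
    if not reports:
        raise AllCasesFailedError(
            f"all {len(failures)} cases failed in {image_dir}"
        )
    ordered = prioritize(reports)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        worklist_frame(ordered).to_csv(out_dir / "worklist.csv", index=False)
        summary = {
            "n_cases": len(reports),
            "n_suspected": sum(r.suspected for r in reports),
            "n_failed": len(failures),
            "triage_threshold": config.triage_threshold,
            "red_threshold": config.red_threshold,
            "model_id": pipeline.model_id_,
            "reports": [r.to_dict() for r in ordered],
            "failures": failures,
        }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return ordered, failures
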