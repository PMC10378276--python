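"""Two-class random-forest pixel classifier and its probability maps.

Training is sparse: the pathologist labels a handful of pixel regions in the
image itself as C1 (regular clusters) or C2 (possible anomalous clusters);
only those labeled pixels enter the fit — unlabeled pixels are never
pseudo-labeled. Prediction produces a per-pixel probability map where
``p_c2`` is the raw fraction of trees voting C2 (vote counting, not
leaf-probability averaging, so an exhaustive per-tree oracle is exact) and
``p_c1 = 1 - p_c2``.

Tree induction is delegated to scikit-learn's ``RandomForestClassifier``;
after fitting, every tree is exported to plain arrays and prediction always
runs through the package's own vectorized tree walk. JSON-persisted models
therefore predict identically to freshly trained ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureStack
from .image_io import LABEL_ANOMALOUS, LABEL_REGULAR

__all__ = [
    "ForestConfig",
    "ProbabilityMap",
    "PerformanceReport",
    "PixelForestClassifier",
    "MissingClassError",
    "train_frf",
    "predict_probability",
    "evaluate",
]

MODEL_FORMAT = "naevoscreen-forest"
MODEL_VERSION = 1


class MissingClassError(ValueError):
    """Training mask lacks labeled pixels for one of the two classes."""


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters. The source method names the algorithm (a
    fast random forest) without stating tree count or split rule; defaults
    follow standard random-forest practice: 200 trees, sqrt features per
    split, unlimited depth, leaves down to one sample."""

    n_trees: int = 200
    max_features_per_split: str | int = "sqrt"
    min_samples_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities; ``p_c1 + p_c2 == 1`` everywhere."""

    p_c1: np.ndarray
    p_c2: np.ndarray

    def __post_init__(self) -> None:
        if self.p_c1.shape != self.p_c2.shape or self.p_c1.ndim != 2:
            raise ValueError("p_c1 and p_c2 must be matching 2-D arrays")
        total = self.p_c1 + self.p_c2
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("class probabilities must sum to 1 at every pixel")

    @property
    def height(self) -> int:
        return self.p_c1.shape[0]

    @property
    def width(self) -> int:
        return self.p_c1.shape[1]


@dataclass(frozen=True)
class PerformanceReport:
    """Precision/recall of the C2 (anomalous) class over labeled pixels.

    When a rate's denominator is zero the rate is NaN and the matching
    ``*_defined`` flag is False — never silently reported as 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    precision_defined: bool
    recall_defined: bool
    decision_threshold: float
    positive_class: int = LABEL_ANOMALOUS

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": None if not self.precision_defined else self.precision,
            "recall": None if not self.recall_defined else self.recall,
            "precision_defined": self.precision_defined,
            "recall_defined": self.recall_defined,
            "decision_threshold": self.decision_threshold,
            "positive_class": self.positive_class,
        }


@dataclass(frozen=True)
class _TreeArrays:
    """One decision tree as flat arrays (children < 0 marks a leaf)."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_class: np.ndarray  # class label at every node (valid at leaves)

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        """Vectorized root-to-leaf descent; returns the voted label per row."""
        node = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            at_leaf = self.children_left[node] < 0
            if at_leaf.all():
                break
            feat = self.feature[node]
            go_left = X[np.arange(X.shape[0]), np.where(at_leaf, 0, feat)] \
                <= self.threshold[node]
            nxt = np.where(go_left, self.children_left[node],
                           self.children_right[node])
            node = np.where(at_leaf, node, nxt)
        return self.leaf_class[node]

    def to_dict(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "leaf_class": self.leaf_class.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_TreeArrays":
        return cls(
            children_left=np.asarray(d["children_left"], dtype=np.int64),
            children_right=np.asarray(d["children_right"], dtype=np.int64),
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=np.float64),
            leaf_class=np.asarray(d["leaf_class"], dtype=np.int64),
        )


def _export_tree(est, classes: np.ndarray) -> _TreeArrays:
    t = est.tree_
    votes = classes[np.argmax(t.value[:, 0, :], axis=1)]
    return _TreeArrays(
        children_left=t.children_left.astype(np.int64),
        children_right=t.children_right.astype(np.int64),
        feature=t.feature.astype(np.int64),
        threshold=t.threshold.astype(np.float64),
        leaf_class=votes.astype(np.int64),
    )


class PixelForestClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest pixel classifier trained from a sparse label mask.

    Parameters mirror :class:`ForestConfig`. ``fit`` takes a feature stack
    and a label mask of the same image; labeled pixels are extracted in
    row-major order, so the fit is invariant to how the caller produced the
    mask. Deterministic for fixed inputs and ``random_state``.
    """

    def __init__(
        self,
        n_trees: int = 200,
        max_features_per_split: str | int = "sqrt",
        min_samples_leaf: int = 1,
        random_state: int = 0,
    ) -> None:
        self.n_trees = n_trees
        self.max_features_per_split = max_features_per_split
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------

    def fit(self, stack: FeatureStack, mask: np.ndarray) -> "PixelForestClassifier":
        X, y = _labeled_pixels(stack, mask)
        return self.fit_samples(X, y, stack.channel_names)

    def fit_samples(
        self, X: np.ndarray, y: np.ndarray, channel_names: tuple[str, ...]
    ) -> "PixelForestClassifier":
        """Fit from already-extracted labeled feature vectors (used when
        training pools pixels from several annotated images)."""
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        y = np.asarray(y)
        for label in (LABEL_REGULAR, LABEL_ANOMALOUS):
            if not np.any(y == label):
                raise MissingClassError(
                    f"training requires at least one pixel of class {label}"
                )
        if X.shape[1] != len(channel_names):
            raise ValueError("feature matrix width must match channel_names")
        forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.max_features_per_split,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
            n_jobs=1,
        )
        forest.fit(np.asarray(X, dtype=np.float32), y)
        classes = forest.classes_.astype(np.int64)
        self.trees_ = [_export_tree(est, classes) for est in forest.estimators_]
        self.classes_ = (LABEL_REGULAR, LABEL_ANOMALOUS)
        self.channel_names_ = tuple(channel_names)
        self.n_features_in_ = len(channel_names)
        self._sklearn_forest_ = forest  # kept for oracle/diagnostic access
        return self

    # -- prediction ------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "trees_"):
            raise RuntimeError("classifier is not fitted")

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting C2 for each row of ``X``."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float32)
        votes = np.zeros(X.shape[0], dtype=np.int64)
        for tree in self.trees_:
            votes += tree.predict_class(X) == LABEL_ANOMALOUS
        return votes / len(self.trees_)

    def predict_proba_map(self, stack: FeatureStack) -> ProbabilityMap:
        """Probability map over a full image's feature stack."""
        self._check_fitted()
        if stack.channel_names != self.channel_names_:
            raise ValueError(
                "feature stack channels do not match the channels the model "
                "was trained on"
            )
        p_c2 = self.vote_fractions(stack.as_matrix()).reshape(
            stack.height, stack.width
        )
        return ProbabilityMap(p_c1=1.0 - p_c2, p_c2=p_c2)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return np.where(self.vote_fractions(X) > threshold,
                        LABEL_ANOMALOUS, LABEL_REGULAR)

    # -- persistence -----------------------------------------------------

    def to_json_dict(self) -> dict:
        self._check_fitted()
        return {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "params": {
                "n_trees": self.n_trees,
                "max_features_per_split": self.max_features_per_split,
                "min_samples_leaf": self.min_samples_leaf,
                "random_state": self.random_state,
            },
            "classes": list(self.classes_),
            "channel_names": list(self.channel_names_),
            "trees": [t.to_dict() for t in self.trees_],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PixelForestClassifier":
        if d.get("format") != MODEL_FORMAT:
            raise ValueError(f"not a {MODEL_FORMAT} model: {d.get('format')!r}")
        if d.get("version") != MODEL_VERSION:
            raise ValueError(f"unsupported model version {d.get('version')!r}")
        model = cls(**d["params"])
        model.trees_ = [_TreeArrays.from_dict(t) for t in d["trees"]]
        model.classes_ = tuple(d["classes"])
        model.channel_names_ = tuple(d["channel_names"])
        model.n_features_in_ = len(model.channel_names_)
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PixelForestClassifier":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def _labeled_pixels(
    stack: FeatureStack, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-major extraction of labeled pixels' feature vectors and labels."""
    mask = np.asarray(mask)
    if mask.shape != (stack.height, stack.width):
        raise ValueError(
            f"mask shape {mask.shape} does not match stack "
            f"({stack.height}, {stack.width})"
        )
    flat = mask.ravel()
    sel = flat != 0
    return stack.as_matrix()[sel], flat[sel].astype(np.int64)


def save_probability_map(path: str | Path, prob: ProbabilityMap) -> None:
    """Persist a probability map as a 2-channel 32-bit TIFF (C1 then C2)."""
    import tifffile

    tifffile.imwrite(
        Path(path),
        np.stack([prob.p_c1, prob.p_c2], axis=0).astype(np.float32),
    )


def load_probability_map(path: str | Path) -> ProbabilityMap:
    import tifffile

    arr = tifffile.imread(Path(path))
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError("expected a 2-channel probability-map TIFF")
    return ProbabilityMap(
        p_c1=arr[0].astype(np.float64), p_c2=arr[1].astype(np.float64)
    )


# -- spec-level convenience wrappers ------------------------------------


def train_frf(
    stack: FeatureStack, mask: np.ndarray, config: ForestConfig | None = None
) -> PixelForestClassifier:
    """Train the two-class forest on the labeled pixels of one image."""
    config = config or ForestConfig()
    model = PixelForestClassifier(
        n_trees=config.n_trees,
        max_features_per_split=config.max_features_per_split,
        min_samples_leaf=config.min_samples_leaf,
        random_state=config.seed,
    )
    return model.fit(stack, mask)


def predict_probability(
    model: PixelForestClassifier, stack: FeatureStack
) -> ProbabilityMap:
    return model.predict_proba_map(stack)


def evaluate(
    prob: ProbabilityMap, truth: np.ndarray, decision_threshold: float = 0.5
) -> PerformanceReport:
    """Precision and recall of the C2 class at a vote-fraction threshold.

    Only labeled pixels of ``truth`` are scored; unlabeled pixels are
    excluded. Pixels with ``p_c2 > decision_threshold`` (strict) are
    predicted C2.
    """
    if not 0 < decision_threshold < 1:
        raise ValueError("decision_threshold must lie in (0, 1)")
    truth = np.asarray(truth)
    if truth.shape != prob.p_c2.shape:
        raise ValueError("truth mask shape does not match probability map")
    labeled = truth != 0
    if not labeled.any():
        raise ValueError("truth mask has no labeled pixels")
    pred_pos = prob.p_c2 > decision_threshold
    true_pos = truth == LABEL_ANOMALOUS
    tp = int(np.sum(labeled & pred_pos & true_pos))
    fp = int(np.sum(labeled & pred_pos & ~true_pos))
    fn = int(np.sum(labeled & ~pred_pos & true_pos))
    tn = int(np.sum(labeled & ~pred_pos & ~true_pos))
    precision_defined = (tp + fp) > 0
    recall_defined = (tp + fn) > 0
    return PerformanceReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=tp / (tp + fp) if precision_defined else float("nan"),
        recall=tp / (tp + fn) if recall_defined else float("nan"),
        precision_defined=precision_defined,
        recall_defined=recall_defined,
        decision_threshold=decision_threshold,
    )
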