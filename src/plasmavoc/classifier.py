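"""Nearest-centroid classification by maximum cosine similarity.

Training reduces each category to the element-wise mean of its feature
vectors (the category centroid).  A test image is assigned the category
whose centroid makes the smallest angle with its feature vector, i.e. the
maximum of

    S_c(x, y) = x . y / (||x|| ||y||),        S_c in [-1, 1],

over all centroids y.  Because block-mean features are nonnegative, S_c is
in fact confined to [0, 1] in this domain, and on real plasma images the
similarities crowd so close to 1 that a min-max rescaling

    S_norm = (S_c - S_min) / (1.0 - S_min)

is applied for display, with S_min the minimum similarity over the entire
classification test (all test images x all categories).  S_norm is an
affine order-preserving map, so it never changes the classification.

All arithmetic is double precision; the argmax uses exact float comparison
with ties broken toward the first label in canonical category order.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import BlockGrid, FeatureVector
from .images import category_sort_key

__all__ = [
    "cosine_similarity",
    "CategoryModel",
    "fit_centroids",
    "classify",
    "SimilarityMatrix",
    "normalize_similarities",
    "Misclassification",
    "EvaluationReport",
    "evaluate",
    "category_similarity_stats",
    "concat_features",
    "plot_similarity_heatmap",
]


def _as_vector(x: FeatureVector | np.ndarray) -> np.ndarray:
    if isinstance(x, FeatureVector):
        return x.values
    return np.asarray(x, dtype=np.float64).ravel()


def cosine_similarity(x: FeatureVector | np.ndarray,
                      y: FeatureVector | np.ndarray) -> float:
    """Cosine of the angle between two nonzero feature vectors.

    Symmetric, bounded in [-1, 1], and invariant under positive scaling of
    either argument.  Zero vectors and length mismatches are rejected.
    """
    xv, yv = _as_vector(x), _as_vector(y)
    if xv.size != yv.size:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")
    if xv.size == 0:
        raise ValueError("empty vectors have no direction")
    nx = float(np.linalg.norm(xv))
    ny = float(np.linalg.norm(yv))
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine similarity requires nonzero feature vectors")
    # clamp float overshoot so the [-1, 1] bound holds exactly
    return float(min(1.0, max(-1.0, np.dot(xv, yv) / (nx * ny))))


@dataclass
class CategoryModel:
    """Per-category average feature vectors plus grid/region metadata.

    ``labels`` are stored in canonical category order; ``centroids`` is the
    matching (n_categories, n_entries) array; ``train_counts`` records how
    many training vectors produced each centroid.
    """

    labels: list[str]
    centroids: np.ndarray
    grid: BlockGrid | None = None
    region_name: str = ""
    train_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.centroids.ndim != 2 or self.centroids.shape[0] != len(self.labels):
            raise ValueError(
                f"centroid array shape {self.centroids.shape} does not match "
                f"{len(self.labels)} labels"
            )
        if not self.labels:
            raise ValueError("a model needs at least one category")
        norms = np.linalg.norm(self.centroids, axis=1)
        if np.any(norms == 0.0):
            zero = [l for l, n in zip(self.labels, norms) if n == 0.0]
            raise ValueError(f"zero centroid for categories {zero}")

    @property
    def n_entries(self) -> int:
        return int(self.centroids.shape[1])

    def centroid(self, label: str) -> np.ndarray:
        try:
            return self.centroids[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"category {label!r} not in model") from None

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "labels": self.labels,
            "grid": self.grid.render() if self.grid else None,
            "region": self.region_name,
            "train_counts": self.train_counts,
            "centroids": [list(map(float, row)) for row in self.centroids],
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CategoryModel":
        payload = json.loads(Path(path).read_text())
        grid = BlockGrid.from_string(payload["grid"]) if payload.get("grid") else None
        return cls(
            labels=list(payload["labels"]),
            centroids=np.array(payload["centroids"], dtype=np.float64),
            grid=grid,
            region_name=payload.get("region", ""),
            train_counts={k: int(v) for k, v in payload.get("train_counts", {}).items()},
        )


def _pairs(training: Iterable) -> list[tuple[FeatureVector, str]]:
    pairs: list[tuple[FeatureVector, str]] = []
    for item in training:
        if isinstance(item, FeatureVector):
            if item.label is None:
                raise ValueError(
                    f"training vector {item.source_id!r} carries no label"
                )
            pairs.append((item, item.label))
        else:
            vec, label = item
            pairs.append((vec, str(label)))
    return pairs


def fit_centroids(training: Iterable) -> CategoryModel:
    """Average each category's training vectors element-wise into centroids.

    ``training`` is either labeled :class:`FeatureVector` objects or
    ``(vector, label)`` pairs; every category needs at least one vector and
    all vectors one common length.
    """
    pairs = _pairs(training)
    if not pairs:
        raise ValueError("empty training set")
    lengths = {len(v) for v, _ in pairs}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent training vector lengths {sorted(lengths)}")
    by_label: dict[str, list[np.ndarray]] = {}
    for vec, label in pairs:
        by_label.setdefault(label, []).append(vec.values)
    labels = sorted(by_label, key=category_sort_key)
    centroids = np.stack(
        [np.mean(np.stack(by_label[l]), axis=0, dtype=np.float64) for l in labels]
    )
    grids = {v.grid for v, _ in pairs}
    regions = {v.region_name for v, _ in pairs}
    return CategoryModel(
        labels=labels,
        centroids=centroids,
        grid=grids.pop() if len(grids) == 1 else None,
        region_name=regions.pop() if len(regions) == 1 else "",
        train_counts={l: len(by_label[l]) for l in labels},
    )


def classify(test: FeatureVector | np.ndarray, model: CategoryModel
             ) -> tuple[str, pd.Series]:
    """Assign ``test`` to the category with maximum cosine similarity.

    Returns the winning label and the full similarity row as a Series
    indexed by category label.  Ties break toward the first label in the
    model's canonical order (np.argmax semantics).
    """
    tv = _as_vector(test)
    if tv.size != model.n_entries:
        raise ValueError(
            f"test vector length {tv.size} does not match model "
            f"centroid length {model.n_entries}"
        )
    nt = float(np.linalg.norm(tv))
    if nt == 0.0:
        raise ValueError("cosine similarity requires nonzero feature vectors")
    sims = (model.centroids @ tv) / (np.linalg.norm(model.centroids, axis=1) * nt)
    sims = np.clip(sims, -1.0, 1.0)
    row = pd.Series(sims, index=model.labels, name="S_c")
    return model.labels[int(np.argmax(sims))], row


@dataclass
class SimilarityMatrix:
    """Test-image x category similarity values (raw or normalized)."""

    row_ids: list[str]
    labels: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.row_ids), len(self.labels)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.labels)} labels"
            )
        lo, hi = (0.0, 1.0) if self.normalized else (-1.0, 1.0)
        if self.values.size and (
            self.values.min() < lo - 1e-12 or self.values.max() > hi + 1e-12
        ):
            raise ValueError(f"entries outside [{lo}, {hi}]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.labels)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index_label="source_id")
        return path


def normalize_similarities(matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Min-max rescale a similarity matrix: the run minimum maps to 0 and 1
    stays fixed.

    The minimum is taken over the entire matrix (all test images x all
    categories, one classification test).  Degenerate matrices whose
    entries are all exactly 1 are rejected.
    """
    if matrix.values.size == 0:
        raise ValueError("empty similarity matrix")
    s_min = float(matrix.values.min())
    if s_min >= 1.0:
        raise ValueError(
            "all similarities equal 1; normalization is degenerate"
        )
    norm = (matrix.values - s_min) / (1.0 - s_min)
    return SimilarityMatrix(
        row_ids=list(matrix.row_ids),
        labels=list(matrix.labels),
        values=norm,
        normalized=True,
    )


@dataclass(frozen=True)
class Misclassification:
    source_id: str
    true_label: str
    predicted_label: str


@dataclass
class EvaluationReport:
    """Accuracy, misclassifications, similarity matrices, and wall time."""

    accuracy: float
    n_test: int
    n_correct: int
    misclassified: list[Misclassification]
    similarities: SimilarityMatrix
    normalized: SimilarityMatrix | None
    wall_time_s: float

    @property
    def accuracy_percent(self) -> float:
        """Accuracy rounded to one decimal percent (report formatting)."""
        return round(100.0 * self.accuracy, 1)

    def misclassification_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.source_id, m.true_label, m.predicted_label)
             for m in self.misclassified],
            columns=["misidentified", "true", "predicted"],
        )


def evaluate(test: Iterable, model: CategoryModel) -> EvaluationReport:
    """Classify a labeled test set and report accuracy Table-style.

    ``test`` is labeled :class:`FeatureVector` objects or ``(vector,
    label)`` pairs.  Accuracy is correct/total; misclassifications are
    listed as (image, predicted category) pairs; both the raw and the
    min-max-normalized similarity matrices are returned (the latter None
    when degenerate).  Wall time covers the classification loop.
    """
    pairs = _pairs(test)
    if not pairs:
        raise ValueError("empty test set")
    t0 = time.perf_counter()
    rows = []
    row_ids = []
    predictions = []
    for i, (vec, _) in enumerate(pairs):
        pred, row = classify(vec, model)
        predictions.append(pred)
        rows.append(row.to_numpy())
        row_ids.append(vec.source_id or f"test_{i:03d}")
    wall = time.perf_counter() - t0
    sims = SimilarityMatrix(row_ids, list(model.labels), np.stack(rows))
    try:
        norm = normalize_similarities(sims)
    except ValueError:
        norm = None
    mis = [
        Misclassification(rid, truth, pred)
        for rid, (vec, truth), pred in zip(row_ids, pairs, predictions)
        if pred != truth
    ]
    n_correct = len(pairs) - len(mis)
    return EvaluationReport(
        accuracy=n_correct / len(pairs),
        n_test=len(pairs),
        n_correct=n_correct,
        misclassified=mis,
        similarities=sims,
        normalized=norm,
        wall_time_s=wall,
    )


def category_similarity_stats(images: Iterable, model: CategoryModel
                              ) -> pd.DataFrame:
    """Per-category (mean, max, max-mean) cosine similarity to the own
    centroid.

    A tight category (e.g. pure-helium plasma) shows a max-mean difference
    orders of magnitude smaller than a variable one.  Every label present
    in ``images`` must exist in the model.
    """
    pairs = _pairs(images)
    if not pairs:
        raise ValueError("empty image set")
    sims: dict[str, list[float]] = {}
    for vec, label in pairs:
        if label not in model.labels:
            raise KeyError(f"category {label!r} not in model")
        sims.setdefault(label, []).append(
            cosine_similarity(vec, model.centroid(label))
        )
    labels = sorted(sims, key=category_sort_key)
    data = {
        "mean": [float(np.mean(sims[l])) for l in labels],
        "max": [float(np.max(sims[l])) for l in labels],
    }
    df = pd.DataFrame(data, index=pd.Index(labels, name="label"))
    df["difference"] = df["max"] - df["mean"]
    return df


def concat_features(a: FeatureVector, b: FeatureVector) -> FeatureVector:
    """Concatenate two feature vectors of the same source image.

    Used to combine regions (e.g. region 2 + region 3 features); the result
    behaves as an ordinary vector downstream.  Rejects empty inputs and
    mismatched source ids.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot concatenate an empty feature vector")
    if a.source_id != b.source_id:
        raise ValueError(
            f"source id mismatch: {a.source_id!r} vs {b.source_id!r}"
        )
    if a.label is not None and b.label is not None and a.label != b.label:
        raise ValueError(f"label mismatch: {a.label!r} vs {b.label!r}")
    region = "+".join(p for p in (a.region_name, b.region_name) if p)
    return FeatureVector(
        np.concatenate([a.values, b.values]),
        grid=None,
        region_name=region,
        source_id=a.source_id,
        label=a.label if a.label is not None else b.label,
    )


def plot_similarity_heatmap(matrix: SimilarityMatrix, path: str | Path,
                            floor: float = 0.90) -> Path:
    """Render a similarity matrix as a heatmap PNG with a display floor.

    ``floor`` sets the lower display limit of the color scale (0.90 by
    default) to highlight small differences between near-1 values; it
    affects display only, never the underlying values.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.3 * len(matrix.labels)),
                 max(3.0, 0.3 * len(matrix.row_ids)))
    )
    im = ax.imshow(matrix.values, vmin=floor, vmax=1.0, cmap="viridis",
                   aspect="auto")
    ax.set_xticks(range(len(matrix.labels)), matrix.labels, rotation=90,
                  fontsize=6)
    ax.set_yticks(range(len(matrix.row_ids)), matrix.row_ids, fontsize=6)
    name = "S_norm" if matrix.normalized else "S_c"
    fig.colorbar(im, ax=ax, label=name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
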