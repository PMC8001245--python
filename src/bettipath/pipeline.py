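"""Preprocessing, the eight-classifier sweep, and exhaustive model selection.

The model-selection procedure enumerates every combination of

* normalization flag (0 = without, 1 = with z-score standardization),
* feature-selection flag (0 = without, 1 = with top-20% ANOVA-F selection),
* non-empty subset of the working image resolutions, and
* classification algorithm (ids 0-7, fixed mapping below),

fits each candidate on the training split, scores it on the validation
split, and selects the configuration with the highest validation accuracy;
the test split is touched only once, to report the selected model's accuracy
and confusion matrix.  With four scales this is 2 x 2 x 15 x 8 = 480
configurations.

Algorithm ids: 0 perceptron, 1 logistic regression, 2 kNN, 3 linear-kernel
SVM, 4 RBF-kernel SVM, 5 decision tree, 6 random forest, 7 gradient tree
boosting (xgboost).  Hyperparameters are the library defaults, pinned in
``algorithm_defaults.yaml``.

Leakage control: standardization statistics and the ANOVA-F ranking are
computed on the training split only and applied unchanged to validation and
test; splits are made at the parent-image level before any patching.
"""

from __future__ import annotations

import importlib
import importlib.resources
import json
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.feature_selection import f_classif

from .imageops import SplitSpec

__all__ = [
    "ALGORITHM_NAMES",
    "ModelConfig",
    "SearchResult",
    "algorithm_defaults",
    "enumerate_configs",
    "evaluate",
    "grid_search",
    "select_features",
    "standardize",
    "train_classifier",
]

logger = logging.getLogger(__name__)


def algorithm_defaults() -> dict[int, dict]:
    """The pinned per-algorithm hyperparameter table (id -> spec)."""
    text = (
        importlib.resources.files("bettipath")
        .joinpath("algorithm_defaults.yaml")
        .read_text()
    )
    raw = yaml.safe_load(text)["algorithms"]
    return {int(k): v for k, v in raw.items()}


_DEFAULTS = algorithm_defaults()
ALGORITHM_NAMES = {k: v["name"] for k, v in _DEFAULTS.items()}


def standardize(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[pd.DataFrame, ...]:
    """Z-score every feature using training-set mean and population SD.

    The same training statistics are applied unchanged to the other tables;
    zero-variance features map to 0 everywhere.
    """
    if train.empty:
        raise ValueError("training table must be non-empty")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    safe = sd.replace(0.0, 1.0)
    out = [(t - mean) / safe for t in (train, *others)]
    zero = sd == 0.0
    if zero.any():
        for t in out:
            t.loc[:, zero.index[zero]] = 0.0
    return tuple(out)


def select_features(
    train: pd.DataFrame, train_labels: Sequence, fraction: float = 0.2
) -> list[str]:
    """Names of the top ``floor(fraction * d)`` features by ANOVA F statistic.

    The F statistic is the between-class to within-class variance ratio,
    computed on the training split only.  Ties (including the all-NaN case
    of zero within-class variance handled by scikit-learn as NaN) are broken
    by column order; NaN scores rank last.
    """
    d = train.shape[1]
    if d == 0:
        raise ValueError("no features to select from")
    labels = np.asarray(train_labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("feature selection requires >= 2 classes")
    k = max(1, int(np.floor(fraction * d)))
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features yield NaN F scores
        f_scores, _ = f_classif(train.to_numpy(), labels)
    f_scores = np.nan_to_num(f_scores, nan=-np.inf)
    # stable sort on negated score preserves column order among ties
    order = np.argsort(-f_scores, kind="stable")
    keep = sorted(order[:k].tolist())
    return [train.columns[i] for i in keep]


def train_classifier(
    algorithm_id: int,
    features: pd.DataFrame | np.ndarray,
    labels: Sequence,
    seed: int = 0,
):
    """Fit one of the eight classifiers with its pinned default parameters.

    Stochastic learners receive ``random_state=seed``.  Returns a fitted
    estimator whose ``predict`` yields labels in the input label space
    (xgboost's integer-class requirement is handled internally).
    """
    if algorithm_id not in _DEFAULTS:
        raise ValueError(f"unknown algorithm id {algorithm_id}; valid ids 0-7")
    spec = _DEFAULTS[algorithm_id]
    module, _, cls_name = spec["class"].rpartition(".")
    cls = getattr(importlib.import_module(module), cls_name)
    params = dict(spec["params"])
    if spec["stochastic"]:
        params["random_state"] = int(seed)
    model = cls(**params)
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if spec["name"] == "gradient_tree_boosting":
        classes = np.unique(y)
        lut = {c: i for i, c in enumerate(classes)}
        model.fit(X, np.array([lut[c] for c in y]))
        return _DecodingModel(model, classes)
    model.fit(X, y)
    return model


class _DecodingModel:
    """Wraps an integer-class estimator to predict in the original labels."""

    def __init__(self, model, classes: np.ndarray):
        self._model = model
        self.classes_ = classes

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.asarray(self._model.predict(np.asarray(X, dtype=np.float64)), dtype=int)]


@dataclass(frozen=True)
class ModelConfig:
    """One point of the exhaustive search grid."""

    normalization: int
    feature_selection: int
    scale_subset: tuple[tuple[int, int], ...]
    algorithm_id: int

    def __post_init__(self) -> None:
        if self.normalization not in (0, 1) or self.feature_selection not in (0, 1):
            raise ValueError("preprocessing flags must be 0 or 1")
        if not self.scale_subset:
            raise ValueError("scale subset must be non-empty")
        if self.algorithm_id not in _DEFAULTS:
            raise ValueError(f"unknown algorithm id {self.algorithm_id}")

    def describe(self) -> str:
        scales = "+".join(str(h) for h, _ in self.scale_subset)
        return (
            f"norm={self.normalization} sel={self.feature_selection} "
            f"scales={scales} algo={self.algorithm_id}"
            f"({ALGORITHM_NAMES[self.algorithm_id]})"
        )


@dataclass
class SearchResult:
    """A fitted configuration with its accuracies and confusion matrix."""

    config: ModelConfig
    validation_accuracy: float
    test_accuracy: float | None = None
    confusion_matrix: pd.DataFrame | None = None
    rank: int | None = None

    def to_dict(self) -> dict:
        d = {
            "normalization": self.config.normalization,
            "feature_selection": self.config.feature_selection,
            "scales": [list(s) for s in self.config.scale_subset],
            "algorithm_id": self.config.algorithm_id,
            "algorithm": ALGORITHM_NAMES[self.config.algorithm_id],
            "validation_accuracy": self.validation_accuracy,
            "test_accuracy": self.test_accuracy,
        }
        if self.confusion_matrix is not None:
            d["confusion_matrix"] = {
                "classes": list(self.confusion_matrix.index),
                "counts": self.confusion_matrix.to_numpy().tolist(),
            }
        return d


def enumerate_configs(
    scales: Sequence[tuple[int, int]],
    algorithms: Sequence[int] = tuple(range(8)),
) -> list[ModelConfig]:
    """All configurations in the fixed deterministic search order.

    Flags ascending, scale subsets by bitmask over scales sorted descending
    by resolution, algorithm id ascending.
    """
    scales = sorted({tuple(s) for s in scales}, key=lambda s: (-s[0] * s[1], s))
    n = len(scales)
    configs = []
    for norm in (0, 1):
        for sel in (0, 1):
            for mask in range(1, 2**n):
                subset = tuple(scales[i] for i in range(n) if mask & (1 << i))
                for algo in algorithms:
                    configs.append(
                        ModelConfig(norm, sel, subset, algo)
                    )
    return configs


def _assemble(
    tables: Mapping[tuple[int, int], pd.DataFrame],
    subset: Sequence[tuple[int, int]],
) -> pd.DataFrame:
    parts = []
    index = None
    for scale in subset:
        t = tables[tuple(scale)]
        if index is None:
            index = t.index
        elif not index.equals(t.index):
            raise ValueError("per-scale feature tables are not aligned on sample_id")
        parts.append(t)
    return pd.concat(parts, axis=1)


def _prepare_xy(
    table: pd.DataFrame,
    labels: Mapping[str, object],
    split: SplitSpec,
    config: ModelConfig,
):
    """Split, optionally standardize and select; returns per-split (X, y)."""
    ids = {s: [i for i in table.index if split[i] == s] for s in ("train", "validation", "test")}
    parts = {s: table.loc[ids[s]] for s in ids}
    if config.normalization:
        parts["train"], parts["validation"], parts["test"] = standardize(
            parts["train"], parts["validation"], parts["test"]
        )
    y = {s: np.asarray([labels[i] for i in ids[s]]) for s in ids}
    if config.feature_selection:
        keep = select_features(parts["train"], y["train"])
        parts = {s: t[keep] for s, t in parts.items()}
    return parts, y


def grid_search(
    tables: Mapping[tuple[int, int], pd.DataFrame],
    labels: Mapping[str, object],
    split: SplitSpec,
    scales: Sequence[tuple[int, int]] | None = None,
    seed: int = 0,
    algorithms: Sequence[int] = tuple(range(8)),
) -> list[SearchResult]:
    """Exhaustive configuration search scored on the validation split.

    Returns all configurations sorted by validation accuracy descending,
    with enumeration order as the tiebreak (``rank`` records the final
    position).  Test-set metrics are *not* computed here; pass the winner
    to :func:`evaluate`.
    """
    tables = {tuple(k): v for k, v in tables.items()}
    if scales is None:
        scales = list(tables)
    configs = enumerate_configs(scales, algorithms)
    results: list[SearchResult] = []
    for order, config in enumerate(configs):
        table = _assemble(tables, config.scale_subset)
        parts, y = _prepare_xy(table, labels, split, config)
        model = train_classifier(config.algorithm_id, parts["train"], y["train"], seed)
        pred = model.predict(parts["validation"].to_numpy())
        acc = float(np.mean(pred == y["validation"]))
        results.append(SearchResult(config=config, validation_accuracy=acc))
        logger.info("[%4d/%d] %s  val_acc=%.4f", order + 1, len(configs), config.describe(), acc)
    order_index = {id(r): i for i, r in enumerate(results)}
    results.sort(key=lambda r: (-r.validation_accuracy, order_index[id(r)]))
    for rank, r in enumerate(results):
        r.rank = rank
    return results


def top_ties(results: Sequence[SearchResult]) -> list[SearchResult]:
    """All configurations tied for the best validation accuracy."""
    if not results:
        return []
    best = results[0].validation_accuracy
    return [r for r in results if r.validation_accuracy == best]


def evaluate(
    config: ModelConfig,
    tables: Mapping[tuple[int, int], pd.DataFrame],
    labels: Mapping[str, object],
    split: SplitSpec,
    seed: int = 0,
) -> SearchResult:
    """Refit a configuration on the training split and score it on the test split.

    Returns a :class:`SearchResult` with validation and test accuracy and the
    class-by-class confusion matrix (rows = ground truth, columns =
    prediction); accuracy equals the matrix trace over its total.
    """
    tables = {tuple(k): v for k, v in tables.items()}
    table = _assemble(tables, config.scale_subset)
    parts, y = _prepare_xy(table, labels, split, config)
    if len(y["test"]) == 0:
        raise ValueError("test split is empty")
    model = train_classifier(config.algorithm_id, parts["train"], y["train"], seed)
    val_pred = model.predict(parts["validation"].to_numpy())
    test_pred = model.predict(parts["test"].to_numpy())
    classes = sorted(set(map(str, labels.values())))
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for truth, pred in zip(y["test"], test_pred):
        cm.loc[str(truth), str(pred)] += 1
    test_acc = float(np.trace(cm.to_numpy()) / cm.to_numpy().sum())
    return SearchResult(
        config=config,
        validation_accuracy=float(np.mean(val_pred == y["validation"])),
        test_accuracy=test_acc,
        confusion_matrix=cm,
    )


def save_results(path, results: Sequence[SearchResult]) -> None:
    """Write search results as JSON (best first)."""
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)
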