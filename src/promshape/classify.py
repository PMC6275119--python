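"""Gradient-boosted tree classifier, stratified splitting, chromosome-fold CV.

The boosted ensemble is trained with XGBoost (binary logistic objective,
single-threaded for determinism).  Leave-one-chromosome-out cross-validation
(LOCO-CV) defines one fold per chromosome so that performance estimates are
not inflated by positional proximity between train and test variants.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

from .errors import ContractError, SchemaError
from .evaluate import roc_auc, threshold_metrics
from .features import FeatureMatrix, FeatureSchema

logger = logging.getLogger(__name__)


@dataclass
class GTBConfig:
    """Gradient-tree-boosting hyperparameters (binary logistic objective)."""

    n_trees: int = 300
    max_depth: int = 8
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ContractError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ContractError("max_depth must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ContractError("learning_rate must lie in (0, 1]")


@dataclass
class TrainedModel:
    """A fitted boosted-tree ensemble bound to the schema it was trained on."""

    booster: xgb.Booster
    schema: FeatureSchema
    config: GTBConfig

    def save(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "schema": list(self.schema.columns),
            "booster": json.loads(bytes(self.booster.save_raw("json"))),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        booster = xgb.Booster()
        booster.load_model(bytearray(json.dumps(payload["booster"]), "utf-8"))
        return cls(
            booster=booster,
            schema=FeatureSchema(tuple(tuple(c) for c in payload["schema"])),
            config=GTBConfig(**payload["config"]),
        )


def stratified_split(
    keys: Sequence[str],
    labels: Sequence[int],
    test_frac: float = 0.2,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified train/test split of variant keys.

    The total test size is ``round(test_frac * n)`` (half away from zero);
    each class gets ``floor(test_frac * n_class)`` seats and the remaining
    seats go to the largest fractional remainders (ties favor the positive
    class).  Sampling within a class is uniform given ``seed``.
    """
    if not 0 < test_frac < 1:
        raise ContractError("test_frac must lie in (0, 1)")
    keys = list(keys)
    y = np.asarray(labels)
    if len(keys) != len(y):
        raise ContractError("keys and labels length mismatch")
    classes = sorted(np.unique(y), reverse=True)  # positive class (1) first
    if len(classes) < 2:
        raise ContractError("both classes must be present")

    n = len(keys)
    total_test = math.floor(test_frac * n + 0.5)  # round half away from zero
    exact = {c: test_frac * int(np.sum(y == c)) for c in classes}
    alloc = {c: math.floor(exact[c]) for c in classes}
    seats = total_test - sum(alloc.values())
    for c in sorted(classes, key=lambda c: (-(exact[c] - alloc[c]), -c)):
        if seats <= 0:
            break
        alloc[c] += 1
        seats -= 1

    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        k = alloc[c]
        if k == 0 and len(idx) == 0:
            raise ContractError(f"class {c} has no members")
        if k > len(idx):
            raise ContractError(f"class {c}: cannot allocate {k} of {len(idx)} to test")
        test_idx.extend(rng.choice(idx, size=k, replace=False))
    test_set = set(test_idx)
    train = [keys[i] for i in range(n) if i not in test_set]
    test = [keys[i] for i in sorted(test_set)]
    return train, test


def _dmatrix(X: np.ndarray, names: Sequence[str], y: np.ndarray | None = None):
    return xgb.DMatrix(X, label=y, feature_names=list(names))


def train_gtb(
    matrix: FeatureMatrix, labels: Sequence[int], config: GTBConfig
) -> TrainedModel:
    """Fit the boosted-tree classifier (deterministic given seed, 1 thread)."""
    if len(matrix.schema) == 0:
        raise ContractError("schema has no columns")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ContractError("both classes must be present for training")
    params = {
        "objective": "binary:logistic",
        "max_depth": config.max_depth,
        "eta": config.learning_rate,
        "seed": config.seed,
        "nthread": 1,
        "tree_method": "hist",
        "subsample": 1.0,
        "colsample_bytree": 1.0,
    }
    dtrain = _dmatrix(matrix.values(), matrix.schema.names, y)
    booster = xgb.train(params, dtrain, num_boost_round=config.n_trees)
    return TrainedModel(booster, matrix.schema, config)


def predict(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Scores in [0, 1], one per row; schema must match the model's exactly."""
    if matrix.schema.names != model.schema.names:
        for a, b in zip(model.schema.names, matrix.schema.names):
            if a != b:
                raise SchemaError(f"schema mismatch: expected column {a!r}, got {b!r}")
        raise SchemaError("schema mismatch: differing column counts")
    if matrix.n == 0:
        return np.empty(0)
    return model.booster.predict(_dmatrix(matrix.values(), matrix.schema.names))


def predict_labels(model: TrainedModel, matrix: FeatureMatrix, thr: float = 0.5) -> np.ndarray:
    return (predict(model, matrix) >= thr).astype(int)


_METRICS = ("auc", "accuracy", "f1", "precision", "recall")


def loco_cv(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    chroms: Sequence[str] | None = None,
    gtb_config: GTBConfig | None = None,
    thr: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Leave-one-chromosome-out cross-validation.

    Returns (per-fold table, aggregate).  Folds whose test chromosome lacks
    a class are skipped with a warning and excluded from aggregation, which
    is the unweighted mean and sample standard deviation across retained
    folds of AUC, accuracy, F1, precision and recall.
    """
    gtb_config = gtb_config or GTBConfig()
    y = np.asarray(labels)
    chrom_arr = np.asarray(chroms if chroms is not None else matrix.chroms)
    unique_chroms = sorted(set(chrom_arr))
    if len(unique_chroms) < 2:
        raise ContractError("LOCO-CV needs at least 2 distinct chromosomes")

    fold_rows = []
    for chrom in unique_chroms:
        test_mask = chrom_arr == chrom
        y_test, y_train = y[test_mask], y[~test_mask]
        if len(np.unique(y_test)) < 2 or len(np.unique(y_train)) < 2:
            logger.warning("loco_cv: fold %s lacks a class; skipped", chrom)
            fold_rows.append({"chrom": chrom, "n_test": int(test_mask.sum()), "retained": False})
            continue
        sub_train = FeatureMatrix(
            matrix.data.loc[~test_mask],
            matrix.schema,
            matrix.chroms.loc[~test_mask],
        )
        sub_test = FeatureMatrix(
            matrix.data.loc[test_mask],
            matrix.schema,
            matrix.chroms.loc[test_mask],
        )
        model = train_gtb(sub_train, y_train, gtb_config)
        scores = predict(model, sub_test)
        tm = threshold_metrics(scores, y_test, thr=thr)
        fold_rows.append(
            {
                "chrom": chrom,
                "n_test": int(test_mask.sum()),
                "retained": True,
                "auc": roc_auc(scores, y_test),
                **tm,
            }
        )

    folds = pd.DataFrame(fold_rows)
    retained = folds[folds["retained"]]
    if retained.empty:
        raise ContractError("no retained folds (every fold lacked a class)")
    agg: dict[str, float] = {}
    for m in _METRICS:
        vals = retained[m].to_numpy(dtype=float)
        agg[m] = float(np.mean(vals))
        agg[f"{m}_std"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    agg["n_folds"] = float(len(retained))
    agg["size"] = float(len(matrix.schema))
    return folds, agg
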