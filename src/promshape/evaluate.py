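"""Metrics, screening statistics, and feature-group permutation ablation.

ROC-AUC uses the rank-sum (Mann-Whitney) identity with half credit for
ties; average precision is the step-wise area under the precision-recall
curve (no interpolation), which makes "area under the PR curve" and
"average precision" the same number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ContractError, UndefinedMetricError

logger = logging.getLogger(__name__)


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":  # string labels
        y = (y == "functional").astype(int)
    return y.astype(int)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """P(random positive outranks random negative); ties count 1/2."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC-AUC undefined with a single class")
    ranks = stats.rankdata(s)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def average_precision(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, list[tuple[float, float]]]:
    """(AP, PR curve) with the step-wise definition AP = sum dR * P.

    Thresholds are the descending unique scores; tied scores are processed
    as one threshold.  The returned curve starts at (0, 1).
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise UndefinedMetricError("average precision undefined with no positives")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    pred = np.arange(1, len(y) + 1)
    # last index of each tied block = one threshold
    last = np.flatnonzero(np.diff(s_sorted, append=np.nan) != 0)
    precision = tp[last] / pred[last]
    recall = tp[last] / n_pos
    ap = 0.0
    prev_r = 0.0
    curve: list[tuple[float, float]] = [(0.0, 1.0)]
    for r, p in zip(recall, precision):
        ap += (r - prev_r) * p
        prev_r = r
        curve.append((float(r), float(p)))
    return float(ap), curve


def threshold_metrics(
    scores: Sequence[float], labels: Sequence[int], thr: float = 0.5
) -> dict[str, float]:
    """Accuracy, precision, recall, F1 at a hard threshold.

    Precision is 0 by convention (logged) when nothing is predicted positive.
    """
    y = _as_binary(labels)
    pred = (np.asarray(scores, dtype=float) >= thr).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    if tp + fp == 0:
        logger.info("threshold_metrics: no positive predictions; precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / len(y)
    return {"accuracy": accuracy, "f1": f1, "precision": precision, "recall": recall}


def welch_t(x: Sequence[float], y: Sequence[float]) -> float:
    """Welch's t statistic; the first argument is the functional class."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ContractError("welch_t needs at least 2 observations per sample")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise UndefinedMetricError("welch_t undefined: both variances are zero")
    return float(stats.ttest_ind(x, y, equal_var=False).statistic)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov (D, asymptotic p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ContractError("ks_two_sample needs non-empty samples")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvalReport:
    """Scalar metrics plus the PR curve (and optionally per-fold results)."""

    auc: float
    average_precision: float
    accuracy: float
    f1: float
    precision: float
    recall: float
    pr_curve: list[tuple[float, float]] = field(default_factory=list)
    folds: pd.DataFrame | None = None

    def to_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "average_precision": self.average_precision,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([self.to_dict()]).to_csv(path, sep="\t", index=False)

    def pr_curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pr_curve, columns=["recall", "precision"])


def evaluate_scores(
    scores: Sequence[float], labels: Sequence[int], thr: float = 0.5
) -> EvalReport:
    """Full report: AUC, AP + PR curve, and thresholded metrics."""
    ap, curve = average_precision(scores, labels)
    tm = threshold_metrics(scores, labels, thr=thr)
    return EvalReport(
        auc=roc_auc(scores, labels),
        average_precision=ap,
        pr_curve=curve,
        **tm,
    )


@dataclass
class AblationResult:
    """Average precision after permuting feature groups in the test matrix."""

    baseline_ap: float
    entries: list[tuple[tuple[str, ...], float]]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("baseline", self.baseline_ap)]
        rows += [("+".join(groups), ap) for groups, ap in self.entries]
        df = pd.DataFrame(rows, columns=["permuted_groups", "average_precision"])
        df["seed"] = self.seed
        return df


def permutation_ablation(
    model,
    matrix,
    labels: Sequence[int],
    group_sets: Sequence[Sequence[str]],
    seed: int = 0,
) -> AblationResult:
    """Destroy feature-group information by row permutation and re-score.

    For each group set, the corresponding columns are jointly permuted with
    one shared row permutation (preserving within-set dependence), the model
    re-scores the permuted matrix, and AP is recomputed.
    """
    from .classify import predict  # local import to avoid a module cycle
    from .features import FeatureMatrix

    baseline_ap, _ = average_precision(predict(model, matrix), labels)
    rng = np.random.default_rng(seed)
    entries = []
    for groups in group_sets:
        cols: list[str] = []
        for g in groups:
            cols.extend(matrix.schema.group_columns(g))  # raises on unknown group
        if not cols:
            raise ConfigurationError(f"no columns for groups {tuple(groups)}")
        perm = rng.permutation(matrix.n)
        data = matrix.data.copy()
        data.loc[:, cols] = data[cols].to_numpy()[perm]
        permuted = FeatureMatrix(data, matrix.schema, matrix.chroms, matrix.labels)
        ap, _ = average_precision(predict(model, permuted), labels)
        entries.append((tuple(groups), ap))
    return AblationResult(baseline_ap=baseline_ap, entries=entries, seed=seed)


def plot_pr_curves(
    curves: dict[str, list[tuple[float, float]]], path: str | Path
) -> None:
    """Render PR curves to an image file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        arr = np.asarray(curve)
        ax.step(arr[:, 0], arr[:, 1], where="post", label=name)
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
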