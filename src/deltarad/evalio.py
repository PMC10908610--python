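"""Binary-classification metrics, run configuration, and table I/O.

AUC uses the Mann--Whitney formulation (ties count 0.5); DeLong's test
compares two correlated AUCs through the covariance of placement values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = ["auc", "delong_test", "confusion_at", "BinaryEval", "RunConfig",
           "write_feature_table", "read_feature_table"]

log = logging.getLogger(__name__)

#: Metadata constant: definition of a positive (R1) resection margin used for
#: the labels this package consumes — tumor present within 1 mm of the
#: resection margin (CAP criteria).  Labels arrive precomputed; no pathology
#: computation happens here.
R1_MARGIN_DEFINITION_MM = 1.0


def auc(labels, scores) -> float:
    """Area under the ROC curve, Mann--Whitney form; ties count 0.5."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def _placements(labels: np.ndarray, scores: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # V10_i = fraction of negatives below positive i (ties half)
    v10 = (np.sum(pos[:, None] > neg[None, :], axis=1)
           + 0.5 * np.sum(pos[:, None] == neg[None, :], axis=1)) / len(neg)
    v01 = (np.sum(pos[None, :] > neg[:, None], axis=1)
           + 0.5 * np.sum(pos[None, :] == neg[:, None], axis=1)) / len(pos)
    return v10, v01


def delong_test(labels, scores_a, scores_b) -> float:
    """Two-sided DeLong p-value for paired AUC difference."""
    labels = np.asarray(labels, dtype=int)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    v10a, v01a = _placements(labels, scores_a)
    v10b, v01b = _placements(labels, scores_b)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        log.info("DeLong variance of AUC difference is zero; p = 1")
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class BinaryEval:
    """Confusion-derived rates at a stated probability threshold."""

    auc: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_at(labels, probabilities, threshold: float = 0.5) -> BinaryEval:
    """Standard confusion-matrix metrics; predicted positive iff p >= threshold.

    PPV/NPV are NaN when no subject is predicted positive/negative.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probabilities, dtype=float)
    pred = probs >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(labels)
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    try:
        a = auc(labels, probs)
    except ValueError:
        a = float("nan")
    return BinaryEval(a, float(threshold), tp, fp, tn, fn, sens, spec, acc, ppv, npv)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 0
    n_subjects: int = 20
    n_validation: int = 0
    cv_repeats: int = 10
    cv_folds: int = 5
    hu_window: tuple[float, float] = (-200.0, 500.0)
    target_spacing: float = 1.0
    quantization_levels: tuple[int, ...] = (8, 16, 32, 64, 128, 256)
    metric_floor: float = 0.5
    spearman_threshold: float = 0.9
    max_features: int = 5
    horizons_months: tuple[int, ...] = (12, 24, 36)
    mcom_population: int = 10
    mcom_generations: int = 5
    grid_shape: tuple[int, int, int] = (48, 48, 48)

    def __post_init__(self) -> None:
        if not 0 < self.metric_floor < 1:
            raise ValueError("metric_floor must be in (0, 1)")
        if not 0 < self.spearman_threshold <= 1:
            raise ValueError("spearman_threshold must be in (0, 1]")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if self.hu_window[0] >= self.hu_window[1]:
            raise ValueError("hu_window must be (lo, hi) with lo < hi")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("hu_window", "quantization_levels", "horizons_months", "grid_shape"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    def config_hash(self) -> str:
        import hashlib
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def write_feature_table(df: pd.DataFrame, path) -> None:
    """UTF-8 CSV, header row of canonical feature names, one subject per row,
    missing values as empty cells."""
    df.to_csv(path, index_label="subject")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject")
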