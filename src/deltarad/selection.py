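"""Repeated cross-validated feature screening and step-forward Cox selection.

The screening protocol ranks every candidate feature by its mean validation
performance over repeated k-fold cross-validation (default 100 repeats of
5 folds): a univariate Cox model per survival task (scored by validation
C-index) or a univariate logistic model for the margin task (validation AUC).
Features averaging below 0.5 are removed (strict inequality), redundancy is
pruned by walking the rank order and dropping any feature with |Spearman rho|
above 0.9 to an already-retained better-ranked feature, and the survivors feed
a greedy step-forward multivariate Cox search capped at five features, scored
by mean cross-validated C-index with strict improvement required.

Fold partitions are drawn once per plan seed and shared across every model
built under the same plan, so clinical and radiomic modalities see identical
splits.  Degenerate folds (no events in training, a single class, no
comparable validation pairs) are skipped and counted, not failed: they are
expected at the cohort sizes this protocol targets (~60 subjects).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .evalio import auc
from .survival import (ConvergenceError, SeparationError, concordance_index,
                       cox_newton, fit_cox, CoxRiskModel)

__all__ = ["CvPlan", "ScreenResult", "cv_univariate_screen", "drop_below_half",
           "spearman_prune", "forward_cox_select"]

log = logging.getLogger(__name__)

METRIC_FLOOR = 0.5
SPEARMAN_THRESHOLD = 0.9
MAX_FORWARD_FEATURES = 5


@dataclass(frozen=True)
class CvPlan:
    """Repeated k-fold partition shared across model builds."""

    n_repeats: int = 100
    n_folds: int = 5
    seed: int = 0

    def assignments(self, n_subjects: int) -> np.ndarray:
        """Fold id per subject, shape (n_repeats, n_subjects); deterministic."""
        rng = np.random.default_rng(self.seed)
        out = np.empty((self.n_repeats, n_subjects), dtype=np.int64)
        base = np.arange(n_subjects) % self.n_folds
        for r in range(self.n_repeats):
            out[r] = rng.permutation(base)
        return out

    def folds(self, n_subjects: int):
        """Yield (repeat, fold, train_idx, val_idx) over all repeats x folds."""
        for r, assign in enumerate(self.assignments(n_subjects)):
            for f in range(self.n_folds):
                val = np.where(assign == f)[0]
                train = np.where(assign != f)[0]
                yield r, f, train, val


@dataclass
class ScreenResult:
    """Per-feature mean validation metric with kept/dropped bookkeeping."""

    table: pd.DataFrame  # index: feature; columns: metric, n_folds_used, kept, reason

    @property
    def kept(self) -> list[str]:
        """Kept features in rank order (best mean metric first)."""
        t = self.table[self.table["kept"]]
        return list(t.sort_values("metric", ascending=False, kind="stable").index)

    def metric(self, feature: str) -> float:
        return float(self.table.loc[feature, "metric"])

    def copy(self) -> "ScreenResult":
        return ScreenResult(self.table.copy())


def _survival_outcome(y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(y, pd.DataFrame):
        return y["time"].to_numpy(float), y["event"].to_numpy(int)
    time, event = y
    return np.asarray(time, float), np.asarray(event, int)


def cv_univariate_screen(X: pd.DataFrame, y, plan: CvPlan,
                         task: str) -> ScreenResult:
    """Mean validation metric per feature over all repeats x folds.

    ``task`` is ``"os"``/``"dfs"`` (univariate Cox, C-index) or ``"margin"``
    (univariate logistic, AUC).  Raises if every fold is degenerate.
    """
    if task not in ("os", "dfs", "margin"):
        raise ValueError(f"unknown task {task!r}")
    n = len(X)
    feats = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    sums = np.zeros(len(feats))
    counts = np.zeros(len(feats), dtype=int)

    if task == "margin":
        labels = np.asarray(y, dtype=int)
        if len(np.unique(labels)) < 2:
            raise ValueError("both classes must be present")
        for _r, _f, tr, va in plan.folds(n):
            if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[va])) < 2:
                continue
            for j in range(len(feats)):
                xj = Xv[tr, j]
                if xj.std() == 0:
                    continue
                clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=200)
                clf.fit(xj[:, None], labels[tr])
                score = float(clf.coef_[0, 0]) * Xv[va, j]
                sums[j] += auc(labels[va], score)
                counts[j] += 1
    else:
        time, event = _survival_outcome(y)
        if event.sum() < 2:
            raise ValueError("need at least 2 events")
        for _r, _f, tr, va in plan.folds(n):
            if event[tr].sum() < 2 or event[va].sum() < 1:
                continue
            for j in range(len(feats)):
                xj = Xv[tr, j]
                if xj.std() == 0:
                    continue
                try:
                    beta, _ = cox_newton(xj[:, None], time[tr], event[tr])
                except (ConvergenceError, SeparationError, ValueError):
                    continue
                try:
                    c = concordance_index(time[va], event[va], beta[0] * Xv[va, j])
                except ValueError:
                    continue
                sums[j] += c
                counts[j] += 1

    if counts.max() == 0:
        raise ValueError("all cross-validation folds were degenerate")
    metric = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame({
        "metric": metric,
        "n_folds_used": counts,
        "kept": counts > 0,
        "reason": ["" if c > 0 else "all folds degenerate" for c in counts],
    }, index=feats)
    return ScreenResult(table)


def drop_below_half(sr: ScreenResult) -> ScreenResult:
    """Drop features whose mean validation metric is strictly below 0.5."""
    out = sr.copy()
    low = out.table["kept"] & (out.table["metric"] < METRIC_FLOOR)
    out.table.loc[low, "kept"] = False
    out.table.loc[low, "reason"] = f"metric < {METRIC_FLOOR}"
    return out


def spearman_prune(X: pd.DataFrame, sr: ScreenResult,
                   threshold: float = SPEARMAN_THRESHOLD) -> ScreenResult:
    """Walk kept features in rank order; drop any with |Spearman rho| >
    threshold against an already-retained better-ranked feature.

    A constant feature has undefined rho; it is treated as |rho| = 0 and
    logged.  The walk is order-dependent by design.
    """
    out = sr.copy()
    retained: list[str] = []
    for feat in sr.kept:
        x = X[feat].to_numpy(dtype=float)
        if x.std() == 0:
            log.info("constant feature %s: Spearman undefined, treated as 0", feat)
            retained.append(feat)
            continue
        drop = False
        for prev in retained:
            xp = X[prev].to_numpy(dtype=float)
            if xp.std() == 0:
                continue
            rho = stats.spearmanr(x, xp).statistic
            if np.isnan(rho):
                rho = 0.0
            if abs(rho) > threshold:
                out.table.loc[feat, "kept"] = False
                out.table.loc[feat, "reason"] = (
                    f"|spearman|>{threshold} vs {prev}")
                drop = True
                break
        if not drop:
            retained.append(feat)
    return out


def forward_cox_select(X: pd.DataFrame, time, event, plan: CvPlan,
                       max_k: int = MAX_FORWARD_FEATURES,
                       rank_order: list[str] | None = None,
                       ) -> tuple[list[str], CoxRiskModel]:
    """Greedy step-forward Cox selection by mean cross-validated C-index.

    At each step the candidate whose addition yields the highest mean
    validation C-index is added; ties break by screening rank (the order of
    ``rank_order``, default the column order).  The search stops when no
    candidate strictly improves the current mean C-index or ``max_k`` features
    are selected.  Candidates whose Cox fit fails on a fold are scored on the
    remaining folds; candidates failing everywhere are skipped with a log
    entry.  Returns the selected names and the model refit on all rows.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    candidates = list(rank_order) if rank_order is not None else list(X.columns)
    candidates = [c for c in candidates if c in X.columns]
    n = len(X)
    fold_list = [(tr, va) for _r, _f, tr, va in plan.folds(n)
                 if event[tr].sum() >= 2 and event[va].sum() >= 1]
    if not fold_list:
        raise ValueError("all folds degenerate")

    selected: list[str] = []
    best_score = -np.inf
    while len(selected) < max_k and candidates:
        step_best = None
        step_score = -np.inf
        for cand in candidates:
            cols = selected + [cand]
            M = X[cols].to_numpy(dtype=float)
            cs = []
            for tr, va in fold_list:
                if M[tr].std(axis=0).min() == 0:
                    continue
                try:
                    beta, _ = cox_newton(M[tr], time[tr], event[tr])
                    cs.append(concordance_index(time[va], event[va], M[va] @ beta))
                except (ConvergenceError, SeparationError, ValueError,
                        np.linalg.LinAlgError):
                    continue
            if not cs:
                log.info("candidate %s skipped: no usable folds", cand)
                continue
            mean_c = float(np.mean(cs))
            if mean_c > step_score:  # strict: ties keep the earlier-ranked one
                step_best, step_score = cand, mean_c
        if step_best is None or step_score <= best_score:
            break
        selected.append(step_best)
        candidates.remove(step_best)
        best_score = step_score

    if not selected:
        raise ValueError("forward selection found no usable feature")
    try:
        model = fit_cox(X[selected], time, event)
    except (ConvergenceError, SeparationError):
        # near-separating features on a small cohort: refit with a light ridge
        log.info("final Cox refit separated; retrying with ridge penalty")
        model = fit_cox(X[selected], time, event, ridge=0.1)
    return selected, model
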