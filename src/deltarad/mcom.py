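"""Multi-classifier, multi-objective, multi-modality margin prediction (mCOM).

The model predicts the probability of an R0 resection margin (positive class)
from one or more feature modalities (e.g. a clinical table and a delta-
radiomics table).  Per modality it trains three base classifiers -- a
margin-maximizing linear classifier with Platt-calibrated probabilities, a
logistic regression, and a linear discriminant with shrinkage-regularized
pooled covariance -- and fuses all member probabilities by a weighted
arithmetic mean.

Which features each modality uses, the classifier regularization strengths,
and the fusion weights are optimized jointly by an iterative multi-objective
immune algorithm (IMIA): a population of candidate solutions undergoes clonal
expansion biased toward Pareto non-dominance on (sensitivity, specificity)
measured on cross-validation folds, hypermutation of feature bitmasks,
hyperparameters, and weights, and an elitist archive of non-dominated
solutions with crowding-based truncation.  The final operating solution is
the archive member with the highest Youden's J (sensitivity + specificity
- 1).  LASSO-selected logistic-regression and linear-SVM baselines are
provided for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.svm import LinearSVC

from .evalio import auc
from .selection import CvPlan

__all__ = ["ImiaConfig", "McomSolution", "ParetoArchive", "train_base_classifiers",
           "fuse_probabilities", "imia_optimize", "ensemble_external_predict",
           "lasso_baselines", "McomResult"]

log = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("svm", "logistic", "lda")


# ---------------------------------------------------------------------------
# Base classifiers
# ---------------------------------------------------------------------------

class _PlattSVC:
    """Linear margin-maximizing classifier with a logistic (Platt) map from
    decision values to probabilities, fitted on the training fold."""

    def __init__(self, c: float):
        self.svc = LinearSVC(C=c, dual=False)
        self.platt = LogisticRegression(C=1.0, solver="liblinear", max_iter=200)

    def fit(self, X, y):
        self.svc.fit(X, y)
        d = self.svc.decision_function(X)
        self.platt.fit(d[:, None], y)
        return self

    def predict_proba(self, X):
        d = self.svc.decision_function(X)
        return self.platt.predict_proba(d[:, None])


def _make_classifier(name: str, params: dict):
    if name == "svm":
        return _PlattSVC(params["svm_c"])
    if name == "logistic":
        return LogisticRegression(C=params["logistic_c"], solver="liblinear",
                                  max_iter=500)
    if name == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr",
                                          shrinkage=params["lda_shrinkage"])
    raise ValueError(f"unknown classifier {name!r}")


# ---------------------------------------------------------------------------
# Solutions and archive
# ---------------------------------------------------------------------------

@dataclass
class McomSolution:
    """One candidate: per-modality feature bitmask, classifier hyperparameters,
    fusion weights over (modality, classifier) members, and the objective
    vector (sensitivity, specificity) measured on validation folds."""

    masks: dict[str, np.ndarray]
    params: dict[str, float]
    weights: np.ndarray
    objectives: tuple[float, float] | None = None
    cv_auc: float = float("nan")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("fusion weights must be >= 0 and sum to 1")
        for mod, m in self.masks.items():
            if not np.asarray(m).any():
                raise ValueError(f"modality {mod!r} has no selected feature")

    @property
    def youden_j(self) -> float:
        if self.objectives is None:
            return float("nan")
        return self.objectives[0] + self.objectives[1] - 1.0

    def to_dict(self) -> dict:
        return {
            "masks": {k: np.asarray(v).astype(int).tolist()
                      for k, v in self.masks.items()},
            "params": dict(self.params),
            "weights": self.weights.tolist(),
            "objectives": list(self.objectives) if self.objectives else None,
            "cv_auc": self.cv_auc,
        }


def _dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """a dominates b when a is >= in both objectives and > in at least one."""
    return a[0] >= b[0] and a[1] >= b[1] and (a[0] > b[0] or a[1] > b[1])


@dataclass
class ParetoArchive:
    """Bounded set of mutually non-dominated solutions."""

    cap: int = 30
    members: list[McomSolution] = field(default_factory=list)

    def update(self, candidates: list[McomSolution]) -> None:
        pool = self.members + [c for c in candidates if c.objectives is not None]
        nd = [s for s in pool
              if not any(_dominates(o.objectives, s.objectives)
                         for o in pool if o is not s)]
        # deduplicate identical objective vectors (keep first)
        seen: dict[tuple[float, float], McomSolution] = {}
        for s in nd:
            seen.setdefault(s.objectives, s)
        nd = list(seen.values())
        if len(nd) > self.cap:
            nd = _crowding_select(nd, self.cap)
        self.members = nd

    def best_by_youden(self) -> McomSolution:
        if not self.members:
            raise RuntimeError("Pareto archive is empty")
        return max(self.members, key=lambda s: s.youden_j)


def _crowding_select(solutions: list[McomSolution], k: int) -> list[McomSolution]:
    """Keep k solutions with the largest crowding distance on the objectives."""
    obj = np.array([s.objectives for s in solutions])
    n = len(solutions)
    dist = np.zeros(n)
    for d in range(2):
        order = np.argsort(obj[:, d], kind="stable")
        dist[order[0]] = dist[order[-1]] = np.inf
        span = obj[order[-1], d] - obj[order[0], d]
        if span > 0:
            for i in range(1, n - 1):
                dist[order[i]] += (obj[order[i + 1], d] - obj[order[i - 1], d]) / span
    keep = np.argsort(-dist, kind="stable")[:k]
    return [solutions[i] for i in sorted(keep)]


def _nondominated_rank(solutions: list[McomSolution]) -> np.ndarray:
    """0 = Pareto front, 1 = next front, ... (brute-force pairwise)."""
    objs = [s.objectives for s in solutions]
    n = len(objs)
    rank = np.full(n, -1)
    remaining = set(range(n))
    level = 0
    while remaining:
        front = [i for i in remaining
                 if not any(_dominates(objs[j], objs[i])
                            for j in remaining if j != i)]
        if not front:  # identical objectives everywhere
            front = list(remaining)
        for i in front:
            rank[i] = level
        remaining -= set(front)
        level += 1
    return rank


# ---------------------------------------------------------------------------
# Training / fusion
# ---------------------------------------------------------------------------

def train_base_classifiers(tables: dict[str, pd.DataFrame], labels,
                           solution: McomSolution) -> list[tuple]:
    """Fit the three-classifier triplet per modality on the solution's feature
    subset.  Returns members as (modality, classifier_name, fitted, columns),
    in the fixed modality-major order the fusion weights index."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in training labels")
    members = []
    for mod in tables:
        cols = list(np.asarray(tables[mod].columns)[solution.masks[mod]])
        X = tables[mod][cols].to_numpy(dtype=float)
        for name in CLASSIFIER_NAMES:
            clf = _make_classifier(name, solution.params)
            clf.fit(X, y)
            members.append((mod, name, clf, cols))
    return members


def _member_probabilities(members, tables: dict[str, pd.DataFrame]) -> np.ndarray:
    probs = []
    for mod, _name, clf, cols in members:
        missing = [c for c in cols if c not in tables[mod].columns]
        if missing:
            raise KeyError(f"features missing from modality {mod!r}: {missing}")
        X = tables[mod][cols].to_numpy(dtype=float)
        probs.append(clf.predict_proba(X)[:, 1])
    return np.vstack(probs)


def fuse_probabilities(member_probs: np.ndarray, weights) -> np.ndarray:
    """Weighted arithmetic mean of member probabilities (convex combination)."""
    member_probs = np.atleast_2d(np.asarray(member_probs, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if member_probs.shape[0] != weights.shape[0]:
        raise ValueError(
            f"{member_probs.shape[0]} member outputs but {weights.shape[0]} weights")
    return weights @ member_probs


# ---------------------------------------------------------------------------
# IMIA optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImiaConfig:
    """Evolution budget and operator rates (all config-exposed defaults)."""

    population: int = 50
    generations: int = 100
    archive_cap: int = 30
    init_feature_prob: float = 0.3
    bit_mutation_rate: float = 0.15
    param_mutation_sd: float = 0.6    # log-normal jitter on hyperparameters
    weight_mutation_sd: float = 0.25
    threshold: float = 0.5
    param_bounds: dict = field(default_factory=lambda: {
        "svm_c": (1e-2, 1e2), "logistic_c": (1e-2, 1e2),
        "lda_shrinkage": (1e-3, 1.0)})


def _random_solution(tables, cfg: ImiaConfig, rng) -> McomSolution:
    masks = {}
    for mod, df in tables.items():
        p = df.shape[1]
        m = rng.random(p) < cfg.init_feature_prob
        if not m.any():
            m[rng.integers(p)] = True
        masks[mod] = m
    params = {k: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
              for k, (lo, hi) in cfg.param_bounds.items()}
    w = rng.dirichlet(np.ones(len(tables) * len(CLASSIFIER_NAMES)))
    return McomSolution(masks, params, w)


def _mutate(sol: McomSolution, tables, cfg: ImiaConfig, rng) -> McomSolution:
    masks = {}
    for mod, m in sol.masks.items():
        m = m.copy()
        flips = rng.random(m.size) < cfg.bit_mutation_rate
        m ^= flips
        if not m.any():
            m[rng.integers(m.size)] = True
        masks[mod] = m
    params = {}
    for k, v in sol.params.items():
        lo, hi = cfg.param_bounds[k]
        params[k] = float(np.clip(v * np.exp(cfg.param_mutation_sd
                                             * rng.standard_normal()), lo, hi))
    w = sol.weights * np.exp(cfg.weight_mutation_sd
                             * rng.standard_normal(sol.weights.size))
    w = np.clip(w, 1e-9, None)
    w /= w.sum()
    return McomSolution(masks, params, w)


def _evaluate(sol: McomSolution, arrays: dict[str, np.ndarray], y, fold_list,
              cfg: ImiaConfig) -> None:
    """Objectives = mean fold-validation sensitivity and specificity of the
    fused probability at the operating threshold; also records mean AUC.

    Operates on pre-converted numpy arrays: this is the optimizer's inner loop.
    """
    sens, spec, aucs = [], [], []
    for tr, va in fold_list:
        member_probs = []
        try:
            for mod, arr in arrays.items():
                cols = np.flatnonzero(sol.masks[mod])
                Xtr = arr[np.ix_(tr, cols)]
                Xva = arr[np.ix_(va, cols)]
                for name in CLASSIFIER_NAMES:
                    clf = _make_classifier(name, sol.params)
                    clf.fit(Xtr, y[tr])
                    member_probs.append(clf.predict_proba(Xva)[:, 1])
        except (ValueError, np.linalg.LinAlgError):
            continue
        probs = sol.weights @ np.vstack(member_probs)
        yv = y[va]
        pred = probs >= cfg.threshold
        n_pos = int((yv == 1).sum())
        n_neg = int((yv == 0).sum())
        if n_pos == 0 or n_neg == 0:
            continue
        sens.append(float((pred & (yv == 1)).sum() / n_pos))
        spec.append(float((~pred & (yv == 0)).sum() / n_neg))
        aucs.append(auc(yv, probs))
    if sens:
        sol.objectives = (float(np.mean(sens)), float(np.mean(spec)))
        sol.cv_auc = float(np.nanmean(aucs))
    else:
        sol.objectives = (0.0, 0.0)


@dataclass
class McomResult:
    archive: ParetoArchive
    best: McomSolution
    fold_list: list


def imia_optimize(tables: dict[str, pd.DataFrame], labels, plan: CvPlan,
                  config: ImiaConfig | None = None,
                  seed: int | None = None) -> McomResult:
    """Evolve mCOM solutions by clonal expansion + hypermutation.

    ``labels``: 1 = R0 (positive class), 0 = R1.  Fold partitions come from
    ``plan``; folds missing a class are skipped.  Deterministic for a fixed
    seed (default: the plan's seed).
    """
    cfg = config or ImiaConfig()
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n = len(y)
    for mod, df in tables.items():
        if len(df) != n:
            raise ValueError(f"modality {mod!r} has {len(df)} rows, expected {n}")
    fold_list = [(tr, va) for _r, _f, tr, va in plan.folds(n)
                 if len(np.unique(y[tr])) == 2 and len(np.unique(y[va])) == 2]
    if not fold_list:
        raise ValueError("all folds degenerate")
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    arrays = {m: np.ascontiguousarray(df.to_numpy(dtype=np.float64))
              for m, df in tables.items()}

    with sklearn.config_context(assume_finite=True):
        population = [_random_solution(tables, cfg, rng)
                      for _ in range(cfg.population)]
        for sol in population:
            _evaluate(sol, arrays, y, fold_list, cfg)
        archive = ParetoArchive(cap=cfg.archive_cap)
        archive.update(population)

        for _gen in range(cfg.generations):
            ranks = _nondominated_rank(population)
            # clonal expansion biased toward non-dominance: parents drawn with
            # probability proportional to 1 / (1 + rank); archive elites join
            probs = 1.0 / (1.0 + ranks)
            probs = probs / probs.sum()
            n_clones = cfg.population
            parents_idx = rng.choice(len(population), size=n_clones, p=probs)
            parents = [population[i] for i in parents_idx]
            if archive.members:
                n_elite = min(len(archive.members), max(1, n_clones // 4))
                elite_idx = rng.choice(len(archive.members), size=n_elite)
                for j, ei in enumerate(elite_idx):
                    parents[j] = archive.members[ei]
            clones = [_mutate(p, tables, cfg, rng) for p in parents]
            for sol in clones:
                _evaluate(sol, arrays, y, fold_list, cfg)
            combined = population + clones
            ranks_c = _nondominated_rank(combined)
            order = np.argsort(ranks_c, kind="stable")
            survivors: list[McomSolution] = []
            level = 0
            while len(survivors) < cfg.population:
                front = [combined[i] for i in order if ranks_c[i] == level]
                if not front:
                    break
                if len(survivors) + len(front) <= cfg.population:
                    survivors.extend(front)
                else:
                    survivors.extend(
                        _crowding_select(front, cfg.population - len(survivors)))
                level += 1
            population = survivors
            archive.update(clones)

    if not archive.members:
        raise RuntimeError(
            f"Pareto archive empty after {cfg.generations} generations "
            f"({len(fold_list)} usable folds)")
    return McomResult(archive, archive.best_by_youden(), fold_list)


def ensemble_external_predict(models: list[tuple[list, np.ndarray]],
                              tables: dict[str, pd.DataFrame]) -> np.ndarray:
    """Average the fused probabilities of already-trained models on external
    subjects; no refitting happens here.

    ``models`` is a list of (members, weights) pairs as produced by
    :func:`train_base_classifiers` plus the owning solution's weights.
    """
    if not models:
        raise ValueError("need at least one trained model")
    preds = [fuse_probabilities(_member_probabilities(members, tables), w)
             for members, w in models]
    return np.mean(preds, axis=0)


# ---------------------------------------------------------------------------
# LASSO baselines
# ---------------------------------------------------------------------------

class _PrevalenceModel:
    """Intercept-only fallback when LASSO shrinks every coefficient to zero."""

    def __init__(self, prevalence: float):
        self.prevalence = float(prevalence)

    def predict_proba(self, X):
        p = np.full(len(X), self.prevalence)
        return np.column_stack([1 - p, p])


@dataclass
class LassoBaseline:
    selected: list[str]
    model: object

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if isinstance(self.model, _PrevalenceModel):
            return self.model.predict_proba(X)
        return self.model.predict_proba(X[self.selected].to_numpy(dtype=float))


def lasso_baselines(features: pd.DataFrame, labels, plan: CvPlan,
                    ) -> tuple[LassoBaseline, LassoBaseline]:
    """LASSO-logistic feature selection feeding (a) a logistic model and (b) a
    Platt-calibrated linear SVM.  The L1 penalty is chosen by inner CV."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = features.to_numpy(dtype=float)
    sel = LogisticRegressionCV(
        penalty="l1", solver="liblinear", Cs=10,
        cv=min(plan.n_folds, int(np.bincount(y).min())),
        random_state=plan.seed, max_iter=500)
    sel.fit(X, y)
    nonzero = np.flatnonzero(np.abs(sel.coef_[0]) > 1e-10)
    cols = [features.columns[i] for i in nonzero]
    if not cols:
        log.info("LASSO shrank all coefficients to zero; intercept-only model")
        prev = _PrevalenceModel(y.mean())
        return (LassoBaseline([], prev), LassoBaseline([], prev))
    Xs = features[cols].to_numpy(dtype=float)
    lr = LogisticRegression(C=1.0, solver="lbfgs", max_iter=500).fit(Xs, y)
    svm = _PlattSVC(c=1.0).fit(Xs, y)
    return (LassoBaseline(cols, lr), LassoBaseline(cols, svm))
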