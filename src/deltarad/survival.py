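"""Cox risk modelling, score fusion, risk stratification and survival metrics.

The Cox proportional-hazards fit maximizes the Efron-tie-corrected partial
likelihood with a dense Newton solver.  The solver is deliberately small and
vectorized because the selection module evaluates tens of thousands of
low-dimensional fits inside repeated cross-validation; its coefficients and
standard errors agree with lifelines' ``CoxPHFitter`` to numerical precision
(asserted in the test suite, where lifelines serves as the independent
reference).  Kaplan--Meier curves and the log-rank test are delegated to
lifelines directly.

Risk-score fusion across models z-scores each stream with its *training*
distribution before averaging: Cox linear predictors are scale-arbitrary
across models, so averaging raw scores would let one model's scale dominate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "CoxRiskModel", "RiskStratification", "ConvergenceError", "SeparationError",
    "cox_newton", "fit_cox", "fuse_scores", "concordance_index",
    "median_stratify", "label_at_horizon", "km_curve", "logrank",
]


class ConvergenceError(RuntimeError):
    """Newton iterations failed to converge."""


class SeparationError(RuntimeError):
    """Monotone likelihood (coefficients diverging); penalization advised."""


def _efron_quantities(beta, X, time, event):
    """Negative log partial likelihood, gradient and Hessian (Efron ties).

    Overflow from diverging coefficients yields non-finite values; the Newton
    driver treats those as failed steps, so float warnings are silenced.
    """
    with np.errstate(all="ignore"):
        return _efron_quantities_raw(beta, X, time, event)


def _efron_quantities_raw(beta, X, time, event):
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]
    # suffix sums: S*(k) = sum over i >= k (the risk set at ts[k])
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev = np.flatnonzero(es == 1)
    tev = ts[ev]
    starts = np.searchsorted(ts, tev, side="left")  # risk-set start per event
    uniq, inv, counts = np.unique(tev, return_inverse=True, return_counts=True)

    loglik = float(eta[ev].sum())
    grad = Xs[ev].sum(axis=0)
    hess = np.zeros((p, p))

    # untied event times: fully vectorized Breslow==Efron contribution
    singles = counts[inv] == 1
    ks = starts[singles]
    if ks.size:
        phi0 = S0[ks]
        a = S1[ks] / phi0[:, None]
        loglik -= float(np.log(phi0).sum())
        grad -= a.sum(axis=0)
        hess += (S2[ks] / phi0[:, None, None]).sum(axis=0) - a.T @ a

    # tied groups: Efron fractional adjustment, loop only over tied times
    for g in np.flatnonzero(counts > 1):
        members = ev[inv == g]
        k = int(np.searchsorted(ts, uniq[g], side="left"))
        d = len(members)
        s0d = w[members].sum()
        s1d = wx[members].sum(axis=0)
        s2d = wxx[members].sum(axis=0)
        frac = np.arange(d) / d
        phi0 = S0[k] - frac * s0d                              # (d,)
        phi1 = S1[k][None, :] - frac[:, None] * s1d            # (d, p)
        phi2 = S2[k][None, :, :] - frac[:, None, None] * s2d   # (d, p, p)
        b = phi1 / phi0[:, None]
        loglik -= float(np.log(phi0).sum())
        grad -= b.sum(axis=0)
        hess += (phi2 / phi0[:, None, None]).sum(axis=0) - b.T @ b

    return -loglik, -grad, hess


def cox_newton(X, time, event, tol: float = 1e-9, max_iter: int = 60,
               ridge: float = 0.0):
    """Fit Cox coefficients by Newton--Raphson with step halving.

    Returns ``(beta, cov)`` where ``cov`` is the inverse observed information.
    Raises :class:`SeparationError` when coefficients diverge (monotone
    likelihood) and :class:`ConvergenceError` on iteration failure.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    if event.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        raise ValueError("constant feature(s) passed to Cox fit")
    p = X.shape[1]
    beta = np.zeros(p)
    nll, grad, hess = _efron_quantities(beta, X, time, event)
    for _ in range(max_iter):
        if ridge > 0:
            hess = hess + ridge * np.eye(p)
            grad = grad + ridge * beta
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        new_beta = beta - step
        new_nll, new_grad, new_hess = _efron_quantities(new_beta, X, time, event)
        halvings = 0
        while ((not np.isfinite(new_nll)) or new_nll > nll + 1e-12) \
                and halvings < 30:
            step /= 2.0
            new_beta = beta - step
            new_nll, new_grad, new_hess = _efron_quantities(new_beta, X, time, event)
            halvings += 1
        if not np.isfinite(new_nll):
            raise SeparationError("partial likelihood overflow; coefficients "
                                  "diverging (likely separation)")
        delta = np.abs(new_beta - beta).max()
        beta, nll, grad, hess = new_beta, new_nll, new_grad, new_hess
        if np.abs(beta * sds).max() > 50:
            raise SeparationError(
                "coefficients diverging (likely separation); consider a ridge penalty")
        if delta < tol:
            cov = np.linalg.inv(hess + (ridge * np.eye(p) if ridge > 0 else 0.0))
            return beta, cov
    raise ConvergenceError(
        f"Newton did not converge in {max_iter} iterations (last step {delta:.2e})")


@dataclass
class CoxRiskModel:
    """Fitted Cox model plus the training risk-score distribution used for
    fusion z-scoring and median stratification."""

    features: list[str]
    coefficients: np.ndarray
    coef_se: np.ndarray
    score_mean: float
    score_sd: float
    score_median: float

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise KeyError(f"features missing from table: {missing}")
        return X[self.features].to_numpy(dtype=float) @ self.coefficients

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "coefficients": self.coefficients.tolist(),
            "coef_se": self.coef_se.tolist(),
            "score_mean": self.score_mean,
            "score_sd": self.score_sd,
            "score_median": self.score_median,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoxRiskModel":
        return cls(list(d["features"]), np.asarray(d["coefficients"]),
                   np.asarray(d["coef_se"]), float(d["score_mean"]),
                   float(d["score_sd"]), float(d["score_median"]))


def fit_cox(X: pd.DataFrame, time, event, ridge: float = 0.0) -> CoxRiskModel:
    """Fit a multivariate Cox model and record its training score distribution.

    Sample weights are not supported: duplicate rows at your own risk (this is
    a documented contract, not a silent reweighting).
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
        X.columns = [str(c) for c in X.columns]
    beta, cov = cox_newton(X.to_numpy(dtype=float), time, event, ridge=ridge)
    scores = X.to_numpy(dtype=float) @ beta
    return CoxRiskModel(
        features=[str(c) for c in X.columns],
        coefficients=beta,
        coef_se=np.sqrt(np.diag(cov)),
        score_mean=float(scores.mean()),
        score_sd=float(scores.std(ddof=0)),
        score_median=float(np.median(scores)),
    )


def fuse_scores(a, b, a_stats: tuple[float, float] | None = None,
                b_stats: tuple[float, float] | None = None) -> np.ndarray:
    """Average two risk-score streams after z-scoring with training stats.

    ``*_stats`` are (mean, sd) from each model's training distribution; when
    omitted they are computed from the scores given.  A zero-variance stream
    contributes 0 after centering.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score streams must cover the same subjects")

    def z(s, stats):
        mu, sd = stats if stats is not None else (s.mean(), s.std(ddof=0))
        if sd == 0:
            return np.zeros_like(s)
        return (s - mu) / sd

    return (z(a, a_stats) + z(b, b_stats)) / 2.0


def concordance_index(time, event, scores) -> float:
    """Harrell's C: higher score should mean shorter survival.

    A pair (i, j) is comparable when ``time_i < time_j`` and subject i had the
    event; concordant when ``score_i > score_j``; score ties count 0.5.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    scores = np.asarray(scores, dtype=float)
    lt = time[:, None] < time[None, :]
    comparable = lt & (event[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    gt = scores[:, None] > scores[None, :]
    eq = scores[:, None] == scores[None, :]
    concordant = (comparable & gt).sum() + 0.5 * (comparable & eq).sum()
    return float(concordant / n_comp)


@dataclass
class RiskStratification:
    scores: np.ndarray
    group: np.ndarray          # "high" / "low"
    threshold: float


def median_stratify(scores, threshold: float) -> RiskStratification:
    """Split subjects into high/low risk: high iff score > threshold.

    The threshold is the training-cohort median risk score and is reused
    unchanged on validation data.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    group = np.where(scores > threshold, "high", "low")
    return RiskStratification(scores, group, float(threshold))


def label_at_horizon(time, event, horizon_months: float) -> np.ndarray:
    """Binary outcome labels at a follow-up horizon (e.g. 12/24/36 months).

    ``event``: event occurred at or before the horizon; ``no_event``: followed
    beyond the horizon; ``excluded``: censored before the horizon with no
    event, so the status at the horizon is unknown.
    """
    if horizon_months <= 0:
        raise ValueError("horizon must be positive")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    out = np.where(time > horizon_months, "no_event",
                   np.where(event == 1, "event", "excluded"))
    return out


def km_curve(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate; returns (times, S(t)) step values."""
    time = np.asarray(time, dtype=float)
    if time.size == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(time, np.asarray(event, dtype=int))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    if len(np.atleast_1d(time_a)) == 0 or len(np.atleast_1d(time_b)) == 0:
        raise ValueError("empty group")
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a,
                      event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)
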