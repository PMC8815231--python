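"""Survival analysis primitives: Kaplan-Meier, log-rank, Cox proportional hazards.

Everything here is implemented directly from the standard estimators so that
each piece has an oracle-testable contract: the product-limit curve can be
checked against a brute-force product over risk sets, the log-rank statistic
against the Cox score test at beta = 0, and the Cox fit against an independent
partial-likelihood maximizer.

Times are in months throughout; an event indicator of 1 means death observed,
0 means right-censored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "km_estimate",
    "km_median",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "univariate_screen",
    "PrecomputedLogRank",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: identifier, follow-up time (months), event indicator."""

    sample: str
    time: float
    event: int

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample}")
        if self.event not in (0, 1):
            raise ValueError(f"event indicator must be 0/1, got {self.event}")


def _coerce(records) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of SurvivalRecord, a (times, events) pair, or a DataFrame."""
    if isinstance(records, tuple) and len(records) == 2:
        t, e = records
        return np.asarray(t, dtype=float), np.asarray(e, dtype=int)
    if isinstance(records, pd.DataFrame):
        return records["os_months"].to_numpy(float), records["os_event"].to_numpy(int)
    recs = list(records)
    if not recs:
        raise ValueError("no survival records provided")
    t = np.array([r.time for r in recs], dtype=float)
    e = np.array([r.event for r in recs], dtype=int)
    return t, e


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray  # ascending, only times with >=1 event
    survival: np.ndarray  # S(t) just after each event time, nonincreasing
    at_risk: np.ndarray  # number at risk just before each event time
    n_events: np.ndarray  # events at each event time

    def survival_at(self, t: float) -> float:
        """S(t); 1.0 before the first event time."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations reduce the risk set but contribute no factor to the
    product. Ties between events and censorings at the same time are resolved
    the standard way: events happen first (censored subjects at t are still at
    risk at t).
    """
    times, events = _coerce(records)
    if len(times) == 0:
        raise ValueError("no survival records provided")
    if events.sum() == 0 and np.all(times == 0):
        warnings.warn("all records censored at time zero; degenerate curve")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, starts = np.unique(t, return_index=True)
    d = np.add.reduceat(e.astype(float), starts)
    n_at_risk = len(t) - starts
    mask = d > 0
    et, dj, nj = uniq[mask], d[mask], n_at_risk[mask].astype(float)
    surv = np.cumprod(1.0 - dj / nj)
    return KMCurve(event_times=et, survival=surv, at_risk=nj.astype(int), n_events=dj.astype(int))


def km_median(curve: KMCurve) -> float:
    """Median survival: earliest event time with S(t) <= 0.5, inf if never reached."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.event_times[below[0]]) if len(below) else np.inf


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed_events: tuple[float, float]
    expected_events: tuple[float, float]


class PrecomputedLogRank:
    """Fast repeated two-group log-rank tests against a fixed cohort.

    The risk-set bookkeeping that depends only on (times, events) is done
    once; each call to :meth:`chi_square` only needs reductions over the
    group-membership indicator. Used heavily by the combination scan, where
    thousands of indicators are tested against one cohort.
    """

    def __init__(self, times: np.ndarray, events: np.ndarray):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=float)
        self.n = len(times)
        self._order = np.argsort(times, kind="stable")
        t = times[self._order]
        self._e = events[self._order]
        _, starts = np.unique(t, return_index=True)
        self._starts = starts
        self._d = np.add.reduceat(self._e, starts)  # events per distinct time
        self._n_risk = (self.n - starts).astype(float)
        self._total_events = float(self._e.sum())

    def statistics(self, indicator: np.ndarray):
        """Return (chi_square, O1, E1, V) for group 1 = indicator == 1."""
        z = np.asarray(indicator, dtype=float)[self._order]
        d1 = np.add.reduceat(self._e * z, self._starts)
        cz = np.concatenate(([0.0], np.cumsum(z)))
        n1 = z.sum() - cz[self._starts]
        dj, nj = self._d, self._n_risk
        mask = dj > 0
        dj, nj, n1j, d1j = dj[mask], nj[mask], n1[mask], d1[mask]
        p1 = n1j / nj
        e1 = dj * p1
        denom = np.maximum(nj - 1.0, 1.0)
        v = dj * p1 * (1.0 - p1) * (nj - dj) / denom
        V = float(v.sum())
        O1, E1 = float(d1j.sum()), float(e1.sum())
        chi = 0.0 if V <= 0 else (O1 - E1) ** 2 / V
        return chi, O1, E1, V

    def p_value(self, indicator: np.ndarray) -> float:
        chi, _, _, V = self.statistics(indicator)
        return 1.0 if V <= 0 else float(special.chdtrc(1, chi))


def logrank_test(group_a, group_b) -> LogRankResult:
    """Standard (unweighted) two-group log-rank test.

    At every distinct event time the expected group-A events come from the
    hypergeometric mean and the variance from the hypergeometric variance; the
    statistic (O - E)^2 / V is referred to chi-square with 1 df.
    """
    ta, ea = _coerce(group_a)
    tb, eb = _coerce(group_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    z = np.concatenate([np.ones_like(ta), np.zeros_like(tb)])
    pre = PrecomputedLogRank(times, events)
    chi, O1, E1, V = pre.statistics(z)
    total = float(events.sum())
    if V <= 0:
        warnings.warn("log-rank variance is zero (no comparable risk sets); p = 1")
        return LogRankResult(0.0, 1.0, (O1, total - O1), (E1, total - E1))
    p = float(stats.chi2.sf(chi, 1))
    return LogRankResult(float(chi), p, (O1, total - O1), (E1, total - E1))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    coefficients: Mapping[str, float]
    hazard_ratios: Mapping[str, float]
    standard_errors: Mapping[str, float]
    wald_p_values: Mapping[str, float]
    conf_int_lower: Mapping[str, float]  # 95% on the HR scale
    conf_int_upper: Mapping[str, float]
    n_iterations: int
    converged: bool
    log_partial_likelihood: float
    covariance: pd.DataFrame = field(repr=False, default=None)


def _cox_loglik(beta, t, e, X, ties):
    """Log partial likelihood with gradient and Hessian (Efron or Breslow).

    Arrays must be pre-sorted by ascending time. Returns (ll, grad, hess).
    """
    n, p = X.shape
    xb = X @ beta
    with np.errstate(over="ignore"):
        w = np.exp(np.clip(xb, -700, 700))
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)

    # Reverse cumulative sums: risk set at time t = all subjects with time >= t.
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    uniq, starts = np.unique(t, return_index=True)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    ends = np.append(starts[1:], n)
    for s, eidx in zip(starts, ends):
        ev = np.nonzero(e[s:eidx])[0] + s
        d = len(ev)
        if d == 0:
            continue
        s0, s1, s2 = S0[s], S1[s], S2[s]
        ll += float(xb[ev].sum())
        grad += X[ev].sum(axis=0)
        if ties == "breslow" or d == 1:
            for _ in range(d):
                z = s1 / s0
                ll -= np.log(s0)
                grad -= z
                hess -= s2 / s0 - np.outer(z, z)
        else:  # efron
            s0d = w[ev].sum()
            s1d = wx[ev].sum(axis=0)
            s2d = wxx[ev].sum(axis=0)
            for l in range(d):
                f = l / d
                phi0 = s0 - f * s0d
                phi1 = s1 - f * s1d
                phi2 = s2 - f * s2d
                z = phi1 / phi0
                ll -= np.log(phi0)
                grad -= z
                hess -= phi2 / phi0 - np.outer(z, z)
    return ll, grad, hess


def _prepare_cox_inputs(records, covariates):
    times, events = _coerce(records)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])]
    if X.shape[0] != len(times):
        raise ValueError("covariate rows must match number of survival records")
    if np.any(np.ptp(X, axis=0) == 0):
        const = [names[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
        raise ValueError(f"constant covariate column(s): {const}")
    return times, events, X, names


def cox_fit(records, covariates, ties: str = "efron", tol: float = 1e-7,
            max_iter: int = 50) -> CoxFit:
    """Newton-Raphson maximization of the Cox partial likelihood.

    Parameters
    ----------
    records : survival input (list of SurvivalRecord, (times, events), or a
        DataFrame with ``os_months`` / ``os_event``)
    covariates : numeric DataFrame or array, one row per record. Binary
        indicators or standardized continuous columns are expected; a constant
        column raises.
    ties : ``"efron"`` (default, better under heavy ties) or ``"breslow"``.
    tol : convergence when the gradient max-norm falls below this.
    max_iter : Newton iteration cap; step-halving guards each update.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    times, events, X, names = _prepare_cox_inputs(records, covariates)
    order = np.argsort(times, kind="stable")
    t, e, Xs = times[order], events[order], X[order]

    p = Xs.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik(beta, t, e, Xs, ties)
    converged = bool(np.max(np.abs(grad)) < tol)
    it = 0
    for it in range(1, (0 if converged else max_iter) + 1):
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular information matrix in Cox fit") from err
        # step-halving on partial-likelihood decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, hess_new = _cox_loglik(cand, t, e, Xs, ties)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        # gradient criterion, with a step-size fallback for datasets whose
        # gradient noise floor sits above tol
        if np.max(np.abs(grad)) < tol or np.max(np.abs(factor * step)) < 1e-12:
            converged = True
            break
    # a diverging coefficient with a vanishing gradient is monotone
    # likelihood (complete separation), not convergence
    if converged and np.max(np.abs(beta)) > 15:
        converged = False
    if not converged:
        warnings.warn(
            "Cox fit did not converge (possible monotone likelihood / "
            "complete separation); coefficients reported as-is")

    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular information matrix in Cox fit") from err
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pvals = 2.0 * stats.norm.sf(np.abs(zstat))
        zcrit = stats.norm.ppf(0.975)
        ci_lo = np.exp(beta - zcrit * se)
        ci_hi = np.exp(beta + zcrit * se)
    return CoxFit(
        coefficients=dict(zip(names, beta)),
        hazard_ratios=dict(zip(names, np.exp(beta))),
        standard_errors=dict(zip(names, se)),
        wald_p_values=dict(zip(names, pvals)),
        conf_int_lower=dict(zip(names, ci_lo)),
        conf_int_upper=dict(zip(names, ci_hi)),
        n_iterations=it,
        converged=converged,
        log_partial_likelihood=float(ll),
        covariance=pd.DataFrame(cov, index=names, columns=names),
    )


def cox_score_test(records, covariate, ties: str = "breslow") -> tuple[float, float]:
    """Score test of beta = 0 for a single covariate: (chi_square, p).

    With one binary covariate and no tied event times this is algebraically
    identical to the two-group log-rank statistic.
    """
    times, events, X, _ = _prepare_cox_inputs(records, covariate)
    order = np.argsort(times, kind="stable")
    t, e, Xs = times[order], events[order], X[order]
    _, grad, hess = _cox_loglik(np.zeros(X.shape[1]), t, e, Xs, ties)
    info = -hess
    chi = float(grad @ np.linalg.solve(info, grad))
    return chi, float(stats.chi2.sf(chi, X.shape[1]))


def univariate_screen(records, covariates: pd.DataFrame, alpha: float = 0.05,
                      ties: str = "efron") -> list[str]:
    """Univariate Cox screen: return covariates with Wald p < alpha.

    Intended as the explicit, optional pre-step before a multivariate fit in
    which only individually significant variables are carried forward.
    """
    keep = []
    for col in covariates.columns:
        fit = cox_fit(records, covariates[[col]], ties=ties)
        if fit.wald_p_values[col] < alpha:
            keep.append(col)
    return keep
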