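"""Survival primitives composed by the pipeline.

The workhorse is :class:`CoxPH`, a Cox proportional-hazards model fitted by
Newton-Raphson on the Efron-tie-corrected partial likelihood.  It is written
directly on numpy because the feature-selection loop refits Cox models tens of
thousands of times; lifelines serves as the cross-check oracle in the test
suite rather than the inner-loop fitter.  Kaplan-Meier estimation and the
log-rank test delegate to lifelines.

Time-dependent ROC curves use the Kaplan-Meier estimator of Heagerty, Lumley
& Pepe (cumulative cases, dynamic controls): at horizon ``t`` a case is a
subject with an event at or before ``t`` and a control is a subject still
event-free past ``t``; censoring is handled through KM weighting rather than
by discarding subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "CoxPH",
    "CoxPHResults",
    "TimeDepROC",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "backward_eliminate",
    "survival_roc",
    "optimal_cutoff",
    "auc_bootstrap_ci",
    "likelihood_ratio_test",
]


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------


class ConvergenceError(RuntimeError):
    """Raised when the partial-likelihood Newton iteration fails."""


@dataclass
class CoxPHResults:
    """Fitted Cox model: coefficients, their uncertainty and diagnostics.

    ``hazard_ratios`` is ``exp(params)`` elementwise, the scale reported in
    clinical tables.  ``loglik_null`` is the partial log-likelihood at
    ``beta = 0`` and feeds the likelihood-ratio test.
    """

    covariates: list[str]
    params: np.ndarray
    bse: np.ndarray
    loglik: float
    loglik_null: float
    nobs: int
    n_events: int
    converged: bool

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def predict_linear(self, X: np.ndarray) -> np.ndarray:
        """Linear predictor (risk score) ``X @ beta`` with no baseline term."""
        return np.asarray(X, dtype=float) @ self.params

    def summary(self) -> pd.DataFrame:
        """Coefficient table in the clinical-reporting layout."""
        return pd.DataFrame(
            {
                "Coef": self.params,
                "SE": self.bse,
                "P": self.pvalues,
                "HR": self.hazard_ratios,
            },
            index=pd.Index(self.covariates, name="ID"),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CoxPHResults: {len(self.covariates)} covariates, "
            f"{self.n_events}/{self.nobs} events, loglik={self.loglik:.3f}>"
        )


class CoxPH:
    """Cox proportional-hazards model on right-censored data.

    Parameters
    ----------
    time, event : array-like
        Follow-up time and event indicator (1 = event observed).
    X : ndarray or DataFrame, shape (n, p)
        Covariate matrix.  Column names are taken from the DataFrame or the
        ``names`` argument.

    Ties among event times are handled with the Efron approximation.  The
    implementation vectorises the common no-tied-events case with reverse
    cumulative sums and falls back to a per-tie-group loop otherwise.
    """

    def __init__(self, time, event, X, names: list[str] | None = None):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(time):
            X = X.T
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        self.X = X
        self.names = list(names) if names is not None else [
            f"x{i}" for i in range(X.shape[1])
        ]
        if self.time.shape[0] != self.X.shape[0]:
            raise ValueError("time and X have incompatible lengths")
        if self.event.sum() < 1:
            raise ValueError("Cox model needs at least one observed event")
        constant = np.ptp(self.X, axis=0) == 0
        if constant.any():
            bad = [n for n, c in zip(self.names, constant) if c]
            raise ValueError(f"constant covariates cannot be fit: {bad}")
        # sort ascending by time once; tie groups share a risk set
        order = np.argsort(self.time, kind="stable")
        self._t = self.time[order]
        self._e = self.event[order]
        self._x = self.X[order]
        ev_times = self._t[self._e == 1]
        self._uniq_ev, counts = np.unique(ev_times, return_counts=True)
        self._tied = bool((counts > 1).any())
        # first index of each event-time's risk group in the sorted arrays
        self._risk_start = np.searchsorted(self._t, self._uniq_ev, side="left")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        duration_col: str,
        event_col: str,
        covariates: list[str] | None = None,
    ) -> "CoxPH":
        if covariates is None:
            covariates = [c for c in df.columns if c not in (duration_col, event_col)]
        return cls(df[duration_col], df[event_col], df[covariates])

    # -- partial likelihood ------------------------------------------------

    def _loglik(self, beta: np.ndarray, x: np.ndarray) -> float:
        """Partial log-likelihood only (cheap path for step-halving)."""
        e, t = self._e, self._t
        eta = np.clip(x @ beta, -200, 200)
        theta = np.exp(eta)
        r0 = np.cumsum(theta[::-1])[::-1]
        ev = e == 1
        ll = float(eta[ev].sum())
        if not self._tied:
            return ll - float(np.log(r0[self._risk_start]).sum())
        ev_idx = np.flatnonzero(ev)
        ev_t = t[ev_idx]
        lo = np.searchsorted(ev_t, self._uniq_ev, side="left")
        hi = np.searchsorted(ev_t, self._uniq_ev, side="right")
        for a, b, fi in zip(lo, hi, self._risk_start):
            d = b - a
            s0d = theta[ev_idx[a:b]].sum()
            ll -= float(np.log(r0[fi] - (np.arange(d) / d) * s0d).sum())
        return ll

    def _loglik_grad_info(self, beta: np.ndarray, x: np.ndarray):
        e, t = self._e, self._t
        n, p = x.shape
        eta = x @ beta
        eta = np.clip(eta, -200, 200)
        theta = np.exp(eta)

        ev = e == 1
        ll = float(eta[ev].sum())
        grad = x[ev].sum(axis=0)
        info = np.zeros((p, p))

        if not self._tied:
            fi = self._risk_start
            aw = theta[:, None] * x
            if p >= 10:
                # risk-set sums via suffix sums of per-event segments;
                # BLAS matmuls beat the O(n p^2) einsum+cumsum at larger p
                d0 = np.add.reduceat(theta, fi)[::-1].cumsum()[::-1]
                d1 = np.add.reduceat(aw, fi, axis=0)[::-1].cumsum(axis=0)[::-1]
                bounds = np.append(fi, n)
                seg = np.empty((fi.size, p, p))
                for k in range(fi.size):
                    a, b = bounds[k], bounds[k + 1]
                    seg[k] = x[a:b].T @ aw[a:b]
                d2 = seg[::-1].cumsum(axis=0)[::-1]
            else:
                r0 = np.cumsum(theta[::-1])[::-1]
                r1 = np.cumsum(aw[::-1], axis=0)[::-1]
                xtx = np.einsum("i,ij,ik->ijk", theta, x, x)
                r2 = np.cumsum(xtx[::-1], axis=0)[::-1]
                d0, d1, d2 = r0[fi], r1[fi], r2[fi]
            ll -= float(np.log(d0).sum())
            w1 = d1 / d0[:, None]
            grad -= w1.sum(axis=0)
            info += np.einsum("ijk,i->jk", d2, 1.0 / d0)
            info -= np.einsum("ij,ik->jk", w1, w1)
            return ll, grad, info
        # tied path below still uses full reverse cumulative sums
        r0 = np.cumsum(theta[::-1])[::-1]
        r1 = np.cumsum((theta[:, None] * x)[::-1], axis=0)[::-1]
        xtx = np.einsum("i,ij,ik->ijk", theta, x, x)
        r2 = np.cumsum(xtx[::-1], axis=0)[::-1]

        # Efron correction for tied event times, vectorised over the tie rank
        ev_idx = np.flatnonzero(ev)
        ev_t = t[ev_idx]
        lo = np.searchsorted(ev_t, self._uniq_ev, side="left")
        hi = np.searchsorted(ev_t, self._uniq_ev, side="right")
        for a, b, fi in zip(lo, hi, self._risk_start):
            members = ev_idx[a:b]
            d = b - a
            thm = theta[members]
            xm = x[members]
            s0d = thm.sum()
            s1d = thm @ xm
            s2d = np.einsum("i,ij,ik->jk", thm, xm, xm)
            frac = np.arange(d) / d
            den = r0[fi] - frac * s0d                        # (d,)
            num1 = r1[fi][None, :] - frac[:, None] * s1d     # (d, p)
            inv = 1.0 / den
            ll -= float(np.log(den).sum())
            grad -= inv @ num1
            info += r2[fi] * inv.sum() - s2d * (frac * inv).sum()
            info -= np.einsum("lj,lk,l->jk", num1, num1, inv**2)
        return ll, grad, info

    def fit(
        self,
        maxiter: int = 100,
        tol: float = 1e-9,
        raise_on_fail: bool = False,
        start: np.ndarray | None = None,
        cols: list[int] | None = None,
    ) -> CoxPHResults:
        """Maximise the partial likelihood by damped Newton-Raphson.

        ``start`` warm-starts the iteration and ``cols`` restricts the model
        to a covariate subset without re-sorting the data — both are used by
        backward elimination, where the previous model minus one column is
        an excellent initial guess.
        """
        x = self._x if cols is None else np.ascontiguousarray(self._x[:, cols])
        names = self.names if cols is None else [self.names[i] for i in cols]
        p = x.shape[1]
        beta = np.zeros(p) if start is None else np.asarray(start, float).copy()
        ll_null = self._loglik(np.zeros(p), x)
        ll_prev = -np.inf
        converged = False
        for _ in range(maxiter):
            ll, grad, info = self._loglik_grad_info(beta, x)
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                break
            # step-halve until the likelihood does not decrease
            scale = 1.0
            ll_new = -np.inf
            for _ in range(30):
                cand = beta + scale * step
                ll_new = self._loglik(cand, x)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            if not np.isfinite(ll_new):
                break
            beta = beta + scale * step
            if abs(ll_new - ll_prev) < tol and np.max(np.abs(scale * step)) < 1e-6:
                converged = True
                ll_prev = ll_new
                break
            ll_prev = ll_new
        # monotone likelihood / separation: effect per covariate sd this large
        # means the partial likelihood has no interior maximum
        if np.max(np.abs(beta) * x.std(axis=0)) > 20:
            converged = False
        if not converged and raise_on_fail:
            raise ConvergenceError("Cox partial likelihood did not converge")
        ll, grad, info = self._loglik_grad_info(beta, x)
        try:
            cov = np.linalg.inv(info)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            bse = np.full(p, np.nan)
            converged = False
        return CoxPHResults(
            covariates=list(names),
            params=beta,
            bse=bse,
            loglik=float(ll),
            loglik_null=float(ll_null),
            nobs=len(self._t),
            n_events=int(self._e.sum()),
            converged=converged,
        )


def cox_fit(
    time,
    event,
    X,
    names: list[str] | None = None,
) -> CoxPHResults:
    """Fit a Cox proportional-hazards model (Efron ties) and return results."""
    return CoxPH(time, event, X, names=names).fit()


def backward_eliminate(
    time,
    event,
    X: pd.DataFrame,
    forced: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[list[str], CoxPHResults | None]:
    """Backward elimination on Wald p-values at cutoff ``alpha``.

    Iteratively refits after dropping the non-forced covariate with the
    largest p-value above ``alpha``; forced covariates are never dropped.
    Returns the retained covariate names (forced ones included) and the final
    fit, or ``(forced, None)`` when nothing (or only forced covariates that
    cannot be fit) remains.  A non-convergent fit propagates as
    ``converged=False`` on the result.
    """
    forced = list(forced or [])
    names = list(X.columns)
    arr = X.to_numpy(dtype=float)
    # constant columns carry no information; a constant forced covariate
    # makes the model infeasible on this (sub)sample
    const = np.ptp(arr, axis=0) == 0
    if any(const[names.index(f)] for f in forced):
        return forced, None
    usable = [i for i in range(len(names)) if not const[i]]
    if not usable:
        return forced, None
    try:
        model = CoxPH(
            time, event, arr[:, usable], names=[names[i] for i in usable]
        )
    except ValueError:
        return forced, None
    current = list(range(len(usable)))
    start = None
    while True:
        try:
            fit = model.fit(cols=current, start=start)
        except np.linalg.LinAlgError:
            return forced, None
        pvals = dict(zip(fit.covariates, fit.pvalues))
        droppable = {
            j: pvals[model.names[j]] for j in current if model.names[j] not in forced
        }
        if not droppable:
            return [model.names[j] for j in current], fit
        worst = max(droppable, key=lambda j: (droppable[j], model.names[j]))
        if not np.isfinite(droppable[worst]) or droppable[worst] > alpha:
            keep = [j for j in current if j != worst]
            if not keep:
                return forced, None
            start = np.array(
                [fit.params[current.index(j)] for j in keep]
            )
            current = keep
            continue
        return [model.names[j] for j in current], fit


def likelihood_ratio_test(nested: CoxPHResults, full: CoxPHResults) -> float:
    """P-value of the likelihood-ratio test of a nested against a full fit."""
    if not set(nested.covariates) <= set(full.covariates):
        raise ValueError("models are not nested")
    df = len(full.covariates) - len(nested.covariates)
    if df == 0:
        return 1.0
    lr = 2.0 * (full.loglik - nested.loglik)
    return float(stats.chi2.sf(max(lr, 0.0), df))


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


def km_estimate(time, event) -> KaplanMeierFitter:
    """Product-limit survival estimate with at-risk counts.

    Returns a fitted :class:`lifelines.KaplanMeierFitter`; the step function
    is ``.survival_function_`` and at-risk counts come from ``.event_table``.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, float), np.asarray(event, int))
    return kmf


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group 1-df log-rank test; returns (chi-square statistic, p)."""
    ea, eb = np.asarray(event_a, int), np.asarray(event_b, int)
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(time_a, time_b, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _km_survival_at(time: np.ndarray, event: np.ndarray, t: float) -> float:
    """S(t) by the product-limit formula; fast numpy path for ROC internals."""
    if time.size == 0:
        return 1.0
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    uniq = np.unique(ts[(es == 1) & (ts <= t)])
    if uniq.size == 0:
        return 1.0
    n = ts.size
    # at risk just before u: count of time >= u
    at_risk = n - np.searchsorted(ts, uniq, side="left")
    deaths = np.array([((ts == u) & (es == 1)).sum() for u in uniq])
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.prod(1.0 - deaths / at_risk)
    return float(s)


# ---------------------------------------------------------------------------
# Time-dependent ROC
# ---------------------------------------------------------------------------


@dataclass
class TimeDepROC:
    """Cumulative-case / dynamic-control ROC at a fixed survival horizon."""

    horizon: float
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_cases: int
    n_controls: int


def survival_roc(marker, time, event, t: float, method: str = "KM") -> TimeDepROC:
    """Time-dependent ROC at horizon ``t`` with Kaplan-Meier weighting.

    Cases are subjects with an event by ``t``; controls are subjects
    event-free beyond ``t``.  Sensitivity and specificity follow the
    KM estimator of Heagerty, Lumley & Pepe:

        sens(c) = [1 - S(t | X > c)] P(X > c) / [1 - S(t)]
        spec(c) = 1 - S(t | X > c) P(X > c) / S(t)

    With no censoring before ``t`` both reduce to the empirical ROC and the
    trapezoid AUC equals pairwise case/control concordance.
    """
    if method != "KM":
        raise ValueError("only the KM estimator variant is implemented")
    marker = np.asarray(marker, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s_t = _km_survival_at(time, event, t)
    if s_t >= 1.0:
        raise ValueError(f"no cases observed by horizon t={t}; AUC undefined")
    n = marker.size
    n_cases = int(((time <= t) & (event == 1)).sum())
    n_controls = int((time > t).sum())
    uniq = np.unique(marker)
    # cutoff grid: below the smallest value, all observed values
    cutoffs = np.concatenate(([uniq[0] - 1.0], uniq))
    sens = np.empty(cutoffs.size)
    spec = np.empty(cutoffs.size)
    for i, c in enumerate(cutoffs):
        above = marker > c
        p_above = above.mean()
        if p_above == 0:
            joint = 0.0
        else:
            joint = _km_survival_at(time[above], event[above], t) * p_above
        sens[i] = ((p_above - joint) / (1.0 - s_t)) if s_t < 1 else 0.0
        spec[i] = 1.0 - joint / s_t
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)
    # traverse the curve by decreasing cutoff: (fpr, sens) walk from (0,0)
    # to (1,1); sorting by fpr instead would scramble vertical segments
    fpr = (1.0 - spec)[::-1]
    auc = float(np.trapezoid(sens[::-1], fpr))
    return TimeDepROC(
        horizon=float(t),
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def optimal_cutoff(roc: TimeDepROC) -> float:
    """Cutoff maximising the Youden index (sens + spec - 1); ties -> smaller."""
    youden = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(youden == youden.max())
    return float(roc.cutoffs[best.min()])


def auc_bootstrap_ci(
    marker,
    time,
    event,
    t: float,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """BCa bootstrap confidence interval for the time-dependent AUC.

    Subjects are resampled jointly (marker, time, event); degenerate
    resamples (no cases by ``t``) are treated as missing by the statistic.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    marker = np.asarray(marker, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)

    def stat(m, tt, ee):
        try:
            return survival_roc(m, tt, ee, t).auc
        except ValueError:
            return np.nan

    rng = np.random.default_rng(seed)
    res = stats.bootstrap(
        (marker, time, event),
        stat,
        n_resamples=n_boot,
        paired=True,
        vectorized=False,
        confidence_level=level,
        method="BCa",
        rng=rng,
    )
    lo = float(np.clip(res.confidence_interval.low, 0.0, 1.0))
    hi = float(np.clip(res.confidence_interval.high, 0.0, 1.0))
    return lo, hi
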