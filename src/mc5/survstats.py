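"""Survival machinery: Kaplan-Meier, log-rank, Cox regression, cutpoints.

Cox models maximize the Breslow partial likelihood by Newton-Raphson
(tolerance 1e-8, at most 50 iterations).  Monotone-likelihood fits
(perfect separation) are returned flagged with an infinite-beta sentinel
rather than raised.  The optimal score cutpoint is the maximally
selected rank statistic: the standardized two-group log-rank statistic
evaluated at every admissible midpoint between consecutive sorted
unique score values, with both resulting groups at least ``minprop`` of
the cohort.  The maximally selected statistic's p-value is not corrected
for multiple cutpoint testing; downstream survival comparisons report
the ordinary log-rank test on the resulting groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KMCurve:
    """Product-limit survival estimate at each distinct event time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    beta: float
    se: float
    z: float
    p: float
    hr: float
    ci_low: float
    ci_high: float
    converged: bool
    name: str = ""


@dataclass
class CutpointResult:
    cutoff: float
    statistic: float  # standardized log-rank statistic at the cutoff
    minprop: float
    n_high: int
    n_low: int


def kaplan_meier(os_time: np.ndarray, os_event: np.ndarray) -> KMCurve:
    """Product-limit estimator; events precede censorings at tied times."""
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=float)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    event_times = np.unique(t[e == 1])
    surv, n_at_risk, d_events = [], [], []
    s = 1.0
    for et in event_times:
        n_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        n_at_risk.append(n_risk)
        d_events.append(d)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(n_at_risk),
        events=np.asarray(d_events),
    )


def _logrank_oe(
    groups: np.ndarray, os_time: np.ndarray, os_event: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed, expected and hypergeometric variance per group (k groups)."""
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=float)
    g = np.asarray(groups)
    levels = np.unique(g)
    k = len(levels)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        n = at_risk.sum()
        d = ((t == et) & (e == 1)).sum()
        n_g = np.array([(at_risk & (g == lv)).sum() for lv in levels], dtype=float)
        d_g = np.array([((t == et) & (e == 1) & (g == lv)).sum() for lv in levels], dtype=float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            c = d * (n - d) / (n - 1)
            for a in range(k):
                for b in range(k):
                    if a == b:
                        V[a, b] += c * n_g[a] * (n - n_g[a]) / n**2
                    else:
                        V[a, b] -= c * n_g[a] * n_g[b] / n**2
    return O, E, V


def logrank_test(
    groups: np.ndarray | pd.Series, os_time: np.ndarray, os_event: np.ndarray
) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi-square, p) with k-1 df."""
    g = np.asarray(groups)
    levels, counts = np.unique(g, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    if np.asarray(os_event, dtype=float).sum() < 1:
        raise ValueError("need at least one event")
    O, E, V = _logrank_oe(g, os_time, os_event)
    k = len(levels)
    u = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        chi2 = float(u @ np.linalg.solve(Vsub, u))
    except np.linalg.LinAlgError:
        chi2 = 0.0
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=k - 1)) if chi2 > 0 else 1.0
    return chi2, p


def logrank_z(groups: np.ndarray, os_time: np.ndarray, os_event: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (O-E)/sqrt(V) for group order."""
    O, E, V = _logrank_oe(groups, os_time, os_event)
    v = V[0, 0]
    return float((O[0] - E[0]) / np.sqrt(v)) if v > 0 else 0.0


def _cox_newton(
    X: np.ndarray, os_time: np.ndarray, os_event: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson on the Breslow partial log-likelihood.

    Returns (beta, covariance, converged).  Non-convergence (monotone
    likelihood) is reported via the flag with the last iterate.
    """
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=float)
    order = np.argsort(-t, kind="mergesort")  # decreasing time: risk sets by cumsum
    Xs = X[order]
    ts = t[order]
    es = e[order]
    n, p = Xs.shape
    beta = np.zeros(p)
    cov = np.full((p, p), np.nan)
    for it in range(max_iter):
        eta = Xs @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w[:, None] * Xs, axis=0)
        s2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
        # Breslow: all subjects with time >= event time are at risk; ties at
        # the event time share the risk-set sums at the last tied index
        last_idx = np.searchsorted(-ts, -ts, side="right") - 1
        S0 = s0[last_idx]
        S1 = s1[last_idx]
        S2 = s2[last_idx]
        ev = es == 1
        grad = (Xs[ev] - S1[ev] / S0[ev, None]).sum(axis=0)
        mu = S1[ev] / S0[ev, None]
        hess = -(S2[ev] / S0[ev, None, None] - mu[:, :, None] * mu[:, None, :]).sum(axis=0)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, cov, False
        beta_new = beta - step
        if np.abs(beta_new - beta).max() > 50:
            return beta_new, cov, False  # runaway: monotone likelihood
        beta = beta_new
        if np.abs(step).max() < tol:
            try:
                cov = np.linalg.inv(-hess)
            except np.linalg.LinAlgError:
                return beta, cov, False
            return beta, cov, True
    return beta, cov, False


def _fit_to_cox(beta: float, var: float, converged: bool, name: str = "") -> CoxFit:
    if not converged or not np.isfinite(var) or var <= 0:
        return CoxFit(
            beta=np.inf if beta > 0 else -np.inf,
            se=np.inf,
            z=np.nan,
            p=np.nan,
            hr=np.inf if beta > 0 else 0.0,
            ci_low=np.nan,
            ci_high=np.nan,
            converged=False,
            name=name,
        )
    se = float(np.sqrt(var))
    z = beta / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return CoxFit(
        beta=float(beta),
        se=se,
        z=float(z),
        p=p,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        converged=True,
        name=name,
    )


def univariate_cox(x: np.ndarray, os_time: np.ndarray, os_event: np.ndarray) -> CoxFit:
    """Univariate Cox proportional-hazards fit (Breslow ties, Wald p)."""
    x = np.asarray(x, dtype=float)
    e = np.asarray(os_event, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariate must be finite")
    if e.sum() < 2:
        raise ValueError("need at least 2 events")
    beta, cov, conv = _cox_newton(x[:, None], os_time, os_event)
    return _fit_to_cox(beta[0], cov[0, 0] if conv else np.nan, conv)


def multivariable_cox(
    covariates: pd.DataFrame, os_time: np.ndarray, os_event: np.ndarray
) -> list[CoxFit]:
    """Multivariable Cox fit; categoricals are one-hot encoded (first level dropped).

    Raises on a rank-deficient design, naming the aliased columns.
    """
    X_df = pd.get_dummies(covariates, drop_first=True).astype(float)
    X = X_df.to_numpy()
    if np.asarray(os_event, dtype=float).sum() < 10:
        raise ValueError("need at least 10 events for a multivariable fit")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < X.shape[1]:
        # identify aliased columns via QR pivoting on the centered design
        _, r = np.linalg.qr(X - X.mean(axis=0))
        diag = np.abs(np.diag(r))
        aliased = [X_df.columns[i] for i in range(len(diag)) if diag[i] < 1e-8 * diag.max()]
        raise ValueError(f"collinear design; aliased columns: {aliased or list(X_df.columns)}")
    beta, cov, conv = _cox_newton(X, os_time, os_event)
    return [
        _fit_to_cox(beta[j], cov[j, j] if conv else np.nan, conv, name=str(X_df.columns[j]))
        for j in range(X.shape[1])
    ]


def optimal_cutpoint(
    score: np.ndarray, os_time: np.ndarray, os_event: np.ndarray, minprop: float = 0.1
) -> CutpointResult:
    """Maximally selected log-rank cutpoint over admissible midpoints.

    Ties in |statistic| resolve to the lower cutoff.
    """
    s = np.asarray(score, dtype=float)
    n = s.size
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct score values")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    best: tuple[float, float] | None = None
    for cut in mids:
        high = s > cut
        n_high = int(high.sum())
        n_low = n - n_high
        if min(n_high, n_low) < minprop * n:
            continue
        z = logrank_z(np.where(high, "high", "low"), os_time, os_event)
        if best is None or abs(z) > abs(best[1]) + 1e-12:
            best = (float(cut), z)
    if best is None:
        raise ValueError("no admissible split under minprop constraint")
    cut, z = best
    n_high = int((s > cut).sum())
    return CutpointResult(cutoff=cut, statistic=z, minprop=minprop, n_high=n_high, n_low=n - n_high)


def relabel_by_prognosis(
    labels: pd.Series, os_time: np.ndarray, os_event: np.ndarray
) -> pd.Series:
    """Renumber two cluster labels so cluster 1 is the better-prognosis group.

    Consensus assignments carry arbitrary numbering; downstream
    conventions (score orientation, specific-DMP direction) treat
    cluster 1 as the favorable subtype, so the labels are anchored by
    the sign of the log hazard of cluster 2 vs cluster 1.
    """
    lv = np.unique(labels.to_numpy())
    if len(lv) != 2:
        return labels
    x = (labels.to_numpy() == lv[1]).astype(float)
    fit = univariate_cox(x, os_time, os_event)
    beta = fit.beta if np.isfinite(fit.beta) else (1.0 if fit.hr > 1 else -1.0)
    if beta < 0:  # group coded 1 (lv[1]) has the better prognosis: swap
        return pd.Series(np.where(labels.to_numpy() == lv[0], 2, 1), index=labels.index, name=labels.name)
    return pd.Series(np.where(labels.to_numpy() == lv[0], 1, 2), index=labels.index, name=labels.name)


def dichotomize(score: np.ndarray | pd.Series, cutoff: float) -> np.ndarray:
    """Labels: score > cutoff -> "high", else "low" (strict)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    s = np.asarray(score, dtype=float)
    return np.where(s > cutoff, "high", "low")
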