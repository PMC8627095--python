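"""Empirical-Bayes moderated two-group differential expression.

Per gene a two-group linear model is fit on log2 expression; residual
variances are shrunk toward a pooled prior by an inverse-chi-square
empirical-Bayes model whose prior degrees of freedom d0 and scale s0^2
are estimated by method of moments on the log residual variances.  The
moderated t statistic uses the posterior variance and d_g + d0 degrees
of freedom; p-values are adjusted by Benjamini-Hochberg.  Genes pass the
signature filter when adjusted P < 0.001 and |log2FC| > 1.5 (strict).

Direction convention: positive log2fc means higher in group 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_core import ExpressionMatrix, logger


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (monotone, tie-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse, Smyth-style)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) from residual variances with df residual dof each.

    Moments of z = log(s2): E[z] = log(s0^2) + psi(df/2) - log(df/2)
    + log(d0/2) - psi(d0/2), Var[z] = psi'(df/2) + psi'(d0/2).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    var_e = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if var_e <= 0:
        # no excess dispersion: complete shrinkage to the common variance,
        # estimated by pooling residual sums of squares across genes
        d0 = np.inf
        s0_2 = float(np.mean(s2[ok]))
    else:
        d0 = 2.0 * _trigamma_inverse(var_e)
        s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t_test(
    expr_log: ExpressionMatrix | pd.DataFrame,
    groups: pd.Series | np.ndarray,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated t-test of group 2 vs group 1 per gene.

    Parameters
    ----------
    expr_log
        Gene-by-sample matrix on log2 scale.
    groups
        Per-sample labels with exactly two levels; the lower-sorting
        level is "group 1".
    prior_df
        Override the estimated prior degrees of freedom (``np.inf``
        collapses the moderated t onto the pooled-variance ordinary t).

    Returns
    -------
    DataFrame indexed by gene with columns log2fc, s2, t, p, adj_p and
    attrs ``d0``, ``s0_2``.
    """
    values = expr_log.values if isinstance(expr_log, ExpressionMatrix) else expr_log
    g = np.asarray(pd.Series(groups).reindex(values.columns) if isinstance(groups, pd.Series) else groups)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    m1 = g == levels[0]
    m2 = g == levels[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    x = values.to_numpy(dtype=float)
    x1, x2 = x[:, m1], x[:, m2]
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    log2fc = mean2 - mean1
    df_res = n1 + n2 - 2
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + ((x2 - mean2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_res

    if prior_df is None:
        d0, s0_2 = _fit_prior(s2, df_res)
    else:
        d0 = float(prior_df)
        s0_2 = float(np.mean(s2)) if np.isinf(d0) else _fit_prior(s2, df_res)[1]
    if np.isfinite(d0):
        s2_post = (d0 * s0_2 + df_res * s2) / (d0 + df_res)
        df_total = df_res + d0
    else:
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    degenerate = (se == 0) & (log2fc == 0)
    if degenerate.any():
        logger.info("%d genes with zero residual variance and zero logFC; t=0, p=1", degenerate.sum())
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    p = np.where((se == 0) & (log2fc != 0), 0.0, p)
    p = np.where(degenerate, 1.0, p)

    out = pd.DataFrame(
        {"log2fc": log2fc, "s2": s2, "t": t, "p": p, "adj_p": bh_adjust(p)},
        index=values.index,
    )
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    out.attrs["group1"], out.attrs["group2"] = levels[0], levels[1]
    return out


def select_degs(
    table: pd.DataFrame, adj_p_max: float = 0.001, min_abs_log2fc: float = 1.5
) -> list[str]:
    """Genes with adj_p < adj_p_max and |log2fc| > min_abs_log2fc (both strict)."""
    mask = (table["adj_p"] < adj_p_max) & (table["log2fc"].abs() > min_abs_log2fc)
    return list(table.index[mask])
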