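"""Single-sample signature scoring and group/correlation statistics.

ssGSEA follows the Barbie running-sum form: within each sample, genes
are ranked by expression (average ranks on ties); walking the genes in
decreasing-expression order, the enrichment score is the sum over the
list of the difference between the weighted in-set ECDF (weights
rank^alpha) and the uniform out-of-set ECDF.  Scores are optionally
normalized by the global (max - min) of the whole score matrix.

The T-cell-inflamed score (TIS) is the fixed-coefficient weighted sum
of 18 IFN-gamma-responsive genes; its coefficients come from a
user-supplied two-column table and are never invented here.  Cancer
immunity cycle step activities are the ssGSEA score of each step's
positively-weighted genes minus that of its negatively-weighted genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .diffexpr import bh_adjust
from .io_core import ExpressionMatrix, GeneSet, GeneSetCollection, logger


@dataclass
class TisWeights:
    """Exactly 18 gene -> coefficient entries."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.weights) != 18:
            raise ValueError(f"TIS requires exactly 18 genes, got {len(self.weights)}")
        if not all(np.isfinite(v) for v in self.weights.values()):
            raise ValueError("TIS coefficients must be finite")

    @classmethod
    def from_tsv(cls, path) -> "TisWeights":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "coef"], dtype={0: str})
        return cls(dict(zip(df["gene"], df["coef"].astype(float))))


def _ssgsea_sample(expr_col: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Barbie running-sum enrichment score for one sample."""
    n = expr_col.size
    ranks = rankdata(expr_col)  # average ranks, 1 = lowest
    order = np.lexsort((np.arange(n), -expr_col))  # decreasing, stable by index
    in_ord = in_set[order]
    w = np.abs(ranks[order]) ** alpha
    w_in = np.where(in_ord, w, 0.0)
    sum_in = w_in.sum()
    n_out = n - int(in_set.sum())
    p_in = np.cumsum(w_in) / sum_in if sum_in > 0 else np.zeros(n)
    p_out = np.cumsum(np.where(in_ord, 0.0, 1.0)) / n_out if n_out > 0 else np.zeros(n)
    return float((p_in - p_out).sum())


def ssgsea(
    expr_log: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Signature-by-sample ssGSEA score matrix.

    Sets with zero overlap with the matrix genes are skipped with a
    warning; an empty collection is an error.
    """
    if len(sets) == 0:
        raise ValueError("empty gene set collection")
    log = expr_log.to_log2()
    x = log.values.to_numpy(dtype=float)
    gene_index = {g: i for i, g in enumerate(log.gene_ids)}
    rows: dict[str, np.ndarray] = {}
    for name, gs in sets:
        idx = [gene_index[g] for g in gs.genes if g in gene_index]
        if not idx:
            logger.warning("signature %s has no overlap with the expression matrix; skipped", name)
            continue
        in_set = np.zeros(x.shape[0], dtype=bool)
        in_set[idx] = True
        rows[name] = np.array(
            [_ssgsea_sample(x[:, j], in_set, alpha) for j in range(x.shape[1])]
        )
    if not rows:
        raise ValueError("no signature overlaps the expression matrix")
    scores = pd.DataFrame(rows, index=log.sample_ids).T
    if normalize:
        rng = scores.to_numpy().max() - scores.to_numpy().min()
        if rng > 0:
            scores = scores / rng
    return scores


def tis(expr_log: ExpressionMatrix, weights: TisWeights) -> pd.Series:
    """Weighted sum of the 18 TIS genes' log2 expression per sample."""
    log = expr_log.to_log2()
    present = [g for g in weights.weights if g in log.values.index]
    if not present:
        raise ValueError("none of the 18 TIS genes present in the expression matrix")
    missing = [g for g in weights.weights if g not in log.values.index]
    if missing:
        logger.warning("TIS genes absent (contribute 0): %s", missing)
    w = np.array([weights.weights[g] for g in present])
    x = log.values.loc[present].to_numpy(dtype=float)
    return pd.Series(w @ x, index=log.sample_ids, name="tis")


def immunity_cycle_activity(
    expr_log: ExpressionMatrix,
    step_sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Step-by-sample activity: ssGSEA(positive genes) - ssGSEA(negative genes)."""
    pos_sets: dict[str, GeneSet] = {}
    neg_sets: dict[str, GeneSet] = {}
    for name, gs in step_sets:
        weights = gs.weights or {g: +1 for g in gs.genes}
        pos = frozenset(g for g in gs.genes if weights[g] == +1)
        neg = frozenset(g for g in gs.genes if weights[g] == -1)
        if pos:
            pos_sets[name] = GeneSet(pos)
        if neg:
            neg_sets[name] = GeneSet(neg)
    pos_scores = ssgsea(expr_log, GeneSetCollection(pos_sets), alpha, normalize)
    out = pos_scores.copy()
    if neg_sets:
        neg_scores = ssgsea(expr_log, GeneSetCollection(neg_sets), alpha, normalize)
        for name in neg_scores.index:
            if name in out.index:
                out.loc[name] = out.loc[name] - neg_scores.loc[name]
            else:
                out.loc[name] = -neg_scores.loc[name]
    return out


def correlate_score(
    score: pd.Series, features: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """Correlation of the score against each feature row, with BH-adjusted p.

    ``features`` is feature-by-sample.  Constant features are emitted
    flagged (NaN coefficient) and excluded from the BH adjustment.
    """
    if method not in {"spearman", "pearson"}:
        raise ValueError("method must be spearman or pearson")
    common = features.columns.intersection(score.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired samples")
    s = score[common].to_numpy(dtype=float)
    rows = []
    for feat in features.index:
        y = features.loc[feat, common].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(s) == 0:
            rows.append((feat, np.nan, np.nan, True))
            continue
        if method == "spearman":
            r, p = stats.spearmanr(s, y)
        else:
            r, p = stats.pearsonr(s, y)
        rows.append((feat, float(r), float(p), False))
    out = pd.DataFrame(rows, columns=["feature", "coefficient", "p", "constant"]).set_index("feature")
    adj = np.full(len(out), np.nan)
    ok = ~out["constant"].to_numpy()
    if ok.any():
        adj[ok] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["adj_p"] = adj
    return out


def compare_groups(
    features: pd.DataFrame, groups: pd.Series | np.ndarray, test: str = "auto"
) -> pd.DataFrame:
    """Two-group tests per feature row with BH adjustment.

    ``auto`` applies Welch's t when Shapiro does not reject normality in
    either group at alpha = 0.05, else Mann-Whitney U; binary features
    under ``auto`` and features under ``fisher`` use Fisher's exact test
    on the 2x2 table.  The reported direction is the group-2 minus
    group-1 difference in means (or log odds ratio sign for Fisher).
    """
    if test not in {"auto", "t", "mwu", "fisher"}:
        raise ValueError(f"unknown test {test!r}")
    g = np.asarray(pd.Series(groups).reindex(features.columns) if isinstance(groups, pd.Series) else groups)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    m1, m2 = g == levels[0], g == levels[1]
    rows = []
    for feat in features.index:
        y = features.loc[feat].to_numpy(dtype=float)
        y1, y2 = y[m1], y[m2]
        binary = np.isin(np.unique(y), (0.0, 1.0)).all()
        chosen = test
        if chosen == "auto":
            chosen = "fisher" if binary else None
            if chosen is None:
                if len(y1) < 3 or len(y2) < 3:
                    raise ValueError("each group needs >= 3 samples for continuous tests")
                normal = (
                    len(np.unique(y1)) > 2
                    and len(np.unique(y2)) > 2
                    and stats.shapiro(y1).pvalue > 0.05
                    and stats.shapiro(y2).pvalue > 0.05
                )
                chosen = "t" if normal else "mwu"
        if chosen == "fisher":
            table = [
                [int(y1.sum()), int(len(y1) - y1.sum())],
                [int(y2.sum()), int(len(y2) - y2.sum())],
            ]
            _, p = stats.fisher_exact(table)
            direction = y2.mean() - y1.mean()
        elif chosen == "t":
            if len(y1) < 3 or len(y2) < 3:
                raise ValueError("each group needs >= 3 samples for continuous tests")
            if np.std(y1) == 0 and np.std(y2) == 0 and y1.mean() == y2.mean():
                p = 1.0
            else:
                _, p = stats.ttest_ind(y1, y2, equal_var=False)
            direction = y2.mean() - y1.mean()
        else:  # mwu
            if len(y1) < 3 or len(y2) < 3:
                raise ValueError("each group needs >= 3 samples for continuous tests")
            _, p = stats.mannwhitneyu(y1, y2, alternative="two-sided", method="asymptotic")
            direction = y2.mean() - y1.mean()
        rows.append((feat, chosen, float(p), float(direction)))
    out = pd.DataFrame(rows, columns=["feature", "test", "p", "direction"]).set_index("feature")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out
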