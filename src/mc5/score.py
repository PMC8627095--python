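"""The PC1-based prognostic score over cluster-derived signature genes.

Signature genes are filtered to those with a univariate Cox Wald
p < alpha; the retained genes are z-scored and the per-sample score is
the projection onto the leading principal component, with the sign
oriented so that cluster 1 has the higher mean score (cluster 1 is the
high-score, better-prognosis subtype).  Applying the model to an
external cohort re-standardizes genes within that cohort by default
(cross-platform comparability); pass ``freeze_standardization=True`` to
reuse the training means and sds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import ClinicalTable, ExpressionMatrix, logger
from .survstats import CoxFit, univariate_cox


@dataclass
class ScoreModel:
    genes: list[str]
    loadings: np.ndarray  # unit-norm PC1 loadings, aligned with genes
    means: np.ndarray  # training standardization constants
    sds: np.ndarray
    sign: int  # orientation: +1 or -1
    explained_variance: float

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.sign not in (+1, -1):
            raise ValueError("orientation sign must be +1 or -1")
        if not np.isclose((self.loadings**2).sum(), 1.0, atol=1e-8):
            raise ValueError("PC1 loadings must have unit norm")
        if (self.sds <= 0).any():
            raise ValueError("standardization sds must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "genes": self.genes,
                    "loadings": self.loadings.tolist(),
                    "means": self.means.tolist(),
                    "sds": self.sds.tolist(),
                    "sign": self.sign,
                    "explained_variance": self.explained_variance,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreModel":
        d = json.loads(Path(path).read_text())
        return cls(
            genes=d["genes"],
            loadings=np.asarray(d["loadings"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            sign=int(d["sign"]),
            explained_variance=float(d["explained_variance"]),
        )


def select_prognostic(
    deg_genes: list[str],
    expr_log: ExpressionMatrix,
    clinical: ClinicalTable,
    alpha: float = 0.05,
) -> tuple[list[str], dict[str, CoxFit]]:
    """Signature genes with univariate Cox Wald p < alpha.

    Non-converged (monotone-likelihood) fits are excluded and logged.
    Returns the selected genes and every fit for reporting.
    """
    if not deg_genes:
        raise ValueError("empty signature gene list")
    common = clinical.table.index.intersection(expr_log.sample_ids)
    values = expr_log.to_log2().values[common]
    os_time = clinical.table.loc[common, "os_time"].to_numpy(dtype=float)
    os_event = clinical.table.loc[common, "os_event"].to_numpy(dtype=float)
    fits: dict[str, CoxFit] = {}
    selected: list[str] = []
    for gene in deg_genes:
        if gene not in values.index:
            continue
        fit = univariate_cox(values.loc[gene].to_numpy(), os_time, os_event)
        fits[gene] = fit
        if not fit.converged:
            logger.warning("gene %s: non-converged Cox fit excluded from prognostic filter", gene)
            continue
        if fit.p < alpha:
            selected.append(gene)
    if not selected:
        raise ValueError(
            f"no prognostic genes at alpha={alpha}; consider relaxing the threshold"
        )
    return selected, fits


def fit_score_model(
    expr_log: ExpressionMatrix, cluster_labels: pd.Series, genes: list[str] | None = None
) -> ScoreModel:
    """Fit the PC1 score model on the given genes, oriented to cluster 1 high.

    Zero-variance genes are dropped with a warning; at least 2 genes and
    3 samples must survive.
    """
    log = expr_log.to_log2()
    if genes is not None:
        log = log.subset_genes(genes)
    x = log.values.to_numpy(dtype=float)
    kept = log.gene_ids
    sds = x.std(axis=1, ddof=1)
    drop = sds == 0
    if drop.any():
        logger.warning("dropping zero-variance genes: %s", [g for g, d in zip(kept, drop) if d])
        x = x[~drop]
        kept = [g for g, d in zip(kept, drop) if not d]
        sds = sds[~drop]
    if len(kept) < 2:
        raise ValueError("need at least 2 genes with nonzero variance")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    means = x.mean(axis=1)
    z = (x - means[:, None]) / sds[:, None]
    cov = np.cov(z)
    evals, evecs = np.linalg.eigh(cov)
    w = evecs[:, -1]
    # deterministic base sign before orientation
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    explained = float(evals[-1] / evals.sum())
    raw = w @ z

    labels = cluster_labels.reindex(log.sample_ids)
    in1 = (labels == labels.min()).to_numpy()
    sign = 1 if raw[in1].mean() >= raw[~in1].mean() else -1
    return ScoreModel(
        genes=kept,
        loadings=w,
        means=means,
        sds=sds,
        sign=sign,
        explained_variance=explained,
    )


def apply_score(
    model: ScoreModel, expr_log: ExpressionMatrix, freeze_standardization: bool = False
) -> pd.Series:
    """Per-sample score: sign * sum_g w_g * z_gj.

    Genes absent from the matrix are imputed at standardized 0 (with a
    warning); more than 50% missing is an error.  Unless standardization
    is frozen, gene means/sds are recomputed within the scored cohort.
    """
    log = expr_log.to_log2()
    present = [g for g in model.genes if g in log.values.index]
    missing = [g for g in model.genes if g not in log.values.index]
    if len(present) < 0.5 * len(model.genes):
        raise ValueError(f"fewer than 50% of model genes present; missing: {missing}")
    if missing:
        logger.warning("imputing %d missing model genes at standardized 0: %s", len(missing), missing)
    idx = [model.genes.index(g) for g in present]
    x = log.values.loc[present].to_numpy(dtype=float)
    if freeze_standardization:
        means = model.means[idx]
        sds = model.sds[idx]
    else:
        means = x.mean(axis=1)
        sds = x.std(axis=1, ddof=1)
        zero = sds == 0
        if zero.any():
            sds = np.where(zero, 1.0, sds)
    z = (x - means[:, None]) / sds[:, None]
    scores = model.sign * (model.loadings[idx] @ z)
    return pd.Series(scores, index=log.sample_ids, name="score")
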