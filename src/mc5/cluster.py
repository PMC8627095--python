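"""Resampling consensus clustering of samples on the regulator genes.

Samples are clustered with PAM (k-medoids, BUILD + SWAP) on 1 - Spearman
correlation distances, under repeated joint resampling of 80% of items
and 80% of genes.  The consensus matrix entry M_k[i, j] is the fraction
of co-sampled repetitions in which samples i and j landed in the same
cluster; k is selected by minimizing the proportion of ambiguous
clustering (PAC).  A purity-corrected variant regresses tumor purity out
of each gene before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .io_core import ExpressionMatrix, RegulatorCatalog, RunConfig, Scale, logger


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape inconsistent with sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, assignments and k-selection diagnostics."""

    sample_ids: list[str]
    consensus: dict[int, np.ndarray]  # k -> M_k
    assignments: dict[int, np.ndarray]  # k -> labels in 1..k
    co_sample_counts: np.ndarray  # N_ij, shared across k
    co_cluster_counts: dict[int, np.ndarray]  # k -> C_ij
    pac: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    subsample_record: list[tuple[np.ndarray, np.ndarray]] | None = None

    def labels(self, k: int | None = None) -> pd.Series:
        k = self.chosen_k if k is None else k
        return pd.Series(self.assignments[k], index=self.sample_ids, name="cluster")


def spearman_distance(expr: ExpressionMatrix) -> DistanceMatrix:
    """1 - Spearman rank correlation between sample columns.

    Ties receive average ranks.  A sample with zero variance across the
    supplied genes has no defined rank correlation and is rejected.
    """
    x = expr.values.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 genes to compute sample-sample distances")
    ranks = rankdata(x, axis=0)
    sd = ranks.std(axis=0)
    if (sd == 0).any():
        bad = expr.sample_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"sample {bad!r} has zero variance across the supplied genes")
    z = (ranks - ranks.mean(axis=0)) / sd
    rho = z.T @ z / x.shape[0]
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return DistanceMatrix(expr.sample_ids, d)


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    dist_near = d[medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate h: sum of max(dist_near - d[h], 0)
        gains = np.maximum(dist_near[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        h = int(np.argmax(gains))
        medoids.append(h)
        dist_near = np.minimum(dist_near, d[h])
    return medoids


def kmedoids(dist: DistanceMatrix, k: int, seed: int = 0) -> np.ndarray:
    """PAM: BUILD initialization then SWAP to a local optimum.

    Deterministic: all argmin/argmax ties break toward the lowest index,
    so the seed only labels the run (kept in the signature for interface
    symmetry with the stochastic stages).
    """
    d = dist.values
    n = d.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for n={n}")
    if k == n:
        return np.arange(1, n + 1)
    medoids = _pam_build(d, k)
    while True:
        med = np.asarray(medoids)
        dmed = d[med]  # k x n
        order = np.argsort(dmed, axis=0)
        d_near = dmed[order[0], np.arange(n)]
        d_second = dmed[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        nearest = order[0]
        cost = d_near.sum()
        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            # distance to nearest medoid excluding medoid mi
            d_wo = np.where(nearest == mi, d_second, d_near)
            cand_costs = np.minimum(d_wo[None, :], d).sum(axis=1)  # n candidates
            cand_costs[med] = np.inf
            h = int(np.argmin(cand_costs))
            delta = cost - cand_costs[h]
            if delta > best_delta + 1e-12:
                best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        medoids = sorted(medoids)
    med = np.asarray(sorted(medoids))
    nearest = np.argmin(d[med], axis=0)
    return nearest + 1


def consensus_cluster(
    expr: ExpressionMatrix,
    config: RunConfig | None = None,
    genes: list[str] | None = None,
    record_subsamples: bool = False,
) -> ConsensusResult:
    """Resampling consensus clustering over k = 2..max_k.

    The expression matrix is restricted to the regulator catalog (or an
    explicit gene list); each repetition subsamples ``p_item`` of the
    samples and ``p_feature`` of the genes without replacement, computes
    the Spearman distance on the subset and runs PAM for every k.  Final
    per-k assignments come from average-linkage hierarchical clustering
    of 1 - M_k cut at k.
    """
    config = config or RunConfig()
    if genes is None:
        genes = RegulatorCatalog().genes
    sub = expr.to_log2().subset_genes(genes)
    found = sub.gene_ids
    if len(found) < 5:
        missing = sorted(set(genes) - set(found))
        raise ValueError(
            f"only {len(found)} catalog genes present (need >= 5); missing: {missing}"
        )
    x = sub.values.to_numpy(dtype=float)
    g, n = x.shape
    sample_ids = sub.sample_ids
    ks = list(range(2, config.max_k + 1))

    n_item = int(np.ceil(config.p_item * n))
    n_feat = int(np.ceil(config.p_feature * g))
    master = np.random.SeedSequence(config.seed)
    rep_seeds = master.spawn(config.reps)

    N = np.zeros((n, n))
    C = {k: np.zeros((n, n)) for k in ks}
    record: list[tuple[np.ndarray, np.ndarray]] | None = [] if record_subsamples else None

    for rep in range(config.reps):
        rng = np.random.default_rng(rep_seeds[rep])
        items = np.sort(rng.choice(n, size=n_item, replace=False))
        feats = np.sort(rng.choice(g, size=n_feat, replace=False))
        if record is not None:
            record.append((items, feats))
        sub_expr = ExpressionMatrix(
            pd.DataFrame(
                x[np.ix_(feats, items)],
                index=[found[i] for i in feats],
                columns=[sample_ids[i] for i in items],
            ),
            Scale.LOG2_TPM_PLUS1,
        )
        dist = spearman_distance(sub_expr)
        N[np.ix_(items, items)] += 1.0
        for k in ks:
            lab = kmedoids(dist, k)
            same = lab[:, None] == lab[None, :]
            C[k][np.ix_(items, items)] += same

    consensus: dict[int, np.ndarray] = {}
    assignments: dict[int, np.ndarray] = {}
    pac: dict[int, float] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in ks:
            M = np.where(N > 0, C[k] / np.where(N > 0, N, 1.0), 0.0)
            np.fill_diagonal(M, 1.0)
            M = (M + M.T) / 2.0
            consensus[k] = M
            dvec = squareform(1.0 - M, checks=False)
            Z = average(dvec)
            assignments[k] = fcluster(Z, t=k, criterion="maxclust")
            off = M[np.triu_indices(n, 1)]
            pac[k] = float(((off > 0.1) & (off < 0.9)).mean())

    delta_area = _delta_area(consensus, ks)
    chosen_k = min(pac, key=lambda k: (pac[k], k))
    return ConsensusResult(
        sample_ids=sample_ids,
        consensus=consensus,
        assignments=assignments,
        co_sample_counts=N,
        co_cluster_counts={k: C[k] for k in ks},
        pac=pac,
        delta_area=delta_area,
        chosen_k=chosen_k,
        subsample_record=record,
    )


def _cdf_area(M: np.ndarray) -> float:
    vals = np.sort(M[np.triu_indices(M.shape[0], 1)])
    if len(vals) == 0:
        return 0.0
    # area under the empirical CDF over [min(vals), 1]
    cdf = np.arange(1, len(vals) + 1) / len(vals)
    widths = np.diff(np.concatenate([vals, [1.0]]))
    return float((cdf * widths).sum())


def _delta_area(consensus: dict[int, np.ndarray], ks: list[int]) -> dict[int, float]:
    areas = {k: _cdf_area(consensus[k]) for k in ks}
    out: dict[int, float] = {}
    prev = None
    for k in ks:
        if prev is None:
            out[k] = areas[k]
        else:
            out[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
        prev = k
    return out


def select_k(result: ConsensusResult) -> tuple[int, pd.DataFrame]:
    """k minimizing PAC (ties toward smaller k), with the diagnostics table."""
    diag = pd.DataFrame(
        {
            "k": list(result.pac),
            "pac": [result.pac[k] for k in result.pac],
            "delta_area": [result.delta_area[k] for k in result.pac],
        }
    )
    chosen = min(result.pac, key=lambda k: (result.pac[k], k))
    return chosen, diag


def purity_adjust(expr: ExpressionMatrix, purity: pd.Series) -> ExpressionMatrix:
    """Regress tumor purity out of each gene's log2 expression.

    Per gene the least-squares line on purity is fit and the adjusted
    value is the residual plus the gene's grand mean, keeping the scale
    interpretable.  A constant purity vector degrades gracefully to mean
    centering (plus grand mean), with a warning.
    """
    p = purity.reindex(expr.sample_ids).to_numpy(dtype=float)
    if np.isnan(p).any():
        raise ValueError("purity missing for some samples")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("purity must be in [0, 1]")
    log = expr.to_log2()
    x = log.values.to_numpy(dtype=float)
    pc = p - p.mean()
    denom = (pc**2).sum()
    if denom == 0:
        logger.warning("constant purity vector; purity adjustment reduces to centering")
        slope = np.zeros(x.shape[0])
    else:
        slope = (x @ pc) / denom
    resid = x - x.mean(axis=1, keepdims=True) - slope[:, None] * pc[None, :]
    adjusted = resid + x.mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(adjusted, index=log.gene_ids, columns=log.sample_ids),
        Scale.LOG2_TPM_PLUS1,
    )
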