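"""Beta-value differential methylation and the specific-probe rules.

DMPs between two groups are tested with the moderated-t engine on beta
values directly (optionally on M-values, log2(beta/(1-beta)) with beta
clipped to [0.001, 0.999]); significance is adjusted P < 0.01, strict.
A significant probe is "group-B-specific hypermethylated" when its mean
beta is > 0.5 in group B and < 0.2 in group A (both strict), and
symmetrically for hypomethylated; the same rule serves the
cancer-vs-normal and cluster-vs-cluster contrasts.  DMPs map to genes
(DMGs) through promoter-region annotations (TSS1500, TSS200, 5'UTR,
1stExon) by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cluster import ConsensusResult, consensus_cluster
from .diffexpr import bh_adjust, moderated_t_test
from .enrich import correlate_score
from .io_core import (
    PROMOTER_REGIONS,
    ExpressionMatrix,
    MethylationMatrix,
    ProbeAnnotation,
    RunConfig,
    Scale,
)


def dmp_test(
    beta: MethylationMatrix,
    groups: pd.Series | np.ndarray,
    adj_p_max: float = 0.01,
    use_m_values: bool = False,
) -> pd.DataFrame:
    """Per-probe moderated-t DMP table with group means and significance flag."""
    values = beta.values
    g = np.asarray(pd.Series(groups).reindex(values.columns) if isinstance(groups, pd.Series) else groups)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    test_values = values
    if use_m_values:
        clipped = values.clip(lower=0.001, upper=0.999)
        test_values = np.log2(clipped / (1.0 - clipped))
    table = moderated_t_test(pd.DataFrame(test_values, index=values.index, columns=values.columns), g)
    x = values.to_numpy(dtype=float)
    m1, m2 = g == levels[0], g == levels[1]
    out = pd.DataFrame(
        {
            "mean_1": x[:, m1].mean(axis=1),
            "mean_2": x[:, m2].mean(axis=1),
            "delta_beta": x[:, m2].mean(axis=1) - x[:, m1].mean(axis=1),
            "t": table["t"],
            "p": table["p"],
            "adj_p": table["adj_p"],
        },
        index=values.index,
    )
    out["significant"] = out["adj_p"] < adj_p_max
    out.attrs["group1"], out.attrs["group2"] = levels[0], levels[1]
    return out


def specific_dmps(
    dmp: pd.DataFrame, low_thresh: float = 0.2, high_thresh: float = 0.5
) -> pd.DataFrame:
    """Classify significant DMPs as group-2 hyper- or hypomethylated specific.

    hyper_specific: mean_2 > high_thresh and mean_1 < low_thresh;
    hypo_specific: mean_2 < low_thresh and mean_1 > high_thresh;
    all inequalities strict, non-significant probes are "none".
    """
    cls = np.full(len(dmp), "none", dtype=object)
    sig = dmp["significant"].to_numpy()
    hyper = sig & (dmp["mean_2"].to_numpy() > high_thresh) & (dmp["mean_1"].to_numpy() < low_thresh)
    hypo = sig & (dmp["mean_2"].to_numpy() < low_thresh) & (dmp["mean_1"].to_numpy() > high_thresh)
    cls[hyper] = "hyper_specific"
    cls[hypo] = "hypo_specific"
    out = dmp.copy()
    out["class"] = cls
    return out


def map_dmps_to_genes(
    dmps: pd.DataFrame, annotation: ProbeAnnotation, promoter_only: bool = True
) -> list[str]:
    """Genes linked to >= 1 classified DMP via a promoter (or any) region."""
    if "class" not in dmps.columns:
        raise ValueError("run specific_dmps first: table lacks a class column")
    classified = dmps.index[dmps["class"] != "none"]
    genes: list[str] = []
    for probe in classified:
        for gene, region in annotation.get(probe):
            if promoter_only and region not in PROMOTER_REGIONS:
                continue
            if gene not in genes:
                genes.append(gene)
    return genes


def dmp_consensus_cluster(
    beta: MethylationMatrix, probes: list[str], config: RunConfig | None = None
) -> ConsensusResult:
    """Consensus clustering of samples on a probe subset of the beta matrix.

    Beta values are used directly (no log transform): they are wrapped in
    an expression container on the log-like scale solely to bypass the
    TPM non-negativity transform.
    """
    keep = [p for p in probes if p in beta.values.index]
    if len(keep) < 5:
        raise ValueError(f"need >= 5 probes present, got {len(keep)}")
    expr = ExpressionMatrix(beta.values.loc[keep], Scale.LOG2_TPM_PLUS1)
    return consensus_cluster(expr, config, genes=keep)


def promoter_methylation_correlation(
    score: pd.Series,
    beta: MethylationMatrix,
    annotation: ProbeAnnotation,
    genes: list[str],
    adj_p_max: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Spearman correlation of the score with each promoter probe of the genes.

    Returns the per-probe correlation table plus summary counts of
    significantly negative / positive probes at the given adjusted-P
    threshold.
    """
    if not genes:
        raise ValueError("empty gene list")
    gene_set = set(genes)
    probes = [
        p
        for p in beta.values.index
        if any(gn in gene_set and region in PROMOTER_REGIONS for gn, region in annotation.get(p))
    ]
    if not probes:
        raise ValueError("no promoter probes annotated to the listed genes")
    table = correlate_score(score, beta.values.loc[probes], method="spearman")
    sig = table["adj_p"] < adj_p_max
    counts = {
        "n_probes": len(table),
        "n_negative_significant": int((sig & (table["coefficient"] < 0)).sum()),
        "n_positive_significant": int((sig & (table["coefficient"] > 0)).sum()),
    }
    return table, counts
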