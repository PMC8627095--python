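"""Downstream evaluation and end-to-end pipeline orchestration.

ROC/AUC of the continuous score against binary labels uses the rank
(Mann-Whitney) statistic with ties counted 0.5, which equals the area
under the threshold-sweep ROC curve.  Cluster-system agreement matches
labels by the maximum-agreement permutation (exhaustive, k <= 6).
Mutation-rate comparison reports per-gene and pooled (>= 1 mutated set
gene per sample) rates per group with Fisher exact p-values.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from . import cluster as _cluster
from . import diffexpr as _diffexpr
from . import enrich as _enrich
from . import methyl as _methyl
from . import score as _score
from . import survstats as _surv
from .io_core import MutationTable, RunConfig, logger
from .synthetic import CHEMO_GENES, SyntheticCohort


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(score: np.ndarray | pd.Series, labels: np.ndarray | pd.Series) -> ROCResult:
    """AUC by the tie-corrected rank statistic plus the threshold-sweep curve."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(labels, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    auc = (r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    fpr = np.array([(s[y == 0] >= th).mean() for th in thresholds])
    tpr = np.array([(s[y == 1] >= th).mean() for th in thresholds])
    return ROCResult(auc=float(auc), fpr=fpr, tpr=tpr, thresholds=thresholds)


def crosstab_agreement(
    labels_a: np.ndarray | pd.Series, labels_b: np.ndarray | pd.Series
) -> dict:
    """Contingency table, permutation-matched reclassification count, test p.

    The number of "reclassified" samples is n minus the maximum
    agreement over all bijections between the (padded) label sets, so it
    is invariant to arbitrary renaming of either labeling.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    tab = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    counts = tab.to_numpy()
    k = max(counts.shape)
    padded = np.zeros((k, k), dtype=int)
    padded[: counts.shape[0], : counts.shape[1]] = counts
    best = max(
        sum(padded[i, perm[i]] for i in range(k)) for perm in itertools.permutations(range(k))
    )
    n = a.size
    if counts.size >= 4 and min(counts.shape) >= 2:
        if counts.shape == (2, 2):
            _, p = stats.fisher_exact(counts)
        else:
            _, p, _, _ = stats.chi2_contingency(counts)
    else:
        p = 1.0
    return {"table": tab, "n_reclassified": int(n - best), "p": float(p)}


def mutation_rate_compare(
    mutations: MutationTable, groups: pd.Series | np.ndarray, gene_set: list[str]
) -> dict:
    """Per-gene and pooled mutation rates per group with Fisher exact tests."""
    if not gene_set:
        raise ValueError("empty gene set")
    t = mutations.table
    g = np.asarray(pd.Series(groups).reindex(t.index) if isinstance(groups, pd.Series) else groups)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    m1, m2 = g == levels[0], g == levels[1]
    present = [gene for gene in gene_set if gene in t.columns]
    skipped = [gene for gene in gene_set if gene not in t.columns]
    if skipped:
        logger.warning("genes absent from mutation table skipped: %s", skipped)
    per_gene = []
    for gene in present:
        x1 = t.loc[m1, gene].to_numpy()
        x2 = t.loc[m2, gene].to_numpy()
        table = [[int(x1.sum()), int(len(x1) - x1.sum())], [int(x2.sum()), int(len(x2) - x2.sum())]]
        _, p = stats.fisher_exact(table)
        per_gene.append((gene, x1.mean(), x2.mean(), float(p)))
    per_gene_df = pd.DataFrame(per_gene, columns=["gene", f"rate_{levels[0]}", f"rate_{levels[1]}", "p"])
    any1 = t.loc[m1, present].to_numpy().max(axis=1) if present else np.zeros(int(m1.sum()))
    any2 = t.loc[m2, present].to_numpy().max(axis=1) if present else np.zeros(int(m2.sum()))
    pool_table = [
        [int(any1.sum()), int(len(any1) - any1.sum())],
        [int(any2.sum()), int(len(any2) - any2.sum())],
    ]
    _, pooled_p = stats.fisher_exact(pool_table)
    return {
        "per_gene": per_gene_df,
        "pooled_rates": {str(levels[0]): float(any1.mean()), str(levels[1]): float(any2.mean())},
        "pooled_p": float(pooled_p),
        "skipped": skipped,
    }


def run_pipeline(
    cohort: SyntheticCohort, config: RunConfig | None = None, out_dir: str | Path | None = None
) -> dict:
    """Execute the full analysis on an in-memory cohort.

    Stages: consensus clustering of the regulator genes, differential
    expression between the two clusters, prognostic PC1 score, optimal
    survival cutpoint and log-rank comparison, signature enrichment and
    score-immune correlation, cluster-specific DMP classification, and
    mutation-rate comparison.  Results come back in one dict; with an
    output directory, tabular artifacts and a manifest are also written.
    """
    config = config or RunConfig()
    results: dict = {"config": config}
    stage = "cluster"
    try:
        expr_log = cohort.expression.to_log2()
        cons = _cluster.consensus_cluster(expr_log, config)
        clusters = _surv.relabel_by_prognosis(
            cons.labels(2), cohort.clinical.os_time, cohort.clinical.os_event
        )
        results["consensus"] = cons
        results["clusters"] = clusters

        stage = "deg"
        deg_table = _diffexpr.moderated_t_test(expr_log, clusters)
        degs = _diffexpr.select_degs(deg_table, config.deg_adj_p_max, config.deg_min_abs_log2fc)
        results["deg_table"] = deg_table
        results["degs"] = degs

        stage = "score"
        prognostic, cox_fits = _score.select_prognostic(
            degs, expr_log, cohort.clinical, alpha=config.cox_alpha
        )
        model = _score.fit_score_model(expr_log, clusters, genes=prognostic)
        scores = _score.apply_score(model, expr_log)
        results["prognostic_genes"] = prognostic
        results["score_model"] = model
        results["scores"] = scores

        stage = "survival"
        os_time = cohort.clinical.os_time
        os_event = cohort.clinical.os_event
        cut = _surv.optimal_cutpoint(
            scores.to_numpy(), os_time, os_event, minprop=config.cutpoint_minprop
        )
        groups = pd.Series(
            _surv.dichotomize(scores.to_numpy(), cut.cutoff), index=scores.index, name="score_group"
        )
        chi2, logrank_p = _surv.logrank_test(groups.to_numpy(), os_time, os_event)
        results["cutpoint"] = cut
        results["score_groups"] = groups
        results["logrank"] = {"chi2": chi2, "p": logrank_p}

        stage = "enrich"
        sig_scores = _enrich.ssgsea(
            expr_log, cohort.marker_sets, alpha=config.ssgsea_alpha, normalize=config.ssgsea_normalize
        )
        corr = _enrich.correlate_score(scores, sig_scores, method="spearman")
        results["signature_scores"] = sig_scores
        results["score_signature_corr"] = corr

        stage = "methyl"
        if cohort.methylation is not None:
            beta_groups = clusters.reindex(cohort.methylation.sample_ids)
            dmp = _methyl.dmp_test(
                cohort.methylation, beta_groups, adj_p_max=config.dmp_adj_p_max,
                use_m_values=config.use_m_values,
            )
            classified = _methyl.specific_dmps(dmp, config.beta_low, config.beta_high)
            dmgs = _methyl.map_dmps_to_genes(classified, cohort.probe_annotation)
            results["dmp_table"] = classified
            results["dmgs"] = dmgs
        else:
            results["dmp_table"] = None
            logger.info("no methylation data; methyl stage skipped")

        stage = "evaluate"
        auc = roc_auc(scores.to_numpy(), (cohort.true_labels.reindex(scores.index) == 1).astype(int))
        mut = mutation_rate_compare(cohort.mutations, groups, [g for g in CHEMO_GENES])
        results["auc_subtype"] = auc
        results["mutation_compare"] = mut
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if out_dir is not None:
        _write_artifacts(results, cohort, config, Path(out_dir))
    return results


def _write_artifacts(results: dict, cohort: SyntheticCohort, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    results["clusters"].rename("cluster").to_csv(out / "clusters.tsv", sep="\t")
    results["deg_table"].to_csv(out / "deg_table.tsv", sep="\t")
    pd.Series(results["degs"], name="gene").to_csv(out / "degs.tsv", sep="\t", index=False)
    results["score_model"].to_json(out / "score_model.json")
    pd.DataFrame(
        {"score": results["scores"], "group": results["score_groups"]}
    ).to_csv(out / "scores.tsv", sep="\t", index_label="sample_id")
    results["score_signature_corr"].to_csv(out / "score_signature_corr.tsv", sep="\t")
    if results.get("dmp_table") is not None:
        results["dmp_table"].to_csv(out / "dmp_table.tsv", sep="\t", index_label="probe")
    manifest = {
        "seed": config.seed,
        "config_sha1": hashlib.sha1(Path(out / "config.yaml").read_bytes()).hexdigest(),
        "n_samples": len(cohort.expression.sample_ids),
        "stages": [
            "cluster", "deg", "score", "survival", "enrich",
            "methyl" if results.get("dmp_table") is not None else "methyl(skipped)",
            "evaluate",
        ],
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
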