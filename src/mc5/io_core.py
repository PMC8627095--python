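"""Domain containers, file readers/writers and run configuration.

All on-disk tabular artifacts are UTF-8 tab-delimited text with a header
row; gene sets use the GMT dialect.  Containers are thin wrappers around
pandas objects that enforce the domain invariants on construction:
expression values non-negative on the linear TPM scale, methylation beta
values in [0, 1], survival times positive, unique identifiers everywhere.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mc5")

PROMOTER_REGIONS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})
REGION_GROUPS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR"})


class Scale(str, enum.Enum):
    """Expression scale: linear TPM or log2(TPM+1)."""

    LINEAR_TPM = "linear_tpm"
    LOG2_TPM_PLUS1 = "log2_tpm_plus1"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample quantification matrix.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    scale
        Whether values are linear TPM or log2(TPM+1).
    """

    values: pd.DataFrame
    scale: Scale = Scale.LINEAR_TPM

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"missing value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if self.scale is Scale.LINEAR_TPM and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative TPM at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_log2(self) -> "ExpressionMatrix":
        """Return the matrix on the log2(TPM+1) scale (identity if already there)."""
        if self.scale is Scale.LOG2_TPM_PLUS1:
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), Scale.LOG2_TPM_PLUS1)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[keep], self.scale)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations with overall survival."""

    table: pd.DataFrame  # index: sample_id

    REQUIRED = ("os_time", "os_event")
    OPTIONAL = ("stage", "grade", "lvi", "age", "purity")

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        os_time = t["os_time"].to_numpy(dtype=float)
        mask = ~np.isnan(os_time)
        if (os_time[mask] <= 0).any():
            bad = t.index[mask][os_time[mask] <= 0][0]
            raise ValueError(f"non-positive os_time for sample {bad!r}")
        ev = t["os_event"].to_numpy(dtype=float)
        ev = ev[~np.isnan(ev)]
        if not np.isin(ev, (0.0, 1.0)).all():
            raise ValueError("os_event must be 0 or 1")
        if "purity" in t.columns:
            p = t["purity"].to_numpy(dtype=float)
            p = p[~np.isnan(p)]
            if ((p < 0) | (p > 1)).any():
                raise ValueError("purity must be in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def os_time(self) -> np.ndarray:
        return self.table["os_time"].to_numpy(dtype=float)

    @property
    def os_event(self) -> np.ndarray:
        return self.table["os_event"].to_numpy(dtype=float)


# 5mC regulator catalog: 3 writers, 4 erasers, 14 readers.  Only eleven
# reader genes are unambiguously named in the literature this catalog
# follows; the remaining three slots ship as explicit placeholders that a
# user can override via configuration rather than silently guessing.
DEFAULT_REGULATORS: dict[str, str] = {
    "DNMT1": "writer",
    "DNMT3A": "writer",
    "DNMT3B": "writer",
    "TET1": "eraser",
    "TET2": "eraser",
    "TET3": "eraser",
    "TDG": "eraser",
    "MBD1": "reader",
    "MBD2": "reader",
    "MBD3": "reader",
    "MBD4": "reader",
    "MECP2": "reader",
    "NEIL1": "reader",
    "NTHL1": "reader",
    "SMUG1": "reader",
    "UHRF1": "reader",
    "UHRF2": "reader",
    "UNG": "reader",
    "READER12": "reader",
    "READER13": "reader",
    "READER14": "reader",
}

_ROLES = frozenset({"writer", "eraser", "reader"})


@dataclass
class RegulatorCatalog:
    """The 21 5mC regulator genes and their writer/eraser/reader roles."""

    entries: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REGULATORS))

    def __post_init__(self) -> None:
        if len(self.entries) != 21:
            raise ValueError(f"catalog must have exactly 21 genes, got {len(self.entries)}")
        bad = {r for r in self.entries.values() if r not in _ROLES}
        if bad:
            raise ValueError(f"invalid regulator roles: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.entries)


@dataclass
class GeneSet:
    genes: frozenset[str]
    weights: dict[str, int] | None = None  # +1/-1 direction per gene

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set is empty")
        if self.weights is not None:
            if set(self.weights) != set(self.genes):
                raise ValueError("direction weights must cover every gene in the set")
            if not set(self.weights.values()) <= {+1, -1}:
                raise ValueError("direction weights must be +1 or -1")


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


@dataclass
class MutationTable:
    """Binary sample-by-gene nonsilent mutation indicator matrix."""

    table: pd.DataFrame  # index: sample_id, columns: genes, values in {0,1}

    def __post_init__(self) -> None:
        arr = self.table.to_numpy(dtype=float)
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError("mutation table entries must be 0 or 1")
        self.table = self.table.astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class MethylationMatrix:
    """Probe-by-sample beta-value matrix, all entries in [0, 1]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("missing beta value")
        if ((arr < 0) | (arr > 1)).any():
            p, s = np.argwhere((arr < 0) | (arr > 1))[0]
            raise ValueError(
                f"beta value outside [0,1] at probe {self.values.index[p]!r}, "
                f"sample {self.values.columns[s]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProbeAnnotation:
    """probe id -> list of (gene symbol, region group) pairs."""

    mapping: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for probe, pairs in self.mapping.items():
            for _, region in pairs:
                if region not in REGION_GROUPS:
                    raise ValueError(f"unknown region group {region!r} for probe {probe!r}")

    def get(self, probe: str) -> list[tuple[str, str]]:
        return self.mapping.get(probe, [])


@dataclass
class RunConfig:
    """All pipeline tunables; defaults follow the published analysis where stated.

    Consensus clustering uses 80% item resampling, 80% gene resampling,
    1000 resamplings and a maximum evaluated k of 6; DEGs require
    adjusted P < 0.001 and |log2FC| > 1.5; DMPs require adjusted
    P < 0.01 with specific-probe beta thresholds 0.2 / 0.5.
    """

    # consensus clustering
    p_item: float = 0.8
    p_feature: float = 0.8
    max_k: int = 6
    reps: int = 1000
    # differential expression
    deg_adj_p_max: float = 0.001
    deg_min_abs_log2fc: float = 1.5
    # prognostic filter
    cox_alpha: float = 0.05
    # ssGSEA
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: bool = True
    # cutpoint
    cutpoint_minprop: float = 0.1
    # methylation
    dmp_adj_p_max: float = 0.01
    beta_low: float = 0.2
    beta_high: float = 0.5
    use_m_values: bool = False
    # reproducibility
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    cols = header[1:]
    if len(set(cols)) != len(cols):
        dups = sorted({c for c in cols if cols.count(c) > 1})
        raise ValueError(f"duplicate sample ids: {dups}")
    return pd.read_csv(path, sep=sep, index_col=0)


def read_expression(path: str | Path, scale_hint: Scale | str = Scale.LINEAR_TPM) -> ExpressionMatrix:
    """Read a gene-by-sample expression TSV/CSV.

    Duplicate gene rows are collapsed by per-sample maximum (the common
    convention when several transcript rows map to one symbol); the
    collapse is logged.  Missing values and duplicate sample columns are
    rejected.
    """
    df = _read_table(path)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if df.isna().any().any():
        stacked = df.isna().stack()
        gene, sample = stacked[stacked].index[0]
        raise ValueError(f"missing value at gene {gene!r}, sample {sample!r}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("collapsing duplicate gene rows by per-sample max: %s", dups)
        df = df.groupby(level=0, sort=False).max()
    return ExpressionMatrix(df.astype(float), Scale(scale_hint))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path: str | Path) -> ClinicalTable:
    return ClinicalTable(_read_table(path))


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.table.to_csv(path, sep="\t", index_label="sample_id")


def read_mutations(path: str | Path) -> MutationTable:
    return MutationTable(_read_table(path))


def write_mutations(mut: MutationTable, path: str | Path) -> None:
    mut.table.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then tab-separated gene tokens.

    Gene tokens may carry a ``|+1`` / ``|-1`` suffix giving a direction
    weight (defaulting to +1 when any token in the line is signed);
    duplicate genes within one line are deduplicated.
    """
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: GMT line needs name, description, >=1 gene")
            name = fields[0].strip()
            if not name:
                raise ValueError(f"line {lineno}: blank set name")
            if name in sets:
                raise ValueError(f"line {lineno}: duplicate set name {name!r}")
            tokens = [t for t in fields[2:] if t.strip()]
            if not tokens:
                raise ValueError(f"line {lineno}: set {name!r} has zero genes")
            genes: list[str] = []
            weights: dict[str, int] = {}
            signed = False
            for tok in tokens:
                if "|" in tok:
                    gene, w = tok.rsplit("|", 1)
                    weights[gene] = int(w)
                    signed = True
                else:
                    gene = tok
                    weights[gene] = +1
                if gene not in genes:
                    genes.append(gene)
            sets[name] = GeneSet(frozenset(genes), weights if signed else None)
    return GeneSetCollection(sets)


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, gs in coll:
            if gs.weights is not None:
                tokens = [f"{g}|{gs.weights[g]:+d}" for g in sorted(gs.genes)]
            else:
                tokens = sorted(gs.genes)
            fh.write("\t".join([name, "na", *tokens]) + "\n")


def read_methylation(
    beta_path: str | Path, annotation_path: str | Path | None = None
) -> tuple[MethylationMatrix, ProbeAnnotation]:
    """Read a probe-by-sample beta TSV and an optional probe annotation TSV.

    Annotation rows are ``probe<TAB>gene;gene<TAB>region;region`` with the
    gene and region lists aligned position by position.  Probes present in
    the beta matrix but absent from the annotation are retained with an
    empty annotation.
    """
    beta = MethylationMatrix(_read_table(beta_path).astype(float))
    mapping: dict[str, list[tuple[str, str]]] = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
        cols = list(ann.columns[:3])
        for _, row in ann.iterrows():
            probe = row[cols[0]]
            genes = str(row[cols[1]]).split(";")
            regions = str(row[cols[2]]).split(";")
            if len(genes) != len(regions):
                raise ValueError(f"probe {probe!r}: gene/region list length mismatch")
            mapping[probe] = list(zip(genes, regions))
    return beta, ProbeAnnotation(mapping)


def write_methylation(
    beta: MethylationMatrix, annotation: ProbeAnnotation, beta_path: str | Path, annotation_path: str | Path
) -> None:
    beta.values.to_csv(beta_path, sep="\t", index_label="probe")
    rows = []
    for probe, pairs in annotation.mapping.items():
        rows.append(
            {
                "probe": probe,
                "gene": ";".join(g for g, _ in pairs),
                "region": ";".join(r for _, r in pairs),
            }
        )
    pd.DataFrame(rows, columns=["probe", "gene", "region"]).to_csv(
        annotation_path, sep="\t", index=False
    )


def read_regulators(path: str | Path) -> RegulatorCatalog:
    """Read a two-column TSV (gene, role) overriding the default catalog."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "role"], dtype=str)
    return RegulatorCatalog(dict(zip(df["gene"], df["role"])))
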