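"""Validated containers and readers/writers for the formats every stage touches.

Expression matrices travel as TSV (genes in rows, header = sample ids),
sample groups as a two-column TSV, gene sets as GMT, interaction networks
as SIF or two-column TSV, and result tables as TSV with a fixed column
order so diffs are stable.  Gene identifiers are case-sensitive strings
and are never remapped.  All containers sort genes internally so that
permuting input rows never changes downstream results.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Set

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
CASE = "case"

#: format used for floating point output; round-trips IEEE doubles exactly
FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------

@dataclass
class ExpressionStudy:
    """A genes x samples log2-scale expression matrix with group labels.

    Parameters
    ----------
    study_id : str
        Free-text identifier for the study.
    values : pandas.DataFrame
        Expression values, genes in rows, samples in columns. Missing
        values are permitted (NaN).
    sample_groups : mapping of sample id -> ``"control"`` or ``"case"``
    gene_chromosomes : mapping of gene id -> chromosome label (optional)
    """

    study_id: str
    values: pd.DataFrame
    sample_groups: Dict[str, str]
    gene_chromosomes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dup = sorted(map(str, idx[idx.duplicated()].unique()))
            raise ValueError(f"duplicate gene id(s): {', '.join(dup)}")
        cols = self.values.columns
        if cols.duplicated().any():
            dup = sorted(map(str, cols[cols.duplicated()].unique()))
            raise ValueError(f"duplicate sample id(s): {', '.join(dup)}")
        absent = [s for s in cols if s not in self.sample_groups]
        if absent:
            raise ValueError(
                f"samples missing from the groups file: {', '.join(map(str, absent))}"
            )
        bad = set(self.sample_groups.values()) - {CONTROL, CASE}
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")
        if not self.controls:
            raise ValueError("study has no control samples")
        if not self.cases:
            raise ValueError("study has no case samples")
        # sorted internal gene order makes outputs row-order invariant
        self.values = self.values.sort_index()
        self.values.index.name = "gene"

    @property
    def controls(self) -> list:
        return [s for s in self.values.columns if self.sample_groups[s] == CONTROL]

    @property
    def cases(self) -> list:
        return [s for s in self.values.columns if self.sample_groups[s] == CASE]

    @property
    def genes(self) -> list:
        return list(self.values.index)

    def drop_sparse_genes(self, max_missing_frac: float = 0.2) -> "ExpressionStudy":
        """Drop genes with missing values in more than ``max_missing_frac``
        of the samples (the downstream filters need complete per-gene
        vectors); the number dropped is logged."""
        frac = self.values.isna().mean(axis=1)
        keep = frac <= max_missing_frac
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning(
                "%s: dropping %d gene(s) with >%g%% missing values",
                self.study_id, n_drop, 100 * max_missing_frac,
            )
        return ExpressionStudy(
            self.study_id, self.values.loc[keep], dict(self.sample_groups),
            dict(self.gene_chromosomes),
        )


def read_groups_tsv(path) -> Dict[str, str]:
    """Two-column (sample, group) TSV without header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    return dict(zip(df["sample"], df["group"]))


def write_groups_tsv(groups: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")


def read_expression_tsv(path, groups_path, study_id: str | None = None,
                        max_missing_frac: float = 0.2) -> ExpressionStudy:
    """Load an expression matrix TSV plus its groups file.

    The first column holds gene ids, the header row sample ids.
    Duplicated gene rows and samples absent from the groups file are hard
    errors; genes too sparse to analyse are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    df.index = df.index.astype(str)
    groups = read_groups_tsv(groups_path)
    study = ExpressionStudy(study_id or str(path), df, groups)
    return study.drop_sparse_genes(max_missing_frac)


def write_expression_tsv(study: ExpressionStudy, path, groups_path=None) -> None:
    study.values.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)
    if groups_path is not None:
        write_groups_tsv(study.sample_groups, groups_path)


def read_chromosomes_tsv(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "chromosome"],
                     dtype=str)
    return dict(zip(df["gene"], df["chromosome"]))


def write_chromosomes_tsv(chromosomes: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(chromosomes):
            fh.write(f"{g}\t{chromosomes[g]}\n")


# ---------------------------------------------------------------------------
# study-level effect tables (meta-analysis summaries)
# ---------------------------------------------------------------------------

EFFECT_COLUMNS = ["gene", "study_id", "log2fc_mean", "se", "presence_p"]


@dataclass
class StudyEffectTable:
    """Long-format per-(gene, study) effect summaries.

    Columns: gene, study_id, log2fc_mean, se (>= 0) and presence_p in
    [0, 1] (per-study evidence that the transcript is expressed).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EFFECT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"effect table missing column(s): {missing}")
        df = self.data[EFFECT_COLUMNS].copy()
        df["gene"] = df["gene"].astype(str)
        df["study_id"] = df["study_id"].astype(str)
        if df.duplicated(["gene", "study_id"]).any():
            dup = df[df.duplicated(["gene", "study_id"])].iloc[0]
            raise ValueError(
                f"duplicate (gene, study) pair: ({dup['gene']}, {dup['study_id']})"
            )
        if ((df["presence_p"] < 0) | (df["presence_p"] > 1)).any():
            raise ValueError("presence_p outside [0, 1]")
        if (df["se"] < 0).any():
            raise ValueError("negative standard error")
        self.data = df.sort_values(["gene", "study_id"], kind="mergesort").reset_index(drop=True)

    @property
    def genes(self) -> list:
        return sorted(self.data["gene"].unique())

    @property
    def studies(self) -> list:
        return sorted(self.data["study_id"].unique())


def read_effect_table(path) -> StudyEffectTable:
    return StudyEffectTable(pd.read_csv(path, sep="\t"))


def write_effect_table(table: StudyEffectTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: Dict[str, Set[str]] = field(default_factory=dict)
    descriptions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = set(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.sets))

    def __getitem__(self, name: str) -> Set[str]:
        return self.sets[name]

    def items(self):
        return ((name, self.sets[name]) for name in self)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB gene TAB gene ...``.

    Duplicate genes within a line are deduplicated with a logged warning;
    a line with fewer than three fields is an error naming the line.
    """
    sets: Dict[str, Set[str]] = {}
    descriptions: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), expected >= 3"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g != ""]
            if len(set(genes)) < len(genes):
                logger.warning("%s:%d: duplicate genes in set %r deduplicated",
                               path, lineno, name)
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# interaction networks (SIF / 2-column TSV)
# ---------------------------------------------------------------------------

def read_edge_list(path) -> nx.Graph:
    """Load an undirected interaction network.

    Accepts two-column TSV (``A<TAB>B``) or three-column SIF
    (``A<sep>interaction<sep>B``, tab- or whitespace-separated). Self
    loops are dropped with a warning, duplicate/reversed edges collapse,
    and a blank gene field is an error naming the line.
    """
    graph = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) == 2:
                a, b = fields
            elif len(fields) == 3:
                a, _, b = fields
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 fields, got {len(fields)}")
            if not a.strip() or not b.strip():
                raise ValueError(f"{path}:{lineno}: blank gene field")
            a, b = a.strip(), b.strip()
            if a == b:
                n_loops += 1
                continue
            graph.add_edge(a, b)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    return graph


def write_sif(graph: nx.Graph, path, interaction: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{interaction}\t{b}\n")


# ---------------------------------------------------------------------------
# plain gene lists and stable result tables
# ---------------------------------------------------------------------------

def read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_result_tsv(df: pd.DataFrame, path, columns: list | None = None) -> None:
    """Write a result table with a fixed column order and stable float
    formatting so reruns are byte-identical."""
    if columns is not None:
        df = df[columns]
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
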