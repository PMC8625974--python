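"""Validated containers and TSV/FASTA/GMT/network readers and writers.

All tabular formats are tab-separated UTF-8 with a mandatory header row and
the gene identifier in column 1.  Readers refuse silently-coerced data:
duplicate identifiers, NaN and negative abundances are hard errors, never
passed through.  Sequence-site coordinates are 0-based half-open on the
target's sense strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import SchemaError, UsageError, ValidationError
from .graph import GeneNetwork

GENE_CLASSES = ("lncRNA", "miRNA", "mRNA")
COMPARTMENTS = ("Cytoplasm", "Nucleus", "Ribosome", "Exosome")

# -- expression matrices ---------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table (FPKM/TPM-like, non-negative).

    ``values`` is a pandas DataFrame indexed by gene id with sample ids as
    columns; ``gene_class`` tags the whole matrix.
    """

    values: pd.DataFrame
    gene_class: str

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValidationError(f"unknown gene class {self.gene_class!r}")
        df = self.values
        if df.shape[0] < 1:
            raise ValidationError("expression matrix must have at least one gene row")
        if df.shape[1] < 2:
            raise ValidationError("expression matrix must have at least two samples")
        dup_genes = df.index[df.index.duplicated()].unique().tolist()
        if dup_genes:
            raise ValidationError(f"duplicate gene ids: {dup_genes}")
        dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise ValidationError(f"duplicate sample ids: {dup_samples}")
        arr = df.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            gi, si = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"non-finite or negative value {arr[gi, si]!r} at "
                f"gene {df.index[gi]!r}, sample {df.columns[si]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(gene_ids)]
        return ExpressionMatrix(self.values.loc[keep].copy(), self.gene_class)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy(dtype=float)


def read_expression_matrix(path: str | Path, gene_class: str) -> ExpressionMatrix:
    """Read a TSV abundance matrix (gene id in column 1, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric abundance in {path}: {exc}") from None
    return ExpressionMatrix(df, gene_class)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


# -- sample design ---------------------------------------------------------


@dataclass
class SampleDesign:
    """Maps sample id -> (stage, replicate) with an explicit stage order."""

    samples: dict[str, tuple[str, int]]
    stage_order: list[str]

    def __post_init__(self) -> None:
        stages_seen = {s for s, _ in self.samples.values()}
        missing = stages_seen - set(self.stage_order)
        if missing:
            raise ValidationError(f"stages missing from stage_order: {sorted(missing)}")
        for stage in self.stage_order:
            if len(self.samples_for_stage(stage)) < 2:
                raise ValidationError(
                    f"stage {stage!r} has fewer than two replicates"
                )

    def samples_for_stage(self, stage: str) -> list[str]:
        return [sid for sid, (s, _) in self.samples.items() if s == stage]

    def check_matrix(self, expr: ExpressionMatrix) -> None:
        unknown = [s for s in expr.sample_ids if s not in self.samples]
        if unknown:
            raise ValidationError(f"samples absent from design: {unknown}")

    @classmethod
    def from_sample_ids(
        cls, sample_ids: Iterable[str], stage_order: list[str] | None = None
    ) -> "SampleDesign":
        """Parse 'STAGE_rep' sample names; stage order = order of appearance."""
        samples: dict[str, tuple[str, int]] = {}
        order: list[str] = []
        for sid in sample_ids:
            stage, _, rep = sid.rpartition("_")
            if not stage or not rep.isdigit():
                raise ValidationError(f"sample id {sid!r} is not of the form STAGE_rep")
            samples[sid] = (stage, int(rep))
            if stage not in order:
                order.append(stage)
        return cls(samples, stage_order if stage_order is not None else order)


def read_sample_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "stage", "replicate"}
    if not required.issubset(df.columns):
        raise SchemaError(f"design file must have columns {sorted(required)}")
    samples = {
        str(r.sample_id): (str(r.stage), int(r.replicate)) for r in df.itertuples()
    }
    if len(samples) != len(df):
        raise ValidationError("duplicate sample ids in design file")
    stage_order = list(dict.fromkeys(df["stage"].astype(str)))
    return SampleDesign(samples, stage_order)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    rows = [
        {"sample_id": sid, "stage": stage, "replicate": rep}
        for sid, (stage, rep) in design.samples.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- localization ----------------------------------------------------------


@dataclass
class LocalizationTable:
    """lncRNA id -> subcellular compartment (fixed four-label vocabulary)."""

    compartments: dict[str, str]

    def __post_init__(self) -> None:
        canon = {c.lower(): c for c in COMPARTMENTS}
        fixed = {}
        for lnc, comp in self.compartments.items():
            if comp.lower() not in canon:
                raise ValidationError(
                    f"unknown compartment {comp!r} for {lnc!r}; "
                    f"expected one of {COMPARTMENTS}"
                )
            fixed[lnc] = canon[comp.lower()]
        self.compartments = fixed

    def is_cytoplasmic(self, lnc_id: str) -> bool | None:
        comp = self.compartments.get(lnc_id)
        return None if comp is None else comp == "Cytoplasm"


def read_localization_table(path: str | Path) -> LocalizationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"lnc_id", "compartment"}
    if not required.issubset(df.columns):
        raise SchemaError(f"localization file must have columns {sorted(required)}")
    if df["lnc_id"].duplicated().any():
        dups = df.loc[df["lnc_id"].duplicated(), "lnc_id"].tolist()
        raise ValidationError(f"duplicate lncRNA ids in localization table: {dups}")
    return LocalizationTable(dict(zip(df["lnc_id"], df["compartment"])))


def write_localization_table(table: LocalizationTable, path: str | Path) -> None:
    pd.DataFrame(
        sorted(table.compartments.items()), columns=["lnc_id", "compartment"]
    ).to_csv(path, sep="\t", index=False)


# -- target tables ---------------------------------------------------------


@dataclass
class TargetTable:
    """Deduplicated miRNA -> target relationships.

    ``frame`` columns: mirna_id, target_id, target_class, site_class, source.
    (miRNA, target) pairs are unique per source tag.
    """

    frame: pd.DataFrame

    COLUMNS = ("mirna_id", "target_id", "target_class", "site_class", "source")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"target table missing columns: {missing}")
        self.frame = (
            self.frame.loc[:, list(self.COLUMNS)]
            .astype(str)
            .drop_duplicates(subset=["mirna_id", "target_id", "source"])
            .sort_values(["mirna_id", "target_id"], kind="stable")
            .reset_index(drop=True)
        )
        per_target = self.frame.groupby("target_id")["target_class"].nunique()
        bad = per_target[per_target > 1].index.tolist()
        if bad:
            raise ValidationError(f"targets with inconsistent class: {bad}")

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.frame["mirna_id"], self.frame["target_id"]))

    def __len__(self) -> int:
        return len(self.frame)


def read_target_table(path: str | Path) -> TargetTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "mirna_id" not in df.columns or "target_id" not in df.columns:
        raise SchemaError(
            "target table requires 'mirna_id' and 'target_id' columns, "
            f"got {list(df.columns)}"
        )
    if "target_class" not in df.columns:
        df["target_class"] = "mRNA"
    if "site_class" not in df.columns:
        df["site_class"] = "external"
    if "source" not in df.columns:
        df["source"] = "external"
    return TargetTable(df)


def write_target_table(table: TargetTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# -- annotation sets (GMT-like) -------------------------------------------


@dataclass
class AnnotationSets:
    """set id -> (description, member gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for sid, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"annotation set {sid!r} is empty")


def read_annotation_sets(path: str | Path) -> AnnotationSets:
    """GMT dialect: set id <TAB> description <TAB> member1 <TAB> member2 ..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise SchemaError(f"{path}:{lineno}: expected id, description, members")
        sid, desc, members = fields[0], fields[1], fields[2:]
        if sid in sets:
            raise ValidationError(f"duplicate set id {sid!r}")
        sets[sid] = (desc, frozenset(m for m in members if m))
    return AnnotationSets(sets)


# -- FASTA -----------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence mapping (ids must be unique)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns


# -- network export --------------------------------------------------------

NETWORK_FORMATS = ("gml", "graphml", "edge_tsv")


def write_network(net: GeneNetwork, path: str | Path, format: str = "gml") -> None:
    """Export with per-node type/degree attributes and per-edge kind."""
    if net.n_nodes == 0:
        raise ValidationError("empty network")
    if format not in NETWORK_FORMATS:
        raise UsageError(f"unknown network format {format!r}; use {NETWORK_FORMATS}")
    g = nx.Graph()
    degrees = net.degrees()
    for n in sorted(net.graph.nodes):
        g.add_node(n, type=net.node_class(n), degree=degrees[n])
    for u, v, d in sorted(net.graph.edges(data=True)):
        g.add_edge(u, v, kind=d["kind"])
    if format == "gml":
        nx.write_gml(g, str(path))
    elif format == "graphml":
        nx.write_graphml(g, str(path))
    else:
        rows = [
            {
                "source": u,
                "target": v,
                "source_class": g.nodes[u]["type"],
                "target_class": g.nodes[v]["type"],
                "kind": d["kind"],
            }
            for u, v, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(
            rows, columns=["source", "target", "source_class", "target_class", "kind"]
        ).to_csv(path, sep="\t", index=False)


def read_network(path: str | Path, format: str = "gml") -> GeneNetwork:
    if format not in NETWORK_FORMATS:
        raise UsageError(f"unknown network format {format!r}; use {NETWORK_FORMATS}")
    net = GeneNetwork()
    if format in ("gml", "graphml"):
        g = nx.read_gml(str(path)) if format == "gml" else nx.read_graphml(str(path))
        for n, d in g.nodes(data=True):
            net.add_node(str(n), d["type"])
        for u, v, d in g.edges(data=True):
            net.add_edge(str(u), str(v), d["kind"])
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"source", "target", "source_class", "target_class", "kind"}
        if not required.issubset(df.columns):
            raise SchemaError(f"edge TSV must have columns {sorted(required)}")
        for r in df.itertuples():
            net.add_node(r.source, r.source_class)
            net.add_node(r.target, r.target_class)
            net.add_edge(r.source, r.target, r.kind)
    return net
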