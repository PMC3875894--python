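"""Indexed store for the four relational inputs of the PPL pipeline.

Four flat tables stand in for the public databases the analysis integrates:
gene coordinates (Gencode-like), miRNA coordinates (miRBase-like), miRNA
target predictions carrying mirSVR scores and conservation labels
(microRNA.org-like), and transcription-factor/target relations
(TargetMine/TFe-like).  All coordinates are 1-based and inclusive on both
ends.  Containment queries (which miRNAs lie inside a gene, which genes
embrace a miRNA) ignore strand: intragenic miRNAs on both the sense and the
anti-sense strand of their host gene count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

GOOD_CONSERVATION = frozenset({"good_conserved", "good_nonconserved"})

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand"]
MIRNA_COLUMNS = ["mirna_name", "chrom", "start", "end", "strand"]
TARGET_COLUMNS = ["mirna_name", "gene_id", "mirsvr_score", "conservation_class"]
TF_COLUMNS = ["tf_gene_id", "target_gene_id", "source"]


class KnowledgeBaseError(ValueError):
    """Malformed input table or unresolvable lookup."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, fully closed genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise KnowledgeBaseError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise KnowledgeBaseError(
                f"end ({self.end}) precedes start ({self.start})"
            )
        if self.strand not in {"+", "-"}:
            raise KnowledgeBaseError(f"strand must be + or -, got {self.strand!r}")

    def contains(self, other: "GenomicInterval") -> bool:
        """Both-ends containment on the same chromosome, strand-blind."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    location: GenomicInterval


@dataclass(frozen=True)
class MirnaRecord:
    mirna_name: str
    location: GenomicInterval


@dataclass(frozen=True)
class TargetPrediction:
    """One miRNA->gene prediction with its mirSVR down-regulation score.

    More negative scores mean stronger predicted down-regulation; only the
    two "good score" conservation classes are trusted by the pipeline.
    """

    mirna_name: str
    target_gene_id: str
    mirsvr_score: float
    conservation_class: str


@dataclass(frozen=True)
class TFRelation:
    tf_gene_id: str
    target_gene_id: str
    source: str


@dataclass
class KnowledgeBase:
    """Validated, indexed collection of the four input tables.

    Interval trees per chromosome answer containment queries; dicts keyed by
    identifier answer the relational joins.  ``dangling_counts`` records how
    many target/TF rows referenced identifiers absent from the coordinate
    tables (tolerated with a warning so partial fixtures stay loadable).
    """

    genes: dict[str, GeneRecord] = field(default_factory=dict)
    mirnas: dict[str, MirnaRecord] = field(default_factory=dict)
    targets: list[TargetPrediction] = field(default_factory=list)
    tf_relations: list[TFRelation] = field(default_factory=list)
    dangling_counts: dict[str, int] = field(default_factory=dict)

    _gene_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _mirna_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _targets_by_mirna: dict[str, list[TargetPrediction]] = field(
        default_factory=dict, repr=False
    )
    _tfs_by_target: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def build_indexes(self) -> None:
        self._gene_trees = {}
        for gene in self.genes.values():
            loc = gene.location
            tree = self._gene_trees.setdefault(loc.chrom, IntervalTree())
            # intervaltree is half-open; +1 keeps closed-interval semantics
            tree.addi(loc.start, loc.end + 1, gene)
        self._mirna_trees = {}
        for mirna in self.mirnas.values():
            loc = mirna.location
            tree = self._mirna_trees.setdefault(loc.chrom, IntervalTree())
            tree.addi(loc.start, loc.end + 1, mirna)
        self._targets_by_mirna = {}
        for pred in self.targets:
            self._targets_by_mirna.setdefault(pred.mirna_name, []).append(pred)
        self._tfs_by_target = {}
        for rel in self.tf_relations:
            self._tfs_by_target.setdefault(rel.target_gene_id, set()).add(
                rel.tf_gene_id
            )


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise KnowledgeBaseError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise KnowledgeBaseError(f"{path}: missing columns {missing}")
    return df[columns]


def _parse_interval(row: pd.Series, path: Path, line: int) -> GenomicInterval:
    try:
        return GenomicInterval(
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
            strand=str(row["strand"]),
        )
    except (ValueError, KnowledgeBaseError) as exc:
        raise KnowledgeBaseError(f"{path}, line {line}: {exc}") from exc


def load_knowledge_base(
    gene_table_path: str | Path,
    mirna_table_path: str | Path,
    target_table_path: str | Path,
    tf_table_path: str | Path,
) -> KnowledgeBase:
    """Load and index the four TSV tables into a :class:`KnowledgeBase`.

    Duplicate gene identifiers or malformed rows raise
    :class:`KnowledgeBaseError` naming the file and line.  Target or TF rows
    referencing unknown miRNAs/genes are kept but counted in
    ``dangling_counts`` and logged.
    """
    kb = KnowledgeBase()

    gene_path = Path(gene_table_path)
    genes_df = _read_table(gene_path, GENE_COLUMNS)
    for i, row in enumerate(genes_df.itertuples(index=False), start=2):
        row = pd.Series(row._asdict())
        gene_id = str(row["gene_id"])
        if not gene_id:
            raise KnowledgeBaseError(f"{gene_path}, line {i}: empty gene_id")
        if gene_id in kb.genes:
            raise KnowledgeBaseError(
                f"{gene_path}, line {i}: duplicate gene_id {gene_id!r}"
            )
        kb.genes[gene_id] = GeneRecord(
            gene_id=gene_id,
            symbol=str(row["symbol"]),
            location=_parse_interval(row, gene_path, i),
        )

    mirna_path = Path(mirna_table_path)
    mirnas_df = _read_table(mirna_path, MIRNA_COLUMNS)
    for i, row in enumerate(mirnas_df.itertuples(index=False), start=2):
        row = pd.Series(row._asdict())
        name = str(row["mirna_name"])
        if not name:
            raise KnowledgeBaseError(f"{mirna_path}, line {i}: empty mirna_name")
        if name in kb.mirnas:
            raise KnowledgeBaseError(
                f"{mirna_path}, line {i}: duplicate mirna_name {name!r}"
            )
        kb.mirnas[name] = MirnaRecord(
            mirna_name=name, location=_parse_interval(row, mirna_path, i)
        )

    target_path = Path(target_table_path)
    targets_df = _read_table(target_path, TARGET_COLUMNS)
    dangling_targets = 0
    seen_target_rows: set[tuple[str, str, str]] = set()
    for i, row in enumerate(targets_df.itertuples(index=False), start=2):
        row = pd.Series(row._asdict())
        try:
            score = float(row["mirsvr_score"])
        except ValueError as exc:
            raise KnowledgeBaseError(
                f"{target_path}, line {i}: bad mirsvr_score {row['mirsvr_score']!r}"
            ) from exc
        if not pd.notna(score) or score != score or abs(score) == float("inf"):
            raise KnowledgeBaseError(
                f"{target_path}, line {i}: non-finite mirsvr_score"
            )
        key = (str(row["mirna_name"]), str(row["gene_id"]), str(row["conservation_class"]))
        if key in seen_target_rows:
            raise KnowledgeBaseError(
                f"{target_path}, line {i}: duplicate prediction row {key}"
            )
        seen_target_rows.add(key)
        if key[0] not in kb.mirnas:
            dangling_targets += 1
        kb.targets.append(
            TargetPrediction(
                mirna_name=key[0],
                target_gene_id=key[1],
                mirsvr_score=score,
                conservation_class=key[2],
            )
        )

    tf_path = Path(tf_table_path)
    tf_df = _read_table(tf_path, TF_COLUMNS)
    dangling_tfs = 0
    seen_tf_rows: set[tuple[str, str, str]] = set()
    for i, row in enumerate(tf_df.itertuples(index=False), start=2):
        row = pd.Series(row._asdict())
        key = (str(row["tf_gene_id"]), str(row["target_gene_id"]), str(row["source"]))
        if key in seen_tf_rows:
            raise KnowledgeBaseError(
                f"{tf_path}, line {i}: duplicate TF relation {key}"
            )
        seen_tf_rows.add(key)
        if key[0] not in kb.genes or key[1] not in kb.genes:
            dangling_tfs += 1
        kb.tf_relations.append(
            TFRelation(tf_gene_id=key[0], target_gene_id=key[1], source=key[2])
        )

    kb.dangling_counts = {"targets": dangling_targets, "tf_relations": dangling_tfs}
    if dangling_targets or dangling_tfs:
        logger.warning(
            "dangling references: %d target rows, %d TF rows",
            dangling_targets,
            dangling_tfs,
        )
    kb.build_indexes()
    return kb


def build_knowledge_base(
    genes: Iterable[GeneRecord],
    mirnas: Iterable[MirnaRecord],
    targets: Iterable[TargetPrediction],
    tf_relations: Iterable[TFRelation],
) -> KnowledgeBase:
    """Assemble a KnowledgeBase directly from records (no file I/O)."""
    kb = KnowledgeBase()
    for g in genes:
        if g.gene_id in kb.genes:
            raise KnowledgeBaseError(f"duplicate gene_id {g.gene_id!r}")
        kb.genes[g.gene_id] = g
    for m in mirnas:
        if m.mirna_name in kb.mirnas:
            raise KnowledgeBaseError(f"duplicate mirna_name {m.mirna_name!r}")
        kb.mirnas[m.mirna_name] = m
    kb.targets = list(targets)
    kb.tf_relations = list(tf_relations)
    kb.dangling_counts = {
        "targets": sum(1 for t in kb.targets if t.mirna_name not in kb.mirnas),
        "tf_relations": sum(
            1
            for r in kb.tf_relations
            if r.tf_gene_id not in kb.genes or r.target_gene_id not in kb.genes
        ),
    }
    kb.build_indexes()
    return kb


def find_intragenic_mirnas(gene: GeneRecord, kb: KnowledgeBase) -> list[MirnaRecord]:
    """miRNAs whose coordinates are embedded in the gene's, either strand.

    Sorted by miRNA name for deterministic downstream enumeration.
    """
    if gene.gene_id not in kb.genes:
        raise KnowledgeBaseError(f"gene {gene.gene_id!r} not in knowledge base")
    loc = gene.location
    tree = kb._mirna_trees.get(loc.chrom)
    if tree is None:
        return []
    hits = [
        iv.data
        for iv in tree.overlap(loc.start, loc.end + 1)
        if loc.contains(iv.data.location)
    ]
    return sorted(hits, key=lambda m: m.mirna_name)


def find_host_genes(mirna: MirnaRecord, kb: KnowledgeBase) -> list[GeneRecord]:
    """Genes whose coordinates embrace the miRNA's; empty if intergenic."""
    if mirna.mirna_name not in kb.mirnas:
        raise KnowledgeBaseError(f"miRNA {mirna.mirna_name!r} not in knowledge base")
    loc = mirna.location
    tree = kb._gene_trees.get(loc.chrom)
    if tree is None:
        return []
    hits = [
        iv.data
        for iv in tree.overlap(loc.start, loc.end + 1)
        if iv.data.location.contains(loc)
    ]
    return sorted(hits, key=lambda g: g.gene_id)


def get_targets(
    mirna_name: str, threshold: float, kb: KnowledgeBase
) -> list[TargetPrediction]:
    """Filtered predictions for one miRNA: good-conservation classes only,
    mirSVR score strictly below ``threshold`` (threshold must be negative).

    Unknown miRNA names yield an empty list.
    """
    if threshold >= 0:
        raise ValueError(f"mirSVR threshold must be negative, got {threshold}")
    preds = kb._targets_by_mirna.get(mirna_name, [])
    return [
        p
        for p in preds
        if p.conservation_class in GOOD_CONSERVATION and p.mirsvr_score < threshold
    ]


def get_tfs(gene_id: str, kb: KnowledgeBase) -> list[str]:
    """Transcription factors of ``gene_id``, merged across sources, sorted."""
    return sorted(kb._tfs_by_target.get(gene_id, set()))
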