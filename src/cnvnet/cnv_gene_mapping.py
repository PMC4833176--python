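"""Assigning genes to copy-number variants.

Copy-number gains and losses are assigned to genes under asymmetric rules
reflecting how each dosage change perturbs a protein product:

* **gain-genes** — a gene is assigned to a gain only if the gain completely
  contains the gene's span (the union of all its transcripts), so every
  expressed isoform gains a copy;
* **loss-genes** — a gene is assigned to a loss only if the loss overlaps at
  least one coding exon in *every* coding transcript of the gene, so no
  isoform escapes with an intact coding sequence.

Coordinates are held internally as 0-based half-open intervals; input tables
may be declared as BED-style (already half-open) or 1-based inclusive.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigurationError, RecordError

logger = logging.getLogger(__name__)


class Dosage(str, Enum):
    GAIN = "gain"
    LOSS = "loss"


class Origin(str, Enum):
    DE_NOVO = "de_novo"
    INHERITED = "inherited"
    UNKNOWN = "unknown"


class AssignmentRule(str, Enum):
    GAIN_FULL_OVERLAP = "gain_full_overlap"
    LOSS_CODING_ALL_TRANSCRIPTS = "loss_coding_all_transcripts"


#: dosage labels accepted by default when loading CNV tables
DEFAULT_DOSAGE_MAP: dict[str, Dosage] = {
    "gain": Dosage.GAIN,
    "loss": Dosage.LOSS,
    "dup": Dosage.GAIN,
    "del": Dosage.LOSS,
    "duplication": Dosage.GAIN,
    "deletion": Dosage.LOSS,
}

COORDINATE_DIALECTS = ("bed", "one_based")


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix; chromosome names stay strings (X, Y)."""
    s = str(chrom).strip()
    return s[3:] if s.lower().startswith("chr") else s


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CnvRecord:
    subject_id: str
    cohort_id: str
    interval: GenomicInterval
    dosage: Dosage
    origin: Origin = Origin.UNKNOWN

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exons plus the coding portion of each exon.

    ``coding_exons`` may be empty for non-coding isoforms.
    """

    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    coding_exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self):
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end or cur.chrom != prev.chrom:
                raise ValueError(
                    f"exons of {self.transcript_id} must be sorted and non-overlapping"
                )
        for ce in self.coding_exons:
            if not any(ex.contains(ce) for ex in self.exons):
                raise ValueError(
                    f"coding exon {ce} of {self.transcript_id} outside exon union"
                )

    @property
    def is_coding(self) -> bool:
        return bool(self.coding_exons)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        chroms = {ex.chrom for tx in self.transcripts for ex in tx.exons}
        if len(chroms) != 1:
            raise ValueError(f"gene {self.gene_id} spans multiple chromosomes")

    @property
    def span(self) -> GenomicInterval:
        """Union extent over all transcripts."""
        starts = [ex.start for tx in self.transcripts for ex in tx.exons]
        ends = [ex.end for tx in self.transcripts for ex in tx.exons]
        chrom = self.transcripts[0].exons[0].chrom
        return GenomicInterval(chrom, min(starts), max(ends))

    @property
    def coding_transcripts(self) -> tuple[TranscriptModel, ...]:
        return tuple(tx for tx in self.transcripts if tx.is_coding)


@dataclass(frozen=True)
class CnvGeneAssignment:
    gene_id: str
    cnv: CnvRecord
    rule: AssignmentRule

    def __post_init__(self):
        expected = (
            AssignmentRule.GAIN_FULL_OVERLAP
            if self.cnv.dosage is Dosage.GAIN
            else AssignmentRule.LOSS_CODING_ALL_TRANSCRIPTS
        )
        if self.rule is not expected:
            raise ValueError(f"rule {self.rule} inconsistent with {self.cnv.dosage}")


# ---------------------------------------------------------------------------
# input / output


def load_cnvs(
    path: str | Path,
    coordinate_dialect: str = "one_based",
    dosage_map: Mapping[str, Dosage] | None = None,
) -> list[CnvRecord]:
    """Read a CNV call table (TSV with header) into internal records.

    Required columns: subject, chrom, start, end, dosage. Optional: cohort,
    origin. ``coordinate_dialect`` is ``"bed"`` (0-based half-open, used
    as-is) or ``"one_based"`` (1-based inclusive; start is shifted by -1).
    Malformed rows are collected and reported together with line numbers.
    """
    if coordinate_dialect not in COORDINATE_DIALECTS:
        raise ConfigurationError(
            f"unknown coordinate dialect {coordinate_dialect!r}; "
            f"expected one of {COORDINATE_DIALECTS}"
        )
    dmap = {k.lower(): v for k, v in (dosage_map or DEFAULT_DOSAGE_MAP).items()}
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject", "chrom", "start", "end", "dosage"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {sorted(missing)}")

    records: list[CnvRecord] = []
    bad: list[tuple[int, str]] = []
    offset = -1 if coordinate_dialect == "one_based" else 0
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        try:
            start = int(row.start) + offset
            end = int(row.end)
        except (TypeError, ValueError):
            bad.append((line_no, f"non-integer coordinates {row.start!r}/{row.end!r}"))
            continue
        if start >= end:
            bad.append((line_no, f"empty interval after conversion [{start}, {end})"))
            continue
        dosage = dmap.get(str(row.dosage).lower())
        if dosage is None:
            bad.append((line_no, f"unknown dosage label {row.dosage!r}"))
            continue
        origin = Origin.UNKNOWN
        if "origin" in df.columns:
            raw = str(getattr(row, "origin"))
            try:
                origin = Origin(raw)
            except ValueError:
                bad.append((line_no, f"unknown origin label {raw!r}"))
                continue
        records.append(
            CnvRecord(
                subject_id=str(row.subject),
                cohort_id=str(getattr(row, "cohort", "unknown")) if "cohort" in df.columns else "unknown",
                interval=GenomicInterval(normalize_chrom(row.chrom), start, end),
                dosage=dosage,
                origin=origin,
            )
        )
    if bad:
        raise RecordError(f"{path}: {len(bad)} malformed row(s)", bad)
    return records


def load_gene_models_tsv(path: str | Path) -> list[GeneModel]:
    """Read a flattened transcript table (one row per exon).

    Columns: gene_id, transcript_id, chrom, exon_start, exon_end and
    optionally cds_start, cds_end (empty for wholly non-coding exons).
    Coordinates are 0-based half-open as written by this package.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "transcript_id": str, "chrom": str})
    required = {"gene_id", "transcript_id", "chrom", "exon_start", "exon_end"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {sorted(missing)}")
    genes: list[GeneModel] = []
    for gene_id, gdf in df.groupby("gene_id", sort=True):
        transcripts = []
        for tx_id, tdf in gdf.groupby("transcript_id", sort=True):
            tdf = tdf.sort_values("exon_start")
            chrom = normalize_chrom(tdf.iloc[0]["chrom"])
            exons = tuple(
                GenomicInterval(chrom, int(r.exon_start), int(r.exon_end))
                for r in tdf.itertuples()
            )
            coding = []
            if {"cds_start", "cds_end"} <= set(tdf.columns):
                for r in tdf.itertuples():
                    if pd.notna(r.cds_start) and pd.notna(r.cds_end):
                        coding.append(GenomicInterval(chrom, int(r.cds_start), int(r.cds_end)))
            transcripts.append(TranscriptModel(str(tx_id), exons, tuple(coding)))
        genes.append(GeneModel(str(gene_id), tuple(transcripts)))
    return genes


def load_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene / mRNA / exon / CDS features).

    GFF3 is 1-based inclusive; coordinates are converted to the internal
    0-based half-open convention on load.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        transcripts = []
        for t in db.children(g, featuretype="mRNA", order_by="start"):
            chrom = normalize_chrom(t.seqid)
            exons = tuple(
                GenomicInterval(chrom, ex.start - 1, ex.end)
                for ex in db.children(t, featuretype="exon", order_by="start")
            )
            cds = tuple(
                GenomicInterval(chrom, c.start - 1, c.end)
                for c in db.children(t, featuretype="CDS", order_by="start")
            )
            transcripts.append(TranscriptModel(t.id, exons, cds))
        if transcripts:
            genes.append(GeneModel(g.id, tuple(transcripts)))
    return genes


def write_assignments(assignments: Iterable[CnvGeneAssignment], path: str | Path) -> None:
    rows = [
        {
            "gene_id": a.gene_id,
            "subject_id": a.cnv.subject_id,
            "cohort_id": a.cnv.cohort_id,
            "chrom": a.cnv.interval.chrom,
            "start": a.cnv.interval.start,
            "end": a.cnv.interval.end,
            "dosage": a.cnv.dosage.value,
            "rule": a.rule.value,
        }
        for a in assignments
    ]
    pd.DataFrame(rows).sort_values(["gene_id", "subject_id", "start"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# assignment rules


def filter_large_cnvs(cnvs: Sequence[CnvRecord], min_length_bp: int) -> list[CnvRecord]:
    """Retain CNVs strictly longer than ``min_length_bp``."""
    if min_length_bp <= 0:
        raise ValueError("min_length_bp must be positive")
    return [c for c in cnvs if c.length > min_length_bp]


def _span_trees(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene in genes:
        span = gene.span
        trees[span.chrom].addi(span.start, span.end, gene)
    return trees


def assign_gain_genes(
    gains: Sequence[CnvRecord],
    genes: Sequence[GeneModel],
    _trees: dict[str, IntervalTree] | None = None,
) -> set[CnvGeneAssignment]:
    """Genes whose whole span is contained within a gain.

    A gene may be assigned to several gains; partial overlap never counts.
    """
    trees = _trees if _trees is not None else _span_trees(genes)
    out: set[CnvGeneAssignment] = set()
    for cnv in gains:
        if cnv.dosage is not Dosage.GAIN:
            raise ValueError(f"assign_gain_genes received a {cnv.dosage.value} record")
        tree = trees.get(cnv.interval.chrom)
        if tree is None:
            continue
        for iv in tree.envelop(cnv.interval.start, cnv.interval.end):
            out.add(CnvGeneAssignment(iv.data.gene_id, cnv, AssignmentRule.GAIN_FULL_OVERLAP))
    return out


def assign_loss_genes(
    losses: Sequence[CnvRecord],
    genes: Sequence[GeneModel],
    _trees: dict[str, IntervalTree] | None = None,
) -> set[CnvGeneAssignment]:
    """Genes for which a loss disrupts a coding exon in every coding transcript.

    Non-coding isoforms are ignored by the all-transcripts quantifier (they
    have no coding exon to disrupt); genes with no coding transcript are
    never loss-genes.
    """
    trees = _trees if _trees is not None else _span_trees(genes)
    out: set[CnvGeneAssignment] = set()
    for cnv in losses:
        if cnv.dosage is not Dosage.LOSS:
            raise ValueError(f"assign_loss_genes received a {cnv.dosage.value} record")
        tree = trees.get(cnv.interval.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(cnv.interval.start, cnv.interval.end):
            gene: GeneModel = iv.data
            coding = gene.coding_transcripts
            if coding and all(
                any(ce.overlaps(cnv.interval) for ce in tx.coding_exons) for tx in coding
            ):
                out.add(
                    CnvGeneAssignment(gene.gene_id, cnv, AssignmentRule.LOSS_CODING_ALL_TRANSCRIPTS)
                )
    return out


def assign_genes(
    cnvs: Sequence[CnvRecord], genes: Sequence[GeneModel]
) -> set[CnvGeneAssignment]:
    """Apply both dosage rules to a mixed CNV list."""
    trees = _span_trees(genes)
    gains = [c for c in cnvs if c.dosage is Dosage.GAIN]
    losses = [c for c in cnvs if c.dosage is Dosage.LOSS]
    return assign_gain_genes(gains, genes, _trees=trees) | assign_loss_genes(
        losses, genes, _trees=trees
    )


def gene_sets_by_dosage(assignments: Iterable[CnvGeneAssignment]) -> dict[Dosage, set[str]]:
    """Collapse assignments to one deduplicated gene set per dosage."""
    out: dict[Dosage, set[str]] = {Dosage.GAIN: set(), Dosage.LOSS: set()}
    for a in assignments:
        out[a.cnv.dosage].add(a.gene_id)
    return out


def filter_control_genes(
    case_genes: Mapping[Dosage, set[str]],
    control_cnvs: Sequence[CnvRecord],
    genes: Sequence[GeneModel],
) -> dict[Dosage, set[str]]:
    """Remove case genes that are copy-changed in the same direction in controls.

    Control CNVs of *all* lengths participate (no size filter), and control
    gene sets are derived with exactly the same assignment rules as cases.
    Direction matters: a gene gained in cases is kept if controls only lose it.
    """
    control_sets = gene_sets_by_dosage(assign_genes(control_cnvs, genes))
    filtered = {
        dosage: set(case_genes.get(dosage, set())) - control_sets[dosage]
        for dosage in (Dosage.GAIN, Dosage.LOSS)
    }
    for dosage in (Dosage.GAIN, Dosage.LOSS):
        removed = len(case_genes.get(dosage, set())) - len(filtered[dosage])
        if removed:
            logger.info("removed %d %s-genes also %sed in controls", removed, dosage.value, dosage.value)
    return filtered
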