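"""Synthetic cohorts with planted structure for every pipeline stage.

The generator emulates, at desk scale, the statistical structure the
analysis assumes:

* a toy genome of non-overlapping multi-transcript gene models (with
  non-coding isoforms and single-exon genes at configurable rates);
* an annotation universe shaped like the real mouse-phenotype resource —
  6,350 annotated genes out of a 26,000-gene pool, a focal behavioural term
  with 439 genes reached through child terms (so ancestor closure is
  exercised), and ~157 sibling behavioural terms with log-uniform sizes;
* case and control CNV cohorts whose gains carry a planted enrichment of
  the focal term among annotated gain-genes, calibrated to a target fold;
* an expression matrix with planted correlated modules under a latent
  factor model, parameterized by the expected within-module correlation.

Everything is deterministic under a fixed seed, and the on-disk writers
emit the same standard formats (TSV / GFF3 / OBO) the loaders consume.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cnv_gene_mapping import (
    CnvRecord,
    Dosage,
    GeneModel,
    GenomicInterval,
    Origin,
    TranscriptModel,
    assign_gain_genes,
)
from .phenotype_annotation import (
    AnnotatedUniverse,
    AnnotationTable,
    OrthologyMap,
    PhenotypeOntology,
    annotate_closure,
)

logger = logging.getLogger(__name__)

# fixed term ids of the synthetic ontology
ROOT_TERM = "PT:0000001"
BEHAVIOURAL_TERM = "PT:0000002"
FOCAL_TERM = "PT:0001000"
GENERIC_TERM = "PT:0900001"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the real cohorts' scale.

    The annotation universe (6,350 annotated genes, 439 in the focal term,
    ~26,000 genes overall) and the CNV cohort (~70 case CNVs above the
    500 kb cutoff, mostly gains) follow the source study's counts; the toy
    genome itself is smaller (3,000 modeled genes on 1.2 Gb) so a full
    pipeline run stays cheap, with annotation sampled uniformly so modeled
    genes are a representative slice of the universe.
    """

    seed: int = 0

    # toy genome & gene models
    n_genes: int = 3000
    n_chromosomes: int = 6
    genome_length: int = 1_200_000_000
    gene_length_range: tuple[int, int] = (5_000, 100_000)
    max_transcripts: int = 5
    max_exons: int = 6
    exon_keep_prob: float = 0.8
    noncoding_isoform_rate: float = 0.1

    # CNV cohorts; the case margins mirror the source cohort's composition
    # (large gains / large losses above the 500 kb cutoff, plus small CNVs)
    n_case_large_gains: int = 52
    n_case_large_losses: int = 19
    n_case_small_cnvs: int = 50
    case_gain_fraction: float = 0.72
    n_control_cnvs: int = 1200
    control_gain_fraction: float = 0.14
    cnv_length_range: tuple[int, int] = (100_000, 5_000_000)
    control_cnv_length_range: tuple[int, int] = (10_000, 5_000_000)
    min_cnv_length: int = 500_000
    de_novo_rate: float = 0.25

    # annotation universe
    total_genes: int = 26_000
    universe_size: int = 6_350
    focal_term_size: int = 439
    n_focal_children: int = 3
    n_other_terms: int = 157
    other_term_size_range: tuple[int, int] = (10, 600)
    planted_fold: float = 3.0

    # expression
    n_samples: int = 120
    n_expression_genes: int = 500
    n_modules: int = 1
    module_size: int = 25
    within_module_r: float = 0.8
    expression_baseline: tuple[float, float] = (4.0, 1.5)
    low_expression_rate: float = 0.1

    def __post_init__(self):
        if self.planted_fold < 0:
            raise ValueError("planted_fold must be >= 0")
        if not self.focal_term_size <= self.universe_size <= self.total_genes:
            raise ValueError("require focal_term_size <= universe_size <= total_genes")
        if not 0 < self.within_module_r < 1:
            raise ValueError("within_module_r must lie in (0, 1)")
        if self.n_modules * self.module_size > self.n_expression_genes:
            raise ValueError("modules do not fit into the expression matrix")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("gene_length_range", "cnv_length_range",
                    "control_cnv_length_range", "other_term_size_range",
                    "expression_baseline"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _human_id(i: int) -> str:
    return f"HG{i + 1:06d}"


def _mouse_id(i: int) -> str:
    return f"MG{i + 1:06d}"


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size=None) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


# ---------------------------------------------------------------------------
# gene models


def make_gene_models(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Non-overlapping gene models packed onto equal-length chromosomes.

    Gene ids are assigned in genomic order from the front of the global
    gene-id pool; which genes end up annotated is decided independently by
    :func:`make_annotation_universe`, so modeled genes are an unbiased
    sample of the universe.
    """
    chrom_len = cfg.genome_length // cfg.n_chromosomes
    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    per_chrom[-1] += cfg.n_genes - sum(per_chrom)

    genes: list[GeneModel] = []
    gene_idx = 0
    for ci in range(cfg.n_chromosomes):
        chrom = str(ci + 1)
        g = per_chrom[ci]
        lengths = _loguniform(rng, *cfg.gene_length_range, size=g).astype(int)
        if lengths.sum() >= chrom_len:
            raise ValueError(
                f"infeasible packing: {g} genes ({lengths.sum()} bp) exceed "
                f"chromosome length {chrom_len}"
            )
        leftover = chrom_len - int(lengths.sum())
        gap_w = rng.random(g + 1) + 0.05
        gaps = np.floor(leftover * gap_w / gap_w.sum()).astype(int)
        starts = np.cumsum(gaps[:g]) + np.concatenate(([0], np.cumsum(lengths[:-1])))
        for j in range(g):
            genes.append(
                _make_gene(
                    cfg, rng, _human_id(gene_idx), chrom, int(starts[j]), int(lengths[j])
                )
            )
            gene_idx += 1
    return genes


def _make_gene(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    start: int,
    length: int,
) -> GeneModel:
    n_ex = int(rng.integers(1, cfg.max_exons + 1))
    n_seg = 2 * n_ex - 1  # exon/intron alternation over the gene span
    w = rng.random(n_seg) + 0.1
    seg = np.maximum((length * w / w.sum()).astype(int), 10)
    bounds = start + np.concatenate(([0], np.cumsum(seg)))
    bounds[-1] = start + length
    master = [
        GenomicInterval(chrom, int(bounds[2 * i]), int(bounds[2 * i + 1]))
        for i in range(n_ex)
        if bounds[2 * i] < bounds[2 * i + 1]
    ]

    n_tx = int(rng.integers(1, cfg.max_transcripts + 1))
    transcripts = []
    for t in range(n_tx):
        keep = rng.random(len(master)) < cfg.exon_keep_prob
        if not keep.any():
            keep[rng.integers(len(master))] = True
        exons = tuple(ex for ex, k in zip(master, keep) if k)
        coding: tuple[GenomicInterval, ...] = ()
        if rng.random() >= cfg.noncoding_isoform_rate:
            first, last = exons[0], exons[-1]
            cds_start = first.start + int(rng.integers(0, max(1, first.length // 2)))
            cds_end = last.end - int(rng.integers(0, max(1, last.length // 2)))
            if cds_start < cds_end:
                coding = tuple(
                    GenomicInterval(chrom, max(ex.start, cds_start), min(ex.end, cds_end))
                    for ex in exons
                    if max(ex.start, cds_start) < min(ex.end, cds_end)
                )
        transcripts.append(TranscriptModel(f"{gene_id}.t{t + 1}", exons, coding))
    return GeneModel(gene_id, tuple(transcripts))


# ---------------------------------------------------------------------------
# annotation universe


def make_annotation_universe(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[PhenotypeOntology, AnnotationTable, OrthologyMap]:
    """Ontology DAG, direct mouse annotations, and a clean 1:1 orthology map.

    The focal term's closure has exactly ``focal_term_size`` genes, all
    annotated onto its child terms so the closure machinery is exercised;
    every universe gene additionally carries a generic (non-behavioural)
    annotation, pinning the universe size at exactly ``universe_size``.
    """
    names = {
        ROOT_TERM: "phenotype (synthetic root)",
        BEHAVIOURAL_TERM: "behavioural/neurological phenotype",
        FOCAL_TERM: "abnormal learning and memory (focal)",
        GENERIC_TERM: "generic non-behavioural phenotype",
    }
    parents: dict[str, frozenset[str]] = {
        ROOT_TERM: frozenset(),
        BEHAVIOURAL_TERM: frozenset({ROOT_TERM}),
        FOCAL_TERM: frozenset({BEHAVIOURAL_TERM}),
        GENERIC_TERM: frozenset({ROOT_TERM}),
    }
    children_ids = [f"PT:{1001 + i:07d}" for i in range(cfg.n_focal_children)]
    for i, cid in enumerate(children_ids):
        parents[cid] = frozenset({FOCAL_TERM})
        names[cid] = f"focal subtype {i + 1}"
    other_ids = [f"PT:{100001 + i:07d}" for i in range(cfg.n_other_terms)]
    for i, oid in enumerate(other_ids):
        parents[oid] = frozenset({BEHAVIOURAL_TERM})
        names[oid] = f"behavioural phenotype {i + 1}"
    onto = PhenotypeOntology(parents=parents, names=names)

    universe_idx = np.sort(rng.choice(cfg.total_genes, size=cfg.universe_size, replace=False))
    focal_idx = rng.choice(universe_idx, size=cfg.focal_term_size, replace=False)

    direct: dict[str, set[str]] = {}

    def _annotate(idx: int, term: str) -> None:
        direct.setdefault(_mouse_id(idx), set()).add(term)

    # focal genes annotated on leaf children only: closure must lift them
    child_choice = rng.integers(0, cfg.n_focal_children, size=focal_idx.size)
    for idx, c in zip(focal_idx, child_choice):
        _annotate(int(idx), children_ids[int(c)])
    # independent sibling behavioural terms with log-uniform sizes
    sizes = _loguniform(rng, *cfg.other_term_size_range, size=len(other_ids)).astype(int)
    for oid, size in zip(other_ids, sizes):
        for idx in rng.choice(universe_idx, size=min(size, universe_idx.size), replace=False):
            _annotate(int(idx), oid)
    # every universe gene has at least the generic annotation
    for idx in universe_idx:
        _annotate(int(idx), GENERIC_TERM)

    ann = AnnotationTable(direct={m: frozenset(ts) for m, ts in direct.items()})
    orth = OrthologyMap(
        human_to_mouse={_human_id(int(i)): _mouse_id(int(i)) for i in universe_idx}
    )
    return onto, ann, orth


# ---------------------------------------------------------------------------
# CNV cohorts


def _draw_cnvs(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    n_gain: int,
    n_loss: int,
    length_range: tuple[int, int],
    cohort_id: str,
    subject_prefix: str,
    subject_pool: int,
) -> list[CnvRecord]:
    chrom_len = cfg.genome_length // cfg.n_chromosomes
    n = n_gain + n_loss
    dosages = [Dosage.GAIN] * n_gain + [Dosage.LOSS] * n_loss
    rng.shuffle(dosages)
    lengths = _loguniform(rng, *length_range, size=n).astype(int)
    chroms = rng.integers(0, cfg.n_chromosomes, size=n)
    subjects = rng.integers(0, max(1, subject_pool), size=n)
    out = []
    for i in range(n):
        L = min(int(lengths[i]), chrom_len - 1)
        start = int(rng.integers(0, chrom_len - L))
        origin = Origin.DE_NOVO if rng.random() < cfg.de_novo_rate else Origin.INHERITED
        out.append(
            CnvRecord(
                subject_id=f"{subject_prefix}{subjects[i] + 1:04d}",
                cohort_id=cohort_id,
                interval=GenomicInterval(str(chroms[i] + 1), start, start + L),
                dosage=dosages[i],
                origin=origin,
            )
        )
    return out


def make_cnv_cohort(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    focal_set: frozenset[str] | set[str],
    rng: np.random.Generator,
    universe_genes: frozenset[str] | set[str] | None = None,
    focal_subsets: Sequence[frozenset[str]] | None = None,
) -> tuple[list[CnvRecord], list[CnvRecord]]:
    """Case and control cohorts with a calibrated focal-gain enrichment.

    Case CNVs start out uniformly placed.  For ``planted_fold`` > 1, large
    gains are then iteratively re-anchored onto not-yet-duplicated focal
    genes until the focal fraction among annotated gain-genes — counted the
    way the analysis counts it, i.e. after removing genes gained in the
    control cohort — matches ``planted_fold`` times the universe baseline.
    At ``planted_fold`` <= 1 no re-anchoring happens, so the cohort is an
    honest null.  When ``focal_subsets`` (e.g. the focal term's child-term
    gene sets) are given, anchors are spread evenly across them so the
    planted signal is a parent-level property rather than concentrated in
    one subtype.  Control CNVs are uniform at all lengths.
    """
    if universe_genes is None:
        universe_genes = set(focal_set)
    if not set(focal_set) <= set(universe_genes):
        raise ValueError("focal_set must be contained in universe_genes")
    lo, hi = cfg.cnv_length_range
    n_case = cfg.n_case_large_gains + cfg.n_case_large_losses + cfg.n_case_small_cnvs
    pool = max(1, int(round(0.94 * n_case)))
    n_small_gain = int(round(cfg.case_gain_fraction * cfg.n_case_small_cnvs))
    # the large/small composition of the case cohort is a fixed study margin
    case = _draw_cnvs(
        cfg, rng, cfg.n_case_large_gains, cfg.n_case_large_losses,
        (max(lo, cfg.min_cnv_length + 1), hi), "case", "caseS", pool,
    )
    case += _draw_cnvs(
        cfg, rng, n_small_gain, cfg.n_case_small_cnvs - n_small_gain,
        (lo, cfg.min_cnv_length), "case", "caseS", pool,
    )
    n_ctrl_gain = int(round(cfg.n_control_cnvs * cfg.control_gain_fraction))
    control = _draw_cnvs(
        cfg, rng, n_ctrl_gain, cfg.n_control_cnvs - n_ctrl_gain,
        cfg.control_cnv_length_range, "control", "ctrlS",
        max(1, int(round(0.94 * cfg.n_control_cnvs))),
    )
    if cfg.planted_fold > 1.0 and focal_set:
        _plant_focal_gains(
            cfg, case, control, genes, set(focal_set), set(universe_genes), rng,
            focal_subsets=focal_subsets,
        )
    return case, control


def _pick_anchors(
    rng: np.random.Generator,
    pool: list[str],
    n: int,
    focal_subsets: Sequence[frozenset[str]] | None,
    current_counts: Sequence[int] | None = None,
) -> list[str]:
    """Choose ``n`` anchor genes from ``pool``.

    With ``focal_subsets`` given, anchors go preferentially to the subset
    with the fewest planted-plus-existing members so the signal stays a
    parent-level property, not a single-subtype artefact.
    """
    if not focal_subsets:
        return list(rng.choice(pool, size=min(n, len(pool)), replace=False))
    buckets = []
    for sub in focal_subsets:
        bucket = [g for g in pool if g in sub]
        rng.shuffle(bucket)
        buckets.append(bucket)
    counts = list(current_counts) if current_counts else [0] * len(buckets)
    anchors: list[str] = []
    while len(anchors) < n and any(buckets):
        nonempty = [i for i, b in enumerate(buckets) if b]
        low = min(counts[i] for i in nonempty)
        choices = [i for i in nonempty if counts[i] == low]
        bi = int(rng.choice(choices))
        anchors.append(buckets[bi].pop())
        counts[bi] += 1
    return anchors


def _plant_focal_gains(
    cfg: SimulationConfig,
    case: list[CnvRecord],
    control: Sequence[CnvRecord],
    genes: Sequence[GeneModel],
    focal: set[str],
    universe: set[str],
    rng: np.random.Generator,
    focal_subsets: Sequence[frozenset[str]] | None = None,
) -> None:
    """Re-anchor large gains onto focal genes until the target fold is met."""
    rho = len(focal) / len(universe)
    by_id = {g.gene_id: g for g in genes}
    chrom_len = cfg.genome_length // cfg.n_chromosomes
    control_gains = [c for c in control if c.dosage is Dosage.GAIN]
    control_gained = {a.gene_id for a in assign_gain_genes(control_gains, genes)}
    modeled_focal = sorted((focal & by_id.keys()) - control_gained)

    for _ in range(6):
        large_idx = [
            i for i, c in enumerate(case)
            if c.dosage is Dosage.GAIN and c.length > cfg.min_cnv_length
        ]
        assignments = assign_gain_genes([case[i] for i in large_idx], genes)
        gain_ids = {a.gene_id for a in assignments} - control_gained
        annotated = gain_ids & universe
        target_k = int(round(cfg.planted_fold * rho * len(annotated)))
        deficit = target_k - len(gain_ids & focal)
        if deficit <= 0:
            break
        pool = [g for g in modeled_focal if g not in gain_ids]
        if not pool:
            logger.warning("no unused modeled focal genes left to anchor on")
            break
        counts = (
            [len(gain_ids & sub) for sub in focal_subsets] if focal_subsets else None
        )
        anchors = _pick_anchors(rng, pool, deficit, focal_subsets, counts)
        # convert gains that currently contribute no focal genes
        focal_hits: dict[int, int] = {i: 0 for i in large_idx}
        for a in assignments:
            if a.gene_id in focal:
                for i in large_idx:
                    if case[i] is a.cnv:
                        focal_hits[i] += 1
        convertible = sorted(i for i in large_idx if focal_hits[i] == 0)
        rng.shuffle(convertible)
        for i, anchor_id in zip(convertible, anchors):
            span = by_id[anchor_id].span
            old = case[i]
            L = max(old.length, span.length + 2_000)
            lo = max(0, span.end - L)
            hi = min(span.start, chrom_len - L)
            start = int(rng.integers(lo, max(lo + 1, hi + 1)))
            case[i] = CnvRecord(
                subject_id=old.subject_id,
                cohort_id=old.cohort_id,
                interval=GenomicInterval(span.chrom, start, start + L),
                dosage=Dosage.GAIN,
                origin=old.origin,
            )


# ---------------------------------------------------------------------------
# expression


def noise_sd_for_r(r: float) -> float:
    """Noise level of the unit-variance factor model with expected Pearson
    correlation ``r`` between two module members: r = 1 / (1 + sd^2)."""
    return math.sqrt(1.0 / r - 1.0)


def make_expression(
    cfg: SimulationConfig,
    module_assignments: Sequence[Sequence[str]],
    rng: np.random.Generator,
    background_genes: Sequence[str] = (),
) -> pd.DataFrame:
    """Latent-factor RPKM-like matrix with planted co-expressed modules.

    Genes in module m share a standard-normal latent factor plus independent
    noise whose level is solved from ``within_module_r``; background genes
    are pure noise.  Profiles are exponentiated (base 2) around a per-gene
    baseline so values are non-negative and RPKM-like; a configurable slice
    of background genes is planted at negligible expression to exercise the
    expression filter.
    """
    flat = [g for mod in module_assignments for g in mod]
    if len(set(flat)) != len(flat):
        raise ValueError("module assignments must be disjoint")
    sd = noise_sd_for_r(cfg.within_module_r)
    S = cfg.n_samples
    mean_mu, sd_mu = cfg.expression_baseline

    rows: dict[str, np.ndarray] = {}
    for mod in module_assignments:
        factor = rng.normal(size=S)
        for g in mod:
            mu = rng.normal(mean_mu, sd_mu)
            rows[g] = 2.0 ** (mu + factor + sd * rng.normal(size=S))
    n_low = int(round(cfg.low_expression_rate * len(background_genes)))
    for j, g in enumerate(background_genes):
        if g in rows:
            raise ValueError(f"background gene {g} also appears in a module")
        mu = -8.0 if j < n_low else rng.normal(mean_mu, sd_mu)
        rows[g] = 2.0 ** (mu + math.sqrt(1 + sd**2) * rng.normal(size=S))
    expr = pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"S{j + 1:03d}" for j in range(S)])
    expr.index.name = "gene_id"
    return expr


# ---------------------------------------------------------------------------
# full datasets and on-disk formats


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list[GeneModel]
    case_cnvs: list[CnvRecord]
    control_cnvs: list[CnvRecord]
    ontology: PhenotypeOntology
    annotations: AnnotationTable
    orthology: OrthologyMap
    universe: AnnotatedUniverse
    expression: pd.DataFrame
    truth: dict


def make_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate every input of the pipeline from one seeded RNG."""
    rng = np.random.default_rng(cfg.seed)
    onto, ann, orth = make_annotation_universe(cfg, rng)
    universe = annotate_closure(onto, ann, orth)
    focal_genes = universe.term_gene_sets[FOCAL_TERM]
    genes = make_gene_models(cfg, rng)
    focal_children = sorted(t for t, ps in onto.parents.items() if FOCAL_TERM in ps)
    case, control = make_cnv_cohort(
        cfg, genes, focal_genes, rng,
        universe_genes=universe.genes,
        focal_subsets=[universe.term_gene_sets[c] for c in focal_children],
    )

    modeled = [g.gene_id for g in genes]
    modeled_focal = sorted(set(modeled) & focal_genes)
    modules: list[list[str]] = []
    used: set[str] = set()
    for m in range(cfg.n_modules):
        if m == 0 and len(modeled_focal) >= cfg.module_size:
            members = list(
                rng.choice(modeled_focal, size=cfg.module_size, replace=False)
            )
        else:
            pool = sorted(set(modeled) - used - set(modeled_focal))
            members = list(rng.choice(pool, size=cfg.module_size, replace=False))
        modules.append(members)
        used |= set(members)
    n_bg = cfg.n_expression_genes - cfg.n_modules * cfg.module_size
    bg_pool = sorted(set(modeled) - used)
    background = list(rng.choice(bg_pool, size=n_bg, replace=False))
    expression = make_expression(cfg, modules, rng, background_genes=background)

    truth = {
        "seed": cfg.seed,
        "focal_term": FOCAL_TERM,
        "behavioural_root": BEHAVIOURAL_TERM,
        "universe_size": universe.size,
        "focal_term_size": universe.term_size(FOCAL_TERM),
        "planted_fold": cfg.planted_fold,
        "modules": modules,
        "within_module_r": cfg.within_module_r,
        "n_case_cnvs": len(case),
        "n_control_cnvs": len(control),
    }
    return SyntheticDataset(
        config=cfg,
        genes=genes,
        case_cnvs=case,
        control_cnvs=control,
        ontology=onto,
        annotations=ann,
        orthology=orth,
        universe=universe,
        expression=expression,
        truth=truth,
    )


def write_cnvs_tsv(cnvs: Sequence[CnvRecord], path: str | Path) -> None:
    """Write in the 1-based inclusive dialect (start + 1, end unchanged)."""
    pd.DataFrame(
        {
            "subject": [c.subject_id for c in cnvs],
            "cohort": [c.cohort_id for c in cnvs],
            "chrom": [c.interval.chrom for c in cnvs],
            "start": [c.interval.start + 1 for c in cnvs],
            "end": [c.interval.end for c in cnvs],
            "dosage": [c.dosage.value for c in cnvs],
            "origin": [c.origin.value for c in cnvs],
        }
    ).to_csv(path, sep="\t", index=False)


def write_gene_models_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            span = gene.span
            fh.write(
                f"{span.chrom}\tcnvnet\tgene\t{span.start + 1}\t{span.end}\t.\t+\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for tx in gene.transcripts:
                t0, t1 = tx.exons[0].start, tx.exons[-1].end
                fh.write(
                    f"{span.chrom}\tcnvnet\tmRNA\t{t0 + 1}\t{t1}\t.\t+\t.\t"
                    f"ID={tx.transcript_id};Parent={gene.gene_id}\n"
                )
                for ex in tx.exons:
                    fh.write(
                        f"{span.chrom}\tcnvnet\texon\t{ex.start + 1}\t{ex.end}\t.\t+\t.\t"
                        f"Parent={tx.transcript_id}\n"
                    )
                for ce in tx.coding_exons:
                    fh.write(
                        f"{span.chrom}\tcnvnet\tCDS\t{ce.start + 1}\t{ce.end}\t.\t+\t0\t"
                        f"Parent={tx.transcript_id}\n"
                    )


def write_obo(onto: PhenotypeOntology, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(onto.parents):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {onto.names.get(term, term)}\n")
            for parent in sorted(onto.parents[term]):
                fh.write(f"is_a: {parent} ! {onto.names.get(parent, parent)}\n")


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write every pipeline input in its standard on-disk format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cnvs_tsv(ds.case_cnvs, outdir / "cnvs_case.tsv")
    write_cnvs_tsv(ds.control_cnvs, outdir / "cnvs_control.tsv")
    write_gene_models_gff3(ds.genes, outdir / "genes.gff3")
    write_obo(ds.ontology, outdir / "ontology.obo")
    pd.DataFrame(
        [
            {"mouse_id": m, "term_id": t}
            for m in sorted(ds.annotations.direct)
            for t in sorted(ds.annotations.direct[m])
        ]
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(ds.orthology.human_to_mouse.items()), columns=["human_id", "mouse_id"]
    ).to_csv(outdir / "orthology.tsv", sep="\t", index=False)
    ds.expression.to_csv(outdir / "expression.tsv", sep="\t")
    (outdir / "truth.json").write_text(json.dumps(ds.truth, indent=2) + "\n")
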