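"""Gene-to-CNV assignment rules, dialects, and control filtering."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnvnet.cnv_gene_mapping import (
    AssignmentRule,
    CnvGeneAssignment,
    Dosage,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    assign_gain_genes,
    assign_genes,
    assign_loss_genes,
    filter_control_genes,
    filter_large_cnvs,
    gene_sets_by_dosage,
    load_cnvs,
    load_gene_models_gff3,
    load_gene_models_tsv,
)
from cnvnet.errors import ConfigurationError, RecordError
from cnvnet.synthetic_data import make_cnv_cohort, make_gene_models, write_gene_models_gff3

from conftest import cnv, gene, small_config

import numpy as np


# ---------------------------------------------------------------------------
# loading and dialects


def _write_cnv_table(tmp_path, rows, header="subject\tchrom\tstart\tend\tdosage"):
    path = tmp_path / "cnvs.tsv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


@pytest.mark.parametrize(
    "dialect,start,end,expected",
    [
        ("one_based", 100, 200, (99, 200)),
        ("bed", 99, 200, (99, 200)),
    ],
)
def test_coordinate_dialects_converge_on_internal_half_open(
    tmp_path, dialect, start, end, expected
):
    path = _write_cnv_table(tmp_path, [f"s1\tchr7\t{start}\t{end}\tgain"])
    (rec,) = load_cnvs(path, coordinate_dialect=dialect)
    assert (rec.interval.start, rec.interval.end) == expected
    assert rec.interval.chrom == "7"  # chr prefix stripped


def test_dosage_labels_mapped_to_gain_loss(tmp_path):
    path = _write_cnv_table(tmp_path, ["s1\t1\t10\t20\tdup", "s2\t1\t10\t20\tdel"])
    a, b = load_cnvs(path)
    assert a.dosage is Dosage.GAIN and b.dosage is Dosage.LOSS


def test_malformed_rows_reported_with_line_numbers(tmp_path):
    path = _write_cnv_table(
        tmp_path,
        ["s1\t1\t10\t20\tgain", "s2\t1\t30\t30\tloss", "s3\t1\t5\t9\ttriplication"],
    )
    with pytest.raises(RecordError) as exc:
        load_cnvs(path, coordinate_dialect="bed")
    lines = [ln for ln, _ in exc.value.bad_rows]
    assert lines == [3, 4]  # line 2 is valid; header is line 1


def test_missing_required_column_is_a_configuration_error(tmp_path):
    path = _write_cnv_table(tmp_path, ["s1\t1\t10\tgain"], header="subject\tchrom\tstart\tdosage")
    with pytest.raises(ConfigurationError):
        load_cnvs(path)


# ---------------------------------------------------------------------------
# size filter


def test_length_filter_is_strictly_greater_than():
    records = [cnv("1", 0, 500_000), cnv("1", 0, 500_001)]
    kept = filter_large_cnvs(records, 500_000)
    assert [c.length for c in kept] == [500_001]


def test_length_filter_count_matches_direct_scan(small_dataset):
    cnvs = small_dataset.case_cnvs
    expected = sum(1 for c in cnvs if c.length > 500_000)
    assert len(filter_large_cnvs(cnvs, 500_000)) == expected
    assert expected == small_config().n_case_large_gains + small_config().n_case_large_losses


# ---------------------------------------------------------------------------
# gain rule: full span containment


def test_gain_requires_complete_overlap():
    g = gene("g1", "1", 1000, 2000, cds=(1100, 1900))
    contained = assign_gain_genes([cnv("1", 500, 5000)], [g])
    partial = assign_gain_genes([cnv("1", 1500, 5000)], [g])
    assert {a.gene_id for a in contained} == {"g1"}
    assert partial == set()


def test_gain_assignment_matches_all_pairs_containment_oracle(rng):
    genes = [
        gene(f"g{i}", "1", s, s + w, cds=(s + 10, s + w - 10))
        for i, (s, w) in enumerate(
            zip(rng.integers(0, 100_000, 10), rng.integers(100, 5_000, 10))
        )
    ]
    gains = [cnv("1", int(s), int(s) + int(w)) for s, w in
             zip(rng.integers(0, 80_000, 3), rng.integers(1_000, 40_000, 3))]
    got = {(a.gene_id, a.cnv.interval.start) for a in assign_gain_genes(gains, genes)}
    expected = {
        (g.gene_id, c.interval.start)
        for g, c in itertools.product(genes, gains)
        if c.interval.contains(g.span)
    }
    assert got == expected


def test_gain_assignment_equivalent_to_brute_force_at_scale():
    cfg = small_config(seed=3)
    genes = make_gene_models(cfg, np.random.default_rng(3))
    case, _ = make_cnv_cohort(cfg, genes, frozenset(), np.random.default_rng(4))
    gains = [c for c in case if c.dosage is Dosage.GAIN]
    got = {(a.gene_id, id(a.cnv)) for a in assign_gain_genes(gains, genes)}
    expected = {
        (g.gene_id, id(c))
        for g, c in itertools.product(genes, gains)
        if c.interval.contains(g.span)
    }
    assert got == expected


@given(
    start=st.integers(0, 1000),
    end=st.integers(1001, 3000),
    grow_left=st.integers(0, 500),
    grow_right=st.integers(0, 500),
)
def test_gain_assignment_monotone_under_interval_growth(start, end, grow_left, grow_right):
    """Enlarging a gain never removes an assignment; shrinking never adds."""
    g = gene("g1", "1", 1200, 1800, cds=(1300, 1700))
    small_cnv = cnv("1", start, end)
    big_cnv = cnv("1", max(0, start - grow_left), end + grow_right)
    small_hit = bool(assign_gain_genes([small_cnv], [g]))
    big_hit = bool(assign_gain_genes([big_cnv], [g]))
    assert big_hit or not small_hit


# ---------------------------------------------------------------------------
# loss rule: coding disruption in all transcripts


def test_loss_hits_single_coding_transcript():
    g = gene("g1", "1", 900, 1500, cds=(1000, 1100))
    hits = assign_loss_genes([cnv("1", 1050, 1200, Dosage.LOSS)], [g])
    assert {a.gene_id for a in hits} == {"g1"}
    assert next(iter(hits)).rule is AssignmentRule.LOSS_CODING_ALL_TRANSCRIPTS


def test_loss_must_disrupt_every_coding_transcript():
    tx2 = TranscriptModel(
        "g1.t2",
        (GenomicInterval("1", 2000, 2500),),
        (GenomicInterval("1", 2100, 2400),),
    )
    g = gene("g1", "1", 900, 1500, cds=(1000, 1100), extra_tx=(tx2,))
    # loss overlaps a coding exon of t1 only -> not assigned
    assert assign_loss_genes([cnv("1", 1050, 1200, Dosage.LOSS)], [g]) == set()
    # loss overlapping coding exons of both -> assigned
    assert assign_loss_genes([cnv("1", 1050, 2200, Dosage.LOSS)], [g]) != set()


def test_loss_in_utr_only_is_not_assigned():
    g = gene("g1", "1", 900, 1500, cds=(1200, 1300))
    assert assign_loss_genes([cnv("1", 950, 1100, Dosage.LOSS)], [g]) == set()


def test_noncoding_isoforms_excluded_from_all_transcripts_quantifier():
    noncoding = TranscriptModel("g1.t2", (GenomicInterval("1", 900, 1500),), ())
    g = gene("g1", "1", 900, 1500, cds=(1000, 1100), extra_tx=(noncoding,))
    hits = assign_loss_genes([cnv("1", 1050, 1200, Dosage.LOSS)], [g])
    assert {a.gene_id for a in hits} == {"g1"}
    # a gene with no coding transcript at all is never a loss-gene
    g_nc = GeneModel("g2", (noncoding,))
    assert assign_loss_genes([cnv("1", 900, 1500, Dosage.LOSS)], [g_nc]) == set()


def test_gain_loss_asymmetry_for_partial_overlap():
    """A partially-overlapped gene can be a loss-gene but never a gain-gene."""
    g = gene("g1", "1", 1000, 2000, cds=(1100, 1900))
    interval = (1500, 5000)
    assert assign_gain_genes([cnv("1", *interval)], [g]) == set()
    assert assign_loss_genes([cnv("1", *interval, Dosage.LOSS)], [g]) != set()


def test_assignment_invariant_under_row_order_and_table_split(rng):
    cfg = small_config(seed=9)
    genes = make_gene_models(cfg, np.random.default_rng(9))
    case, _ = make_cnv_cohort(cfg, genes, frozenset(), np.random.default_rng(10))
    whole = gene_sets_by_dosage(assign_genes(case, genes))
    shuffled = list(case)
    rng.shuffle(shuffled)
    assert gene_sets_by_dosage(assign_genes(shuffled, genes)) == whole
    part = gene_sets_by_dosage(assign_genes(case[::2], genes))
    rest = gene_sets_by_dosage(assign_genes(case[1::2], genes))
    union = {d: part[d] | rest[d] for d in part}
    assert union == whole


# ---------------------------------------------------------------------------
# control-cohort filtering


def test_control_filter_is_direction_matched():
    g1 = gene("g1", "1", 1000, 2000, cds=(1100, 1900))
    g2 = gene("g2", "1", 5000, 6000, cds=(5100, 5900))
    case_sets = {Dosage.GAIN: {"g1", "g2"}, Dosage.LOSS: set()}
    # control gains g1; control loses g2 (whole-gene loss disrupts its CDS)
    controls = [cnv("1", 900, 2100), cnv("1", 4900, 6100, Dosage.LOSS)]
    filtered = filter_control_genes(case_sets, controls, [g1, g2])
    assert filtered[Dosage.GAIN] == {"g2"}


def test_control_filter_matches_set_difference_oracle_and_is_idempotent(small_dataset):
    ds = small_dataset
    case = filter_large_cnvs(ds.case_cnvs, 500_000)
    case_sets = gene_sets_by_dosage(assign_genes(case, ds.genes))
    control_sets = gene_sets_by_dosage(assign_genes(ds.control_cnvs, ds.genes))
    filtered = filter_control_genes(case_sets, ds.control_cnvs, ds.genes)
    for d in (Dosage.GAIN, Dosage.LOSS):
        assert filtered[d] == case_sets[d] - control_sets[d]
    assert filter_control_genes(filtered, ds.control_cnvs, ds.genes) == filtered


# ---------------------------------------------------------------------------
# gene-model IO


def test_gene_models_round_trip_through_gff3(tmp_path, small_dataset):
    genes = small_dataset.genes[:40]
    path = tmp_path / "genes.gff3"
    write_gene_models_gff3(genes, path)
    loaded = {g.gene_id: g for g in load_gene_models_gff3(path)}
    assert set(loaded) == {g.gene_id for g in genes}
    for g in genes:
        assert loaded[g.gene_id].span == g.span
        orig_coding = {
            (tx.transcript_id, tx.coding_exons) for tx in g.transcripts
        }
        got_coding = {
            (tx.transcript_id, tx.coding_exons) for tx in loaded[g.gene_id].transcripts
        }
        assert got_coding == orig_coding


def test_gene_models_flat_tsv_loader(tmp_path):
    path = tmp_path / "genes.tsv"
    path.write_text(
        "gene_id\ttranscript_id\tchrom\texon_start\texon_end\tcds_start\tcds_end\n"
        "g1\tg1.t1\t1\t100\t200\t150\t200\n"
        "g1\tg1.t1\t1\t300\t400\t300\t350\n"
        "g1\tg1.t2\t1\t100\t400\t\t\n"
    )
    (g,) = load_gene_models_tsv(path)
    assert g.span == GenomicInterval("1", 100, 400)
    t1, t2 = sorted(g.transcripts, key=lambda t: t.transcript_id)
    assert len(t1.coding_exons) == 2 and not t2.is_coding
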