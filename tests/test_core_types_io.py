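"""Domain types, coordinate conventions and file format round-trips."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from v2gtier import (
    FormatError,
    GeneModel,
    GenomicInterval,
    Variant,
    position_in_interval,
    read_bed,
    read_bed12_genes,
    read_bedpe,
    read_fasta,
    read_motifs,
    read_summary_stats,
)
from v2gtier.core_types_io import (
    fetch_sequence,
    write_bed,
    write_bed12_genes,
    write_bedpe,
    write_fasta,
    write_motifs,
    write_summary_stats,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# Variant
# ---------------------------------------------------------------------------

@given(chrom=st.sampled_from(["chr1", "chr7", "chrX"]),
       pos=st.integers(min_value=1, max_value=3_000_000_000),
       alleles=st.sampled_from([(r, a) for r in "ACGT" for a in "ACGT" if r != a]))
@settings(max_examples=50, deadline=None)
def test_vid_round_trips(chrom, pos, alleles):
    v = Variant(chrom, pos, *alleles)
    assert Variant.from_vid(v.vid) == v


def test_variant_rejects_non_snp_and_identical_alleles():
    with pytest.raises(ValueError):
        Variant("chr1", 10, "A", "A")
    with pytest.raises(ValueError):
        Variant("chr1", 10, "AT", "A")


@pytest.mark.parametrize("ref,alt,ambiguous", [
    ("A", "T", True), ("C", "G", True), ("A", "G", False), ("C", "T", False)])
def test_strand_ambiguity_flag(ref, alt, ambiguous):
    assert Variant("chr1", 5, ref, alt).strand_ambiguous is ambiguous


def test_half_open_conversion_rule():
    # 1-based pos falls in [start, end) iff pos-1 in the half-open interval
    assert position_in_interval(101, 100, 200)
    assert position_in_interval(200, 100, 200)
    assert not position_in_interval(100, 100, 200)
    assert not position_in_interval(201, 100, 200)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _write_gwas(path, rows):
    header = "chrom\tpos\tref\talt\teffect_allele\tbeta\tse\tpvalue\n"
    path.write_text(header + "".join(rows))


def test_read_summary_stats_drops_indels_and_recomputes_z(tmp_path):
    f = tmp_path / "gwas.tsv"
    _write_gwas(f, [
        "chr1\t100\tA\tG\tG\t0.2\t0.1\t0.045\n",
        "chr1\t200\tC\tT\tT\t-0.3\t0.1\t0.002\n",
        "chr1\t300\tAT\tA\tA\t0.5\t0.1\t0.001\n",   # indel: dropped
        "chr1\t400\tG\tC\tC\t0.1\t0.2\t0.6\n",
    ])
    records = read_summary_stats(f, "gwas")
    assert len(records) == 3
    assert records[0].z == pytest.approx(2.0)


def test_read_summary_stats_empty_file_and_bad_se(tmp_path):
    empty = tmp_path / "empty.tsv"
    _write_gwas(empty, [])
    assert read_summary_stats(empty, "gwas") == []

    bad = tmp_path / "bad.tsv"
    _write_gwas(bad, ["chr1\t100\tA\tG\tG\t0.2\t0\t0.05\n",
                      "chr1\t200\tA\tG\tG\t0.2\t0.1\t0.05\n"])
    records = read_summary_stats(bad, "gwas")
    assert len(records) == 1 and records[0].variant.pos == 200


def test_read_summary_stats_missing_column_names_it(tmp_path):
    f = tmp_path / "gwas.tsv"
    f.write_text("chrom\tpos\tref\talt\tbeta\tse\tpvalue\nchr1\t1\tA\tG\t0.1\t0.1\t0.5\n")
    with pytest.raises(FormatError, match="effect_allele"):
        read_summary_stats(f, "gwas")


def test_summary_stats_round_trip(tmp_path):
    records = [make_record(100, 0.2, 0.1, gene_id="G1", tissue="cortex",
                           source="GTEx"),
               make_record(200, -0.4, 0.2, gene_id="G2", tissue="cortex",
                           source="GTEx")]
    f = tmp_path / "eqtl.tsv"
    write_summary_stats(records, str(f))
    back = read_summary_stats(f, "eqtl")
    assert back == records


# ---------------------------------------------------------------------------
# BED / BED12 / BEDPE
# ---------------------------------------------------------------------------

def test_read_bed_parses_track_dialect(tmp_path):
    f = tmp_path / "t.bed"
    f.write_text("chr1\t100\t200\tEpiMAP|brain_cortex|enhancer\n")
    (iv,) = read_bed(f)
    assert (iv.chrom, iv.start, iv.end) == ("chr1", 100, 200)
    assert iv.name == "EpiMAP" and iv.tissue == "brain_cortex"
    assert iv.class_label == "enhancer"


def test_read_bed_rejects_empty_interval(tmp_path):
    f = tmp_path / "t.bed"
    f.write_text("chr1\t5\t5\tx\n")
    with pytest.raises(FormatError, match=":1"):
        read_bed(f)


def test_bed_round_trip(tmp_path):
    ivs = [GenomicInterval("chr1", 10, 50, name="ROADMAP", tissue="brain",
                           class_label="enhancer"),
           GenomicInterval("chr2", 0, 7, name="x")]
    f = tmp_path / "t.bed"
    write_bed(ivs, str(f))
    assert read_bed(f) == ivs


def test_bed12_two_exon_gene_coordinates(tmp_path):
    # blocks: [1000,1200) and [1500,2000); CDS (thick) = [1100,1800)
    f = tmp_path / "g.bed12"
    f.write_text("chr1\t1000\t2000\tGENE\t0\t+\t1100\t1800\t0\t2\t200,500\t0,500\n")
    (g,) = read_bed12_genes(f)
    assert g.exons == ((1000, 1200), (1500, 2000))
    assert (g.cds_start, g.cds_end) == (1100, 1800)
    assert g.tss == 1001                       # + strand: first base, 1-based
    assert g.introns() == [(1200, 1500)]
    promoter = g.promoter(1000)
    assert (promoter.start, promoter.end) == (0, 1000)


def test_bed12_minus_strand_tss_and_round_trip(tmp_path):
    g = GeneModel(gene_id="G", chrom="chr2", strand="-",
                  exons=((500, 700), (900, 1200)), cds_start=600, cds_end=1100)
    assert g.tss == 1200                       # - strand: 5' end is chromEnd
    f = tmp_path / "g.bed12"
    write_bed12_genes([g], str(f))
    assert read_bed12_genes(f) == [g]


def test_bedpe_single_line_and_round_trip(tmp_path):
    f = tmp_path / "x.bedpe"
    f.write_text("chr1\t10\t20\tchr1\t500\t600\tNott|microglia|HiC\n")
    (pair,) = read_bedpe(f)
    assert pair.anchor1.start == 10 and pair.anchor2.end == 600
    assert (pair.source, pair.celltype, pair.assay) == ("Nott", "microglia", "HiC")
    out = tmp_path / "y.bedpe"
    write_bedpe([pair], str(out))
    assert read_bedpe(out) == [pair]


# ---------------------------------------------------------------------------
# FASTA / motifs
# ---------------------------------------------------------------------------

def test_fasta_identity_lookup(tmp_path):
    f = tmp_path / "g.fa"
    write_fasta({"chr1": "ACGT"}, str(f))
    genome = read_fasta(f)
    assert fetch_sequence(genome, "chr1", 1, 4) == "ACGT"
    assert fetch_sequence(genome, "chr1", 2, 3) == "CG"


def test_motif_reader_rejects_duplicates_and_round_trips(tmp_path):
    f = tmp_path / "m.txt"
    f.write_text(">AC\tM1\t0\n0.5 0.3 0.1 0.1\n0.1 0.5 0.2 0.2\n"
                 ">GG\tM2\t0\n0.1 0.1 0.7 0.1\n0.1 0.1 0.7 0.1\n")
    motifs = read_motifs(f)
    assert [m.motif_id for m in motifs] == ["M1", "M2"]
    out = tmp_path / "m2.txt"
    write_motifs(motifs, str(out))
    back = read_motifs(out)
    for orig, rt in zip(motifs, back):
        assert rt.motif_id == orig.motif_id
        assert rt.matrix == pytest.approx(orig.matrix, abs=1e-5)

    dup = tmp_path / "dup.txt"
    dup.write_text(">AC\tM1\t0\n0.5 0.3 0.1 0.1\n>AC\tM1\t0\n0.5 0.3 0.1 0.1\n")
    with pytest.raises(FormatError, match="duplicate"):
        read_motifs(dup)
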