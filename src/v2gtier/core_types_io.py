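"""Shared domain types, coordinate conventions, and file readers/writers.

Coordinate conventions
----------------------
Variant positions are 1-based (as printed in summary-statistic files and in
identifiers such as ``chr7:54881563:A:G``).  All interval files (BED, BEDPE,
TADs, enhancer tracks) are 0-based half-open, the BED standard.  The single
conversion rule between the two worlds is :func:`position_in_interval`:
a variant at 1-based position ``pos`` falls inside ``[start, end)`` iff
``pos - 1 ∈ [start, end)``.  Every containment test in the package goes
through that function.

File dialects
-------------
* Summary statistics: TSV with header
  ``chrom pos ref alt effect_allele beta se pvalue`` plus, for eQTL files,
  ``gene_id tissue source`` (an optional ``rsid`` column is carried through
  as a display label).
* BED4+: the name field encodes ``dataset|tissue|class``.
* BED12: gene models; ``thickStart == thickEnd`` marks a non-coding (lncRNA)
  transcript, otherwise the thick region is the CDS.
* BEDPE6+: the 7th column, when present, encodes ``source|celltype|assay``.
* Motif files: HOMER-like text, ``>CONSENSUS<TAB>name<TAB>threshold`` header
  followed by one ``A C G T`` probability row per motif position.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger("v2gtier")

NUCLEOTIDES = frozenset("ACGT")

#: complementary base pairs; used both for reverse complement and for
#: detecting strand-ambiguous (palindromic) alleles
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


class ParameterError(ValueError):
    """A parameter combination is invalid or unattainable."""


# ---------------------------------------------------------------------------
# coordinate conversion — the one rule
# ---------------------------------------------------------------------------

def position_in_interval(pos: int, start: int, end: int) -> bool:
    """True iff 1-based ``pos`` lies in the 0-based half-open ``[start, end)``."""
    return start <= pos - 1 < end


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Variant:
    """A single-nucleotide variant, identified canonically by ``chrom:pos:ref:alt``."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    rsid: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"non-SNP alleles {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def vid(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_vid(cls, vid: str, rsid: Optional[str] = None) -> "Variant":
        parts = vid.split(":")
        if len(parts) != 4:
            raise FormatError(f"malformed variant id {vid!r}")
        chrom, pos, ref, alt = parts
        return cls(chrom=chrom, pos=int(pos), ref=ref.upper(), alt=alt.upper(), rsid=rsid)

    @property
    def strand_ambiguous(self) -> bool:
        """A/T and C/G variants cannot be oriented without strand information."""
        return COMPLEMENT[self.ref] == self.alt


@dataclass(frozen=True)
class AssocRecord:
    """One variant's association summary for a trait (GWAS or an eQTL gene/tissue)."""

    variant: Variant
    effect_allele: str
    beta: float
    se: float
    pvalue: float
    gene_id: Optional[str] = None   # eQTL only
    tissue: Optional[str] = None    # eQTL only
    source: Optional[str] = None    # eQTL only

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"se must be > 0, got {self.se}")
        if self.effect_allele not in (self.variant.ref, self.variant.alt):
            raise ValueError(
                f"effect allele {self.effect_allele} is neither ref nor alt "
                f"of {self.variant.vid}"
            )
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"pvalue {self.pvalue} outside (0, 1]")

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def trait_key(self):
        """(gene_id, tissue, source) for eQTL records, "gwas" otherwise."""
        if self.gene_id is None:
            return "gwas"
        return (self.gene_id, self.tissue, self.source)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval carrying dataset/tissue/class labels."""

    chrom: str
    start: int
    end: int
    name: str = ""
    tissue: str = ""
    class_label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return position_in_interval(pos, self.start, self.end)


@dataclass(frozen=True)
class InteractionPair:
    """A chromatin contact with two anchors (e.g. enhancer–promoter interaction)."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    assay: str = ""
    source: str = ""
    celltype: str = ""


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: strand-aware TSS, exon structure and CDS bounds.

    ``exons`` are sorted, disjoint 0-based half-open (start, end) tuples.
    ``cds_start == cds_end`` means a non-coding transcript.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple
    cds_start: int
    cds_end: int
    biotype: str = "mRNA"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon in {self.gene_id}")
            if s < prev_end:
                raise ValueError(f"exons overlap or unsorted in {self.gene_id}")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """1-based transcription start site: 5'-most base respecting strand."""
        return self.start + 1 if self.strand == "+" else self.end

    @property
    def coding(self) -> bool:
        return self.cds_end > self.cds_start

    def promoter(self, length: int = 1000) -> GenomicInterval:
        """``length`` bp immediately upstream of the TSS, strand-aware (half-open)."""
        if self.strand == "+":
            start = max(0, self.start - length)
            return GenomicInterval(self.chrom, start, max(self.start, start + 1),
                                   name=self.gene_id, class_label="promoter")
        return GenomicInterval(self.chrom, self.end, self.end + length,
                               name=self.gene_id, class_label="promoter")

    def introns(self) -> list:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

_GWAS_COLUMNS = ["chrom", "pos", "ref", "alt", "effect_allele", "beta", "se", "pvalue"]
_EQTL_COLUMNS = _GWAS_COLUMNS + ["gene_id", "tissue", "source"]


def read_summary_stats(path: str, trait_kind: str = "gwas") -> list:
    """Read a TSV of association summary statistics into :class:`AssocRecord` s.

    Indel rows (multi-base ref or alt) are dropped with a logged count; rows
    with non-positive standard errors are rejected with a logged reason.  The
    Z-score is always ``beta / se`` recomputed from the parsed columns.
    """
    if trait_kind not in ("gwas", "eqtl"):
        raise ParameterError(f"trait_kind must be gwas or eqtl, got {trait_kind!r}")
    required = _EQTL_COLUMNS if trait_kind == "eqtl" else _GWAS_COLUMNS
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"summary-statistic file {path} missing column {col!r}")
    records: list = []
    n_indel = 0
    n_bad_se = 0
    for row in df.itertuples(index=False):
        ref = str(row.ref).upper()
        alt = str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1:
            n_indel += 1
            continue
        if row.se <= 0:
            n_bad_se += 1
            logger.warning("dropping %s:%s: se=%s is not positive", row.chrom, row.pos, row.se)
            continue
        rsid = getattr(row, "rsid", None)
        variant = Variant(str(row.chrom), int(row.pos), ref, alt,
                          rsid=None if rsid in (None, "", ".") or pd.isna(rsid) else str(rsid))
        records.append(AssocRecord(
            variant=variant,
            effect_allele=str(row.effect_allele).upper(),
            beta=float(row.beta),
            se=float(row.se),
            pvalue=float(row.pvalue),
            gene_id=str(row.gene_id) if trait_kind == "eqtl" else None,
            tissue=str(row.tissue) if trait_kind == "eqtl" else None,
            source=str(row.source) if trait_kind == "eqtl" else None,
        ))
    if n_indel:
        logger.info("%s: dropped %d indel rows (SNPs only)", path, n_indel)
    if n_bad_se:
        logger.info("%s: rejected %d rows with se <= 0", path, n_bad_se)
    return records


def write_summary_stats(records: Sequence[AssocRecord], path: str) -> None:
    rows = []
    eqtl = any(r.gene_id is not None for r in records)
    for r in records:
        row = {
            "chrom": r.variant.chrom, "pos": r.variant.pos,
            "ref": r.variant.ref, "alt": r.variant.alt,
            "effect_allele": r.effect_allele, "beta": r.beta, "se": r.se,
            "pvalue": r.pvalue, "rsid": r.variant.rsid or ".",
        }
        if eqtl:
            row.update(gene_id=r.gene_id, tissue=r.tissue, source=r.source)
        rows.append(row)
    cols = (_EQTL_COLUMNS if eqtl else _GWAS_COLUMNS) + ["rsid"]
    # %.17g guarantees floats survive the text round-trip bit-exactly
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False,
                                            float_format="%.17g")


# ---------------------------------------------------------------------------
# BED / BED12 / BEDPE
# ---------------------------------------------------------------------------

def _parse_track_name(name: str):
    parts = name.split("|")
    dataset = parts[0]
    tissue = parts[1] if len(parts) > 1 else ""
    class_label = parts[2] if len(parts) > 2 else ""
    return dataset, tissue, class_label


def read_bed(path: str) -> list:
    """Read a BED4+ file; the name field encodes ``dataset|tissue|class``."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            dataset, tissue, class_label = _parse_track_name(name)
            intervals.append(GenomicInterval(chrom, start, end, name=dataset,
                                             tissue=tissue, class_label=class_label))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            # trailing empty parts are dropped; empty middle parts survive
            name = f"{iv.name}|{iv.tissue}|{iv.class_label}".rstrip("|") or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bed12_genes(path: str) -> list:
    """Read gene models from BED12. Name column is the gene id; a transcript
    with ``thickStart == thickEnd`` is treated as non-coding (lncRNA)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED12 columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            block_count = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
            if exons[-1][1] != end:
                raise FormatError(f"{path}:{lineno}: blocks do not span chromEnd")
            biotype = "mRNA" if thick_end > thick_start else "lncRNA"
            genes.append(GeneModel(gene_id=name, chrom=chrom, strand=strand,
                                   exons=exons, cds_start=thick_start,
                                   cds_end=thick_end, biotype=biotype))
    return genes


def write_bed12_genes(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write("\t".join(map(str, [
                g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                g.cds_start, g.cds_end, "0,0,0", len(g.exons), sizes, starts,
            ])) + "\n")


def read_bedpe(path: str, known_chroms: Optional[set] = None) -> list:
    """Read BEDPE6+; the 7th column, if present, encodes ``source|celltype|assay``.

    Anchors on chromosomes outside ``known_chroms`` (when given) are warned
    about but the pair is kept.
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 BEDPE columns")
            a1 = GenomicInterval(f[0], int(f[1]), int(f[2]))
            a2 = GenomicInterval(f[3], int(f[4]), int(f[5]))
            source = celltype = assay = ""
            if len(f) >= 7 and f[6] not in (".", ""):
                parts = f[6].split("|")
                source = parts[0]
                celltype = parts[1] if len(parts) > 1 else ""
                assay = parts[2] if len(parts) > 2 else ""
            if known_chroms is not None:
                for anchor in (a1, a2):
                    if anchor.chrom not in known_chroms:
                        logger.warning("%s:%d: anchor on unknown chromosome %s (kept)",
                                       path, lineno, anchor.chrom)
            pairs.append(InteractionPair(anchor1=a1, anchor2=a2, assay=assay,
                                         source=source, celltype=celltype))
    return pairs


def write_bedpe(pairs: Iterable[InteractionPair], path: str) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            name = f"{p.source}|{p.celltype}|{p.assay}".rstrip("|") or "."
            fh.write("\t".join(map(str, [
                p.anchor1.chrom, p.anchor1.start, p.anchor1.end,
                p.anchor2.chrom, p.anchor2.start, p.anchor2.end, name,
            ])) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict:
    """Read a FASTA file into a {chrom: uppercase sequence} map."""
    from Bio import SeqIO  # standard-format parsing

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def fetch_sequence(genome: Mapping[str, str], chrom: str, start1: int, end1: int) -> str:
    """1-based inclusive slice of a chromosome sequence."""
    return genome[chrom][start1 - 1:end1]


# ---------------------------------------------------------------------------
# motifs (HOMER-like text)
# ---------------------------------------------------------------------------

def read_motifs(path: str, probability_floor: float = 0.001) -> list:
    """Read a HOMER-like motif file into a list of :class:`~v2gtier.tfbs_scan.PWM`.

    Duplicate motif names are an error.  Probability rows are floored at
    ``probability_floor`` and renormalized so log-odds scores stay finite.
    """
    from .tfbs_scan import PWM  # deferred: PWM lives with the scanner

    import numpy as np

    motifs = []
    seen = set()
    header = None
    rows: list = []

    def _flush():
        if header is None:
            return
        consensus, name = header
        if not rows:
            raise FormatError(f"{path}: motif {name!r} has no probability rows")
        matrix = np.asarray(rows, dtype=float)
        motifs.append(PWM(motif_id=name, tf_name=name.split("/")[0],
                          matrix=matrix, probability_floor=probability_floor))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                rows = []
                fields = line[1:].split("\t")
                consensus = fields[0]
                name = fields[1] if len(fields) > 1 else consensus
                if name in seen:
                    raise FormatError(f"{path}:{lineno}: duplicate motif name {name!r}")
                seen.add(name)
                header = (consensus, name)
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 probabilities (A C G T)")
                rows.append(vals)
    _flush()
    return motifs


def write_motifs(motifs, path: str) -> None:
    with open(path, "w") as fh:
        for pwm in motifs:
            fh.write(f">{pwm.consensus}\t{pwm.motif_id}\t0\n")
            for row in pwm.matrix:
                fh.write("\t".join(f"{p:.6f}" for p in row) + "\n")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(tables: Mapping[str, pd.DataFrame], out_dir: str,
                 summary: Optional[Mapping] = None) -> dict:
    """Write stage tables as TSVs plus a JSON run summary with stage counts.

    Returns {table name: path}.  The summary mirrors the pipeline funnel:
    number of regions, variants, pairs and genes surviving each stage.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    summary_path = os.path.join(out_dir, "run_summary.json")
    with open(summary_path, "w") as fh:
        json.dump(dict(summary or {}), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["run_summary"] = summary_path
    return paths


def normal_pvalue(z: float) -> float:
    """Two-sided p-value for a Z-score under the standard normal."""
    return math.erfc(abs(z) / math.sqrt(2.0))
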