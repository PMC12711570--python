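"""Hierarchical, disjoint genomic partition and variant classification.

Gene models are decomposed into seven primary element classes, made mutually
exclusive by ordered subtraction: each class's genome-wide merged intervals
have every higher-ranked class removed.  The hierarchy (highest first) is

    5'UTR exon > 5'UTR intron > 3'UTR exon > 3'UTR intron >
    promoter > mRNA exon > mRNA intron

with promoters defined as a fixed span (default 1000 bp) immediately
upstream of the TSS, strand-aware.  A variant is assigned the single
highest-ranked class containing it, or "intergenic" when none does; overlap
with repeat elements and with lncRNA exons/introns is reported as
independent flags, not as primary classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .core_types_io import GeneModel, GenomicInterval, Variant

logger = logging.getLogger("v2gtier")

CLASS_ORDER = (
    "utr5_exon",
    "utr5_intron",
    "utr3_exon",
    "utr3_intron",
    "promoter",
    "mrna_exon",
    "mrna_intron",
)

AUX_CLASSES = ("repeat", "lncrna_exon", "lncrna_intron")

IntervalSet = Dict[str, List[Tuple[int, int]]]   # chrom -> sorted disjoint list


def _merge(intervals: Iterable[Tuple[str, int, int]]) -> IntervalSet:
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        if s < e:
            by_chrom.setdefault(chrom, []).append((s, e))
    merged: IntervalSet = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def _subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Set difference a − b on merged interval sets (both half-open)."""
    result: IntervalSet = {}
    for chrom, ivs in a.items():
        cutters = b.get(chrom, [])
        out = []
        for s, e in ivs:
            cur = s
            for cs, ce in cutters:
                if ce <= cur or cs >= e:
                    continue
                if cs > cur:
                    out.append((cur, cs))
                cur = max(cur, ce)
                if cur >= e:
                    break
            if cur < e:
                out.append((cur, e))
        if out:
            result[chrom] = out
    return result


def _union(sets: Sequence[IntervalSet]) -> IntervalSet:
    triples = [(c, s, e) for iset in sets for c, ivs in iset.items() for s, e in ivs]
    return _merge(triples)


@dataclass
class PartitionIndex:
    """Disjoint per-class interval sets plus auxiliary (repeat/lncRNA) sets."""

    classes: Dict[str, IntervalSet]
    aux: Dict[str, IntervalSet]
    _trees: Dict[str, Dict[str, IntervalTree]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name, iset in list(self.classes.items()) + list(self.aux.items()):
            self._trees[name] = {
                chrom: IntervalTree.from_tuples(ivs) for chrom, ivs in iset.items()
            }

    def overlaps(self, name: str, variant: Variant) -> bool:
        tree = self._trees.get(name, {}).get(variant.chrom)
        return bool(tree is not None and tree.overlap(variant.pos - 1, variant.pos))


def _gene_class_intervals(gene: GeneModel, promoter_len: int = 1000):
    """Raw (pre-subtraction) class intervals for one coding gene model."""
    chrom = gene.chrom
    exons = list(gene.exons)
    introns = gene.introns()
    if gene.strand == "+":
        utr5_span = (gene.start, gene.cds_start)
        utr3_span = (gene.cds_end, gene.end)
    else:
        utr5_span = (gene.cds_end, gene.end)
        utr3_span = (gene.start, gene.cds_start)

    def clip(ivs, span):
        s0, e0 = span
        return [(chrom, max(s, s0), min(e, e0)) for s, e in ivs
                if max(s, s0) < min(e, e0)]

    promoter = gene.promoter(promoter_len)
    return {
        "utr5_exon": clip(exons, utr5_span),
        "utr5_intron": clip(introns, utr5_span),
        "utr3_exon": clip(exons, utr3_span),
        "utr3_intron": clip(introns, utr3_span),
        "promoter": [(chrom, promoter.start, promoter.end)],
        "mrna_exon": [(chrom, s, e) for s, e in exons],
        "mrna_intron": [(chrom, s, e) for s, e in introns],
    }


def build_partition(gene_models: Sequence[GeneModel],
                    repeats: Optional[Sequence[GenomicInterval]] = None,
                    lncrnas: Optional[Sequence[GeneModel]] = None,
                    promoter_len: int = 1000) -> PartitionIndex:
    """Build the disjoint partition from coding gene models.

    ``gene_models`` entries with ``biotype == "lncRNA"`` (or the explicit
    ``lncrnas`` list) populate the auxiliary lncRNA exon/intron sets instead
    of the primary hierarchy; ``repeats`` populate the repeat flag set.
    """
    coding = [g for g in gene_models if g.coding and g.biotype != "lncRNA"]
    lnc = list(lncrnas or []) + [g for g in gene_models
                                 if not g.coding or g.biotype == "lncRNA"]

    raw: Dict[str, list] = {name: [] for name in CLASS_ORDER}
    for gene in coding:
        per_gene = _gene_class_intervals(gene, promoter_len)
        for name in CLASS_ORDER:
            raw[name].extend(per_gene[name])

    merged = {name: _merge(raw[name]) for name in CLASS_ORDER}
    classes: Dict[str, IntervalSet] = {}
    higher: List[IntervalSet] = []
    for name in CLASS_ORDER:
        classes[name] = _subtract(merged[name], _union(higher)) if higher else merged[name]
        higher.append(classes[name])

    aux: Dict[str, IntervalSet] = {
        "repeat": _merge((iv.chrom, iv.start, iv.end) for iv in (repeats or [])),
        "lncrna_exon": _merge((g.chrom, s, e) for g in lnc for s, e in g.exons),
        "lncrna_intron": _merge((g.chrom, s, e) for g in lnc for s, e in g.introns()),
    }
    return PartitionIndex(classes=classes, aux=aux)


def classify_variant(variant: Variant, index: PartitionIndex):
    """Assign the single primary class (or "intergenic") plus repeat/lncRNA flags."""
    label = "intergenic"
    for name in CLASS_ORDER:
        if index.overlaps(name, variant):
            label = name
            break
    flags = {name: index.overlaps(name, variant) for name in AUX_CLASSES}
    return label, flags


def class_frequencies(variants: Sequence[Variant], index: PartitionIndex) -> Dict[str, float]:
    """Fraction of variants per primary class (sums to 1 over classes + intergenic)."""
    counts = {name: 0 for name in CLASS_ORDER + ("intergenic",)}
    for v in variants:
        label, _ = classify_variant(v, index)
        counts[label] += 1
    total = max(1, len(variants))
    return {name: c / total for name, c in counts.items()}
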