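"""Cross-dataset validation: effect-allele harmonization, directionality
consistency, McNemar comparison of inconsistency rates, dual-anchor
interaction/TAD support, independent eQTL replication, and per-variant /
per-gene evidence profiles.

Harmonization orients every association Z-score to the ALT allele of the
canonical variant: records reported against the REF allele have their sign
flipped.  Strand-ambiguous (A/T, C/G) variants are never flipped silently —
they are flagged, and excluded from consistency counting when the reporting
strand is unknown.  Directionality consistency compares the harmonized sign
in each (source, brain-region group) against a reference sign (by default
the sign of the mean reference-panel Z, mirroring an averaged-GTEx column);
a pair is inconsistent when more than half of the informative groups
disagree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core_types_io import (
    AssocRecord,
    GeneModel,
    GenomicInterval,
    InteractionPair,
    Variant,
)

logger = logging.getLogger("v2gtier")

REGDB_FUNCTIONAL_RANKS = frozenset({"1a", "1b", "1c", "1d", "1e"})


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonizedZ:
    """A Z-score oriented to the ALT allele of the canonical variant."""

    vid: str
    gene_id: Optional[str]
    tissue: Optional[str]
    source: Optional[str]
    z: float
    ambiguous: bool = False   # strand-ambiguous alleles: flagged, never flipped blindly


def harmonize_z(record: AssocRecord, canonical: Variant) -> HarmonizedZ:
    """Flip the record's Z iff its effect allele is the canonical REF allele.

    Raises ValueError when the effect allele matches neither canonical
    allele.  The result is a fixed point: harmonizing an already
    ALT-oriented record changes nothing.
    """
    if record.effect_allele == canonical.alt:
        z = record.z
    elif record.effect_allele == canonical.ref:
        z = -record.z
    else:
        raise ValueError(
            f"effect allele {record.effect_allele} matches neither allele of "
            f"{canonical.vid}")
    ambiguous = canonical.strand_ambiguous
    if ambiguous:
        logger.warning("strand-ambiguous variant %s: orientation unverifiable",
                       canonical.vid)
    return HarmonizedZ(vid=canonical.vid, gene_id=record.gene_id,
                       tissue=record.tissue, source=record.source,
                       z=z, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# directionality consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsistencyVerdict:
    pair_key: Tuple
    n_groups: int
    n_disagree: int
    fraction_disagree: float
    inconsistent: bool


def group_evidence(evidence: Sequence[HarmonizedZ],
                   group_map: Mapping[str, str]) -> Dict[Tuple[str, str], float]:
    """Average harmonized Z within each (source, brain-region group).

    Ambiguous-variant records and records whose tissue has no group are
    dropped (logged).
    """
    sums: Dict[Tuple[str, str], List[float]] = {}
    for hz in evidence:
        if hz.ambiguous:
            logger.info("consistency: dropping ambiguous-variant record %s", hz.vid)
            continue
        group = group_map.get(hz.tissue or "")
        if group is None:
            logger.info("consistency: tissue %r has no brain-region group", hz.tissue)
            continue
        sums.setdefault((hz.source or "", group), []).append(hz.z)
    return {k: float(np.mean(v)) for k, v in sums.items()}


def directionality_consistency(pair_key: Tuple,
                               group_z: Mapping[Tuple[str, str], float],
                               reference_z: Optional[float],
                               fraction_threshold: float = 0.5
                               ) -> Optional[ConsistencyVerdict]:
    """Compare each group's sign with the reference sign.

    Groups with zero or missing Z are excluded from the denominator.
    Returns None (undetermined) when there is no usable reference.
    """
    if reference_z is None or reference_z == 0 or math.isnan(reference_z):
        return None
    ref_sign = math.copysign(1.0, reference_z)
    informative = {k: z for k, z in group_z.items()
                   if z is not None and z != 0 and not math.isnan(z)}
    n_groups = len(informative)
    n_disagree = sum(1 for z in informative.values()
                     if math.copysign(1.0, z) != ref_sign)
    fraction = n_disagree / n_groups if n_groups else 0.0
    return ConsistencyVerdict(pair_key=pair_key, n_groups=n_groups,
                              n_disagree=n_disagree, fraction_disagree=fraction,
                              inconsistent=fraction > fraction_threshold)


# ---------------------------------------------------------------------------
# McNemar comparison of paired inconsistency flags
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McNemarResult:
    percent_reduction: int
    statistic: Optional[float]   # chi-square on discordant counts; None if b+c=0
    pvalue: float
    b: int                       # 1 -> 0 (resolved by harmonization)
    c: int                       # 0 -> 1 (introduced)
    method: str                  # "exact" | "chi2" | "degenerate"


def mcnemar_improvement(before_flags: Sequence[bool],
                        after_flags: Sequence[bool],
                        method: str = "auto",
                        exact_below: int = 25) -> McNemarResult:
    """Paired comparison of inconsistency flags before vs after harmonization.

    percent_reduction = round(100 · (n_before − n_after) / n_before).
    The test statistic is McNemar's χ² = (b−c)²/(b+c) on the discordant
    counts (no continuity correction); for small discordant totals
    (b + c < ``exact_below``) the exact two-sided binomial p-value is used.
    """
    if len(before_flags) != len(after_flags):
        raise ValueError("before/after flag vectors must be paired (equal length)")
    before = np.asarray(before_flags, dtype=bool)
    after = np.asarray(after_flags, dtype=bool)
    n_before = int(before.sum())
    n_after = int(after.sum())
    b = int((before & ~after).sum())
    c = int((~before & after).sum())
    if n_before > 0:
        percent = round(100.0 * (n_before - n_after) / n_before)
    else:
        percent = 0
    if b + c == 0:
        return McNemarResult(percent_reduction=percent, statistic=None,
                             pvalue=1.0, b=b, c=c, method="degenerate")
    chi2 = (b - c) ** 2 / (b + c)
    use_exact = method == "exact" or (method == "auto" and b + c < exact_below)
    if use_exact:
        p = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), b + c, 0.5)))
        return McNemarResult(percent, chi2, p, b, c, "exact")
    p = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(percent, chi2, p, b, c, "chi2")


# ---------------------------------------------------------------------------
# dual-anchor interaction / TAD support
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructuralSupport:
    epi_sources: Tuple[str, ...]
    tad_sources: Tuple[str, ...]

    @property
    def epi_supported(self) -> bool:
        return bool(self.epi_sources)

    @property
    def tad_supported(self) -> bool:
        return bool(self.tad_sources)


def _intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def epi_tad_support(variant: Variant, gene_id: str,
                    interactions: Sequence[InteractionPair],
                    tads: Sequence[GenomicInterval],
                    gene_models: Mapping[str, GeneModel],
                    promoter_len: int = 1000) -> StructuralSupport:
    """Dual-anchor support: the variant in one anchor and the gene's promoter
    overlapping the other (either orientation); TAD support when variant and
    TSS fall in the same TAD interval."""
    gene = gene_models.get(gene_id)
    if gene is None:
        logger.warning("epi/tad support: gene %s absent from models", gene_id)
        return StructuralSupport(epi_sources=(), tad_sources=())
    promoter = gene.promoter(promoter_len)
    epi_sources: Set[str] = set()
    for pair in interactions:
        v_in_1 = pair.anchor1.chrom == variant.chrom and pair.anchor1.contains(variant.pos)
        v_in_2 = pair.anchor2.chrom == variant.chrom and pair.anchor2.contains(variant.pos)
        if (v_in_1 and _intervals_overlap(promoter, pair.anchor2)) or \
           (v_in_2 and _intervals_overlap(promoter, pair.anchor1)):
            epi_sources.add(pair.source or pair.assay or "EPI")
    tad_sources: Set[str] = set()
    for tad in tads:
        if tad.chrom == variant.chrom and tad.contains(variant.pos) and tad.contains(gene.tss):
            tad_sources.add(tad.name or "TAD")
    return StructuralSupport(epi_sources=tuple(sorted(epi_sources)),
                             tad_sources=tuple(sorted(tad_sources)))


# ---------------------------------------------------------------------------
# independent eQTL replication
# ---------------------------------------------------------------------------

def eqtl_replication(variant: Variant, gene_id: str, reference_sign: float,
                     external_records: Sequence[AssocRecord]) -> Set[str]:
    """Sources replicating the pair: same variant, same gene, same harmonized sign."""
    if reference_sign == 0:
        return set()
    replicated: Set[str] = set()
    for rec in external_records:
        if rec.variant.vid != variant.vid or rec.gene_id != gene_id:
            continue
        hz = harmonize_z(rec, variant)
        if hz.ambiguous:
            continue
        if hz.z != 0 and math.copysign(1.0, hz.z) == math.copysign(1.0, reference_sign):
            replicated.add(rec.source or "external")
    return replicated


# ---------------------------------------------------------------------------
# evidence profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvidenceProfile:
    """Variant-level independent regulatory evidence (the V-tier inputs)."""

    histone: bool = False      # overlaps an active histone mark peak with q < 0.05
    atac: bool = False         # inside an open-chromatin (ATAC) peak
    effect_pred: bool = False  # CADD > 10 (strict) or RegulomeDB rank 1a–1e
    other_gwas: bool = False   # associated in an independent GWAS of the trait
    cadd: Optional[float] = None
    regdb: Optional[str] = None
    histone_q: Optional[float] = None

    @property
    def count(self) -> int:
        return sum((self.histone, self.atac, self.effect_pred, self.other_gwas))

    @property
    def validated(self) -> bool:
        return self.count > 0


@dataclass(frozen=True)
class GeneEvidence:
    nominated: bool = False        # on a disease gene-nomination list
    brain_expressed: bool = False  # protein-coding and expressed in brain

    @property
    def count(self) -> int:
        return int(self.nominated) + int(self.brain_expressed)

    @property
    def validated(self) -> bool:
        return self.count > 0


def evidence_profiles(variant: Variant, gene_id: str,
                      variant_table: pd.DataFrame,
                      gene_table: pd.DataFrame,
                      cadd_min: float = 10.0,
                      histone_q_max: float = 0.05
                      ) -> Tuple[EvidenceProfile, GeneEvidence]:
    """Look up the evidence tables and derive boolean profiles.

    Table schemas: variant table ``vid cadd regdb histone_q atac other_gwas``;
    gene table ``gene_id nominated brain_expressed``.  Missing rows yield
    all-false profiles; a malformed RegulomeDB rank is treated as absent
    with a warning.
    """
    row = variant_table.loc[variant_table["vid"] == variant.vid]
    if row.empty:
        profile = EvidenceProfile()
    else:
        r = row.iloc[0]
        cadd = None if pd.isna(r.get("cadd")) else float(r["cadd"])
        regdb = r.get("regdb")
        regdb = None if regdb is None or pd.isna(regdb) else str(regdb).strip().lower()
        if regdb is not None and not (len(regdb) == 2 and regdb[0].isdigit()
                                      and regdb[1].isalpha()):
            logger.warning("malformed RegulomeDB rank %r for %s; ignored",
                           regdb, variant.vid)
            regdb = None
        hq = None if pd.isna(r.get("histone_q")) else float(r["histone_q"])
        effect = (cadd is not None and cadd > cadd_min) or \
                 (regdb in REGDB_FUNCTIONAL_RANKS)
        profile = EvidenceProfile(
            histone=hq is not None and hq < histone_q_max,
            atac=bool(r.get("atac", 0)),
            effect_pred=bool(effect),
            other_gwas=bool(r.get("other_gwas", 0)),
            cadd=cadd, regdb=regdb, histone_q=hq)
    grow = gene_table.loc[gene_table["gene_id"] == gene_id]
    if grow.empty:
        gene_ev = GeneEvidence()
    else:
        g = grow.iloc[0]
        gene_ev = GeneEvidence(nominated=bool(g.get("nominated", 0)),
                               brain_expressed=bool(g.get("brain_expressed", 0)))
    return profile, gene_ev
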