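"""End-to-end orchestration of the four stages:

    Preprocess     LD pruning of significant GWAS variants to tags,
                   expansion of each tag into an analysis region.
    Characterize   genome-partition annotation of candidate variants,
                   per-(gene, tissue) Bayesian colocalization in each region,
                   TFBS-disruption scanning, enhancer overlap, and the
                   confluent-context filter.
    Validate       harmonized cross-dataset directionality, replication,
                   dual-anchor interaction/TAD support, evidence profiles,
                   and the raw-vs-harmonized McNemar comparison.
    Tier           component tiers, overall tier, ranked output.

``run_pipeline`` consumes a :class:`RunConfig` (all file paths plus every
threshold, loadable from YAML), writes stage tables and a JSON run summary
with the per-stage funnel counts, and is deterministic given the config.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import colocalization as coloc
from . import genome_partition as partition
from . import insilico_validation as validation
from . import ld_regions
from . import tfbs_scan
from .confluence import ConfluentPair, EnhancerIndex, confluent_v2g
from .core_types_io import (
    AssocRecord,
    Variant,
    read_bed,
    read_bed12_genes,
    read_bedpe,
    read_fasta,
    read_motifs,
    read_summary_stats,
    write_report,
)

logger = logging.getLogger("v2gtier")


class PipelineError(RuntimeError):
    """A stage cannot run: names the stage and the missing/empty input."""


@dataclass
class RunConfig:
    """Every input path and every threshold of the pipeline, with defaults
    matching the framework's published operating point."""

    # inputs
    gwas: str = ""
    panel: str = ""
    eqtl: str = ""
    genome: str = ""
    motifs: str = ""
    enhancers: str = ""
    genes: str = ""
    epi: str = ""
    tads: str = ""
    validation_eqtls: str = ""
    variant_evidence: str = ""
    gene_evidence: str = ""
    tissue_map: str = ""
    groups: str = ""
    repeats: str = ""
    lncrnas: str = ""
    out_dir: str = "v2gtier_out"
    # thresholds
    p_thresh: float = 5e-8
    prune_r2: float = 0.7
    window_bp: int = 500_000
    expand_r2: float = 0.7
    max_bp: int = 1_000_000
    max_rank_dist: int = 1000
    nominal_alpha: float = 0.05
    pp_h4_min: float = 0.7
    snp_pp_min: float = 0.5
    delta_threshold: float = 2.0
    cadd_min: float = 10.0
    histone_q_max: float = 0.05
    consistency_fraction: float = 0.5
    promoter_len: int = 1000
    epi_cap: int = 2
    # coloc priors
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    W: float = 0.0225
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def priors(self) -> coloc.ColocPriors:
        return coloc.ColocPriors(p1=self.p1, p2=self.p2, p12=self.p12, W=self.W)


def _require(path: str, stage: str, what: str) -> str:
    if not path or not os.path.exists(path):
        raise PipelineError(f"stage {stage!r}: required input {what!r} missing ({path!r})")
    return path


# ---------------------------------------------------------------------------
# stage 1: preprocess
# ---------------------------------------------------------------------------

def preprocess(config: RunConfig):
    from .synthetic_data import read_panel

    gwas = read_summary_stats(_require(config.gwas, "preprocess", "gwas"), "gwas")
    panel = read_panel(_require(config.panel, "preprocess", "panel"))
    tags = ld_regions.prune_variants(gwas, panel, p_thresh=config.p_thresh,
                                     prune_r2=config.prune_r2,
                                     window_bp=config.window_bp)
    regions = [ld_regions.expand_region(tag, panel, expand_r2=config.expand_r2,
                                        max_bp=config.max_bp,
                                        max_rank_dist=config.max_rank_dist)
               for tag in tags]
    return gwas, panel, tags, regions


# ---------------------------------------------------------------------------
# stage 2: characterize
# ---------------------------------------------------------------------------

def colocalize_regions(regions: Sequence[ld_regions.LDRegion],
                       gwas: Sequence[AssocRecord],
                       eqtl: Sequence[AssocRecord],
                       priors: coloc.ColocPriors,
                       nominal_alpha: float = 0.05,
                       pp_h4_min: float = 0.7,
                       snp_pp_min: float = 0.5
                       ) -> Tuple[List[coloc.V2GPair], List[coloc.ColocResult]]:
    """Per-region, per-(gene, tissue, source) colocalization and pair calling.

    Duplicate (variant, gene, tissue, source) calls from overlapping regions
    keep the highest PP(H4).
    """
    gwas_by_vid = {r.variant.vid: r for r in gwas}
    results: List[coloc.ColocResult] = []
    best: Dict[Tuple, coloc.V2GPair] = {}
    for region in regions:
        region_vids = {v.vid for v in region.all_region_variants}
        gwas_locus = [gwas_by_vid[v] for v in sorted(region_vids) if v in gwas_by_vid]
        if not gwas_locus:
            continue
        eqtl_locus = [r for r in eqtl if r.variant.vid in region_vids]
        groups = coloc.filter_nominal_eqtl_genes(eqtl_locus, alpha=nominal_alpha)
        for key in sorted(groups):
            recs = groups[key]
            shared = {r.variant.vid for r in recs} & {r.variant.vid for r in gwas_locus}
            if not shared:
                continue
            result = coloc.coloc_posteriors(gwas_locus, recs, priors,
                                            locus_id=f"{region.tag.vid}|{key[0]}|{key[1]}")
            results.append(result)
            pair = coloc.call_v2g(result, recs, pp_h4_min=pp_h4_min,
                                  snp_pp_min=snp_pp_min)
            if pair is not None:
                k = (pair.variant.vid, pair.gene_id, pair.tissue, pair.source)
                if k not in best or pair.pp_h4 > best[k].pp_h4:
                    best[k] = pair
    pairs = [best[k] for k in sorted(best)]
    return pairs, results


def characterize(config: RunConfig, regions, gwas, panel):
    eqtl = read_summary_stats(_require(config.eqtl, "characterize", "eqtl"), "eqtl")
    pairs, coloc_results = colocalize_regions(
        regions, gwas, eqtl, config.priors(),
        nominal_alpha=config.nominal_alpha,
        pp_h4_min=config.pp_h4_min, snp_pp_min=config.snp_pp_min)

    genome = read_fasta(_require(config.genome, "characterize", "genome"))
    motifs = read_motifs(_require(config.motifs, "characterize", "motifs"))
    tfbs_calls: Dict[str, List[str]] = {}
    tfbs_rows = []
    for variant in sorted({p.variant for p in pairs}):
        hits = tfbs_scan.scan_variant(variant, motifs, genome,
                                      threshold=config.delta_threshold)
        tfbs_calls[variant.vid] = [h.motif_id for h in hits]
        for h in hits:
            tfbs_rows.append(dict(vid=variant.vid, motif_id=h.motif_id,
                                  ref_score=h.ref_score, alt_score=h.alt_score,
                                  delta=h.delta))

    enhancers = read_bed(_require(config.enhancers, "characterize", "enhancers"))
    index = EnhancerIndex(enhancers)
    with open(_require(config.tissue_map, "characterize", "tissue map")) as fh:
        tissue_map = yaml.safe_load(fh) or {}
    tissue_map = {k: (v if isinstance(v, list) else [v]) for k, v in tissue_map.items()}
    confluent = confluent_v2g(pairs, tfbs_calls, index, tissue_map)
    return eqtl, pairs, coloc_results, tfbs_rows, confluent


# ---------------------------------------------------------------------------
# stage 3: in silico validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationRecord:
    pair: coloc.V2GPair
    reference_z: Optional[float]
    consistency: Optional[validation.ConsistencyVerdict]
    raw_inconsistent: Optional[bool]
    replication_sources: Tuple[str, ...]
    epi_sources: Tuple[str, ...]
    tad_sources: Tuple[str, ...]
    evidence: validation.EvidenceProfile
    gene_evidence: validation.GeneEvidence


def _mean_reference_z(pair: coloc.V2GPair,
                      discovery_eqtl: Sequence[AssocRecord]) -> Optional[float]:
    """Mean harmonized discovery-panel Z for the pair's variant+gene across
    tissues (the averaged-reference column of the directionality display)."""
    zs = []
    for rec in discovery_eqtl:
        if rec.variant.vid == pair.variant.vid and rec.gene_id == pair.gene_id:
            hz = validation.harmonize_z(rec, pair.variant)
            if not hz.ambiguous:
                zs.append(hz.z)
    return float(sum(zs) / len(zs)) if zs else None


def validate_pairs(config: RunConfig, confluent: Sequence[ConfluentPair],
                   discovery_eqtl: Sequence[AssocRecord]) -> List[ValidationRecord]:
    external = read_summary_stats(
        _require(config.validation_eqtls, "validate", "validation eqtls"), "eqtl")
    interactions = read_bedpe(_require(config.epi, "validate", "interactions"))
    tads = read_bed(_require(config.tads, "validate", "tads"))
    gene_models = {g.gene_id: g
                   for g in read_bed12_genes(_require(config.genes, "validate", "genes"))}
    with open(_require(config.groups, "validate", "brain-region groups")) as fh:
        group_map = yaml.safe_load(fh) or {}
    variant_table = pd.read_csv(
        _require(config.variant_evidence, "validate", "variant evidence"), sep="\t")
    gene_table = pd.read_csv(
        _require(config.gene_evidence, "validate", "gene evidence"), sep="\t")

    out = []
    for cp in confluent:
        pair = cp.pair
        key = (pair.variant.vid, pair.gene_id)
        ext_records = [r for r in external
                       if r.variant.vid == pair.variant.vid
                       and r.gene_id == pair.gene_id]
        harmonized = [validation.harmonize_z(r, pair.variant) for r in ext_records]
        # raw view: signs exactly as reported, before allele orientation
        raw = [validation.HarmonizedZ(vid=h.vid, gene_id=h.gene_id, tissue=h.tissue,
                                      source=h.source, z=r.z, ambiguous=h.ambiguous)
               for r, h in zip(ext_records, harmonized)]
        reference_z = _mean_reference_z(pair, discovery_eqtl)
        group_z = validation.group_evidence(harmonized, group_map)
        group_z_raw = validation.group_evidence(raw, group_map)
        verdict = validation.directionality_consistency(
            key, group_z, reference_z, fraction_threshold=config.consistency_fraction)
        raw_verdict = validation.directionality_consistency(
            key, group_z_raw, reference_z, fraction_threshold=config.consistency_fraction)
        replication = validation.eqtl_replication(
            pair.variant, pair.gene_id, reference_z or 0.0, ext_records)
        support = validation.epi_tad_support(
            pair.variant, pair.gene_id, interactions, tads, gene_models,
            promoter_len=config.promoter_len)
        profile, gene_ev = validation.evidence_profiles(
            pair.variant, pair.gene_id, variant_table, gene_table,
            cadd_min=config.cadd_min, histone_q_max=config.histone_q_max)
        out.append(ValidationRecord(
            pair=pair, reference_z=reference_z, consistency=verdict,
            raw_inconsistent=None if raw_verdict is None else raw_verdict.inconsistent,
            replication_sources=tuple(sorted(replication)),
            epi_sources=support.epi_sources, tad_sources=support.tad_sources,
            evidence=profile, gene_evidence=gene_ev))
    return out


# ---------------------------------------------------------------------------
# stage 4: tiering + report
# ---------------------------------------------------------------------------

def tier_stage(config: RunConfig, validated: Sequence[ValidationRecord]):
    from .tiering import compute_tiers, rank_pairs

    scored = []
    for rec in validated:
        score = compute_tiers(rec.pair, rec.consistency,
                              set(rec.replication_sources), rec.epi_sources,
                              rec.evidence, rec.gene_evidence,
                              reference_z=rec.reference_z, epi_cap=config.epi_cap)
        scored.append((rec.pair, score))
    return rank_pairs(scored)


def _pairs_table(pairs: Sequence[coloc.V2GPair]) -> pd.DataFrame:
    return pd.DataFrame([dict(vid=p.variant.vid, gene_id=p.gene_id,
                              tissue=p.tissue, source=p.source,
                              pp_h4=p.pp_h4, snp_pp_h4=p.snp_pp_h4,
                              z_eqtl=p.z_eqtl, locus_id=p.locus_id)
                         for p in pairs],
                        columns=["vid", "gene_id", "tissue", "source", "pp_h4",
                                 "snp_pp_h4", "z_eqtl", "locus_id"])


def run_pipeline(config: RunConfig) -> dict:
    """Run all four stages; returns {"tables": ..., "summary": ..., "paths": ...}."""
    gwas, panel, tags, regions = preprocess(config)
    n_significant = sum(1 for r in gwas if r.pvalue < config.p_thresh)
    candidate_vids = sorted({v.vid for reg in regions for v in reg.proxies})

    tables: Dict[str, pd.DataFrame] = {}
    tables["tags"] = pd.DataFrame(
        [dict(vid=t.vid, chrom=t.chrom, pos=t.pos) for t in tags],
        columns=["vid", "chrom", "pos"])
    tables["regions"] = pd.DataFrame(
        [dict(tag=r.tag.vid, chrom=r.bounds[0], min_pos=r.bounds[1],
              max_pos=r.bounds[2], n_proxies=len(r.proxies),
              n_region_variants=len(r.all_region_variants),
              proxies=",".join(v.vid for v in r.proxies))
         for r in regions],
        columns=["tag", "chrom", "min_pos", "max_pos", "n_proxies",
                 "n_region_variants", "proxies"])

    # genome-partition annotation of candidate variants (optional inputs)
    partition_summary: Dict[str, float] = {}
    if config.genes and os.path.exists(config.genes):
        gene_models = read_bed12_genes(config.genes)
        repeats = read_bed(config.repeats) if config.repeats and os.path.exists(config.repeats) else None
        lncrnas = read_bed12_genes(config.lncrnas) if config.lncrnas and os.path.exists(config.lncrnas) else None
        index = partition.build_partition(gene_models, repeats=repeats,
                                          lncrnas=lncrnas,
                                          promoter_len=config.promoter_len)
        cand_variants = [Variant.from_vid(v) for v in candidate_vids]
        rows = []
        for v in cand_variants:
            label, flags = partition.classify_variant(v, index)
            rows.append(dict(vid=v.vid, class_label=label,
                             **{k: int(b) for k, b in flags.items()}))
        tables["partition"] = pd.DataFrame(
            rows, columns=["vid", "class_label"] + [k for k in partition.AUX_CLASSES])
        partition_summary = partition.class_frequencies(cand_variants, index)

    if regions:
        eqtl, pairs, coloc_results, tfbs_rows, confluent = characterize(
            config, regions, gwas, panel)
    else:
        eqtl, pairs, coloc_results, tfbs_rows, confluent = [], [], [], [], []
    tables["coloc_pairs"] = _pairs_table(pairs)
    tables["tfbs"] = pd.DataFrame(
        tfbs_rows, columns=["vid", "motif_id", "ref_score", "alt_score", "delta"])
    tables["confluent_pairs"] = pd.DataFrame(
        [dict(vid=cp.pair.variant.vid, gene_id=cp.pair.gene_id,
              tissue=cp.pair.tissue, source=cp.pair.source,
              pp_h4=cp.pair.pp_h4, snp_pp_h4=cp.pair.snp_pp_h4,
              motifs=",".join(cp.tfbs_hits),
              enhancers=",".join(f"{d}:{t}" for d, t, _ in cp.enhancer_hits))
         for cp in confluent],
        columns=["vid", "gene_id", "tissue", "source", "pp_h4", "snp_pp_h4",
                 "motifs", "enhancers"])

    validated = validate_pairs(config, confluent, eqtl) if confluent else []
    tables["validation"] = pd.DataFrame(
        [dict(vid=r.pair.variant.vid, gene_id=r.pair.gene_id,
              tissue=r.pair.tissue, source=r.pair.source,
              reference_z="" if r.reference_z is None else r.reference_z,
              n_groups=0 if r.consistency is None else r.consistency.n_groups,
              n_disagree=0 if r.consistency is None else r.consistency.n_disagree,
              inconsistent="" if r.consistency is None else int(r.consistency.inconsistent),
              raw_inconsistent="" if r.raw_inconsistent is None else int(r.raw_inconsistent),
              replication=",".join(r.replication_sources),
              epi=",".join(r.epi_sources), tad=",".join(r.tad_sources),
              ev_histone=int(r.evidence.histone), ev_atac=int(r.evidence.atac),
              ev_effect_pred=int(r.evidence.effect_pred),
              ev_other_gwas=int(r.evidence.other_gwas),
              gene_nominated=int(r.gene_evidence.nominated),
              gene_brain_expressed=int(r.gene_evidence.brain_expressed))
         for r in validated],
        columns=["vid", "gene_id", "tissue", "source", "reference_z", "n_groups",
                 "n_disagree", "inconsistent", "raw_inconsistent", "replication",
                 "epi", "tad", "ev_histone", "ev_atac", "ev_effect_pred",
                 "ev_other_gwas", "gene_nominated", "gene_brain_expressed"])

    # raw-vs-harmonized inconsistency comparison over determinable pairs
    determined = [r for r in validated
                  if r.consistency is not None and r.raw_inconsistent is not None]
    mcnemar_summary: Dict = {}
    if determined:
        before = [r.raw_inconsistent for r in determined]
        after = [r.consistency.inconsistent for r in determined]
        mc = validation.mcnemar_improvement(before, after)
        mcnemar_summary = dict(n_pairs=len(determined),
                               n_inconsistent_before=int(sum(before)),
                               n_inconsistent_after=int(sum(after)),
                               percent_reduction=mc.percent_reduction,
                               statistic=mc.statistic, pvalue=mc.pvalue,
                               method=mc.method)

    ranked = tier_stage(config, validated)
    tables["ranked_pairs"] = pd.DataFrame(
        [dict(rank=i + 1, vid=p.variant.vid, gene_id=p.gene_id,
              tissue=p.tissue, source=p.source, pp_h4=p.pp_h4,
              v2g_eqtl_tier=s.v2g_eqtl, v2g_epi_tier=s.v2g_epi,
              v_tier=s.v, g_tier=s.g, overall_tier=s.overall)
         for i, (p, s) in enumerate(ranked)],
        columns=["rank", "vid", "gene_id", "tissue", "source", "pp_h4",
                 "v2g_eqtl_tier", "v2g_epi_tier", "v_tier", "g_tier",
                 "overall_tier"])

    summary = {
        "config": config.to_dict(),
        "stages": {
            "preprocess": {
                "n_gwas_records": len(gwas),
                "n_significant": n_significant,
                "n_tags": len(tags),
                "n_regions": len(regions),
                "n_candidate_variants": len(candidate_vids),
            },
            "characterize": {
                "n_coloc_tests": len(coloc_results),
                "n_coloc_pairs": len(pairs),
                "n_variants_with_tfbs": len({r["vid"] for r in tfbs_rows}),
                "n_confluent_pairs": len(confluent),
                "n_genes": len({cp.pair.gene_id for cp in confluent}),
            },
            "validate": {
                "n_validated_pairs": len(validated),
                "mcnemar": mcnemar_summary,
            },
            "tier": {
                "n_tiered_pairs": len(ranked),
                "top_tier": ranked[0][1].overall if ranked else None,
            },
        },
        "partition_class_frequencies": partition_summary,
    }
    paths = write_report(tables, config.out_dir, summary)
    return {"tables": tables, "summary": summary, "paths": paths,
            "ranked": ranked, "regions": regions}
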