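"""LD-structured haplotypes, planted association signals, and toy annotation
resources, so every downstream stage of the pipeline can be exercised without
any external download.

The haplotype generator uses a template-copying model: a small number of
template haplotypes are drawn at random, each simulated haplotype copies one
template within blocks of consecutive variants, switches to a random template
at block boundaries with a configurable probability, and each copied allele
is flipped with a small per-site mutation probability.  This produces blocky
linkage disequilibrium whose strength decays with distance — the feature of
real reference panels (such as a 1000 Genomes EUR panel) that LD pruning and
expansion actually depend on — without attempting to match any real LD map.

Association summary statistics are simulated at the Z-score level with the
standard LD-propagation model: with a single causal variant c carrying
non-centrality ``ncp``, the Z vector is multivariate normal

    z ~ MVN(R[:, c] * ncp,  R),

where R is the signed allelic correlation matrix of the panel.  Marginally
each z_j ~ Normal(r_{j,c} * ncp, 1); the noise is correlated through LD
exactly as the means are, which is what makes the causal variant
statistically identifiable among its proxies.  The *signed* correlation
drives propagation so effect directions are meaningful downstream;
beta = z * se and se = 1 / sqrt(n_samples).
Effect alleles are always reported as ALT by the generator; harmonization
stages re-orient deliberately scrambled copies.

``plant_v2g_scenario`` assembles a full test scenario (shared, distinct or
null causal configuration across a GWAS trait and one or more eQTL tissues)
and ``generate_annotation_bundle`` writes a truth-consistent file bundle:
the planted causal variant sits inside an enhancer whose tissue matches the
eQTL tissue, under a motif whose allelic delta exceeds the disruption
threshold, inside an interaction anchor paired with the target gene's
promoter — so the confluence and tiering stages have a known positive.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .core_types_io import (
    AssocRecord,
    COMPLEMENT,
    GeneModel,
    GenomicInterval,
    InteractionPair,
    ParameterError,
    Variant,
    write_bed,
    write_bed12_genes,
    write_bedpe,
    write_fasta,
    write_motifs,
    write_summary_stats,
)
from .ld_regions import compute_r2

logger = logging.getLogger("v2gtier")

BASES = "ACGT"


# ---------------------------------------------------------------------------
# haplotype panel
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Phased haplotypes over one chromosome: 0 = ref allele, 1 = alt."""

    chrom: str
    positions: np.ndarray          # sorted 1-based, strictly increasing
    alleles: List[Tuple[str, str]]  # per-variant (ref, alt)
    matrix: np.ndarray             # n_hap x n_var of {0, 1}

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.matrix.shape[1] != len(self.positions) or len(self.alleles) != len(self.positions):
            raise ValueError("matrix/positions/alleles shapes disagree")

    @property
    def n_hap(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_var(self) -> int:
        return self.matrix.shape[1]

    def maf(self, j: int) -> float:
        f = float(self.matrix[:, j].mean())
        return min(f, 1.0 - f)

    def variant(self, j: int) -> Variant:
        ref, alt = self.alleles[j]
        return Variant(self.chrom, int(self.positions[j]), ref, alt)

    def variants(self) -> List[Variant]:
        return [self.variant(j) for j in range(self.n_var)]

    def index_of(self, variant: Variant) -> Optional[int]:
        if variant.chrom != self.chrom:
            return None
        hits = np.nonzero(self.positions == variant.pos)[0]
        for j in hits:
            if self.alleles[j] == (variant.ref, variant.alt):
                return int(j)
        return None


def generate_haplotype_panel(n_hap: int = 200, n_var: int = 100,
                             block_len: int = 20, switch_prob: float = 0.1,
                             maf_floor: float = 0.05, seed: int = 0,
                             n_templates: int = 4, mutation_prob: float = 0.01,
                             spacing_bp: int = 1000, chrom: str = "chr1",
                             first_pos: int = 10_001) -> HaplotypePanel:
    """Template-copying haplotype simulator (see module docstring).

    Deterministic given the parameters and seed.  Columns failing
    ``maf_floor`` have their template alleles redrawn (copying assignments
    kept) until every column is sufficiently polymorphic; a floor that the
    panel size cannot satisfy raises :class:`ParameterError`.
    """
    if n_hap < 4 or n_var < 2:
        raise ParameterError("need n_hap >= 4 and n_var >= 2")
    if not (0 <= maf_floor <= 0.5):
        raise ParameterError("maf_floor must be in [0, 0.5]")
    if maf_floor > 0 and math.ceil(maf_floor * n_hap) > n_hap // 2:
        raise ParameterError(f"maf_floor {maf_floor} unattainable with {n_hap} haplotypes")
    rng = np.random.default_rng(seed)

    positions = first_pos + np.cumsum(
        rng.integers(max(1, spacing_bp // 2), spacing_bp + spacing_bp // 2 + 1, size=n_var))
    # ref uniform; alt never the complement of ref, so no variant is
    # strand-ambiguous (keeps motif/harmonization truth constructions exact)
    alleles = []
    for _ in range(n_var):
        ref = BASES[rng.integers(4)]
        choices = [b for b in BASES if b not in (ref, COMPLEMENT[ref])]
        alleles.append((ref, choices[rng.integers(2)]))

    templates = rng.integers(0, 2, size=(n_templates, n_var)).astype(np.uint8)
    # assignment[h, j] = which template haplotype h copies at variant j;
    # round-robin start guarantees all templates are represented
    assignment = np.empty((n_hap, n_var), dtype=np.int64)
    current = np.arange(n_hap) % n_templates
    n_blocks = (n_var + block_len - 1) // block_len
    for b in range(n_blocks):
        if b > 0:
            switch = rng.random(n_hap) < switch_prob
            current = np.where(switch, rng.integers(0, n_templates, size=n_hap), current)
        j0, j1 = b * block_len, min((b + 1) * block_len, n_var)
        assignment[:, j0:j1] = current[:, None]
    mutate = (rng.random((n_hap, n_var)) < mutation_prob).astype(np.uint8)
    matrix = templates[assignment, np.arange(n_var)[None, :]] ^ mutate

    def _column_ok(j: int) -> bool:
        f = matrix[:, j].mean()
        return min(f, 1.0 - f) >= maf_floor and 0.0 < f < 1.0

    for j in range(n_var):
        attempts = 0
        while not _column_ok(j):
            attempts += 1
            if attempts > 200:
                raise ParameterError(
                    f"maf_floor {maf_floor} unattainable at column {j} "
                    f"(templates used: {len(set(assignment[:, j]))})")
            templates[:, j] = rng.integers(0, 2, size=n_templates)
            matrix[:, j] = templates[assignment[:, j], j] ^ mutate[:, j]
    return HaplotypePanel(chrom=chrom, positions=positions, alleles=alleles,
                          matrix=matrix)


def write_panel(panel: HaplotypePanel, path: str) -> None:
    cols = {"chrom": panel.chrom, "pos": panel.positions,
            "ref": [a[0] for a in panel.alleles],
            "alt": [a[1] for a in panel.alleles]}
    hap = pd.DataFrame(panel.matrix.T,
                       columns=[f"h{h}" for h in range(panel.n_hap)])
    pd.concat([pd.DataFrame(cols), hap], axis=1).to_csv(path, sep="\t", index=False)


def read_panel(path: str) -> HaplotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    hap_cols = [c for c in df.columns if c.startswith("h") and c[1:].isdigit()]
    hap_cols.sort(key=lambda c: int(c[1:]))
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ParameterError("panel files hold a single chromosome")
    return HaplotypePanel(
        chrom=str(chroms[0]),
        positions=df["pos"].to_numpy(),
        alleles=list(zip(df["ref"].str.upper(), df["alt"].str.upper())),
        matrix=df[hap_cols].to_numpy().T,
    )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _signed_correlation_matrix(panel: HaplotypePanel) -> np.ndarray:
    m = panel.matrix.astype(float)
    centered = m - m.mean(axis=0)
    sd = centered.std(axis=0)
    R = (centered / sd).T @ (centered / sd) / panel.n_hap
    np.fill_diagonal(R, 1.0)
    return R


def simulate_summary_stats(panel: HaplotypePanel, causal_index: Optional[int],
                           ncp: float, n_samples: int, seed: int,
                           gene_id: Optional[str] = None,
                           tissue: Optional[str] = None,
                           source: Optional[str] = None) -> List[AssocRecord]:
    """Z-level association simulation with LD propagation (module docstring).

    ``causal_index=None`` simulates a null trait (all means zero).  Effect
    alleles are reported as ALT for every record.
    """
    if ncp < 0:
        raise ParameterError("ncp must be non-negative")
    if causal_index is not None and not (0 <= causal_index < panel.n_var):
        raise ParameterError(f"causal_index {causal_index} out of range")
    rng = np.random.default_rng(seed)
    se = 1.0 / math.sqrt(n_samples)
    R = _signed_correlation_matrix(panel)
    if causal_index is None or ncp == 0:
        means = np.zeros(panel.n_var)
    else:
        means = R[:, causal_index] * ncp
    # noise correlated through LD: eigenvalue square root of R (clipping
    # tiny negative eigenvalues from floating point)
    evals, evecs = np.linalg.eigh(R)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    z = means + root @ rng.standard_normal(panel.n_var)
    records = []
    for j in range(panel.n_var):
        ref, alt = panel.alleles[j]
        p = math.erfc(abs(z[j]) / math.sqrt(2.0))
        records.append(AssocRecord(
            variant=Variant(panel.chrom, int(panel.positions[j]), ref, alt),
            effect_allele=alt, beta=float(z[j] * se), se=se,
            pvalue=max(p, 5e-324), gene_id=gene_id, tissue=tissue, source=source))
    return records


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioTruth:
    """Everything needed to score recovery of the planted configuration."""

    gwas_causal_index: Optional[int]
    eqtl_causal_index: Optional[int]
    target_gene: Optional[str]
    expected_pairs: List[Tuple[str, str]]   # (vid, gene_id)


@dataclass
class Scenario:
    kind: str
    panel: HaplotypePanel
    gwas: List[AssocRecord]
    eqtls: Dict[Tuple[str, str, str], List[AssocRecord]]
    truth: ScenarioTruth
    seed: int


DEFAULT_PANEL_PARAMS = dict(n_hap=200, n_var=60, block_len=12,
                            switch_prob=0.1, maf_floor=0.05,
                            n_templates=4, mutation_prob=0.01)


def _pick_causal_column(panel: HaplotypePanel, rng: np.random.Generator,
                        avoid: Optional[int] = None,
                        max_partner_r2: float = 0.9) -> int:
    """Pick a causal column whose strongest LD partner stays below
    ``max_partner_r2`` (perfect proxies make the planted variant
    statistically unidentifiable); fall back to the most identifiable one."""
    best_j, best_max = None, np.inf
    order = rng.permutation(panel.n_var)
    for j in order:
        if avoid is not None and j == avoid:
            continue
        mx = max(compute_r2(panel, int(j), k)
                 for k in range(panel.n_var) if k != j)
        if mx < max_partner_r2:
            return int(j)
        if mx < best_max:
            best_j, best_max = int(j), mx
    return best_j


def plant_v2g_scenario(kind: str, panel_params: Optional[dict] = None,
                       ncp_gwas: float = 8.0, ncp_eqtl: float = 8.0,
                       tissues: Sequence[str] = ("brain_cortex",),
                       seed: int = 0, n_samples: int = 10_000,
                       source: str = "GTEx",
                       target_gene: str = "GENE1") -> Scenario:
    """Assemble a shared / distinct / null causal scenario with its truth."""
    if kind not in ("shared", "distinct", "null"):
        raise ParameterError(f"unknown scenario kind {kind!r}")
    params = dict(DEFAULT_PANEL_PARAMS)
    params.update(panel_params or {})
    ss = np.random.SeedSequence(seed)
    panel_seed, pick_seed, gwas_seed, *eqtl_seeds = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3 + len(tissues))]
    panel = generate_haplotype_panel(seed=panel_seed, **params)
    rng = np.random.default_rng(pick_seed)

    if kind == "null":
        gwas_c = eqtl_c = None
    elif kind == "shared":
        gwas_c = eqtl_c = _pick_causal_column(panel, rng)
    else:  # distinct: two causal columns in linkage equilibrium
        gwas_c = _pick_causal_column(panel, rng)
        candidates = [j for j in range(panel.n_var)
                      if j != gwas_c and compute_r2(panel, j, gwas_c) < 0.1]
        if not candidates:
            raise ParameterError("no column pair with r^2 < 0.1 available")
        eqtl_c = int(rng.choice(candidates))

    gwas = simulate_summary_stats(panel, gwas_c, ncp_gwas, n_samples, gwas_seed)
    eqtls = {}
    for tissue, t_seed in zip(tissues, eqtl_seeds):
        key = (target_gene, tissue, source)
        eqtls[key] = simulate_summary_stats(panel, eqtl_c, ncp_eqtl, n_samples,
                                            t_seed, gene_id=target_gene,
                                            tissue=tissue, source=source)
    expected = []
    if kind == "shared":
        expected = [(panel.variant(gwas_c).vid, target_gene)]
    truth = ScenarioTruth(gwas_causal_index=gwas_c, eqtl_causal_index=eqtl_c,
                          target_gene=target_gene if kind != "null" else None,
                          expected_pairs=expected)
    return Scenario(kind=kind, panel=panel, gwas=gwas, eqtls=eqtls,
                    truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# annotation bundle
# ---------------------------------------------------------------------------

def _truth_motif(ref: str, alt: str, length: int = 7):
    """A PWM whose best-placement delta between ref and alt exceeds 2.

    The center column strongly prefers the ref base (0.8) over the alt
    (0.05); all other columns are uninformative.  With the surrounding
    genome bases drawn from {alt, complement(alt)} no alternative placement
    (either strand) can rescue the alt allele, pinning the delta near
    log2(0.8/0.25) + |log2(0.075/0.25)| ≈ 3.4.
    """
    from .tfbs_scan import BASE_INDEX, PWM

    m = np.full((length, 4), 0.25)
    center = length // 2
    row = np.full(4, 0.075)
    row[BASE_INDEX[ref]] = 0.8
    row[BASE_INDEX[alt]] = 0.05
    m[center] = row
    return PWM(motif_id="TRUTH_MOTIF", tf_name="TRUTH", matrix=m)


def _decoy_motif(rng: np.random.Generator, name: str, length: int = 8):
    from .tfbs_scan import PWM

    m = rng.dirichlet(np.full(4, 5.0), size=length)  # mild preferences only
    return PWM(motif_id=name, tf_name=name, matrix=m)


def generate_annotation_bundle(panel: HaplotypePanel, scenario: Scenario,
                               out_dir: str, seed: int = 0,
                               include_truth: bool = True,
                               n_decoys: int = 4,
                               enhancer_halfwidth: int = 250,
                               promoter_len: int = 1000) -> Dict[str, str]:
    """Write a truth-consistent (or decoy-only) annotation file bundle.

    Returns a {component: path} map covering: genome FASTA, gene models
    (BED12), enhancer/histone/ATAC tracks (BED), enhancer–promoter
    interactions (BEDPE), TADs (BED), motifs, external validation eQTLs
    (TSV), variant/gene evidence tables (TSV), and tissue/group maps (YAML).
    """
    from .tfbs_scan import best_allele_scores

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    chrom = panel.chrom
    truth = scenario.truth
    tissues = sorted({k[1] for k in scenario.eqtls})
    causal = (truth.eqtl_causal_index if truth.eqtl_causal_index is not None
              else None)
    causal_var = panel.variant(causal) if causal is not None else None

    # ---- genome ----
    gene_tss0 = int(panel.positions[-1]) + 5000        # 0-based TSS of target gene
    genome_len = gene_tss0 + 12_000
    seq = rng.choice(list(BASES), size=genome_len)
    for j in range(panel.n_var):
        seq[panel.positions[j] - 1] = panel.alleles[j][0]
    if include_truth and causal_var is not None:
        # controlled neighborhood so the truth motif's delta is unambiguous
        safe = [causal_var.alt, COMPLEMENT[causal_var.alt]]
        for off in range(-6, 7):
            if off == 0:
                continue
            idx = causal_var.pos - 1 + off
            if 0 <= idx < genome_len and (panel.positions != idx + 1).all():
                seq[idx] = safe[rng.integers(2)]
    genome = {chrom: "".join(seq)}
    paths = {"genome": os.path.join(out_dir, "genome.fa")}
    write_fasta(genome, paths["genome"])

    # ---- gene models ----
    target = truth.target_gene or "GENE1"
    exon1 = (gene_tss0, gene_tss0 + 400)
    exon2 = (gene_tss0 + 900, gene_tss0 + 1600)
    genes = [GeneModel(gene_id=target, chrom=chrom, strand="+",
                       exons=(exon1, exon2),
                       cds_start=gene_tss0 + 100, cds_end=gene_tss0 + 1400),
             GeneModel(gene_id="DECOY_GENE", chrom=chrom, strand="-",
                       exons=((gene_tss0 + 6000, gene_tss0 + 6500),
                              (gene_tss0 + 7000, gene_tss0 + 7800)),
                       cds_start=gene_tss0 + 6100, cds_end=gene_tss0 + 7500)]
    paths["genes"] = os.path.join(out_dir, "genes.bed12")
    write_bed12_genes(genes, paths["genes"])

    # ---- enhancer / histone / ATAC tracks ----
    def _decoy_interval(cls: str, tissue: str, dataset: str) -> GenomicInterval:
        # placed beyond the gene region: overlaps no panel variant
        start = gene_tss0 + 8000 + int(rng.integers(0, 3000))
        return GenomicInterval(chrom, start, start + 200, name=dataset,
                               tissue=tissue, class_label=cls)

    enhancers, histones, atacs = [], [], []
    if include_truth and causal_var is not None:
        s0 = max(0, causal_var.pos - 1 - enhancer_halfwidth)
        e0 = causal_var.pos - 1 + enhancer_halfwidth
        for tissue in tissues:
            enhancers.append(GenomicInterval(chrom, s0, e0, name="EpiMAP",
                                             tissue=tissue, class_label="enhancer"))
        histones.append(GenomicInterval(chrom, s0, e0, name="ENCODE",
                                        tissue=tissues[0], class_label="H3K27ac"))
        atacs.append(GenomicInterval(chrom, s0, e0, name="ENCODE",
                                     tissue=tissues[0], class_label="ATAC"))
    for _ in range(n_decoys):
        enhancers.append(_decoy_interval("enhancer", "liver", "EpiMAP"))
        histones.append(_decoy_interval("H3K27ac", "liver", "ENCODE"))
        atacs.append(_decoy_interval("ATAC", "liver", "ENCODE"))
    paths["enhancers"] = os.path.join(out_dir, "enhancers.bed")
    paths["histone"] = os.path.join(out_dir, "histone.bed")
    paths["atac"] = os.path.join(out_dir, "atac.bed")
    write_bed(enhancers, paths["enhancers"])
    write_bed(histones, paths["histone"])
    write_bed(atacs, paths["atac"])

    # ---- enhancer-promoter interactions + TADs ----
    promoter = genes[0].promoter(promoter_len)
    pairs = []
    if include_truth and causal_var is not None:
        left = GenomicInterval(chrom, max(0, causal_var.pos - 1 - enhancer_halfwidth),
                               causal_var.pos - 1 + enhancer_halfwidth)
        right = GenomicInterval(chrom, promoter.start, promoter.end)
        for source in ("3DGenome", "Nott"):
            pairs.append(InteractionPair(anchor1=left, anchor2=right,
                                         assay="HiC", source=source,
                                         celltype="microglia"))
    pairs.append(InteractionPair(
        anchor1=_decoy_interval("", "liver", "x"),
        anchor2=GenomicInterval(chrom, gene_tss0 + 11_000, gene_tss0 + 11_500),
        assay="HiC", source="4DGenome", celltype="liver"))
    paths["epi"] = os.path.join(out_dir, "epi.bedpe")
    write_bedpe(pairs, paths["epi"])

    tads = []
    if include_truth and causal_var is not None:
        tads.append(GenomicInterval(chrom, max(0, causal_var.pos - 2000),
                                    gene_tss0 + 3000, name="3DGenome",
                                    tissue="brain", class_label="TAD"))
    tads.append(GenomicInterval(chrom, gene_tss0 + 8000, gene_tss0 + 11_900,
                                name="3DGenome", tissue="liver", class_label="TAD"))
    paths["tads"] = os.path.join(out_dir, "tads.bed")
    write_bed(tads, paths["tads"])

    # ---- motifs ----
    motifs = []
    if include_truth and causal_var is not None:
        tm = _truth_motif(causal_var.ref, causal_var.alt)
        motifs.append(tm)
        hit = best_allele_scores(tm, genome, causal_var)
        if hit is None or abs(hit.delta) <= 2.0:
            logger.warning("truth motif delta %s not above threshold",
                           None if hit is None else hit.delta)
    for k in range(n_decoys):
        motifs.append(_decoy_motif(rng, f"DECOY_{k}"))
    paths["motifs"] = os.path.join(out_dir, "motifs.txt")
    write_motifs(motifs, paths["motifs"])

    # ---- external validation eQTLs (non-GTEx sources, truth-consistent sign)
    ext = []
    if include_truth and causal_var is not None and truth.eqtl_causal_index is not None:
        gtex = next(iter(scenario.eqtls.values()))
        truth_z = next(r.z for r in gtex
                       if r.variant.vid == causal_var.vid)
        for source, tissue in (("MetaBrain", "frontal_cortex"),
                               ("MetaBrain", "basal_ganglia"),
                               ("eQTLCatalogue", "limbic_system"),
                               ("eQTLCatalogue", "brain_stem")):
            z = truth_z * float(rng.uniform(0.7, 1.1))
            # half the records are deliberately REF-oriented; harmonization
            # must recover the common direction
            flip = bool(rng.integers(2))
            ext.append(AssocRecord(
                variant=causal_var,
                effect_allele=causal_var.ref if flip else causal_var.alt,
                beta=(-z if flip else z) * 0.01, se=0.01,
                pvalue=max(math.erfc(abs(z) / math.sqrt(2)), 5e-324),
                gene_id=target, tissue=tissue, source=source))
    paths["validation_eqtls"] = os.path.join(out_dir, "validation_eqtls.tsv")
    if ext:
        write_summary_stats(ext, paths["validation_eqtls"])
    else:
        pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "effect_allele",
                              "beta", "se", "pvalue", "gene_id", "tissue",
                              "source", "rsid"]).to_csv(
            paths["validation_eqtls"], sep="\t", index=False)

    # ---- evidence tables ----
    ev_rows = []
    if include_truth and causal_var is not None:
        ev_rows.append(dict(vid=causal_var.vid, cadd=15.0, regdb="1b",
                            histone_q=0.01, atac=1, other_gwas=1))
    paths["variant_evidence"] = os.path.join(out_dir, "variant_evidence.tsv")
    pd.DataFrame(ev_rows, columns=["vid", "cadd", "regdb", "histone_q",
                                   "atac", "other_gwas"]).to_csv(
        paths["variant_evidence"], sep="\t", index=False)
    ge_rows = []
    if include_truth and truth.target_gene:
        ge_rows.append(dict(gene_id=target, nominated=1, brain_expressed=1))
    paths["gene_evidence"] = os.path.join(out_dir, "gene_evidence.tsv")
    pd.DataFrame(ge_rows, columns=["gene_id", "nominated", "brain_expressed"]).to_csv(
        paths["gene_evidence"], sep="\t", index=False)

    # ---- tissue map + brain-region groups ----
    tissue_map = {t: [t] for t in tissues}
    paths["tissue_map"] = os.path.join(out_dir, "tissue_map.yaml")
    with open(paths["tissue_map"], "w") as fh:
        yaml.safe_dump(tissue_map, fh)
    groups = {"frontal_cortex": "Frontal Cortex", "limbic_system": "Limbic System",
              "basal_ganglia": "Basal Ganglia", "brain_stem": "Brain Stem"}
    groups.update({t: "Frontal Cortex" for t in tissues})
    paths["groups"] = os.path.join(out_dir, "groups.yaml")
    with open(paths["groups"], "w") as fh:
        yaml.safe_dump(groups, fh)

    return paths
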