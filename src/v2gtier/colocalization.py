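"""Bayesian colocalization of two association signals from summary statistics.

Given per-SNP effect estimates (beta, se) for two traits measured over the
same locus, each SNP's evidence for association is summarized by a Wakefield
approximate Bayes factor (ABF) under a normal prior N(0, W) on the true
effect:

    log ABF = 1/2 log(V / (V + W)) + 1/2 z^2 W / (V + W),   V = se^2.

Assuming at most one causal variant per trait, the posterior over five
hypotheses is obtained by enumerating causal configurations:

    H0  neither trait associated
    H1  trait 1 only             H2  trait 2 only
    H3  both, different causal variants
    H4  both, the same causal variant

With per-SNP log-ABF vectors a, b and S1 = Σ exp(a), S2 = Σ exp(b),
S12 = Σ exp(a+b), the unnormalized hypothesis weights are 1, p1·S1, p2·S2,
p1·p2·(S1·S2 − S12) and p12·S12, where p1/p2/p12 are per-SNP prior
probabilities of causality.  All sums run in log space (log-sum-exp); the
H3 difference uses log1p to avoid catastrophic cancellation.  Given H4, the
per-SNP posterior of being the shared causal variant is the softmax of a+b.

A variant–gene (V2G) pair is called when PP(H4) > 0.7, the best per-SNP
posterior exceeds 0.5, and the locus holds more than one variant; the
locus-level false-discovery rate is 1 − PP(H4).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .core_types_io import AssocRecord, Variant

logger = logging.getLogger("v2gtier")

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior causal probabilities and the ABF prior effect variance."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    W: float = 0.15 ** 2   # quantitative-trait prior effect variance

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.W <= 0:
            raise ValueError("prior effect variance W must be positive")


@dataclass(frozen=True)
class ColocResult:
    """Posteriors over H0–H4 for one locus plus per-SNP H4 posteriors."""

    locus_id: str
    n_snps: int
    pp: Dict[str, float]
    snp_pp_h4: Dict[str, float]     # vid -> posterior given H4
    priors: ColocPriors

    @property
    def fdr(self) -> float:
        """1 − PP(H4): probability the two traits do not share a causal SNP."""
        return 1.0 - self.pp["H4"]


@dataclass(frozen=True)
class V2GPair:
    """A called (variant, gene, tissue) claim with its colocalization evidence."""

    variant: Variant
    gene_id: str
    tissue: str
    source: str
    pp_h4: float
    snp_pp_h4: float
    z_eqtl: float
    locus_id: str = ""


def log_abf(record: AssocRecord, W: float) -> float:
    """Wakefield log approximate Bayes factor for one association record."""
    if W <= 0:
        raise ValueError("W must be positive")
    V = record.se ** 2
    shrink = W / (V + W)
    return 0.5 * math.log(V / (V + W)) + 0.5 * record.z ** 2 * shrink


def _log_abf_vector(records: Sequence[AssocRecord], W: float) -> np.ndarray:
    return np.array([log_abf(r, W) for r in records])


def coloc_posteriors(trait1_records: Sequence[AssocRecord],
                     trait2_records: Sequence[AssocRecord],
                     priors: Optional[ColocPriors] = None,
                     locus_id: str = "") -> ColocResult:
    """Enumerate single-causal configurations and return hypothesis posteriors.

    Records are intersected on variant id; both traits must already be
    harmonized to the same (ALT) effect allele.  Only |z| enters the ABF, so
    orientation does not change posteriors, but harmonized input keeps the
    per-SNP bookkeeping coherent with the directionality stages downstream.
    """
    priors = priors or ColocPriors()
    by_vid1 = {r.variant.vid: r for r in trait1_records}
    by_vid2 = {r.variant.vid: r for r in trait2_records}
    shared = sorted(set(by_vid1) & set(by_vid2),
                    key=lambda v: (by_vid1[v].variant.chrom, by_vid1[v].variant.pos, v))
    if not shared:
        raise ValueError("no shared variants between the two traits at this locus")
    a = _log_abf_vector([by_vid1[v] for v in shared], priors.W)
    b = _log_abf_vector([by_vid2[v] for v in shared], priors.W)

    log_s1 = logsumexp(a)
    log_s2 = logsumexp(b)
    log_s12 = logsumexp(a + b)

    log_w = np.empty(5)
    log_w[0] = 0.0
    log_w[1] = math.log(priors.p1) + log_s1
    log_w[2] = math.log(priors.p2) + log_s2
    # H3 weight is p1*p2*(S1*S2 - S12) = p1*p2*sum_{i != j} a_i*b_j.  The
    # subtraction form cancels catastrophically when one SNP dominates both
    # traits (S12 -> S1*S2), so sum the off-diagonal pair terms exactly for
    # loci of ordinary size; fall back to log1p for very large loci.
    n = len(shared)
    if n == 1:
        log_w[3] = -np.inf
    elif n <= 4000:
        pair_terms = a[:, None] + b[None, :]
        off_diag = ~np.eye(n, dtype=bool)
        log_w[3] = (math.log(priors.p1) + math.log(priors.p2)
                    + logsumexp(pair_terms[off_diag]))
    else:
        diff = log_s12 - log_s1 - log_s2
        if diff >= 0:
            logger.warning("H3 weight negative from floating point; clamped to 0")
            log_w[3] = -np.inf
        else:
            log_w[3] = (math.log(priors.p1) + math.log(priors.p2)
                        + log_s1 + log_s2 + math.log1p(-math.exp(diff)))
    log_w[4] = math.log(priors.p12) + log_s12

    log_total = logsumexp(log_w)
    pp = {h: float(math.exp(lw - log_total)) for h, lw in zip(HYPOTHESES, log_w)}

    snp_log = a + b - log_s12
    snp_pp = {vid: float(math.exp(lp)) for vid, lp in zip(shared, snp_log)}
    return ColocResult(locus_id=locus_id, n_snps=len(shared), pp=pp,
                       snp_pp_h4=snp_pp, priors=priors)


def coloc_fdr(result: ColocResult) -> float:
    """Locus-level FDR: P(H0)+P(H1)+P(H2)+P(H3) = 1 − P(H4)."""
    return result.fdr


def call_v2g(result: ColocResult, eqtl_records: Sequence[AssocRecord],
             pp_h4_min: float = 0.7, snp_pp_min: float = 0.5) -> Optional[V2GPair]:
    """Call a V2G pair when PP(H4), the best SNP posterior, and locus size all pass.

    All thresholds are strict (>).  The pair's variant is the argmax of the
    per-SNP H4 posterior; its eQTL Z-score is carried for directionality work.
    """
    if result.n_snps <= 1:
        return None
    if not result.pp["H4"] > pp_h4_min:
        return None
    best_vid = max(result.snp_pp_h4, key=lambda v: (result.snp_pp_h4[v], v))
    best_pp = result.snp_pp_h4[best_vid]
    if not best_pp > snp_pp_min:
        return None
    rec = next((r for r in eqtl_records if r.variant.vid == best_vid), None)
    if rec is None:
        logger.warning("called variant %s missing from eQTL records", best_vid)
        return None
    return V2GPair(variant=rec.variant, gene_id=rec.gene_id or "",
                   tissue=rec.tissue or "", source=rec.source or "",
                   pp_h4=result.pp["H4"], snp_pp_h4=best_pp,
                   z_eqtl=rec.z, locus_id=result.locus_id)


def filter_nominal_eqtl_genes(eqtl_records: Sequence[AssocRecord],
                              alpha: float = 0.05) -> dict:
    """Group eQTL records by (gene, tissue, source), keeping nominally
    significant genes: those whose best SNP has p < alpha."""
    groups: dict = {}
    for r in eqtl_records:
        groups.setdefault(r.trait_key, []).append(r)
    return {k: v for k, v in groups.items() if min(r.pvalue for r in v) < alpha}
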