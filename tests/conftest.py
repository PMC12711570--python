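"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from typing import List, Optional, Sequence

import numpy as np
import pytest

from v2gtier import AssocRecord, ColocPriors, HaplotypePanel, Variant


def make_panel(matrix, positions: Optional[Sequence[int]] = None,
               alleles=None, chrom: str = "chr1") -> HaplotypePanel:
    """Build a HaplotypePanel straight from a 0/1 matrix (rows = haplotypes)."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    n_var = matrix.shape[1]
    if positions is None:
        positions = [1000 * (j + 1) for j in range(n_var)]
    if alleles is None:
        alleles = [("A", "G")] * n_var
    return HaplotypePanel(chrom=chrom, positions=np.asarray(positions),
                          alleles=list(alleles), matrix=matrix)


def make_record(pos: int, beta: float, se: float, pvalue: Optional[float] = None,
                chrom: str = "chr1", ref: str = "A", alt: str = "G",
                effect_allele: Optional[str] = None, gene_id=None,
                tissue=None, source=None) -> AssocRecord:
    z = beta / se
    if pvalue is None:
        pvalue = max(math.erfc(abs(z) / math.sqrt(2.0)), 5e-324)
    return AssocRecord(variant=Variant(chrom, pos, ref, alt),
                       effect_allele=effect_allele or alt, beta=beta, se=se,
                       pvalue=pvalue, gene_id=gene_id, tissue=tissue,
                       source=source)


def enumerate_coloc_oracle(records1: Sequence[AssocRecord],
                           records2: Sequence[AssocRecord],
                           priors: ColocPriors) -> dict:
    """Brute-force posterior oracle: explicit enumeration of every
    single-causal configuration (null; causal-for-1 at each SNP;
    causal-for-2 at each SNP; one causal per trait for every ordered SNP
    pair, split into shared i == j and distinct i != j).

    Plain-float arithmetic, no log-sum-exp, no shared code with the
    implementation under test.
    """
    def abf(r):
        V = r.se ** 2
        z = r.beta / r.se
        return math.sqrt(V / (V + priors.W)) * math.exp(0.5 * z * z * priors.W / (V + priors.W))

    by_vid1 = {r.variant.vid: r for r in records1}
    by_vid2 = {r.variant.vid: r for r in records2}
    vids = sorted(set(by_vid1) & set(by_vid2))
    a = [abf(by_vid1[v]) for v in vids]
    b = [abf(by_vid2[v]) for v in vids]
    n = len(vids)

    w_h0 = 1.0
    w_h1 = sum(priors.p1 * a[i] for i in range(n))
    w_h2 = sum(priors.p2 * b[j] for j in range(n))
    w_h3 = sum(priors.p1 * priors.p2 * a[i] * b[j]
               for i in range(n) for j in range(n) if i != j)
    w_h4 = sum(priors.p12 * a[i] * b[i] for i in range(n))
    total = w_h0 + w_h1 + w_h2 + w_h3 + w_h4
    pp = {"H0": w_h0 / total, "H1": w_h1 / total, "H2": w_h2 / total,
          "H3": w_h3 / total, "H4": w_h4 / total}
    s12 = sum(a[i] * b[i] for i in range(n))
    snp = {vids[i]: a[i] * b[i] / s12 for i in range(n)}
    return {"pp": pp, "snp_pp_h4": snp}


@pytest.fixture
def two_template_panel() -> HaplotypePanel:
    """Deterministic panel: 8 haplotypes copying 2 complementary templates."""
    t0 = np.array([0, 1, 0, 1, 1, 0])
    t1 = 1 - t0
    rows = [t0] * 4 + [t1] * 4
    return make_panel(np.vstack(rows))
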