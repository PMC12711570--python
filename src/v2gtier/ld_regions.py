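"""Linkage-disequilibrium statistics, tag-variant pruning, and region expansion.

Pruning reduces the genome-wide significant variant set to pairwise
"independent" tags: walking variants in ascending p-value order, a variant
becomes a tag only if its r² to every already-accepted tag within the window
stays below the pruning threshold (defaults r² < 0.7 within ±500 kb — a
standard clumping setup).  Each tag is then expanded into an analysis region
holding every panel variant in strong LD with it (r² ≥ 0.7, within 1 Mb and
within 1000 variants by rank), with region bounds set by the outermost
proxies; *all* panel variants inside the bounds — associated or not — form
the colocalization input for the region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, List, Sequence, Tuple

import numpy as np

from .core_types_io import AssocRecord, ParameterError, Variant

if TYPE_CHECKING:  # panel type lives with the generator; only duck-typed here
    from .synthetic_data import HaplotypePanel

logger = logging.getLogger("v2gtier")

DEFAULT_P_THRESH = 5e-8
DEFAULT_PRUNE_R2 = 0.7
DEFAULT_WINDOW_BP = 500_000
DEFAULT_EXPAND_R2 = 0.7
DEFAULT_MAX_BP = 1_000_000
DEFAULT_MAX_RANK_DIST = 1000


@dataclass(frozen=True)
class LDRegion:
    """A tag variant with its proxy set and the region they span."""

    tag: Variant
    proxies: Tuple[Variant, ...]           # includes the tag
    bounds: Tuple[str, int, int]           # (chrom, min_pos, max_pos), 1-based
    all_region_variants: Tuple[Variant, ...]


def _haplotype_stats(panel: "HaplotypePanel", i: int, j: int):
    a = panel.matrix[:, i].astype(float)
    b = panel.matrix[:, j].astype(float)
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ParameterError(f"r^2 undefined for monomorphic column ({i}, {j})")
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    return d, denom


def compute_r2(panel: "HaplotypePanel", i: int, j: int) -> float:
    """r² = D² / (pA(1−pA) pB(1−pB)) from haplotype counts; symmetric in i, j."""
    d, denom = _haplotype_stats(panel, i, j)
    return float(d * d / denom)


def signed_r(panel: "HaplotypePanel", i: int, j: int) -> float:
    """Signed allelic correlation D / sqrt(pA(1−pA) pB(1−pB)) ∈ [−1, 1]."""
    d, denom = _haplotype_stats(panel, i, j)
    return float(d / math.sqrt(denom))


def prune_variants(gwas: Sequence[AssocRecord], panel: "HaplotypePanel",
                   p_thresh: float = DEFAULT_P_THRESH,
                   prune_r2: float = DEFAULT_PRUNE_R2,
                   window_bp: int = DEFAULT_WINDOW_BP) -> List[Variant]:
    """Greedy LD clumping of significant variants into tags (see module docstring).

    Significant variants absent from the panel carry no LD information and
    are excluded (logged).  Output order is acceptance order; ties in
    p-value break by (chrom, pos).
    """
    candidates = []
    n_missing = 0
    for rec in gwas:
        if rec.pvalue >= p_thresh:
            continue
        idx = panel.index_of(rec.variant)
        if idx is None:
            n_missing += 1
            logger.warning("significant variant %s absent from panel; excluded",
                           rec.variant.vid)
            continue
        candidates.append((rec.pvalue, rec.variant.chrom, rec.variant.pos, rec.variant, idx))
    if n_missing:
        logger.info("pruning: %d significant variants had no panel match", n_missing)
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    tags: List[Tuple[Variant, int]] = []
    for _, _, _, variant, idx in candidates:
        independent = True
        for tag_var, tag_idx in tags:
            if tag_var.chrom != variant.chrom:
                continue
            if abs(tag_var.pos - variant.pos) > window_bp:
                continue
            if compute_r2(panel, idx, tag_idx) >= prune_r2:
                independent = False
                break
        if independent:
            tags.append((variant, idx))
    return [v for v, _ in tags]


def expand_region(tag: Variant, panel: "HaplotypePanel",
                  expand_r2: float = DEFAULT_EXPAND_R2,
                  max_bp: int = DEFAULT_MAX_BP,
                  max_rank_dist: int = DEFAULT_MAX_RANK_DIST) -> LDRegion:
    """Expand a tag into its proxy set and analysis region.

    Proxies satisfy r²(tag, v) ≥ ``expand_r2``, |pos(v) − pos(tag)| ≤
    ``max_bp`` and a position-rank distance among the chromosome's panel
    variants of at most ``max_rank_dist``.  Region bounds span the outermost
    proxies; ``all_region_variants`` is every panel variant inside.
    """
    tag_idx = panel.index_of(tag)
    if tag_idx is None:
        raise ParameterError(f"tag {tag.vid} not present in panel")
    proxy_idx = [tag_idx]
    for j in range(panel.n_var):
        if j == tag_idx:
            continue
        if abs(int(panel.positions[j]) - tag.pos) > max_bp:
            continue
        if abs(j - tag_idx) > max_rank_dist:
            continue
        if compute_r2(panel, tag_idx, j) >= expand_r2:
            proxy_idx.append(j)
    proxy_idx.sort()
    proxies = tuple(panel.variant(j) for j in proxy_idx)
    min_pos = min(v.pos for v in proxies)
    max_pos = max(v.pos for v in proxies)
    inside = np.nonzero((panel.positions >= min_pos) & (panel.positions <= max_pos))[0]
    return LDRegion(tag=tag, proxies=proxies,
                    bounds=(tag.chrom, min_pos, max_pos),
                    all_region_variants=tuple(panel.variant(int(j)) for j in inside))
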