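"""Position weight matrix scoring of reference vs alternative alleles.

A PWM holds per-position base probabilities for a transcription factor's
binding preference.  A window of sequence is scored as the sum of per-base
log2 odds against a background distribution (uniform by default).  For a
variant, every placement of the motif that covers the variant position is
scored on both strands for each allele; the per-allele score is the maximum
over placements, and the delta score (ref − alt, on the log2-odds scale)
measures the predicted change in binding.  A variant "disrupts" a TFBS when
``|delta| > threshold`` (default 2) for any motif — gain of binding counts
the same as loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core_types_io import Variant, reverse_complement

logger = logging.getLogger("v2gtier")

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: strict threshold on |delta| for calling a disruption
DEFAULT_DELTA_THRESHOLD = 2.0


@dataclass(frozen=True)
class PWM:
    """A positional weight matrix of base probabilities (columns A, C, G, T)."""

    motif_id: str
    tf_name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    probability_floor: float = 0.001

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be L x 4")
        if np.any(m < 0):
            raise ValueError(f"{self.motif_id}: negative probabilities")
        # smooth: floor every entry, renormalize rows
        m = np.maximum(m, self.probability_floor)
        m = m / m.sum(axis=1, keepdims=True)
        object.__setattr__(self, "matrix", m)
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6:
            raise ValueError(f"{self.motif_id}: background must be 4 probabilities summing to 1")
        object.__setattr__(self, "background", bg)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=1))


@dataclass(frozen=True)
class MotifHit:
    """Best ref/alt scores of one motif around one variant."""

    motif_id: str
    ref_score: float
    alt_score: float
    strand: str            # strand of the best-scoring ref placement
    offset: int            # variant index within the motif for that placement
    disrupted: bool = False

    @property
    def delta(self) -> float:
        return self.ref_score - self.alt_score


def pwm_score(pwm: PWM, window: str) -> float:
    """Log2-odds score of ``window`` (length = motif length) against background.

    Raises ValueError on length mismatch; a window containing an ambiguous
    base has no defined score (callers skip such windows).
    """
    window = window.upper()
    if len(window) != len(pwm):
        raise ValueError(f"window length {len(window)} != motif length {len(pwm)}")
    score = 0.0
    for i, base in enumerate(window):
        j = BASE_INDEX.get(base)
        if j is None:
            raise ValueError(f"ambiguous base {base!r} in window")
        score += np.log2(pwm.matrix[i, j] / pwm.background[j])
    return float(score)


def _best_score(pwm: PWM, context: str, var_index: int):
    """Max log2-odds over all placements covering ``var_index`` on both strands.

    Returns (score, strand, offset) or (None, None, None) when no placement
    is scoreable (contig edge or ambiguous bases everywhere).
    """
    L = len(pwm)
    best = None
    for offset in range(L):
        start = var_index - offset
        if start < 0 or start + L > len(context):
            continue
        window = context[start:start + L]
        if any(b not in BASE_INDEX for b in window):
            logger.warning("%s: window with ambiguous base skipped", pwm.motif_id)
            continue
        fwd = pwm_score(pwm, window)
        rev = pwm_score(pwm, reverse_complement(window))
        if best is None or fwd > best[0]:
            best = (fwd, "+", offset)
        if rev > best[0]:
            best = (rev, "-", L - 1 - offset)
    return best if best is not None else (None, None, None)


def best_allele_scores(pwm: PWM, genome: Mapping[str, str],
                       variant: Variant) -> Optional[MotifHit]:
    """Score both alleles of ``variant`` with ``pwm``; None if unscoreable."""
    L = len(pwm)
    seq = genome.get(variant.chrom)
    if seq is None:
        logger.warning("%s: chromosome %s not in genome", pwm.motif_id, variant.chrom)
        return None
    lo = variant.pos - 1 - (L - 1)          # 0-based context start
    hi = variant.pos - 1 + L                # exclusive context end
    if lo < 0 or hi > len(seq):
        logger.warning("variant %s too close to contig edge for %s (L=%d)",
                       variant.vid, pwm.motif_id, L)
        return None
    context = seq[lo:hi].upper()
    var_index = variant.pos - 1 - lo
    if context[var_index] != variant.ref:
        logger.warning("reference mismatch at %s: genome has %s",
                       variant.vid, context[var_index])
    ref_ctx = context[:var_index] + variant.ref + context[var_index + 1:]
    alt_ctx = context[:var_index] + variant.alt + context[var_index + 1:]
    ref_score, strand, offset = _best_score(pwm, ref_ctx, var_index)
    alt_score, _, _ = _best_score(pwm, alt_ctx, var_index)
    if ref_score is None or alt_score is None:
        return None
    return MotifHit(motif_id=pwm.motif_id, ref_score=ref_score,
                    alt_score=alt_score, strand=strand, offset=offset)


def call_disruption(hits: Sequence[MotifHit],
                    threshold: float = DEFAULT_DELTA_THRESHOLD) -> list:
    """Keep hits with ``|delta| > threshold`` (strict); flag them disrupted."""
    disrupted = []
    for h in hits:
        if abs(h.delta) > threshold:
            disrupted.append(MotifHit(motif_id=h.motif_id, ref_score=h.ref_score,
                                      alt_score=h.alt_score, strand=h.strand,
                                      offset=h.offset, disrupted=True))
    return disrupted


def scan_variant(variant: Variant, motifs: Sequence[PWM],
                 genome: Mapping[str, str],
                 threshold: float = DEFAULT_DELTA_THRESHOLD) -> list:
    """All disrupted motif hits for a variant; empty list = TFBS-negative."""
    hits = []
    for pwm in motifs:
        hit = best_allele_scores(pwm, genome, variant)
        if hit is not None:
            hits.append(hit)
    return call_disruption(hits, threshold=threshold)
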