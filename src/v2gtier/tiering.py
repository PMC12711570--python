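"""Additive evidence tiers for validated variant–gene pairs, and ranking.

Four components are summed:

* ``v2g_eqtl`` (1–4): one point each for (1) consistent directionality
  across external (non-discovery) eQTL sources, (2) presence of any
  external brain eQTL for the pair, (3) agreement between external and
  discovery-panel eQTLs (replication with the same harmonized sign), and
  (4) a negative, consistent Z-score across brain regions; the component is
  floored at 1 — a colocalized pair starts with one point.
* ``v2g_epi`` (0–2): one point per interaction data source supporting the
  pair, capped at 2.
* ``v`` (0–4): the variant evidence profile count (histone, ATAC,
  CADD/RegulomeDB effect prediction, independent GWAS).
* ``g`` (0–2): the gene evidence count (nominated, brain-expressed).

The arithmetic maximum of the sum is 12; totals above 11 are surfaced with
a warning since the component definitions make the joint maximum
practically unreachable on real resources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Set, Tuple

from .colocalization import V2GPair
from .insilico_validation import (
    ConsistencyVerdict,
    EvidenceProfile,
    GeneEvidence,
)

logger = logging.getLogger("v2gtier")


@dataclass(frozen=True)
class TierScore:
    v2g_eqtl: int
    v2g_epi: int
    v: int
    g: int

    def __post_init__(self) -> None:
        if not (1 <= self.v2g_eqtl <= 4):
            raise ValueError(f"v2g_eqtl tier {self.v2g_eqtl} outside 1..4")
        if not (0 <= self.v2g_epi <= 2):
            raise ValueError(f"v2g_epi tier {self.v2g_epi} outside 0..2")
        if not (0 <= self.v <= 4):
            raise ValueError(f"v tier {self.v} outside 0..4")
        if not (0 <= self.g <= 2):
            raise ValueError(f"g tier {self.g} outside 0..2")

    @property
    def overall(self) -> int:
        return self.v2g_eqtl + self.v2g_epi + self.v + self.g


def compute_tiers(pair: V2GPair,
                  consistency: Optional[ConsistencyVerdict],
                  replication_sources: Set[str],
                  epi_sources: Sequence[str],
                  evidence: EvidenceProfile,
                  gene_evidence: GeneEvidence,
                  reference_z: Optional[float] = None,
                  epi_cap: int = 2) -> TierScore:
    """Score one pair from its upstream evidence (see module docstring).

    A missing evidence block contributes nothing to its component (logged),
    so partial evidence degrades the tier rather than failing.
    """
    f_consistent = (consistency is not None and consistency.n_groups > 0
                    and not consistency.inconsistent)
    f_presence = consistency is not None and consistency.n_groups > 0
    f_agree = bool(replication_sources)
    f_neg_z = (f_consistent and reference_z is not None and reference_z < 0)
    if consistency is None:
        logger.info("tiering %s/%s: no consistency verdict", pair.variant.vid, pair.gene_id)
    v2g_eqtl = max(1, int(f_consistent) + int(f_presence) + int(f_agree) + int(f_neg_z))

    v2g_epi = min(epi_cap, len(set(epi_sources)))
    score = TierScore(v2g_eqtl=v2g_eqtl, v2g_epi=v2g_epi,
                      v=evidence.count, g=gene_evidence.count)
    if score.overall > 11:
        logger.warning("pair %s/%s reaches overall tier %d (>11)",
                       pair.variant.vid, pair.gene_id, score.overall)
    return score


def rank_pairs(scored_pairs: Sequence[Tuple[V2GPair, TierScore]]
               ) -> List[Tuple[V2GPair, TierScore]]:
    """Descending overall tier; ties by descending PP(H4), then variant id."""
    return sorted(scored_pairs,
                  key=lambda pt: (-pt[1].overall, -pt[0].pp_h4,
                                  pt[0].variant.vid, pt[0].gene_id))
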