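"""Confluent-context filtering of colocalized variant–gene pairs.

A colocalized pair survives only when independent regulatory evidence
converges on the variant in a matching biological context: the variant must
(1) carry a colocalization call, (2) disrupt at least one transcription
factor binding site, (3) fall inside at least one enhancer interval, and
(4) have an enhancer whose tissue label maps to the pair's eQTL tissue
under an explicit tissue map.  A pair failing any criterion is excluded,
with the reason recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

from intervaltree import IntervalTree

from .colocalization import V2GPair
from .core_types_io import GenomicInterval, Variant

logger = logging.getLogger("v2gtier")


@dataclass(frozen=True)
class ConfluentPair:
    """A retained pair with its full evidence trail."""

    pair: V2GPair
    enhancer_hits: Tuple[Tuple[str, str, GenomicInterval], ...]  # (dataset, tissue, iv)
    tfbs_hits: Tuple[str, ...]                                   # motif ids
    context_matched: bool = True


class EnhancerIndex:
    """Interval-tree lookup of labelled enhancer tracks."""

    def __init__(self, tracks: Sequence[GenomicInterval]):
        self._trees: Dict[str, IntervalTree] = {}
        for iv in tracks:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def hits(self, variant: Variant) -> List[Tuple[str, str, GenomicInterval]]:
        tree = self._trees.get(variant.chrom)
        if tree is None:
            return []
        found = [h.data for h in tree.overlap(variant.pos - 1, variant.pos)]
        found.sort(key=lambda iv: (iv.name, iv.tissue, iv.start))
        return [(iv.name, iv.tissue, iv) for iv in found]


def overlap_enhancers(variant: Variant,
                      tracks: Sequence[GenomicInterval]) -> List[Tuple[str, str, GenomicInterval]]:
    """All track intervals containing the variant (half-open rule), with labels."""
    return EnhancerIndex(tracks).hits(variant)


def confluent_v2g(pairs: Sequence[V2GPair],
                  tfbs_calls: Mapping[str, Sequence[str]],
                  enhancer_index: EnhancerIndex,
                  tissue_map: Mapping[str, Sequence[str]]) -> List[ConfluentPair]:
    """Apply the four confluence criteria to called pairs.

    ``tfbs_calls`` maps variant id to the motif ids it disrupts;
    ``tissue_map`` maps each eQTL tissue label to the track tissue labels it
    is considered equivalent to (many-to-many).  A pair whose eQTL tissue is
    absent from the map cannot be context-matched and is excluded.
    """
    retained = []
    for pair in pairs:
        vid = pair.variant.vid
        motifs = tuple(tfbs_calls.get(vid, ()))
        if not motifs:
            logger.info("confluence: %s/%s excluded (no TFBS disruption)", vid, pair.gene_id)
            continue
        hits = enhancer_index.hits(pair.variant)
        if not hits:
            logger.info("confluence: %s/%s excluded (no enhancer overlap)", vid, pair.gene_id)
            continue
        allowed = tissue_map.get(pair.tissue)
        if allowed is None:
            logger.info("confluence: %s/%s excluded (tissue %r not in tissue map)",
                        vid, pair.gene_id, pair.tissue)
            continue
        allowed = set(allowed)
        matched = [h for h in hits if h[1] in allowed]
        if not matched:
            logger.info("confluence: %s/%s excluded (enhancer tissues %s do not match %r)",
                        vid, pair.gene_id, sorted({h[1] for h in hits}), pair.tissue)
            continue
        retained.append(ConfluentPair(pair=pair, enhancer_hits=tuple(matched),
                                      tfbs_hits=motifs, context_matched=True))
    return retained
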