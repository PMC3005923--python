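"""Paired-end / mate-pair library QC.

Each read pair with at least one mapped end is placed in exactly one of
seven categories: good pair, unpaired (only end 1 mapped / only end 2
mapped), different chromosome, wrong orientation, separation below the
expected library range, separation above it.  Chimeric categories
(different chromosome, wrong orientation) are genuine candidates for
fusion / inversion events — but a high chimera fraction points at
library preparation problems rather than biology.

Classification uses unique hits only: a non-uniquely mapped end is
treated as unmapped here, since an ambiguous location cannot support a
separation or orientation call.  The signed pair distance is defined as
``start1 - start2`` (so it can be negative) while the range check uses
its absolute value; good-pair distances are histogrammed separately by
the strand of the first end so strand bias is visible.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .formats import AlignmentHit, PairConfig, normalize_read_id

logger = logging.getLogger(__name__)

__all__ = [
    "PairCategory",
    "PairSummary",
    "pair_distance",
    "classify_pair",
    "pair_up",
    "summarize_pairs",
]


class PairCategory(str, Enum):
    GOOD_PAIR = "good_pair"
    UNPAIRED_FORWARD = "unpaired_forward"   # only end 1 mapped
    UNPAIRED_REVERSE = "unpaired_reverse"   # only end 2 mapped
    DIFFERENT_CHROMOSOME = "different_chromosome"
    WRONG_ORIENTATION = "wrong_orientation"
    BELOW_RANGE = "below_range"
    ABOVE_RANGE = "above_range"


def pair_distance(end1: AlignmentHit, end2: AlignmentHit) -> int:
    """Signed separation: start of end 1 minus start of end 2 (bp).

    Defined only when both ends map to the same reference.
    """
    if end1.reference != end2.reference or end1.reference is None:
        raise ValueError("pair_distance requires both ends on the same reference")
    return end1.start - end2.start


def _usable(end: Optional[AlignmentHit]) -> bool:
    """An end supports classification iff mapped and unique."""
    return end is not None and end.reference is not None and end.unique


def classify_pair(end1: Optional[AlignmentHit], end2: Optional[AlignmentHit],
                  cfg: PairConfig, orientation: str = "convergent"
                  ) -> Optional[PairCategory]:
    """Assign one category to a read pair; None if neither end is usable.

    Precedence: unpaired (exactly one usable end) -> different chromosome
    -> wrong orientation -> |distance| outside [min, max] (closed
    interval: the bounds themselves are good) -> good pair.

    ``orientation``: ``"convergent"`` libraries expect the two ends on
    opposite strands; ``"same"`` (some mate-pair protocols) expects them
    on the same strand.
    """
    m1, m2 = _usable(end1), _usable(end2)
    if not m1 and not m2:
        return None
    if m1 != m2:
        return PairCategory.UNPAIRED_FORWARD if m1 else PairCategory.UNPAIRED_REVERSE
    if end1.reference != end2.reference:
        return PairCategory.DIFFERENT_CHROMOSOME
    same_strand = end1.strand == end2.strand
    if orientation == "convergent":
        wrong = same_strand
    elif orientation == "same":
        wrong = not same_strand
    else:
        raise ValueError(f"unknown orientation convention {orientation!r}")
    if wrong:
        return PairCategory.WRONG_ORIENTATION
    d = abs(pair_distance(end1, end2))
    if d < cfg.min_distance:
        return PairCategory.BELOW_RANGE
    if d > cfg.max_distance:
        return PairCategory.ABOVE_RANGE
    return PairCategory.GOOD_PAIR


def pair_up(hits: Iterable[AlignmentHit]
            ) -> dict[str, list[Optional[AlignmentHit]]]:
    """Group hits into [end1-hits..., end2-hits...] slots by fragment id.

    Returns fragment id -> [end1, end2] where each slot is the single
    hit of that end when uniquely mapped, a representative unmapped /
    multiply-mapped hit otherwise, or None when that end never appears.
    """
    ends: dict[str, list[Optional[AlignmentHit]]] = {}
    for h in hits:
        rid = normalize_read_id(h.read_id)
        mate = h.mate if h.mate in (1, 2) else 1
        slot = ends.setdefault(rid, [None, None])
        prev = slot[mate - 1]
        if prev is None or (prev.reference is None and h.reference is not None):
            slot[mate - 1] = h
    return ends


@dataclass
class PairSummary:
    """Category counts plus strand-split signed-distance histograms."""

    counts: dict[PairCategory, int] = field(
        default_factory=lambda: {c: 0 for c in PairCategory})
    both_unmapped: int = 0
    hist_bin: int = 100
    distance_histogram_plus: Counter = field(default_factory=Counter)
    distance_histogram_minus: Counter = field(default_factory=Counter)

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())

    @property
    def chimera_fraction(self) -> float:
        n = self.n_classified
        if n == 0:
            return float("nan")
        chim = (self.counts[PairCategory.DIFFERENT_CHROMOSOME]
                + self.counts[PairCategory.WRONG_ORIENTATION])
        return chim / n


def summarize_pairs(pairs: Iterable[tuple[Optional[AlignmentHit], Optional[AlignmentHit]]],
                    cfg: PairConfig, hist_bin: int = 100,
                    orientation: str = "convergent") -> PairSummary:
    """Classify a stream of (end1, end2) pairs and build distance histograms.

    Good-pair signed distances (start1 - start2) go into per-strand
    histograms keyed by the strand of end 1, binned at ``hist_bin`` bp
    (bin key = floor(distance / hist_bin) * hist_bin).  Pairs with no
    usable end are counted in ``both_unmapped`` and excluded from the
    category counts; the chimera fraction is reported over classified
    pairs.
    """
    summary = PairSummary(hist_bin=hist_bin)
    for end1, end2 in pairs:
        cat = classify_pair(end1, end2, cfg, orientation)
        if cat is None:
            summary.both_unmapped += 1
            continue
        summary.counts[cat] += 1
        if cat is PairCategory.GOOD_PAIR:
            d = pair_distance(end1, end2)
            key = (d // hist_bin) * hist_bin
            if end1.strand == "+":
                summary.distance_histogram_plus[key] += 1
            else:
                summary.distance_histogram_minus[key] += 1
    return summary
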