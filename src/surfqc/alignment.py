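"""Alignment-derived QC statistics.

Genomic hit counts per tile are often the most sensitive indicator of a
surface quality problem: a region whose reads carry subtle composition
or quality defects loses alignments long before the defect is obvious in
the raw-signal maps.  This module tallies mapped reads per tile by
mismatch stratum (0 / 1 / 2 / 3+) and hit level (unique vs multiple),
computes the per-cycle mismatch rate from unique hits, and bins hit
starts along the reference for coverage-style plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .formats import AlignmentHit, LayoutSpec, SurfaceCoordinate, normalize_read_id

logger = logging.getLogger(__name__)

__all__ = [
    "MISMATCH_BUCKETS",
    "HitTally",
    "TallyResult",
    "tally_hits",
    "mismatch_rate_per_cycle",
    "target_hit_histogram",
]

MISMATCH_BUCKETS: tuple = (0, 1, 2, "3+")
HIT_LEVELS = ("unique", "multiple")


def mismatch_bucket(nm: int):
    return nm if nm < 3 else "3+"


@dataclass
class HitTally:
    """Per-tile alignment outcome counts.

    ``counts`` maps (mismatch bucket, hit level) -> reads; ``unmapped``
    counts reads of this tile with no mapped hit; ``nm_unknown`` counts
    mapped reads lacking an NM tag (excluded from the mismatch strata).
    ``spatial_hits`` is an optional gx x gy grid of unique-hit read
    counts at within-tile coordinates.
    """

    tile_id: str
    counts: dict = field(default_factory=lambda: {
        (b, lv): 0 for b in MISMATCH_BUCKETS for lv in HIT_LEVELS})
    unmapped: int = 0
    nm_unknown: int = 0
    spatial_hits: Optional[np.ndarray] = None

    def total(self, unique_only: bool = True) -> int:
        levels = ("unique",) if unique_only else HIT_LEVELS
        return sum(self.counts[(b, lv)] for b in MISMATCH_BUCKETS for lv in levels) + (
            0 if unique_only else self.nm_unknown)


@dataclass
class TallyResult:
    per_tile: dict[str, HitTally]
    unlocatable: int = 0


def tally_hits(hits: Iterable[AlignmentHit],
               coords: Mapping[str, SurfaceCoordinate],
               layout: Optional[LayoutSpec] = None,
               grid_resolution: Optional[tuple[int, int]] = None) -> TallyResult:
    """Collapse alignment hits to one outcome per read and tally per tile.

    ``coords`` maps normalized read ids to surface coordinates (see
    :func:`surfqc.subsets.tile_assignments`).  Each read contributes
    exactly once: its hit set collapses to unique (one mapped hit) or
    multiple, with the mismatch stratum taken from the best (lowest-NM)
    hit.  Reads whose ids cannot be located on the surface land in the
    ``unlocatable`` counter.  When ``layout`` and ``grid_resolution`` are
    given, unique hits are additionally placed on a within-tile grid so
    that hit-count unevenness can be ranked per tile.
    """
    by_read: dict[tuple[str, Optional[int]], list[AlignmentHit]] = {}
    for h in hits:
        by_read.setdefault((normalize_read_id(h.read_id), h.mate), []).append(h)

    per_tile: dict[str, HitTally] = {}
    unlocatable = 0
    gx = gy = None
    if grid_resolution is not None:
        if layout is None:
            raise ValueError("spatial hit grids need a layout")
        gx, gy = grid_resolution

    for (rid, _mate), group in by_read.items():
        coord = coords.get(rid)
        if coord is None:
            unlocatable += 1
            continue
        tally = per_tile.get(coord.tile_id)
        if tally is None:
            tally = per_tile[coord.tile_id] = HitTally(coord.tile_id)
            if gx is not None:
                tally.spatial_hits = np.zeros((gx, gy), dtype=np.int64)
        mapped = [h for h in group if h.reference is not None]
        if not mapped:
            tally.unmapped += 1
            continue
        level = "unique" if len(mapped) == 1 else "multiple"
        nms = [h.mismatches for h in mapped if h.mismatches is not None]
        if not nms:
            tally.nm_unknown += 1
        else:
            tally.counts[(mismatch_bucket(min(nms)), level)] += 1
        if level == "unique" and tally.spatial_hits is not None:
            gi = min(coord.x * gx // layout.tile_x_extent, gx - 1)
            gj = min(coord.y * gy // layout.tile_y_extent, gy - 1)
            tally.spatial_hits[max(gi, 0), max(gj, 0)] += 1

    if layout is not None:
        for tid in layout.tiles:
            if tid not in per_tile:
                t = per_tile[tid] = HitTally(tid)
                if gx is not None:
                    t.spatial_hits = np.zeros((gx, gy), dtype=np.int64)
    return TallyResult(per_tile, unlocatable)


def mismatch_rate_per_cycle(hits: Iterable[AlignmentHit]) -> np.ndarray:
    """Fraction of mismatching reads at each sequencing cycle.

    Only unique mapped hits carrying a mismatch mask enter; the
    denominator at cycle c is the number of such reads covering c, so
    ragged read lengths are handled.  Returns an empty array (logged)
    when no usable hit exists.
    """
    num = np.zeros(0, dtype=np.int64)
    den = np.zeros(0, dtype=np.int64)
    for h in hits:
        if h.reference is None or not h.unique or h.mismatch_mask is None:
            continue
        L = len(h.mismatch_mask)
        if L > len(num):
            num = np.concatenate([num, np.zeros(L - len(num), dtype=np.int64)])
            den = np.concatenate([den, np.zeros(L - len(den), dtype=np.int64)])
        num[:L] += h.mismatch_mask
        den[:L] += 1
    if not den.size or den.max() == 0:
        logger.warning("mismatch_rate_per_cycle: no unique hits with masks")
        return np.zeros(0)
    return num / den


def target_hit_histogram(hits: Iterable[AlignmentHit], bin_size: int,
                         references: Mapping[str, int],
                         unique_only: bool = True) -> dict[str, np.ndarray]:
    """Hit-start counts per ``bin_size``-bp bin along each reference.

    Each mapped read is counted once at the bin of its alignment start
    (no per-base pileup).  ``references`` maps reference name to length,
    typically :attr:`surfqc.formats.SamData.references`.  A hit on a
    reference absent from that mapping is a hard error.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    out = {ref: np.zeros(int(np.ceil(length / bin_size)) or 1, dtype=np.int64)
           for ref, length in references.items()}
    for h in hits:
        if h.reference is None or (unique_only and not h.unique):
            continue
        if h.reference not in out:
            raise KeyError(f"hit on reference {h.reference!r} absent from header")
        out[h.reference][h.start // bin_size] += 1
    return out
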