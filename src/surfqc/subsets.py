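"""QC for user-defined read lists.

Reads supporting a specific biological conclusion (a fusion candidate, a
novel splice junction, a set of differentially expressed genes) should
be scattered over the sequencing surface like any random subset of the
run.  This module maps a user-supplied list of read ids back onto the
surface, renders its per-tile distribution next to the whole-sample
distribution, and adds a chi-square uniformity test of the subset
against the expectation proportional to the full per-tile counts.  The
formal test supplements the primary side-by-side visual comparison; a
small p-value says the subset clusters spatially, which is a warning
sign that the "discovery" tracks an assay artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
from scipy import stats

from .formats import LayoutSpec, ReadRecord, SurfaceCoordinate, normalize_read_id
from .metrics import SampleGrid

logger = logging.getLogger(__name__)

__all__ = [
    "IdList",
    "load_id_list",
    "tile_assignments",
    "SubsetComparison",
    "subset_sample_matrix",
    "subset_uniformity_test",
]


@dataclass
class IdList:
    """A normalized, de-duplicated set of read ids."""

    ids: set[str]
    n_duplicates: int = 0

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __contains__(self, item: str) -> bool:
        return item in self.ids


def load_id_list(path) -> IdList:
    """Load one read id per line; blanks ignored, mate suffixes stripped.

    Duplicates (after normalization) are collapsed and their count
    logged.  A file with no ids at all is a hard error.
    """
    ids: set[str] = set()
    n_dup = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            rid = normalize_read_id(line)
            if rid in ids:
                n_dup += 1
            else:
                ids.add(rid)
    if not ids:
        raise ValueError(f"{path}: id list is empty")
    if n_dup:
        logger.info("%s: collapsed %d duplicate ids", path, n_dup)
    return IdList(ids, n_dup)


def tile_assignments(reads: Iterable[ReadRecord]
                     ) -> dict[str, SurfaceCoordinate]:
    """Map normalized read id -> surface coordinate for a read stream."""
    out: dict[str, SurfaceCoordinate] = {}
    for r in reads:
        if r.coord is not None:
            out[normalize_read_id(r.read_id)] = r.coord
    return out


@dataclass
class SubsetComparison:
    """Per-tile read counts of a subset next to the whole sample."""

    subset: SampleGrid
    full: SampleGrid
    n_matched: int
    n_unmatched: int
    unmatched_examples: list[str]
    statistic: float = float("nan")
    p_value: float = float("nan")


def subset_sample_matrix(ids: Union[IdList, set[str]],
                         assignments: Mapping[str, SurfaceCoordinate],
                         layout: LayoutSpec) -> SubsetComparison:
    """Per-tile counts of the listed reads, paired with the full sample.

    Both grids share the layout and missing-data conventions so they can
    be rendered side by side.  Unmatched ids are counted; zero matches is
    a hard error naming the first five offenders.  The uniformity test
    below is run automatically over tiles with data.
    """
    full_counts: dict[str, int] = {t: 0 for t in layout.tiles}
    subset_counts: dict[str, int] = {t: 0 for t in layout.tiles}
    matched = 0
    for rid, coord in assignments.items():
        if coord.tile_id in full_counts:
            full_counts[coord.tile_id] += 1
            if rid in ids:
                matched += 1
                subset_counts[coord.tile_id] += 1
    unmatched = [rid for rid in ids if rid not in assignments]
    if matched == 0:
        raise ValueError(
            "no listed id matches the sample; first unmatched ids: "
            + ", ".join(sorted(unmatched)[:5]))

    def grid(counts: dict[str, int], name: str) -> SampleGrid:
        values = np.full((layout.n_rows, layout.n_cols), np.nan)
        for tid, (r, c) in layout.tiles.items():
            values[r, c] = counts[tid]
        return SampleGrid(layout, values, name)

    cmp = SubsetComparison(
        subset=grid(subset_counts, "subset-read-count"),
        full=grid(full_counts, "read-count"),
        n_matched=matched,
        n_unmatched=len(unmatched),
        unmatched_examples=sorted(unmatched)[:5],
    )
    tids = [t for t in layout.tiles if full_counts[t] > 0]
    sub = np.array([subset_counts[t] for t in tids], dtype=float)
    ful = np.array([full_counts[t] for t in tids], dtype=float)
    cmp.statistic, cmp.p_value = subset_uniformity_test(sub, ful)
    return cmp


def subset_uniformity_test(subset_counts: np.ndarray,
                           full_counts: np.ndarray,
                           min_expected: float = 5.0
                           ) -> tuple[float, float]:
    """Chi-square test of a subset against proportionality to the sample.

    Expected subset count in tile i is ``n_subset * full_i / n_full``.
    Tiles with expected count below ``min_expected`` are pooled (smallest
    expectations first) so the chi-square approximation holds; fewer than
    two bins after pooling leaves the test undefined (NaN, logged).
    Returns (statistic, p_value).
    """
    sub = np.asarray(subset_counts, dtype=float)
    ful = np.asarray(full_counts, dtype=float)
    if sub.shape != ful.shape:
        raise ValueError("subset and full count vectors differ in shape")
    keep = ful > 0
    sub, ful = sub[keep], ful[keep]
    n_sub, n_ful = sub.sum(), ful.sum()
    if n_sub == 0 or n_ful == 0:
        logger.warning("subset_uniformity_test undefined: empty counts")
        return float("nan"), float("nan")
    expected = n_sub * ful / n_ful

    order = np.argsort(expected)
    obs_bins: list[float] = []
    exp_bins: list[float] = []
    acc_o = acc_e = 0.0
    for i in order:
        acc_o += sub[i]
        acc_e += expected[i]
        if acc_e >= min_expected:
            obs_bins.append(acc_o)
            exp_bins.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if exp_bins:
            obs_bins[-1] += acc_o
            exp_bins[-1] += acc_e
        else:
            obs_bins, exp_bins = [acc_o], [acc_e]
    if len(exp_bins) < 2:
        logger.warning("subset_uniformity_test undefined: <2 bins after pooling")
        return float("nan"), float("nan")
    o = np.array(obs_bins)
    e = np.array(exp_bins)
    statistic = float(((o - e) ** 2 / e).sum())
    p = float(stats.chi2.sf(statistic, len(e) - 1))
    return statistic, p
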