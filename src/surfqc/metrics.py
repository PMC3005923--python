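"""Surface-space and cycle-space composition / quality statistics.

A run is summarized at three spatial levels:

* within-tile, on a fixed ``gx x gy`` grid of cells (spatial composition
  maps, read density, mean quality);
* across tiles at identical within-tile coordinates (the *stacked x-y
  summary*, which amplifies weak artifacts repeated on every tile, such
  as donut-shaped or striped imaging defects);
* across the whole sample, one value per tile laid out in the physical
  chip/slide arrangement (:class:`SampleGrid` heat maps).

Composition fractions are always over *called* symbols: 'N' (basespace)
and '.' (colorspace) count toward read totals but never toward
denominators.  All pooling is count-weighted — counts are summed first
and divided once — so aggregates are exact, not means of means.

Spatial uniformity of counts within a tile is quantified by the
*unevenness score*: the Pearson chi-square statistic of the grid-cell
counts against a uniform expectation, divided by its degrees of freedom
(cells - 1).  The score is 0 for perfectly even counts and has
expectation ~1 under random scatter, so tiles of equal grid size are
directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np

from .formats import LayoutSpec, ReadRecord

logger = logging.getLogger(__name__)

__all__ = [
    "BASE_ALPHABET",
    "COLOR_ALPHABET",
    "TileMetrics",
    "SampleGrid",
    "accumulate_tile",
    "merge_tile_metrics",
    "spatial_composition_map",
    "cycle_composition",
    "stack_tiles_xy",
    "sample_matrix",
    "unevenness_score",
    "rank_tiles_by_unevenness",
]

BASE_ALPHABET = "ACGT"
COLOR_ALPHABET = "0123"
_NOCALL = {"base": "N", "color": "."}

DEFAULT_GRID = (20, 20)


def _lut(alphabet: str, nocall: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
    lut[ord(nocall)] = len(alphabet)
    return lut


_LUTS = {
    "base": _lut(BASE_ALPHABET, "N"),
    "color": _lut(COLOR_ALPHABET, "."),
}


class TileMetrics:
    """Single-pass accumulators for one tile/panel.

    Memory is proportional to ``cycles x alphabet + gx x gy``, never to
    the number of reads.
    """

    def __init__(self, tile_id: str, alphabet: str, grid: tuple[int, int],
                 extents: tuple[int, int]):
        self.tile_id = tile_id
        self.alphabet = alphabet
        self.gx, self.gy = grid
        self.x_extent, self.y_extent = extents
        k = len(alphabet)
        self.read_count = 0
        self.n_out_of_bounds = 0
        self.per_cycle_symbol_counts = np.zeros((0, k), dtype=np.int64)
        self.per_cycle_nocall = np.zeros(0, dtype=np.int64)
        self.per_cycle_qual_sum = np.zeros(0, dtype=np.float64)
        self.per_cycle_coverage = np.zeros(0, dtype=np.int64)
        self.cell_symbol_counts = np.zeros((self.gx, self.gy, k), dtype=np.int64)
        self.cell_read_counts = np.zeros((self.gx, self.gy), dtype=np.int64)
        self.cell_qual_sum = np.zeros((self.gx, self.gy), dtype=np.float64)
        self.cell_qual_count = np.zeros((self.gx, self.gy), dtype=np.int64)

    def _grow(self, n_cycles: int) -> None:
        cur = len(self.per_cycle_nocall)
        if n_cycles <= cur:
            return
        k = len(self.alphabet)
        self.per_cycle_symbol_counts = np.vstack(
            [self.per_cycle_symbol_counts, np.zeros((n_cycles - cur, k), dtype=np.int64)])
        for name in ("per_cycle_nocall", "per_cycle_coverage"):
            setattr(self, name, np.concatenate(
                [getattr(self, name), np.zeros(n_cycles - cur, dtype=np.int64)]))
        self.per_cycle_qual_sum = np.concatenate(
            [self.per_cycle_qual_sum, np.zeros(n_cycles - cur)])

    def add(self, read: ReadRecord, lut: np.ndarray) -> None:
        codes = lut[np.frombuffer(read.symbols.encode("ascii"), dtype=np.uint8)]
        L = len(codes)
        self._grow(L)
        self.read_count += 1
        k = len(self.alphabet)
        called = (codes >= 0) & (codes < k)
        cyc = np.nonzero(called)[0]
        self.per_cycle_symbol_counts[cyc, codes[cyc]] += 1
        self.per_cycle_nocall[: L][codes == k] += 1
        self.per_cycle_qual_sum[:L] += read.quals
        self.per_cycle_coverage[:L] += 1

        gi = read.coord.x * self.gx // self.x_extent
        gj = read.coord.y * self.gy // self.y_extent
        if not (0 <= gi < self.gx and 0 <= gj < self.gy):
            self.n_out_of_bounds += 1
            gi = min(max(gi, 0), self.gx - 1)
            gj = min(max(gj, 0), self.gy - 1)
        self.cell_symbol_counts[gi, gj] += np.bincount(codes[called], minlength=k)
        self.cell_read_counts[gi, gj] += 1
        self.cell_qual_sum[gi, gj] += float(read.quals.sum())
        self.cell_qual_count[gi, gj] += L

    @property
    def n_cycles(self) -> int:
        return len(self.per_cycle_nocall)

    @property
    def cell_called_counts(self) -> np.ndarray:
        return self.cell_symbol_counts.sum(axis=2)

    def mean_quality(self) -> float:
        tot = self.per_cycle_coverage.sum()
        return float(self.per_cycle_qual_sum.sum() / tot) if tot else float("nan")


@dataclass
class SampleGrid:
    """One value per tile position, laid out as on the physical surface.

    ``values`` is ``n_rows x n_cols`` with NaN at unused/undefined
    positions; ``scale`` is auto-ranged to the extrema of the non-missing
    cells (the convention used for all sample-level heat maps).
    """

    layout: LayoutSpec
    values: np.ndarray
    metric_name: str
    scale: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size:
            self.scale = (float(finite.min()), float(finite.max()))
        else:
            self.scale = (float("nan"), float("nan"))


def accumulate_tile(reads: Iterable[ReadRecord], layout: LayoutSpec,
                    grid_resolution: tuple[int, int] = DEFAULT_GRID,
                    alphabet: Optional[str] = None) -> dict[str, TileMetrics]:
    """Accumulate per-tile metrics from a read stream in one pass.

    Every layout tile gets an entry even if no read maps to it.  Reads
    from tiles absent from the layout are accumulated under their own
    tile id (and flagged by the readers); reads whose x/y exceed the tile
    extents are counted and clamped into the nearest edge cell, never
    dropped.  ``alphabet`` is ``"base"`` or ``"color"``; when None it is
    detected from the first read.
    """
    gx, gy = grid_resolution
    if gx < 1 or gy < 1:
        raise ValueError("grid resolution must be >= (1, 1)")
    extents = (layout.tile_x_extent, layout.tile_y_extent)
    tiles: dict[str, TileMetrics] = {}
    symbols = BASE_ALPHABET if alphabet == "base" else COLOR_ALPHABET if alphabet == "color" else None
    lut = _LUTS[alphabet] if alphabet else None
    for read in reads:
        if read.coord is None:
            continue
        if symbols is None:
            alphabet = "color" if read.colorspace else "base"
            symbols = COLOR_ALPHABET if read.colorspace else BASE_ALPHABET
            lut = _LUTS[alphabet]
        tm = tiles.get(read.coord.tile_id)
        if tm is None:
            tm = tiles[read.coord.tile_id] = TileMetrics(
                read.coord.tile_id, symbols, grid_resolution, extents)
        tm.add(read, lut)
    if symbols is None:
        symbols, alphabet = BASE_ALPHABET, "base"
    for tid in layout.tiles:
        if tid not in tiles:
            tiles[tid] = TileMetrics(tid, symbols, grid_resolution, extents)
    return tiles


def merge_tile_metrics(tms: Iterable[TileMetrics],
                       tile_id: str = "<merged>") -> TileMetrics:
    """Count-weighted pooling of several tiles into one accumulator."""
    tms = list(tms)
    if not tms:
        raise ValueError("nothing to merge")
    first = tms[0]
    out = TileMetrics(tile_id, first.alphabet, (first.gx, first.gy),
                      (first.x_extent, first.y_extent))
    out._grow(max(t.n_cycles for t in tms))
    for t in tms:
        if (t.gx, t.gy) != (out.gx, out.gy):
            raise ValueError("cannot merge tiles with different grid resolutions")
        n = t.n_cycles
        out.read_count += t.read_count
        out.n_out_of_bounds += t.n_out_of_bounds
        out.per_cycle_symbol_counts[:n] += t.per_cycle_symbol_counts
        out.per_cycle_nocall[:n] += t.per_cycle_nocall
        out.per_cycle_qual_sum[:n] += t.per_cycle_qual_sum
        out.per_cycle_coverage[:n] += t.per_cycle_coverage
        out.cell_symbol_counts += t.cell_symbol_counts
        out.cell_read_counts += t.cell_read_counts
        out.cell_qual_sum += t.cell_qual_sum
        out.cell_qual_count += t.cell_qual_count
    return out


def spatial_composition_map(tm: TileMetrics, symbol: str) -> np.ndarray:
    """Fraction of ``symbol`` among called symbols per grid cell.

    Empty cells are NaN.  ``symbol`` must belong to the tile's alphabet.
    """
    if symbol not in tm.alphabet:
        raise ValueError(f"symbol {symbol!r} not in alphabet {tm.alphabet!r}")
    idx = tm.alphabet.index(symbol)
    called = tm.cell_called_counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = tm.cell_symbol_counts[:, :, idx] / called
    frac[called == 0] = np.nan
    return frac


Scope = Union[str, tuple[str, Union[int, str]]]


def _resolve_scope(tiles: dict[str, TileMetrics], layout: Optional[LayoutSpec],
                   scope: Scope) -> list[TileMetrics]:
    if scope == "sample":
        return list(tiles.values())
    kind, which = scope
    if kind == "tile":
        return [tiles[which]] if which in tiles else []
    if layout is None:
        raise ValueError("row/column scopes need a layout")
    if kind == "row":
        ids = layout.tiles_in_row(int(which))
    elif kind == "col":
        ids = layout.tiles_in_col(int(which))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return [tiles[t] for t in ids if t in tiles]


def cycle_composition(tiles: dict[str, TileMetrics],
                      layout: Optional[LayoutSpec] = None,
                      scope: Scope = "sample") -> "pandas.DataFrame":
    """Per-cycle symbol fractions over called symbols within a scope.

    ``scope`` is ``"sample"``, ``("row", r)``, ``("col", c)`` or
    ``("tile", tile_id)``.  Returns a DataFrame indexed by cycle with one
    column per alphabet symbol; each row sums to 1 where any symbol was
    called.  An empty scope yields an empty frame and a logged warning.
    """
    import pandas as pd

    members = [t for t in _resolve_scope(tiles, layout, scope) if t.read_count]
    if not members:
        logger.warning("cycle_composition: empty scope %r", scope)
        cols = list(next(iter(tiles.values())).alphabet) if tiles else []
        return pd.DataFrame(columns=cols)
    pooled = merge_tile_metrics(members)
    called = pooled.per_cycle_symbol_counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = pooled.per_cycle_symbol_counts / called
    df = pd.DataFrame(frac, columns=list(pooled.alphabet))
    df.index.name = "cycle"
    return df


def stack_tiles_xy(tiles: dict[str, TileMetrics], metric: str,
                   symbol: Optional[str] = None) -> np.ndarray:
    """Aggregate a within-tile metric at identical x-y cells across tiles.

    ``metric`` is ``"symbol-fraction"`` (requires ``symbol``),
    ``"read-density"`` or ``"mean-quality"``.  Counts are pooled cell-wise
    across tiles, then converted, so the result is the exact pooled value.
    """
    tms = [t for t in tiles.values() if t.read_count] or list(tiles.values())
    if not tms:
        raise ValueError("no tiles to stack")
    pooled = merge_tile_metrics(tms)
    if metric == "read-density":
        return pooled.cell_read_counts.astype(float)
    if metric == "symbol-fraction":
        if symbol is None:
            raise ValueError("symbol-fraction needs a symbol")
        return spatial_composition_map(pooled, symbol)
    if metric == "mean-quality":
        cnt = pooled.cell_qual_count.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = pooled.cell_qual_sum / cnt
        q[cnt == 0] = np.nan
        return q
    raise ValueError(f"unknown stacking metric {metric!r}")


def sample_matrix(tiles: dict[str, TileMetrics], layout: LayoutSpec, metric: str,
                  symbol: Optional[str] = None,
                  hit_tallies: Optional[dict] = None,
                  unique_only: bool = True) -> SampleGrid:
    """One value per tile laid out on the physical surface.

    ``metric``: ``"read-count"``, ``"mean-quality"``, ``"symbol-fraction"``
    (requires ``symbol``) or ``"hit-count"`` (requires ``hit_tallies``
    from :func:`surfqc.alignment.tally_hits`; unique hits only unless
    ``unique_only=False``).  Unused layout positions and positions
    without a tile are NaN; empty tiles are NaN for ratio metrics and 0
    for read-count.
    """
    values = np.full((layout.n_rows, layout.n_cols), np.nan)
    for tid, (r, c) in layout.tiles.items():
        tm = tiles.get(tid)
        if metric == "read-count":
            values[r, c] = tm.read_count if tm else 0
        elif tm is None or tm.read_count == 0:
            if metric == "hit-count" and hit_tallies is not None and tid in hit_tallies:
                values[r, c] = hit_tallies[tid].total(unique_only=unique_only)
            continue
        elif metric == "mean-quality":
            values[r, c] = tm.mean_quality()
        elif metric == "symbol-fraction":
            if symbol is None:
                raise ValueError("symbol-fraction needs a symbol")
            idx = tm.alphabet.index(symbol)
            called = tm.per_cycle_symbol_counts.sum()
            if called:
                values[r, c] = tm.per_cycle_symbol_counts[:, idx].sum() / called
        elif metric == "hit-count":
            if hit_tallies is None:
                raise ValueError("hit-count needs hit_tallies")
            if tid in hit_tallies:
                values[r, c] = hit_tallies[tid].total(unique_only=unique_only)
        else:
            raise ValueError(f"unknown sample metric {metric!r}")
    name = metric if symbol is None else f"{metric}({symbol})"
    return SampleGrid(layout, values, name)


def unevenness_score(cell_counts: np.ndarray) -> float:
    """Chi-square/df departure of grid-cell counts from spatial uniformity.

    ``cell_counts`` may contain NaN for missing cells; those are excluded
    from the uniform expectation.  Returns 0 iff all non-missing cells
    are equal, and NaN (with a log message) when the total count is zero
    or fewer than two cells carry data.
    """
    a = np.asarray(cell_counts, dtype=float).ravel()
    a = a[np.isfinite(a)]
    n = a.sum()
    if a.size < 2 or n <= 0:
        logger.warning("unevenness_score undefined (cells=%d, total=%s)", a.size, n)
        return float("nan")
    expected = n / a.size
    chi2 = float(((a - expected) ** 2 / expected).sum())
    return chi2 / (a.size - 1)


def rank_tiles_by_unevenness(tiles: dict[str, TileMetrics],
                             measure: str = "read-count",
                             hit_tallies: Optional[dict] = None
                             ) -> list[tuple[str, float]]:
    """Tiles ordered by within-tile unevenness, worst first.

    ``measure`` is ``"read-count"`` (grid-cell read counts) or
    ``"hit-count"`` (grid-cell unique-hit counts from
    :func:`surfqc.alignment.tally_hits` run with a spatial grid).  Ties
    break lexicographically by tile id; tiles with undefined scores (no
    data) are listed last.
    """
    scored: list[tuple[str, float]] = []
    for tid in sorted(tiles):
        if measure == "read-count":
            counts = tiles[tid].cell_read_counts
        elif measure == "hit-count":
            if hit_tallies is None:
                raise ValueError("hit-count ranking needs hit_tallies")
            tally = hit_tallies.get(tid)
            if tally is None or tally.spatial_hits is None:
                scored.append((tid, float("nan")))
                continue
            counts = tally.spatial_hits
        else:
            raise ValueError(f"unknown unevenness measure {measure!r}")
        if counts.sum() == 0:
            scored.append((tid, float("nan")))
        else:
            scored.append((tid, unevenness_score(counts)))
    defined = [s for s in scored if np.isfinite(s[1])]
    undefined = [s for s in scored if not np.isfinite(s[1])]
    defined.sort(key=lambda s: (-s[1], s[0]))
    return defined + undefined
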