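"""Composition/quality accumulators and the unevenness statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from surfqc.formats import ReadRecord, SurfaceCoordinate, builtin_layout
from surfqc.metrics import (SampleGrid, accumulate_tile, cycle_composition,
                            merge_tile_metrics, rank_tiles_by_unevenness,
                            sample_matrix, spatial_composition_map,
                            stack_tiles_xy, unevenness_score)


def make_read(tile="1", x=0, y=0, symbols="ACGT", qual=30, rid="r"):
    return ReadRecord(rid, SurfaceCoordinate(tile, x, y),
                      symbols, np.full(len(symbols), qual, dtype=np.int16))


def test_all_A_reads_fill_cells_with_fraction_one(mini_layout):
    rng = np.random.default_rng(0)
    reads = [make_read(x=int(rng.integers(1000)), y=int(rng.integers(1000)),
                       symbols="AAAA", rid=f"r{i}") for i in range(100)]
    tiles = accumulate_tile(reads, mini_layout, (4, 4))
    frac = spatial_composition_map(tiles["1"], "A")
    filled = np.isfinite(frac)
    assert filled.any()
    assert np.allclose(frac[filled], 1.0)


def test_empty_tile_present_with_missing_cells(mini_layout):
    tiles = accumulate_tile([make_read()], mini_layout, (2, 2))
    assert tiles["7"].read_count == 0
    assert np.isnan(spatial_composition_map(tiles["7"], "A")).all()


def test_composition_fraction_counts_called_only():
    lay = builtin_layout("mini_20")
    # one cell: A=30, C=10, G=5, T=5, N=2 called over several reads
    syms = "A" * 30 + "C" * 10 + "G" * 5 + "T" * 5 + "N" * 2
    reads = [make_read(symbols=s, rid=f"r{i}") for i, s in enumerate(syms)]
    tiles = accumulate_tile(reads, lay, (1, 1))
    assert spatial_composition_map(tiles["1"], "A")[0, 0] == pytest.approx(0.60)


def test_unknown_symbol_is_hard_error(mini_layout):
    tiles = accumulate_tile([make_read()], mini_layout, (2, 2))
    with pytest.raises(ValueError):
        spatial_composition_map(tiles["1"], "Z")


def test_uniform_composition_within_binomial_bounds(flat_tiles):
    """I.i.d. uniform symbols: per-cycle A-fraction within 5 binomial SD."""
    tiles, _ = flat_tiles
    comp = cycle_composition(tiles, scope="sample")
    n = merge_tile_metrics(list(tiles.values())).per_cycle_symbol_counts.sum(axis=1)
    sd = np.sqrt(0.25 * 0.75 / n)
    assert (np.abs(comp["A"].to_numpy() - 0.25) < 5 * sd).all()


def test_cycle_fractions_sum_to_one(flat_tiles):
    tiles, _ = flat_tiles
    comp = cycle_composition(tiles, scope="sample")
    assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-9)


def test_single_read_scope_gives_indicators(mini_layout):
    reads = [make_read(symbols="ACGT")]
    tiles = accumulate_tile(reads, mini_layout)
    comp = cycle_composition(tiles, mini_layout, ("tile", "1"))
    assert set(np.unique(comp.to_numpy())) == {0.0, 1.0}
    assert comp.loc[0, "A"] == 1.0 and comp.loc[3, "T"] == 1.0


def test_pooling_equivalence(flat_tiles, mini_layout):
    """Sample-scope composition equals count-weighted pooling of tiles."""
    tiles, _ = flat_tiles
    whole = cycle_composition(tiles, mini_layout, "sample")
    counts = None
    for tm in tiles.values():
        c = tm.per_cycle_symbol_counts
        counts = c.copy() if counts is None else counts + c
    manual = counts / counts.sum(axis=1, keepdims=True)
    assert np.allclose(whole.to_numpy(), manual, atol=1e-12)


def test_row_and_column_scopes_partition_sample(flat_tiles, mini_layout):
    tiles, _ = flat_tiles
    total = sum(tiles[t].read_count for t in mini_layout.tiles)
    by_row = sum(
        merge_tile_metrics([tiles[t] for t in mini_layout.tiles_in_row(r)]).read_count
        for r in range(mini_layout.n_rows))
    assert by_row == total


def test_stacking_identical_tiles_is_idempotent(mini_layout):
    reads = ([make_read("1", x, y, "AAAA", rid=f"a{x}{y}")
              for x in (100, 900) for y in (100, 900)]
             + [make_read("2", x, y, "AAAA", rid=f"b{x}{y}")
                for x in (100, 900) for y in (100, 900)])
    tiles = accumulate_tile(reads, mini_layout, (2, 2))
    stacked = stack_tiles_xy(tiles, "read-density")
    assert np.array_equal(stacked, 2 * tiles["1"].cell_read_counts)


def test_stacked_counts_conserve_cellwise(flat_tiles):
    tiles, _ = flat_tiles
    stacked = stack_tiles_xy(tiles, "read-density")
    manual = sum(t.cell_read_counts for t in tiles.values())
    assert np.array_equal(stacked, manual)
    pooled = merge_tile_metrics(list(tiles.values()))
    manual_sym = sum(t.cell_symbol_counts for t in tiles.values())
    assert np.array_equal(pooled.cell_symbol_counts, manual_sym)


def test_sample_matrix_mean_quality_exact(mini_layout):
    reads = [make_read(t, 5, 5, "ACGT", qual=30, rid=f"r{t}")
             for t in mini_layout.tiles]
    tiles = accumulate_tile(reads, mini_layout)
    grid = sample_matrix(tiles, mini_layout, "mean-quality")
    assert np.allclose(grid.values[np.isfinite(grid.values)], 30.0)


def test_sample_matrix_poisson_read_counts(mini_layout, tmp_path):
    from surfqc.synthetic import generate_flowcell
    lam = 5000 / 20  # expected reads per tile at uniform weights
    fc = generate_flowcell(mini_layout, 5000, 10, tmp_path, seed=3)
    tiles = accumulate_tile(
        _records_from(fc), mini_layout, (2, 2))
    grid = sample_matrix(tiles, mini_layout, "read-count")
    vals = grid.values[np.isfinite(grid.values)]
    assert ((vals > lam - 5 * np.sqrt(lam)) & (vals < lam + 5 * np.sqrt(lam))).all()


def _records_from(fc):
    from surfqc.formats import read_fastq
    return iter(read_fastq(fc.paths["fastq"], fc.layout))


def test_scale_auto_range(mini_layout):
    vals = np.full((5, 4), np.nan)
    vals[0, 0], vals[1, 1], vals[2, 2] = 10.0, 25.0, 40.0
    grid = SampleGrid(mini_layout, vals, "demo")
    assert grid.scale == (10.0, 40.0)


def test_unused_positions_stay_missing(tmp_path):
    lay = builtin_layout("solid_corners")
    reads = [make_read("1", 5, 5, "0123", rid="s1")]
    reads[0].colorspace = True
    tiles = accumulate_tile(reads, lay)
    grid = sample_matrix(tiles, lay, "mean-quality")
    for r, c in lay.unused_regions:
        assert np.isnan(grid.values[r, c])


# ---- unevenness ----------------------------------------------------------

def test_unevenness_trivial_cases():
    assert unevenness_score(np.array([25, 25, 25, 25])) == 0.0
    assert unevenness_score(np.array([100, 0, 0, 0])) == pytest.approx(100.0)
    assert np.isnan(unevenness_score(np.array([0, 0])))


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_unevenness_matches_scipy_chisquare(seed):
    """Brute-force oracle: Pearson chi-square / df via scipy."""
    rng = np.random.default_rng(seed)
    shape = (int(rng.integers(2, 12)), int(rng.integers(1, 12)))
    counts = rng.integers(0, 50, size=shape)
    if counts.sum() == 0:
        counts.flat[0] = 1
    stat, _ = stats.chisquare(counts.ravel())
    expected = stat / (counts.size - 1)
    assert unevenness_score(counts) == pytest.approx(expected, rel=1e-9)


def test_unevenness_null_mean_is_one():
    """Chi-square/df has expectation 1 under multinomial uniformity."""
    rng = np.random.default_rng(42)
    scores = [unevenness_score(rng.multinomial(10_000, np.full(100, 0.01)))
              for _ in range(200)]
    se = np.sqrt(2 / 99 / 200)  # Var(chi2/df) = 2/df, 200 replicates
    assert abs(np.mean(scores) - 1) < 3 * se


def test_rank_tiles_flags_injected_density_cliff(mini_layout, tmp_path):
    from surfqc.synthetic import Effects, generate_flowcell
    hits = 0
    for rep in range(20):
        cell_w = np.ones((4, 4))
        fc_dir = tmp_path / f"rep{rep}"
        # tile "7" gets half its reads squeezed into one grid column
        from surfqc.formats import read_fastq
        fc = generate_flowcell(mini_layout, 4000, 10, fc_dir, seed=100 + rep)
        reader = read_fastq(fc.paths["fastq"], mini_layout)
        recs = []
        for r in reader:
            if r.coord.tile_id == "7":
                r.coord.x = r.coord.x % 250  # density cliff: all reads in 1/4 of x
            recs.append(r)
        tiles = accumulate_tile(recs, mini_layout, (4, 4))
        ranking = rank_tiles_by_unevenness(tiles, "read-count")
        if ranking[0][0] == "7":
            hits += 1
    assert hits >= 19  # >= 95 % of seeded replicates


def test_rank_ties_and_empty_tiles(mini_layout):
    reads = [make_read("1", 5, 5, "AAAA", rid="a"),
             make_read("2", 5, 5, "AAAA", rid="b")]
    tiles = accumulate_tile(reads, mini_layout, (2, 2))
    ranking = rank_tiles_by_unevenness(tiles, "read-count")
    assert ranking[0][0] == "1" and ranking[1][0] == "2"  # tie -> lexicographic
    assert np.isnan(ranking[-1][1])  # empty tiles last, flagged undefined
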