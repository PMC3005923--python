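"""End-to-end orchestration: reads + alignments + lists -> result tree.

``run_sample`` is the library entry point behind the ``surfqc run`` CLI:
it streams the reads once, computes every applicable QC measure, writes
TSV tables and PNG plots under ``<out>/<sample>/`` and records a
``manifest.json`` that :func:`surfqc.report.render_report` turns into
the hierarchical HTML report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import alignment as am
from . import metrics as mc
from . import pairs as pe
from . import report as rp
from . import subsets as sq
from .formats import (LayoutSpec, PairConfig, ReadRecord, normalize_read_id,
                      read_sam)

logger = logging.getLogger(__name__)

__all__ = ["run_sample"]


def run_sample(name: str,
               reads: Iterable[ReadRecord],
               layout: LayoutSpec,
               out_dir: Union[str, Path],
               sam_path: Optional[Union[str, Path]] = None,
               pair_config: Optional[PairConfig] = None,
               pair_sam_path: Optional[Union[str, Path]] = None,
               subset_lists: Optional[dict[str, sq.IdList]] = None,
               grid_resolution: tuple[int, int] = mc.DEFAULT_GRID,
               hist_bin: int = 10_000,
               pair_hist_bin: int = 100,
               orientation: str = "convergent",
               reader=None) -> Path:
    """Compute and write all QC measures for one sample.

    Returns the sample output directory.  ``reader`` may be the stream's
    originating reader object (for its error counters).  ``sam_path``
    enables alignment-based measures; ``pair_config`` (+
    ``pair_sam_path``, defaulting to ``sam_path``) enables paired-end
    library QC; ``subset_lists`` maps list names to
    :class:`surfqc.subsets.IdList`.
    """
    out = Path(out_dir) / name
    tables = out / "tables"
    plots = out / "plots"
    tables.mkdir(parents=True, exist_ok=True)
    plots.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"sample": name, "sections": {}, "counters": {}}

    assignments: dict = {}

    def tee(stream):
        for r in stream:
            if r.coord is not None:
                assignments[normalize_read_id(r.read_id)] = r.coord
            yield r

    tiles = mc.accumulate_tile(tee(reads), layout, grid_resolution)
    alphabet = next(iter(tiles.values())).alphabet

    sam = read_sam(sam_path) if sam_path else None
    tallies = None
    if sam is not None:
        result = am.tally_hits(sam.hits, {k: v for k, v in assignments.items()},
                               layout, grid_resolution)
        tallies = result.per_tile
        manifest["counters"]["unlocatable hits"] = result.unlocatable
        manifest["counters"]["records without NM"] = sam.n_missing_nm

    if reader is not None:
        for attr, label in (("n_records", "reads in"),
                            ("n_coordinateless", "coordinate-less reads"),
                            ("n_out_of_extent", "reads outside tile extents"),
                            ("n_unknown_tile", "reads from unknown tiles")):
            if hasattr(reader, attr):
                manifest["counters"][label] = getattr(reader, attr)

    def rel(p: Path) -> str:
        return str(p.relative_to(out))

    # ---- section 1: full sample view -----------------------------------
    sec1 = []
    metrics1 = [("read-count", None), ("mean-quality", None),
                ("symbol-fraction", alphabet[0])]
    if tallies is not None:
        metrics1.append(("hit-count", None))
    for metric, symbol in metrics1:
        grid = mc.sample_matrix(tiles, layout, metric, symbol=symbol,
                                hit_tallies=tallies)
        stem = grid.metric_name.replace("(", "_").replace(")", "")
        tsv = tables / f"sample_{stem}.tsv"
        png = plots / f"sample_{stem}.png"
        rp.save_grid_tsv(grid.values, tsv,
                         row_labels=range(layout.n_rows),
                         col_labels=range(layout.n_cols))
        rp.heatmap_png(grid.values, png, f"{grid.metric_name} per tile",
                       scale=grid.scale)
        sec1.append({"title": grid.metric_name, "png": rel(png), "tsv": rel(tsv)})
    manifest["sections"]["full_sample"] = sec1

    # ---- section 2: stacked x-y summary --------------------------------
    sec2 = []
    for metric, symbol in (("read-density", None), ("mean-quality", None),
                           ("symbol-fraction", alphabet[0])):
        stacked = mc.stack_tiles_xy(tiles, metric, symbol=symbol)
        stem = metric if symbol is None else f"{metric}_{symbol}"
        tsv = tables / f"stacked_{stem}.tsv"
        png = plots / f"stacked_{stem}.png"
        rp.save_grid_tsv(stacked, tsv)
        rp.heatmap_png(stacked, png, f"stacked {metric} across tiles")
        sec2.append({"title": f"stacked {metric}", "png": rel(png), "tsv": rel(tsv)})
    manifest["sections"]["stacked"] = sec2

    # ---- section 3: per-tile unevenness ranking ------------------------
    ranking = mc.rank_tiles_by_unevenness(tiles, "read-count")
    rank_rows = [(t, s) for t, s in ranking if np.isfinite(s)]
    pd.DataFrame(ranking, columns=["tile", "unevenness"]).to_csv(
        tables / "tile_unevenness.tsv", sep="\t", index=False, na_rep="NA")
    sec3: dict = {"ranking": rank_rows[:20], "plots": []}
    if rank_rows:
        worst = tiles[rank_rows[0][0]]
        png = plots / "worst_tile_density.png"
        tsv = tables / "worst_tile_density.tsv"
        rp.save_grid_tsv(worst.cell_read_counts.astype(float), tsv)
        rp.heatmap_png(worst.cell_read_counts.astype(float), png,
                       f"read density, most uneven tile {worst.tile_id}")
        sec3["plots"].append({"title": f"tile {worst.tile_id} read density",
                              "png": rel(png), "tsv": rel(tsv)})
    manifest["sections"]["per_tile"] = sec3

    # ---- section 4: cycle-based plots ----------------------------------
    sec4 = []
    comp = mc.cycle_composition(tiles, layout, "sample")
    tsv = tables / "cycle_composition_sample.tsv"
    png = plots / "cycle_composition_sample.png"
    comp.to_csv(tsv, sep="\t", na_rep="NA")
    rp.line_png(comp, png, "per-cycle composition (whole sample)")
    sec4.append({"title": "per-cycle composition", "png": rel(png), "tsv": rel(tsv)})

    focal = alphabet[0]
    by_col = {}
    for c in range(layout.n_cols):
        series = mc.cycle_composition(tiles, layout, ("col", c))
        if not series.empty:
            by_col[f"col {c}"] = series[focal]
    if by_col:
        df = pd.DataFrame(by_col)
        tsv = tables / f"cycle_{focal}_by_column.tsv"
        png = plots / f"cycle_{focal}_by_column.png"
        df.to_csv(tsv, sep="\t", na_rep="NA")
        rp.line_png(df, png, f"'{focal}' fraction per cycle, by tile column")
        sec4.append({"title": f"'{focal}' fraction by tile column",
                     "png": rel(png), "tsv": rel(tsv)})

    if sam is not None:
        rates = am.mismatch_rate_per_cycle(sam.hits)
        if rates.size:
            df = pd.DataFrame({"mismatch_rate": rates})
            df.index.name = "cycle"
            tsv = tables / "mismatch_rate_per_cycle.tsv"
            png = plots / "mismatch_rate_per_cycle.png"
            df.to_csv(tsv, sep="\t")
            rp.line_png(df, png, "mismatch rate per cycle (unique hits)",
                        ylabel="rate")
            sec4.append({"title": "mismatch rate per cycle",
                         "png": rel(png), "tsv": rel(tsv)})
    manifest["sections"]["cycle"] = sec4

    # ---- section 5: target hit histogram -------------------------------
    if sam is not None and sam.references:
        sec5 = []
        hists = am.target_hit_histogram(sam.hits, hist_bin, sam.references)
        rows = []
        for ref, counts in hists.items():
            for b, cnt in enumerate(counts):
                rows.append((ref, b * hist_bin,
                             min((b + 1) * hist_bin, sam.references[ref]), cnt))
        bed = pd.DataFrame(rows, columns=["reference", "start", "end", "count"])
        tsv = tables / "target_hits.tsv"
        bed.to_csv(tsv, sep="\t", index=False)
        for ref, counts in hists.items():
            png = plots / f"target_hits_{ref}.png"
            df = pd.DataFrame({"hits": counts},
                              index=np.arange(len(counts)) * hist_bin)
            rp.line_png(df, png, f"unique hit starts along {ref} "
                        f"({hist_bin} bp bins)", xlabel="position", ylabel="hits")
            sec5.append({"title": f"hits along {ref}", "png": rel(png),
                         "tsv": rel(tsv)})
        manifest["sections"]["target"] = sec5

    # ---- section 6: user-defined subsets -------------------------------
    if subset_lists:
        sec6 = []
        for list_name, ids in subset_lists.items():
            cmpres = sq.subset_sample_matrix(ids, assignments, layout)
            pair_cells = []
            for tag, grid in (("subset", cmpres.subset), ("all reads", cmpres.full)):
                stem = f"subset_{list_name}_{tag.replace(' ', '_')}"
                tsv = tables / f"{stem}.tsv"
                png = plots / f"{stem}.png"
                rp.save_grid_tsv(grid.values, tsv)
                rp.heatmap_png(grid.values, png, f"{list_name}: {tag}")
                pair_cells.append({"title": f"{list_name}: {tag}",
                                   "png": rel(png), "tsv": rel(tsv)})
            note = (f"{cmpres.n_matched} ids matched, {cmpres.n_unmatched} "
                    f"unmatched; uniformity chi-square = {cmpres.statistic:.2f}, "
                    f"p = {cmpres.p_value:.3g} (supplementary to the visual "
                    "side-by-side comparison)")
            pair_cells[0]["note"] = note
            sec6.append(pair_cells)
        manifest["sections"]["subset"] = sec6

    # ---- section 7: paired-end library QC ------------------------------
    if pair_config is not None:
        psam_path = pair_sam_path or sam_path
        if psam_path is None:
            raise ValueError("paired-end QC needs an alignment file")
        psam = read_sam(psam_path) if psam_path != sam_path or sam is None else sam
        ends = pe.pair_up(psam.hits)
        summary = pe.summarize_pairs(ends.values(), pair_config,
                                     hist_bin=pair_hist_bin,
                                     orientation=orientation)
        labels = [c.value for c in pe.PairCategory]
        values = [summary.counts[c] for c in pe.PairCategory]
        tsv = tables / "pair_categories.tsv"
        pd.DataFrame({"category": labels, "count": values}).to_csv(
            tsv, sep="\t", index=False)
        png = plots / "pair_categories.png"
        rp.bar_png(labels, values, png,
                   f"pair categories (chimera fraction "
                   f"{summary.chimera_fraction:.1%})")
        sec7 = [{"title": "pair categories", "png": rel(png), "tsv": rel(tsv)}]

        rows = ([(b, "+", c) for b, c in sorted(summary.distance_histogram_plus.items())]
                + [(b, "-", c) for b, c in sorted(summary.distance_histogram_minus.items())])
        hist_df = pd.DataFrame(rows, columns=["bin_start", "first_end_strand", "count"])
        tsv = tables / "pair_distances.tsv"
        hist_df.to_csv(tsv, sep="\t", index=False)
        if rows:
            png = plots / "pair_distances.png"
            fig_df = {}
            for strand, histo in (("+", summary.distance_histogram_plus),
                                  ("-", summary.distance_histogram_minus)):
                if histo:
                    s = pd.Series(histo).sort_index()
                    fig_df[f"first end {strand}"] = s
            rp.line_png(pd.DataFrame(fig_df).fillna(0), png,
                        "good-pair signed distances by strand of first end",
                        xlabel="distance (bp)", ylabel="pairs")
            sec7.append({"title": "pair distance distribution",
                         "png": rel(png), "tsv": rel(tsv)})
        manifest["sections"]["pairs"] = sec7
        manifest["counters"]["pairs with both ends unusable"] = summary.both_unmapped

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out
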