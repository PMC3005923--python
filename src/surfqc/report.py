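"""Rendering: TSV exports, matplotlib plots, three-layer HTML report.

Plots are views, never the source of truth: every PNG written here has a
sibling TSV holding the exact numbers, and re-rendering unchanged
results produces byte-identical HTML and PNGs (plot timestamps are
suppressed).  The report is a static tree — layer 1 lists samples,
layer 2 the QC measures of a sample, layer 3 the individual plots — and
needs no server to view, though :func:`serve` provides one.
"""

from __future__ import annotations

import html
import http.server
import json
import logging
from functools import partial
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .metrics import SampleGrid

logger = logging.getLogger(__name__)

__all__ = ["save_grid_tsv", "heatmap_png", "line_png", "bar_png",
           "render_report", "serve"]

_PNG_META = {"metadata": {"Date": None}}  # deterministic PNG bytes


def save_grid_tsv(values: np.ndarray, path: Union[str, Path],
                  row_labels=None, col_labels=None) -> None:
    """Write a 2D matrix as TSV with row/column headers."""
    df = pd.DataFrame(values, index=row_labels, columns=col_labels)
    df.to_csv(path, sep="\t", na_rep="NA")


def heatmap_png(values: np.ndarray, path: Union[str, Path], title: str,
                scale: Optional[tuple[float, float]] = None) -> None:
    """Heat map with missing cells in a reserved color, auto-ranged scale."""
    fig, ax = plt.subplots(figsize=(5, 4))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("black")
    masked = np.ma.masked_invalid(np.asarray(values, dtype=float))
    vmin, vmax = scale if scale else (None, None)
    im = ax.imshow(masked.T, origin="lower", aspect="auto", cmap=cmap,
                   vmin=vmin, vmax=vmax, interpolation="nearest")
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=90, **_PNG_META)
    plt.close(fig)


def line_png(df: pd.DataFrame, path: Union[str, Path], title: str,
             xlabel: str = "cycle", ylabel: str = "fraction") -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for col in df.columns:
        ax.plot(df.index, df[col], label=str(col), linewidth=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(title, fontsize=9)
    if len(df.columns) <= 8:
        ax.legend(fontsize=7)
    fig.savefig(path, dpi=90, **_PNG_META)
    plt.close(fig)


def bar_png(labels: list[str], counts: list[float], path: Union[str, Path],
            title: str) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(range(len(labels)), counts, color="steelblue")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=30, ha="right", fontsize=7)
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=90, **_PNG_META)
    plt.close(fig)


# ---------------------------------------------------------------------------
# HTML assembly
# ---------------------------------------------------------------------------

_SECTION_ORDER = [
    ("full_sample", "1. Full sample view"),
    ("stacked", "2. All tiles/panels summary view"),
    ("per_tile", "3. Individual tile/panel QC"),
    ("cycle", "4. Cycle-based QC plots"),
    ("target", "5. Target hit plot"),
    ("subset", "6. QC for user-defined sequence lists"),
    ("pairs", "7. Paired-end / mate-pair library QC"),
]

_CSS = """body{font-family:sans-serif;margin:1.5em}h2{border-bottom:1px solid #999}
.item{display:inline-block;margin:8px;vertical-align:top}
.item img{border:1px solid #ccc}.note{color:#777;font-style:italic}
.sbs{display:flex;gap:12px}table{border-collapse:collapse}
td,th{border:1px solid #bbb;padding:2px 8px;font-size:90%}"""


def _plot_cell(entry: dict) -> str:
    cap = html.escape(entry.get("title", ""))
    parts = [f'<div class="item"><div>{cap}</div>']
    if "png" in entry:
        parts.append(f'<img src="{entry["png"]}" alt="{cap}">')
    if "tsv" in entry:
        parts.append(f'<div><a href="{entry["tsv"]}">data (TSV)</a></div>')
    if "note" in entry:
        parts.append(f'<div class="note">{html.escape(entry["note"])}</div>')
    parts.append("</div>")
    return "".join(parts)


def render_report(results_dir: Union[str, Path]) -> Path:
    """Assemble index.html and per-sample pages from run manifests.

    Each sample directory under ``results_dir`` must hold a
    ``manifest.json`` written by the pipeline (see
    :mod:`surfqc.pipeline`).  Missing measures render as an explanatory
    placeholder, never a broken link.
    """
    results_dir = Path(results_dir)
    manifests = sorted(results_dir.glob("*/manifest.json"))
    if not manifests:
        raise FileNotFoundError(f"no sample manifests under {results_dir}")

    sample_links = []
    for mpath in manifests:
        with open(mpath) as fh:
            manifest = json.load(fh)
        sample = manifest["sample"]
        page = _render_sample_page(manifest)
        (mpath.parent / "sample.html").write_text(page)
        sample_links.append(
            f'<li><a href="{html.escape(sample)}/sample.html">{html.escape(sample)}</a></li>')

    index = (f"<!DOCTYPE html><html><head><meta charset='utf-8'>"
             f"<title>sequencing run QC</title><style>{_CSS}</style></head><body>"
             f"<h1>Sequencing run QC</h1><p>Samples:</p><ul>"
             + "".join(sample_links) + "</ul></body></html>")
    out = results_dir / "index.html"
    out.write_text(index)
    return out


def _render_sample_page(manifest: dict) -> str:
    sample = html.escape(manifest["sample"])
    body = [f"<h1>{sample}</h1>"]
    counters = manifest.get("counters", {})
    if counters:
        rows = "".join(f"<tr><td>{html.escape(k)}</td><td>{v}</td></tr>"
                       for k, v in counters.items())
        body.append(f"<h2>Input accounting</h2><table>{rows}</table>")
    sections = manifest.get("sections", {})
    for key, heading in _SECTION_ORDER:
        body.append(f"<h2>{heading}</h2>")
        sec = sections.get(key)
        if not sec:
            body.append(f'<p class="note">{html.escape(_absence_note(key))}</p>')
            continue
        if key == "subset":
            for pair in sec:
                body.append('<div class="sbs">' + "".join(
                    _plot_cell(e) for e in pair) + "</div>")
        elif key == "per_tile" and isinstance(sec, dict):
            rows = "".join(
                f"<tr><td>{html.escape(t)}</td><td>{s:.3f}</td></tr>"
                for t, s in sec.get("ranking", []))
            body.append("<p>Tiles ranked by within-tile unevenness "
                        "(chi-square / df; worst first):</p>"
                        f"<table><tr><th>tile</th><th>score</th></tr>{rows}</table>")
            for e in sec.get("plots", []):
                body.append(_plot_cell(e))
        else:
            for e in sec:
                body.append(_plot_cell(e))
    return (f"<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<title>{sample}</title><style>{_CSS}</style></head><body>"
            + "".join(body) + "</body></html>")


def _absence_note(key: str) -> str:
    notes = {
        "target": "No alignment file was supplied; alignment-based measures "
                  "were not computed.",
        "subset": "No user-defined read lists were supplied.",
        "pairs": "No pair configuration was supplied; paired-end library QC "
                 "was not computed.",
    }
    return notes.get(key, "Not computed for this run.")


def serve(results_dir: Union[str, Path], port: int = 8080) -> None:
    """Serve a rendered report tree over HTTP (blocking)."""
    results_dir = Path(results_dir)
    if not (results_dir / "index.html").exists():
        raise SystemExit(
            f"{results_dir} holds no index.html; run the pipeline and "
            "'surfqc report' first")
    handler = partial(http.server.SimpleHTTPRequestHandler,
                      directory=str(results_dir))
    try:
        server = http.server.ThreadingHTTPServer(("", port), handler)
    except OSError as exc:
        raise SystemExit(f"cannot listen on port {port}: {exc}") from exc
    logger.info("serving %s on port %d", results_dir, port)
    try:
        server.serve_forever()
    finally:
        server.server_close()
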