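"""Synthetic flowcell, alignment and pair generators with known truth.

Every QC statistic in this package is validated by parameter recovery:
the generators here write standard FASTQ / csfasta+qual / SAM files with
*injected* effects — a spatial composition gradient, a periodic
per-cycle composition bias, per-tile quality defects, within-tile
density masks (e.g. a donut-shaped deficit repeated on every tile),
per-cycle substitution rates, per-tile mappability drops, and exact
paired-end category mixes — and return a :class:`TruthRecord` from which
every expected statistic can be recomputed.

Effects are stylized and parametric by design; they emulate the *shape*
of real artifacts (fluidics bands, ligation-chemistry periodicity,
imaging donuts), not a platform's base-caller noise.

All randomness flows from a single integer seed; the same seed yields
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Optional, Union

import numpy as np

from .formats import LayoutSpec, PairConfig
from .pairs import PairCategory

__all__ = [
    "EffectError",
    "GradientEffect",
    "CycleBiasEffect",
    "Effects",
    "donut_cell_weights",
    "TruthRecord",
    "SimulatedFlowcell",
    "SimulatedAlignments",
    "SimulatedPairs",
    "generate_flowcell",
    "generate_alignments",
    "generate_pairs",
]


class EffectError(ValueError):
    """An effect specification that cannot keep probabilities in [0, 1]."""


@dataclass
class GradientEffect:
    """Linear spatial composition gradient along within-tile x.

    The probability of ``symbol`` at fractional position u = x / x_extent
    is ``0.25 + amplitude * u``; the other three symbols share the
    remainder equally.  The same gradient repeats on every tile, so it is
    visible both in per-tile maps and in the stacked x-y summary.
    """

    symbol: str = "A"
    amplitude: float = 0.05


@dataclass
class CycleBiasEffect:
    """Additive composition excess at periodic cycles.

    At cycles with ``cycle % period == phase`` the probability of
    ``symbol`` gains ``amplitude`` (others compensating equally) —
    emulating chemistry-cycle periodicity such as primer-reset artifacts
    in sequencing-by-ligation.
    """

    symbol: str = "0"
    amplitude: float = 0.05
    period: int = 5
    phase: int = 0


@dataclass
class Effects:
    """Bundle of injected biases for :func:`generate_flowcell`."""

    gradient: Optional[GradientEffect] = None
    cycle_bias: Optional[CycleBiasEffect] = None
    tile_quality_delta: dict[str, float] = field(default_factory=dict)
    tile_weights: Optional[dict[str, float]] = None
    cell_weights: Optional[np.ndarray] = None  # (gx, gy) within-tile placement weights
    nocall_rate: float = 0.0


def donut_cell_weights(gx: int, gy: int, r_inner: float = 0.25,
                       r_outer: float = 0.4, retention: float = 0.3
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Within-tile placement weights with an annular density deficit.

    Cells whose center falls in the ring ``r_inner <= r <= r_outer``
    (radii as fractions of the tile half-diagonal frame, centered) keep
    only ``retention`` of the uniform weight.  Returns (weights, mask)
    where mask flags the deficit cells.
    """
    ix, iy = np.meshgrid(np.arange(gx), np.arange(gy), indexing="ij")
    cx = (ix + 0.5) / gx - 0.5
    cy = (iy + 0.5) / gy - 0.5
    r = np.hypot(cx, cy)
    mask = (r >= r_inner) & (r <= r_outer)
    weights = np.ones((gx, gy))
    weights[mask] = retention
    return weights, mask


@dataclass
class TruthRecord:
    """Everything needed to recompute expected statistics of a fixture."""

    seed: int
    platform: str
    kind: str
    params: dict = field(default_factory=dict)
    per_tile_counts: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def save(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=_jsonable)

    @staticmethod
    def load(path: Union[str, Path]) -> "TruthRecord":
        with open(path) as fh:
            return TruthRecord(**json.load(fh))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Flowcell generation
# ---------------------------------------------------------------------------

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclass
class SimulatedFlowcell:
    """In-memory handle to a generated read set plus its truth."""

    layout: LayoutSpec
    alphabet: str             # "base" | "color"
    read_length: int
    read_ids: list[str]
    tile_ids: list[str]       # per read
    x: np.ndarray
    y: np.ndarray
    paths: dict[str, Path]
    truth: TruthRecord


def _validate_probs(gradient: Optional[GradientEffect],
                    bias: Optional[CycleBiasEffect], symbols: str) -> None:
    g = gradient.amplitude if gradient else 0.0
    b = bias.amplitude if bias else 0.0
    for ga in (0.0, g):
        for ba in (0.0, b):
            p_max = 0.25 + max(ga, 0) + max(ba, 0)
            p_min = 0.25 + min(ga, 0) + min(ba, 0)
            comp = (1 - p_max) / 3
            if p_max > 1 or p_min < 0 or comp < 0:
                raise EffectError(
                    f"effect amplitudes (gradient={g}, cycle={b}) leave "
                    "symbol probabilities outside [0, 1]")
    if gradient and gradient.symbol not in symbols:
        raise EffectError(f"gradient symbol {gradient.symbol!r} not in {symbols!r}")
    if bias and bias.symbol not in symbols:
        raise EffectError(f"cycle-bias symbol {bias.symbol!r} not in {symbols!r}")


def generate_flowcell(layout: LayoutSpec, n_reads: int, read_length: int,
                      out_dir: Union[str, Path], alphabet: str = "base",
                      effects: Optional[Effects] = None, seed: int = 0,
                      dialect: Optional[str] = None, base_quality: float = 30.0,
                      name: str = "sample") -> SimulatedFlowcell:
    """Write a synthetic read set with known injected biases.

    ``alphabet`` selects basespace FASTQ (``"base"``) or SOLiD colorspace
    csfasta+qual output (``"color"``).  ``dialect`` picks the read-id
    format: ``"legacy"`` (default for basespace), ``"casava"``, or the
    SOLiD bead naming (forced for colorspace).  Read ids encode the true
    (tile, x, y), so coordinate parsing is exactly invertible.
    """
    from .metrics import BASE_ALPHABET, COLOR_ALPHABET

    eff = effects or Effects()
    symbols = BASE_ALPHABET if alphabet == "base" else COLOR_ALPHABET
    nocall = "N" if alphabet == "base" else "."
    _validate_probs(eff.gradient, eff.cycle_bias, symbols)
    if not (0.0 <= eff.nocall_rate < 1.0):
        raise EffectError("nocall_rate must be in [0, 1)")
    if dialect is None:
        dialect = "legacy" if alphabet == "base" else "solid"
    if alphabet == "color" and dialect != "solid":
        raise ValueError("colorspace output uses SOLiD bead naming")

    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tile_list = list(layout.tiles)
    if eff.tile_weights:
        w = np.array([eff.tile_weights.get(t, 1.0) for t in tile_list], dtype=float)
    else:
        w = np.ones(len(tile_list))
    w = w / w.sum()
    tidx = rng.choice(len(tile_list), size=n_reads, p=w)

    xe, ye = layout.tile_x_extent, layout.tile_y_extent
    if eff.cell_weights is not None:
        cw = np.asarray(eff.cell_weights, dtype=float)
        gx, gy = cw.shape
        flat = (cw / cw.sum()).ravel()
        cells = rng.choice(gx * gy, size=n_reads, p=flat)
        ci, cj = np.divmod(cells, gy)
        x = ((ci + rng.random(n_reads)) * xe / gx).astype(np.int64)
        y = ((cj + rng.random(n_reads)) * ye / gy).astype(np.int64)
    else:
        x = rng.integers(0, xe, size=n_reads)
        y = rng.integers(0, ye, size=n_reads)
    x = np.minimum(x, xe - 1)
    y = np.minimum(y, ye - 1)

    # Per-cycle symbol sampling: base 1/4 each, focal symbols adjusted.
    codes = np.empty((n_reads, read_length), dtype=np.int8)
    u_frac = x / xe
    k = len(symbols)
    for c in range(read_length):
        p = np.full((n_reads, k), 0.25)
        if eff.gradient:
            gi = symbols.index(eff.gradient.symbol)
            g = eff.gradient.amplitude * u_frac
            p[:, gi] += g
            for j in range(k):
                if j != gi:
                    p[:, j] -= g / 3
        if eff.cycle_bias and c % eff.cycle_bias.period == eff.cycle_bias.phase:
            bi = symbols.index(eff.cycle_bias.symbol)
            b = eff.cycle_bias.amplitude
            p[:, bi] += b
            for j in range(k):
                if j != bi:
                    p[:, j] -= b / 3
        cum = np.cumsum(p, axis=1)
        u = rng.random(n_reads)
        codes[:, c] = (u[:, None] > cum).sum(axis=1).clip(0, k - 1)

    if eff.nocall_rate > 0:
        nc = rng.random((n_reads, read_length)) < eff.nocall_rate
        codes[nc] = k

    ascii_lut = np.frombuffer((symbols + nocall).encode(), dtype=np.uint8)
    sym_bytes = ascii_lut[codes].tobytes().decode("ascii")

    deltas = np.array([eff.tile_quality_delta.get(t, 0.0) for t in tile_list])
    qmeans = base_quality + deltas[tidx]
    quals = np.clip(np.rint(rng.normal(qmeans[:, None], 3.0,
                                       (n_reads, read_length))), 2, 41).astype(np.uint8)
    qual_bytes = (quals + 33).tobytes().decode("latin1")

    tile_ids = [tile_list[i] for i in tidx]
    L = read_length
    read_ids: list[str] = []
    paths: dict[str, Path] = {}

    if alphabet == "base":
        lines: list[str] = []
        for i in range(n_reads):
            # serial in the instrument field keeps ids unique even when
            # two reads land on the same coordinate
            if dialect == "legacy":
                rid = f"SIM{i:06d}:1:{tile_ids[i]}:{x[i]}:{y[i]}#0/1"
                header = rid
            else:
                rid = f"SIM{i:06d}:1:FC:1:{tile_ids[i]}:{x[i]}:{y[i]}"
                header = f"{rid} 1:N:0:ACGT"
            read_ids.append(rid)
            lines.append(f"@{header}\n{sym_bytes[i*L:(i+1)*L]}\n+\n{qual_bytes[i*L:(i+1)*L]}\n")
        paths["fastq"] = out_dir / f"{name}.fastq"
        paths["fastq"].write_text("".join(lines))
    else:
        cs_lines = [f"# synthetic colorspace reads, seed {seed}\n"]
        q_lines = [f"# synthetic colorspace quals, seed {seed}\n"]
        for i in range(n_reads):
            rid = f"{tile_ids[i]}_{x[i]}_{y[i]}_F3"
            read_ids.append(rid)
            cs_lines.append(f">{rid}\nT{sym_bytes[i*L:(i+1)*L]}\n")
            q_lines.append(f">{rid}\n{' '.join(map(str, quals[i]))}\n")
        paths["csfasta"] = out_dir / f"{name}.csfasta"
        paths["qual"] = out_dir / f"{name}.qual"
        paths["csfasta"].write_text("".join(cs_lines))
        paths["qual"].write_text("".join(q_lines))

    per_tile = {t: 0 for t in tile_list}
    for t in tile_ids:
        per_tile[t] += 1
    truth = TruthRecord(
        seed=seed, platform=layout.platform_name, kind="flowcell",
        params={
            "n_reads": n_reads, "read_length": read_length,
            "alphabet": alphabet, "dialect": dialect,
            "base_quality": base_quality,
            "gradient": asdict(eff.gradient) if eff.gradient else None,
            "cycle_bias": asdict(eff.cycle_bias) if eff.cycle_bias else None,
            "tile_quality_delta": eff.tile_quality_delta,
            "nocall_rate": eff.nocall_rate,
            "cell_weights": eff.cell_weights,
            "tile_weights": eff.tile_weights,
        },
        per_tile_counts=per_tile,
    )
    truth.save(out_dir / f"{name}.truth.json")
    paths["truth"] = out_dir / f"{name}.truth.json"

    return SimulatedFlowcell(layout, alphabet, read_length, read_ids,
                             tile_ids, x, y, paths, truth)


# ---------------------------------------------------------------------------
# Alignment generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedAlignments:
    sam_path: Path
    truth: TruthRecord


def _md_string(seq: str, mask: np.ndarray) -> str:
    """MD tag for a gapless alignment whose mismatches are ``mask``."""
    parts: list[str] = []
    run = 0
    for i, mm in enumerate(mask):
        if mm:
            parts.append(str(run))
            base = seq[i]
            parts.append("A" if base != "A" else "C")
            run = 0
        else:
            run += 1
    parts.append(str(run))
    return "".join(parts)


def generate_alignments(fc: SimulatedFlowcell, reference_length: int,
                        out_path: Union[str, Path],
                        per_cycle_rate: Union[float, np.ndarray, Callable[[np.ndarray], np.ndarray]] = 0.0,
                        tile_mappability: Optional[Mapping[str, float]] = None,
                        multi_hit_fraction: float = 0.0,
                        seed: int = 0,
                        reference_name: str = "chr1") -> SimulatedAlignments:
    """Write a SAM file for a simulated flowcell with injected errors.

    ``per_cycle_rate`` is the substitution probability per cycle (scalar,
    length-L vector, or a function of the cycle-index vector);
    ``tile_mappability`` gives the probability that a read of a tile
    aligns at all (default 1.0 everywhere); ``multi_hit_fraction`` of the
    mapped reads receive a second hit and therefore count as multiple.
    NM and MD tags are exactly consistent with the injected mismatch
    masks; reverse-strand alignments store the mask (and a random
    sequence) in reference orientation.
    """
    rng = np.random.default_rng(seed)
    n = len(fc.read_ids)
    L = fc.read_length
    if reference_length <= L:
        raise EffectError("reference_length must exceed the read length")

    cyc = np.arange(L)
    if callable(per_cycle_rate):
        rates = np.asarray(per_cycle_rate(cyc), dtype=float)
    else:
        rates = np.broadcast_to(np.asarray(per_cycle_rate, dtype=float), (L,)).copy()
    if rates.min() < 0 or rates.max() > 1:
        raise EffectError("per-cycle substitution rates must lie in [0, 1]")

    mappability = tile_mappability or {}
    p_map = np.array([mappability.get(t, 1.0) for t in fc.tile_ids])
    mapped = rng.random(n) < p_map
    reverse = rng.random(n) < 0.5
    pos = rng.integers(0, reference_length - L, size=n)
    mm_mask = rng.random((n, L)) < rates[None, :]
    multi = mapped & (rng.random(n) < multi_hit_fraction)
    alt_pos = rng.integers(0, reference_length - L, size=n)

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq_codes = rng.integers(0, 4, size=(n, L))
    seq_bytes = bases[seq_codes].tobytes()

    qual = "I" * L
    per_tile_mapped: dict[str, int] = {t: 0 for t in fc.layout.tiles}
    per_tile_unmapped: dict[str, int] = {t: 0 for t in fc.layout.tiles}

    with open(out_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{reference_name}\tLN:{reference_length}\n")
        fh.write("@PG\tID:surfqc-sim\tPN:surfqc-sim\n")
        for i in range(n):
            rid = fc.read_ids[i].split("/")[0].split(" ")[0]
            seq = seq_bytes[i * L:(i + 1) * L].decode("ascii")
            tile = fc.tile_ids[i]
            if not mapped[i]:
                per_tile_unmapped[tile] = per_tile_unmapped.get(tile, 0) + 1
                fh.write(f"{rid}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n")
                continue
            per_tile_mapped[tile] = per_tile_mapped.get(tile, 0) + 1
            cycle_mask = mm_mask[i]
            stored_mask = cycle_mask[::-1] if reverse[i] else cycle_mask
            stored_seq = (seq.encode().translate(_COMPLEMENT)[::-1].decode()
                          if reverse[i] else seq)
            nm = int(stored_mask.sum())
            md = _md_string(stored_seq, stored_mask)
            flag = 16 if reverse[i] else 0
            fh.write(f"{rid}\t{flag}\t{reference_name}\t{pos[i]+1}\t60\t{L}M\t*\t0\t0\t"
                     f"{stored_seq}\t{qual}\tNM:i:{nm}\tMD:Z:{md}\n")
            if multi[i]:
                fh.write(f"{rid}\t{flag | 256}\t{reference_name}\t{alt_pos[i]+1}\t0\t{L}M"
                         f"\t*\t0\t0\t{stored_seq}\t{qual}\tNM:i:{nm}\tMD:Z:{md}\n")

    truth = TruthRecord(
        seed=seed, platform=fc.layout.platform_name, kind="alignments",
        params={
            "reference_name": reference_name,
            "reference_length": reference_length,
            "per_cycle_rate": rates,
            "tile_mappability": dict(mappability),
            "multi_hit_fraction": multi_hit_fraction,
        },
        per_tile_counts={t: per_tile_mapped[t] for t in per_tile_mapped},
        extra={
            "per_tile_unmapped": per_tile_unmapped,
            "n_multi": int(multi.sum()),
            "n_mapped": int(mapped.sum()),
        },
    )
    out_path = Path(out_path)
    truth.save(out_path.with_suffix(".truth.json"))
    return SimulatedAlignments(out_path, truth)


# ---------------------------------------------------------------------------
# Paired-end generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPairs:
    sam_path: Path
    end1_path: Path
    end2_path: Path
    pair_config_path: Path
    config: PairConfig
    truth: TruthRecord


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    for _ in range(20):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, lo, hi)


def generate_pairs(category_counts: Mapping[Union[PairCategory, str], int],
                   cfg: Optional[PairConfig] = None,
                   layout: Optional[LayoutSpec] = None,
                   out_dir: Union[str, Path] = ".",
                   seed: int = 0,
                   insert_mean: float = 2000.0, insert_sd: float = 300.0,
                   reference_lengths: Optional[Mapping[str, int]] = None,
                   read_length: int = 36,
                   name: str = "pairs") -> SimulatedPairs:
    """Write two read files plus a SAM realizing an exact category mix.

    ``category_counts`` maps :class:`~surfqc.pairs.PairCategory` (or its
    string value) to the number of pairs to emit; running
    :func:`surfqc.pairs.summarize_pairs` over the output reproduces the
    counts exactly.  Good-pair separations are drawn from a normal
    distribution truncated to the configured range, with the first end
    equally likely on either strand.
    """
    from .formats import builtin_layout

    rng = np.random.default_rng(seed)
    cfg = cfg or PairConfig("end1.fastq", "end2.fastq", 500, 5000)
    layout = layout or builtin_layout("mini_20")
    refs = dict(reference_lengths or {"chr1": 1_000_000, "chr2": 1_000_000})
    if len(refs) < 2:
        raise EffectError("need at least two references for chimeric pairs")
    ref_names = list(refs)
    L = read_length
    counts = {PairCategory(k): int(v) for k, v in category_counts.items()}
    for cat, v in counts.items():
        if v < 0:
            raise EffectError(f"negative count for {cat}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sam_path = out_dir / f"{name}.sam"
    end1_path = out_dir / cfg.end1_file
    end2_path = out_dir / cfg.end2_file
    tile_list = list(layout.tiles)

    @dataclass
    class _End:
        mapped: bool
        ref: str = "chr1"
        pos: int = 0
        strand: str = "+"

    records: list[tuple[str, _End, _End]] = []
    serial = 0
    main_ref = ref_names[0]
    span = refs[main_ref] - int(insert_mean + 10 * insert_sd) - L - cfg.max_distance * 2

    def new_id() -> str:
        nonlocal serial
        serial += 1
        tile = tile_list[rng.integers(0, len(tile_list))]
        xx = int(rng.integers(0, layout.tile_x_extent))
        yy = int(rng.integers(0, layout.tile_y_extent))
        return f"SIMP{serial:06d}:1:{tile}:{xx}:{yy}"

    def separated_pair(insert: int, same_strand: bool = False,
                       ref2: Optional[str] = None) -> tuple[_End, _End]:
        base = int(rng.integers(0, max(span, 1)))
        s1 = "+" if rng.random() < 0.5 else "-"
        if s1 == "+":
            p1, p2 = base, base + insert
        else:
            p1, p2 = base + insert, base
        s2 = s1 if same_strand else ("-" if s1 == "+" else "+")
        e1 = _End(True, main_ref, p1, s1)
        e2 = _End(True, ref2 or main_ref, p2, s2)
        return e1, e2

    good_inserts = _truncated_normal(
        rng, insert_mean, insert_sd, cfg.min_distance, cfg.max_distance,
        counts.get(PairCategory.GOOD_PAIR, 0)).astype(int)
    for ins in good_inserts:
        records.append((new_id(), *separated_pair(int(ins))))
    for _ in range(counts.get(PairCategory.UNPAIRED_FORWARD, 0)):
        e1, _ = separated_pair(int(insert_mean))
        records.append((new_id(), e1, _End(False)))
    for _ in range(counts.get(PairCategory.UNPAIRED_REVERSE, 0)):
        _, e2 = separated_pair(int(insert_mean))
        records.append((new_id(), _End(False), e2))
    for _ in range(counts.get(PairCategory.DIFFERENT_CHROMOSOME, 0)):
        e1, e2 = separated_pair(int(insert_mean), ref2=ref_names[1])
        e2.pos = int(rng.integers(0, refs[ref_names[1]] - L))
        records.append((new_id(), e1, e2))
    for _ in range(counts.get(PairCategory.WRONG_ORIENTATION, 0)):
        ins = int(_truncated_normal(rng, insert_mean, insert_sd,
                                    cfg.min_distance, cfg.max_distance, 1)[0])
        records.append((new_id(), *separated_pair(ins, same_strand=True)))
    for _ in range(counts.get(PairCategory.BELOW_RANGE, 0)):
        ins = int(rng.integers(0, cfg.min_distance))
        records.append((new_id(), *separated_pair(ins)))
    for _ in range(counts.get(PairCategory.ABOVE_RANGE, 0)):
        ins = int(rng.integers(cfg.max_distance + 1, cfg.max_distance * 2))
        records.append((new_id(), *separated_pair(ins)))

    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    qual = "I" * L

    def rand_seq() -> str:
        return bases[rng.integers(0, 4, L)].tobytes().decode("ascii")

    with open(sam_path, "w") as sam, open(end1_path, "w") as f1, open(end2_path, "w") as f2:
        sam.write("@HD\tVN:1.6\tSO:unknown\n")
        for ref, ln in refs.items():
            sam.write(f"@SQ\tSN:{ref}\tLN:{ln}\n")
        for rid, e1, e2 in records:
            for mate, end, fq in ((1, e1, f1), (2, e2, f2)):
                seq = rand_seq()
                fq.write(f"@{rid}#0/{mate}\n{seq}\n+\n{qual}\n")
                flag = 0x1 | (0x40 if mate == 1 else 0x80)
                if not end.mapped:
                    sam.write(f"{rid}\t{flag | 0x4}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n")
                    continue
                if end.strand == "-":
                    flag |= 0x10
                sam.write(f"{rid}\t{flag}\t{end.ref}\t{end.pos+1}\t60\t{L}M\t*\t0\t0\t"
                          f"{seq}\t{qual}\tNM:i:0\tMD:Z:{L}\n")

    pair_config_path = out_dir / f"{name}.pair"
    pair_config_path.write_text(
        f"pair: {cfg.end1_file} {cfg.end2_file}\n"
        f"range: {cfg.min_distance} {cfg.max_distance}\n")

    truth = TruthRecord(
        seed=seed, platform=layout.platform_name, kind="pairs",
        params={
            "category_counts": {c.value: v for c, v in counts.items()},
            "insert_mean": insert_mean, "insert_sd": insert_sd,
            "min_distance": cfg.min_distance, "max_distance": cfg.max_distance,
        },
    )
    truth.save(out_dir / f"{name}.truth.json")
    return SimulatedPairs(sam_path, end1_path, end2_path, pair_config_path, cfg, truth)
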