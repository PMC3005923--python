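"""Readers and core data types for surface-resolved sequencing QC.

Every external representation the pipeline touches is handled here:

* FASTQ (basespace reads, quality-offset autodetection),
* csfasta + qual file pairs (SOLiD colorspace reads),
* SAM alignments (via pysam; uniqueness derived from the file itself),
* plain-text layout files describing the tile/panel arrangement of a
  sequencing surface,
* plain-text pair-configuration files for paired-end / mate-pair libraries,
* coordinate extraction from platform read identifiers.

The central idea is that every read identifier encodes where on the
two-dimensional sequencing surface the read was captured (tile/panel id
plus x/y within the tile).  Parsing those coordinates is what lets all
downstream statistics be mapped back onto the physical surface.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np
import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceCoordinate",
    "LayoutSpec",
    "ReadRecord",
    "AlignmentHit",
    "PairConfig",
    "SamData",
    "ReadIdError",
    "FormatError",
    "parse_illumina_read_id",
    "parse_solid_read_id",
    "normalize_read_id",
    "parse_layout_file",
    "write_layout_file",
    "builtin_layout",
    "parse_pair_config",
    "read_fastq",
    "read_csfasta",
    "read_sam",
    "FastqReader",
    "CsfastaReader",
]


class FormatError(ValueError):
    """A malformed input file (hard error; carries file/line context)."""


class ReadIdError(ValueError):
    """A read identifier from which no surface coordinate can be extracted."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SurfaceCoordinate:
    """Position of a read on the sequencing surface.

    ``tile_id`` keys into a :class:`LayoutSpec`; ``x``/``y`` are platform
    pixel/bead units within the tile, treated as 0-based.  ``mate`` is the
    end label (1/2 for paired reads, or a SOLiD tag such as ``"F3"``).
    """

    tile_id: str
    x: int
    y: int
    mate: Optional[Union[int, str]] = None


@dataclass
class LayoutSpec:
    """Arrangement of tiles/panels on a chip/slide, plus per-tile extents.

    ``tiles`` maps tile_id -> (row, col) grid position.  ``unused_regions``
    are grid positions excluded by assay design (e.g. slide corners); they
    render as missing data in every sample-level matrix.
    """

    platform_name: str
    n_rows: int
    n_cols: int
    tile_x_extent: int
    tile_y_extent: int
    tiles: dict[str, tuple[int, int]] = field(default_factory=dict)
    unused_regions: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.tile_x_extent <= 0 or self.tile_y_extent <= 0:
            raise FormatError("tile extents must be strictly positive")
        seen: dict[tuple[int, int], str] = {}
        for tid, (r, c) in self.tiles.items():
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise FormatError(
                    f"tile {tid!r} at ({r}, {c}) outside {self.n_rows}x{self.n_cols} grid"
                )
            if (r, c) in seen:
                raise FormatError(f"grid position ({r}, {c}) assigned twice")
            if (r, c) in self.unused_regions:
                raise FormatError(f"grid position ({r}, {c}) both used and unused")
            seen[(r, c)] = tid

    def position(self, tile_id: str) -> tuple[int, int]:
        return self.tiles[tile_id]

    @property
    def tile_ids(self) -> list[str]:
        return list(self.tiles)

    def tiles_in_row(self, row: int) -> list[str]:
        return [t for t, (r, _c) in self.tiles.items() if r == row]

    def tiles_in_col(self, col: int) -> list[str]:
        return [t for t, (_r, c) in self.tiles.items() if c == col]


@dataclass
class ReadRecord:
    """One sequencing read with its surface coordinate.

    ``symbols`` is over {A,C,G,T,N} for basespace reads, or over
    {0,1,2,3,.} for colorspace reads (the leading primer base of the raw
    colorspace record is kept separately in ``primer``).  'N' and '.' are
    no-calls: they count toward read totals but never toward composition
    denominators.  ``quals`` has one Phred score per called symbol.
    """

    read_id: str
    coord: Optional[SurfaceCoordinate]
    symbols: str
    quals: np.ndarray
    colorspace: bool = False
    primer: Optional[str] = None


@dataclass
class AlignmentHit:
    """One alignment of one read end.

    ``reference`` is None for recorded-unmapped reads (kept so that pair
    accounting can see orphaned ends).  ``unique`` means this read end
    aligned to exactly one location in the file.  ``mismatch_mask`` is in
    sequencing-cycle order (reverse-strand alignments are flipped back)."""

    read_id: str
    reference: Optional[str]
    start: int = -1
    strand: str = "+"
    mismatches: Optional[int] = None
    unique: bool = True
    mate: Optional[int] = None
    mismatch_mask: Optional[np.ndarray] = None


@dataclass
class PairConfig:
    """Expected paired-end library geometry: the two read files and the
    acceptable |separation| range in bp (closed interval)."""

    end1_file: str
    end2_file: str
    min_distance: int
    max_distance: int

    def __post_init__(self) -> None:
        if not (0 < self.min_distance < self.max_distance):
            raise FormatError(
                f"pair range must satisfy 0 < min < max, got "
                f"({self.min_distance}, {self.max_distance})"
            )


# ---------------------------------------------------------------------------
# Read-identifier parsing
# ---------------------------------------------------------------------------

_LEGACY_Y = re.compile(r"^(\d+)(?:#([^/\s]*))?(?:/(\d))?$")


def detect_illumina_dialect(id_string: str) -> str:
    """Return ``"casava"`` or ``"legacy"`` for an Illumina read id."""
    head = id_string.split(" ", 1)[0].split("\t", 1)[0]
    if head.count(":") == 6:
        return "casava"
    return "legacy"


def parse_illumina_read_id(id_string: str, dialect: Optional[str] = None) -> SurfaceCoordinate:
    """Extract (tile, x, y, mate) from an Illumina read identifier.

    Two dialects are supported and autodetected when ``dialect`` is None:

    * legacy  ``machine:lane:tile:x:y#index/mate``
    * CASAVA 1.8  ``instr:run:fc:lane:tile:x:y read:filter:0:index``

    Raises :class:`ReadIdError` for identifiers that match neither.
    """
    s = id_string.lstrip("@").strip()
    if not s:
        raise ReadIdError("empty read id")
    if dialect is None:
        dialect = detect_illumina_dialect(s)
    try:
        if dialect == "casava":
            head, _, tail = s.partition(" ")
            fields = head.split(":")
            if len(fields) != 7:
                raise ValueError("expected 7 colon fields")
            tile_id = fields[4]
            x, y = int(fields[5]), int(fields[6])
            mate: Optional[int] = None
            if tail:
                mate = int(tail.split(":", 1)[0])
            return SurfaceCoordinate(tile_id, x, y, mate)
        fields = s.split(" ", 1)[0].split(":")
        if len(fields) < 5:
            raise ValueError("expected >=5 colon fields")
        tile_id = fields[2]
        x = int(fields[3])
        m = _LEGACY_Y.match(fields[4])
        if m is None:
            raise ValueError(f"cannot parse y field {fields[4]!r}")
        y = int(m.group(1))
        mate = int(m.group(3)) if m.group(3) else None
        return SurfaceCoordinate(tile_id, x, y, mate)
    except (ValueError, IndexError) as exc:
        raise ReadIdError(f"unparseable Illumina read id {id_string!r}: {exc}") from exc


def parse_solid_read_id(id_string: str) -> SurfaceCoordinate:
    """Extract (panel, x, y, tag) from a SOLiD bead name like ``1_52_85_F3``."""
    s = id_string.lstrip(">").strip()
    parts = s.split("_")
    if len(parts) < 3:
        raise ReadIdError(f"unparseable SOLiD read id {id_string!r}")
    try:
        x, y = int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise ReadIdError(f"unparseable SOLiD read id {id_string!r}") from exc
    mate = "_".join(parts[3:]) if len(parts) > 3 else None
    return SurfaceCoordinate(parts[0], x, y, mate)


_MATE_SUFFIX = re.compile(r"/[12]$")
_INDEX_SUFFIX = re.compile(r"#[A-Za-z0-9]*$")
_SOLID_TAG = re.compile(r"_(F3|R3|F5(?:-[A-Za-z0-9]+)?)$")


def normalize_read_id(read_id: str) -> str:
    """Canonical read id used for cross-file matching.

    Strips everything after the first whitespace, then mate suffixes
    (``/1``, ``/2``), barcode-index suffixes (``#0``) and SOLiD tag
    suffixes (``_F3``, ``_R3``, ``_F5-P2``), so that the two ends of a
    pair and entries in user id lists collapse to one key.
    """
    s = read_id.lstrip("@>").split()[0] if read_id.strip() else ""
    s = _MATE_SUFFIX.sub("", s)
    s = _INDEX_SUFFIX.sub("", s)
    s = _SOLID_TAG.sub("", s)
    return s


# ---------------------------------------------------------------------------
# Layout files
# ---------------------------------------------------------------------------

def parse_layout_file(path: Union[str, Path]) -> LayoutSpec:
    """Parse a layout-definition file into a :class:`LayoutSpec`.

    Schema (ASCII, ``#`` comments)::

        platform: <name>
        rows: <int>
        cols: <int>
        tile_x: <int>
        tile_y: <int>
        <row> <col> <tile_id>
        <row> <col> - unused

    One body line per grid position; ``- unused`` marks a position
    excluded by assay design.
    """
    path = Path(path)
    header: dict[str, str] = {}
    tiles: dict[str, tuple[int, int]] = {}
    unused: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                header[key.strip().lower()] = value.strip()
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise FormatError(f"{path}:{lineno}: malformed layout line {raw!r}")
            try:
                r, c = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad grid position") from exc
            if len(parts) == 4:
                if parts[3].lower() != "unused":
                    raise FormatError(f"{path}:{lineno}: unknown flag {parts[3]!r}")
                unused.add((r, c))
                continue
            tid = parts[2]
            if tid == "-":
                raise FormatError(f"{path}:{lineno}: '-' tile without 'unused' flag")
            if tid in tiles:
                raise FormatError(f"{path}:{lineno}: duplicate tile id {tid!r}")
            tiles[tid] = (r, c)
    try:
        layout = LayoutSpec(
            platform_name=header.get("platform", path.stem),
            n_rows=int(header["rows"]),
            n_cols=int(header["cols"]),
            tile_x_extent=int(header["tile_x"]),
            tile_y_extent=int(header["tile_y"]),
            tiles=tiles,
            unused_regions=unused,
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing header key {exc}") from exc
    return layout


def write_layout_file(layout: LayoutSpec, path: Union[str, Path]) -> None:
    """Write ``layout`` in the schema understood by :func:`parse_layout_file`."""
    with open(path, "w") as fh:
        fh.write(f"platform: {layout.platform_name}\n")
        fh.write(f"rows: {layout.n_rows}\ncols: {layout.n_cols}\n")
        fh.write(f"tile_x: {layout.tile_x_extent}\ntile_y: {layout.tile_y_extent}\n")
        for tid, (r, c) in layout.tiles.items():
            fh.write(f"{r} {c} {tid}\n")
        for r, c in sorted(layout.unused_regions):
            fh.write(f"{r} {c} - unused\n")


def builtin_layout(name: str) -> LayoutSpec:
    """Construct one of the layouts shipped with the package.

    ``mini_20``
        5 rows x 4 columns of tiles (ids "1".."20"), 1000x1000 extent —
        a miniature single-lane flowcell used throughout the test suite.
    ``solid_corners``
        8 rows x 8 columns with the four corner positions unused by
        design, emulating a slide whose corners carry no assay.
    """
    if name == "mini_20":
        tiles = {str(r * 4 + c + 1): (r, c) for r in range(5) for c in range(4)}
        return LayoutSpec("mini_20", 5, 4, 1000, 1000, tiles)
    if name == "solid_corners":
        corners = {(0, 0), (0, 7), (7, 0), (7, 7)}
        tiles: dict[str, tuple[int, int]] = {}
        k = 1
        for r in range(8):
            for c in range(8):
                if (r, c) in corners:
                    continue
                tiles[str(k)] = (r, c)
                k += 1
        return LayoutSpec("solid_corners", 8, 8, 500, 500, tiles, corners)
    raise KeyError(f"unknown builtin layout {name!r}")


# ---------------------------------------------------------------------------
# Pair configuration
# ---------------------------------------------------------------------------

def parse_pair_config(path: Union[str, Path]) -> PairConfig:
    """Parse a pair-configuration file.

    The file has a ``pair: <END1> <END2>`` line naming the two read files
    and a ``range: <min> <max>`` line giving the expected minimum and
    maximum separation (bp) between the two ends of a fragment.
    """
    path = Path(path)
    pair_line: Optional[list[str]] = None
    range_line: Optional[list[str]] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.lower().startswith("pair:"):
                pair_line = line.split(":", 1)[1].split()
            elif line.lower().startswith("range:"):
                range_line = line.split(":", 1)[1].split()
            else:
                raise FormatError(f"{path}:{lineno}: unrecognized line {raw!r}")
    if pair_line is None or len(pair_line) != 2:
        raise FormatError(f"{path}: missing or malformed 'pair:' line")
    if range_line is None or len(range_line) != 2:
        raise FormatError(f"{path}: missing or malformed 'range:' line")
    try:
        lo, hi = int(range_line[0]), int(range_line[1])
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer range bounds") from exc
    if lo >= hi:
        raise FormatError(f"{path}: range min {lo} must be < max {hi}")
    return PairConfig(pair_line[0], pair_line[1], lo, hi)


# ---------------------------------------------------------------------------
# FASTQ reader
# ---------------------------------------------------------------------------

class FastqReader:
    """Iterate :class:`ReadRecord` from a 4-line FASTQ file.

    The Phred offset (+33 vs +64) is autodetected from the first
    ``detect_limit`` records; an ambiguous range defaults to +33 with a
    logged warning.  The read-id dialect is fixed from the first record.
    Reads whose identifiers carry no coordinate are counted in
    ``n_coordinateless`` and not yielded; the whole file is rejected only
    if more than half of the first 1000 identifiers fail.  x/y are
    re-based by subtracting the per-file minimum seen in the detection
    buffer.  Counters are final once iteration completes.
    """

    _DETECT_LIMIT = 10_000
    _REJECT_PROBE = 1000

    def __init__(self, path: Union[str, Path], layout: Optional[LayoutSpec] = None):
        self.path = Path(path)
        self.layout = layout
        self.encoding_offset: Optional[int] = None
        self.dialect: Optional[str] = None
        self.n_records = 0
        self.n_coordinateless = 0
        self.n_out_of_extent = 0
        self.n_unknown_tile = 0
        self._x0 = 0
        self._y0 = 0

    def _detect_offset(self, qual_strings: list[str]) -> int:
        lo = min((min(q) for q in qual_strings if q), default="I")
        if ord(lo) < 59:
            return 33
        if ord(lo) >= 64:
            return 64
        logger.warning("%s: ambiguous quality range, assuming Phred+33", self.path)
        return 33

    def _coord(self, title: str) -> Optional[SurfaceCoordinate]:
        try:
            return parse_illumina_read_id(title, self.dialect)
        except ReadIdError:
            self.n_coordinateless += 1
            return None

    def _finish(self, title: str, seq: str, qual: str,
                coord: Optional[SurfaceCoordinate]) -> Optional[ReadRecord]:
        if coord is None:
            return None
        coord.x = max(coord.x - self._x0, 0)
        coord.y = max(coord.y - self._y0, 0)
        if self.layout is not None:
            if coord.tile_id not in self.layout.tiles:
                self.n_unknown_tile += 1
            elif not (coord.x < self.layout.tile_x_extent
                      and coord.y < self.layout.tile_y_extent):
                self.n_out_of_extent += 1
        quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
        quals -= self.encoding_offset
        return ReadRecord(title.split()[0] if " " in title else title,
                          coord, seq.upper(), quals)

    def __iter__(self) -> Iterator[ReadRecord]:
        buffer: list[tuple[str, str, str]] = []
        with open(self.path) as fh:
            it = FastqGeneralIterator(fh)
            try:
                for rec in it:
                    buffer.append(rec)
                    if len(buffer) >= self._DETECT_LIMIT:
                        break
            except ValueError as exc:
                raise FormatError(f"{self.path}: truncated or malformed FASTQ: {exc}") from exc
            if not buffer:
                logger.warning("%s: empty FASTQ file", self.path)
                return
            self.encoding_offset = self._detect_offset([q for _, _, q in buffer])
            self.dialect = detect_illumina_dialect(buffer[0][0])

            probe = buffer[: self._REJECT_PROBE]
            coords = [self._coord(title) for title, _, _ in buffer]
            n_probe_fail = sum(1 for c in coords[: len(probe)] if c is None)
            if n_probe_fail * 2 > len(probe):
                raise FormatError(
                    f"{self.path}: {n_probe_fail}/{len(probe)} of leading read ids "
                    "carry no surface coordinate; wrong dialect or not a platform FASTQ"
                )
            good = [c for c in coords if c is not None]
            if good:
                self._x0 = min(c.x for c in good)
                self._y0 = min(c.y for c in good)

            for (title, seq, qual), coord in zip(buffer, coords):
                self.n_records += 1
                rec = self._finish(title, seq, qual, coord)
                if rec is not None:
                    yield rec
            try:
                for title, seq, qual in it:
                    self.n_records += 1
                    rec = self._finish(title, seq, qual, self._coord(title))
                    if rec is not None:
                        yield rec
            except ValueError as exc:
                raise FormatError(f"{self.path}: truncated or malformed FASTQ: {exc}") from exc


def read_fastq(path: Union[str, Path], layout: Optional[LayoutSpec] = None) -> FastqReader:
    """Open a FASTQ file as a stream of :class:`ReadRecord`."""
    return FastqReader(path, layout)


# ---------------------------------------------------------------------------
# csfasta + qual reader (SOLiD colorspace)
# ---------------------------------------------------------------------------

def _fasta_like(path: Path) -> Iterator[tuple[str, str]]:
    header: Optional[str] = None
    body: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(body)
                header = line[1:].strip()
                body = []
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence line before first header")
                body.append(line)
    if header is not None:
        yield header, "".join(body)


class CsfastaReader:
    """Iterate :class:`ReadRecord` from a SOLiD csfasta/qual file pair.

    Headers of the two files must pair up 1:1 in order; the first
    divergence is a hard error.  The leading primer base is kept as
    metadata and the remaining color codes become the record symbols.
    """

    def __init__(self, csfasta_path: Union[str, Path], qual_path: Union[str, Path],
                 layout: Optional[LayoutSpec] = None):
        self.csfasta_path = Path(csfasta_path)
        self.qual_path = Path(qual_path)
        self.layout = layout
        self.n_records = 0
        self.n_coordinateless = 0
        self.n_out_of_extent = 0
        self.n_unknown_tile = 0

    def __iter__(self) -> Iterator[ReadRecord]:
        seqs = _fasta_like(self.csfasta_path)
        quals = _fasta_like(self.qual_path)
        sentinel = object()
        while True:
            s = next(seqs, sentinel)
            q = next(quals, sentinel)
            if s is sentinel and q is sentinel:
                return
            if s is sentinel or q is sentinel:
                short = self.csfasta_path if s is sentinel else self.qual_path
                raise FormatError(f"{short}: fewer records than its partner file")
            (sh, sbody), (qh, qbody) = s, q
            if sh != qh:
                raise FormatError(
                    f"csfasta/qual header mismatch: {sh!r} vs {qh!r}"
                )
            self.n_records += 1
            if not sbody or sbody[0].upper() not in "ACGT":
                raise FormatError(f"{self.csfasta_path}: record {sh!r} lacks a primer base")
            primer, colors = sbody[0].upper(), sbody[1:]
            qvals = np.array([int(v) for v in qbody.split()], dtype=np.int16)
            if len(qvals) != len(colors):
                raise FormatError(
                    f"record {sh!r}: {len(colors)} color calls but {len(qvals)} quality values"
                )
            try:
                coord = parse_solid_read_id(sh)
            except ReadIdError:
                self.n_coordinateless += 1
                continue
            if self.layout is not None:
                if coord.tile_id not in self.layout.tiles:
                    self.n_unknown_tile += 1
                elif not (coord.x < self.layout.tile_x_extent
                          and coord.y < self.layout.tile_y_extent):
                    self.n_out_of_extent += 1
            yield ReadRecord(sh, coord, colors, qvals, colorspace=True, primer=primer)


def read_csfasta(csfasta_path: Union[str, Path], qual_path: Union[str, Path],
                 layout: Optional[LayoutSpec] = None) -> CsfastaReader:
    """Open a csfasta/qual pair as a stream of colorspace :class:`ReadRecord`."""
    return CsfastaReader(csfasta_path, qual_path, layout)


# ---------------------------------------------------------------------------
# SAM reader
# ---------------------------------------------------------------------------

@dataclass
class SamData:
    """All alignment hits of a SAM file plus the reference dictionary.

    ``n_missing_nm`` counts mapped records without an NM tag (their
    mismatch count is unknown and excluded from mismatch-criterion
    tallies, but the hits themselves are kept)."""

    hits: list[AlignmentHit]
    references: dict[str, int]
    n_missing_nm: int = 0
    n_unmapped: int = 0


def _mate_of(read: "pysam.AlignedSegment") -> Optional[int]:
    if read.is_paired:
        return 1 if read.is_read1 else 2
    m = _MATE_SUFFIX.search(read.query_name)
    return int(m.group(0)[1]) if m else None


def _mismatch_mask(read: "pysam.AlignedSegment") -> Optional[np.ndarray]:
    if not read.has_tag("MD") or read.query_length == 0:
        return None
    mask = np.zeros(read.query_length, dtype=bool)
    for qpos, _rpos, ref_base in read.get_aligned_pairs(with_seq=True):
        if qpos is not None and ref_base is not None and ref_base.islower():
            mask[qpos] = True
    if read.is_reverse:
        mask = mask[::-1].copy()  # back to sequencing-cycle order
    return mask


def read_sam(path: Union[str, Path]) -> SamData:
    """Load a SAM file into :class:`AlignmentHit` records.

    A hit is *unique* iff its (read id, mate) maps to exactly one location
    in the file — a single-pass tally that is agnostic to aligner-specific
    tags.  Unmapped records are kept with ``reference=None`` so that
    paired-end accounting can classify orphaned ends.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    mapped_count: dict[tuple[str, Optional[int]], int] = {}
    n_missing_nm = 0
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        references = dict(zip(sam.references, sam.lengths))
        for read in sam:
            # secondary/supplementary records are real hits of the same
            # read and enter the uniqueness tally like any other
            mate = _mate_of(read)
            if read.is_unmapped:
                n_unmapped += 1
                hits.append(AlignmentHit(read.query_name, None, mate=mate))
                continue
            key = (read.query_name, mate)
            mapped_count[key] = mapped_count.get(key, 0) + 1
            if read.has_tag("NM"):
                nm: Optional[int] = int(read.get_tag("NM"))
            else:
                nm = None
                n_missing_nm += 1
            hits.append(AlignmentHit(
                read_id=read.query_name,
                reference=read.reference_name,
                start=read.reference_start,
                strand="-" if read.is_reverse else "+",
                mismatches=nm,
                unique=True,  # fixed below
                mate=mate,
                mismatch_mask=_mismatch_mask(read),
            ))
    for h in hits:
        if h.reference is not None:
            h.unique = mapped_count[(h.read_id, h.mate)] == 1
    return SamData(hits, references, n_missing_nm, n_unmapped)
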