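"""Readers, identifier parsing and layout/pair-config files."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surfqc import formats
from surfqc.formats import (FormatError, PairConfig, ReadIdError,
                            parse_illumina_read_id, parse_layout_file,
                            parse_pair_config, parse_solid_read_id,
                            read_csfasta, read_fastq, read_sam)


@pytest.mark.parametrize("rid, tile, x, y, mate", [
    ("HWUSI-EAS100R:6:73:941:1973#0/1", "73", 941, 1973, 1),
    ("M1:RUN:FC:1:1101:5:7 1:N:0:ACGT", "1101", 5, 7, 1),
    ("MACHINE:3:12:100:200", "12", 100, 200, None),
    ("@MACHINE:3:12:100:200#ACGT/2", "12", 100, 200, 2),
])
def test_illumina_id_dialects(rid, tile, x, y, mate):
    c = parse_illumina_read_id(rid)
    assert (c.tile_id, c.x, c.y, c.mate) == (tile, x, y, mate)


@pytest.mark.parametrize("rid, tile, x, y, mate", [
    (">1_52_85_F3", "1", 52, 85, "F3"),
    (">429_1003_22_R3", "429", 1003, 22, "R3"),
    ("7_10_20", "7", 10, 20, None),
])
def test_solid_id(rid, tile, x, y, mate):
    c = parse_solid_read_id(rid)
    assert (c.tile_id, c.x, c.y, c.mate) == (tile, x, y, mate)


@pytest.mark.parametrize("parser, bad", [
    (parse_illumina_read_id, "noCoordsHere"),
    (parse_illumina_read_id, "a:b"),
    (parse_solid_read_id, ">1_52"),
])
def test_coordinateless_ids_raise(parser, bad):
    with pytest.raises(ReadIdError):
        parser(bad)


@given(tile=st.integers(1, 999), x=st.integers(0, 99999),
       y=st.integers(0, 99999), mate=st.integers(1, 2))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_id_round_trip_property(tile, x, y, mate):
    """Coordinates embedded in any supported dialect re-parse exactly."""
    legacy = f"M:1:{tile}:{x}:{y}#0/{mate}"
    casava = f"I:1:FC:2:{tile}:{x}:{y} {mate}:N:0:ACGT"
    solid = f"{tile}_{x}_{y}_F3"
    for rid, parser in ((legacy, parse_illumina_read_id),
                        (casava, parse_illumina_read_id)):
        c = parser(rid)
        assert (c.tile_id, c.x, c.y, c.mate) == (str(tile), x, y, mate)
    c = parse_solid_read_id(solid)
    assert (c.tile_id, c.x, c.y) == (str(tile), x, y)


@pytest.mark.parametrize("rid, expected", [
    ("HWUSI:6:73:941:1973#0/1", "HWUSI:6:73:941:1973"),
    ("HWUSI:6:73:941:1973#0/2", "HWUSI:6:73:941:1973"),
    ("1_52_85_F3", "1_52_85"),
    ("1_52_85_R3", "1_52_85"),
    ("M1:RUN:FC:1:1101:5:7 1:N:0:ACGT", "M1:RUN:FC:1:1101:5:7"),
])
def test_normalize_read_id(rid, expected):
    assert formats.normalize_read_id(rid) == expected


def test_layout_file_round_trip(tmp_path):
    text = """\
platform: demo
rows: 3
cols: 2
tile_x: 1000
tile_y: 2000
0 0 t1
0 1 t2
1 0 t3
1 1 t4
2 0 t5
2 1 t6
"""
    p = tmp_path / "demo.tile"
    p.write_text(text)
    lay = parse_layout_file(p)
    assert len(lay.tiles) == 6
    assert lay.position("t1") == (0, 0) and lay.position("t6") == (2, 1)
    assert (lay.tile_x_extent, lay.tile_y_extent) == (1000, 2000)
    p2 = tmp_path / "copy.tile"
    formats.write_layout_file(lay, p2)
    again = parse_layout_file(p2)
    assert again.tiles == lay.tiles and again.unused_regions == lay.unused_regions


def test_layout_unused_corners(tmp_path):
    p = tmp_path / "c.tile"
    p.write_text("platform: c\nrows: 2\ncols: 2\ntile_x: 10\ntile_y: 10\n"
                 "0 0 a\n0 1 b\n1 0 c\n1 1 - unused\n")
    lay = parse_layout_file(p)
    assert lay.unused_regions == {(1, 1)}


@pytest.mark.parametrize("body", [
    "platform: d\nrows: 1\ncols: 2\ntile_x: 10\ntile_y: 10\n0 0 a\n0 1 a\n",  # dup id
    "platform: d\nrows: 1\ncols: 1\ntile_x: 0\ntile_y: 10\n0 0 a\n",          # bad extent
    "platform: d\nrows: 1\ncols: 1\ntile_x: 10\ntile_y: 10\nnot a line here x\n",
])
def test_layout_errors(tmp_path, body):
    p = tmp_path / "bad.tile"
    p.write_text(body)
    with pytest.raises(FormatError):
        parse_layout_file(p)


def test_pair_config(tmp_path):
    p = tmp_path / "x.pair"
    p.write_text("pair: end1.fq end2.fq\nrange: 500 5000\n")
    cfg = parse_pair_config(p)
    assert cfg == PairConfig("end1.fq", "end2.fq", 500, 5000)


@pytest.mark.parametrize("body", [
    "pair: a b\nrange: 5000 500\n",
    "pair: a b\n",
    "range: 1 2\n",
])
def test_pair_config_errors(tmp_path, body):
    p = tmp_path / "x.pair"
    p.write_text(body)
    with pytest.raises(FormatError):
        parse_pair_config(p)


def test_fastq_reader_counts_and_offset(tmp_path, mini_layout):
    p = tmp_path / "r.fastq"
    p.write_text(
        "@M:1:1:10:20#0/1\nACGTN\n+\nIIII#\n"
        "@M:1:2:30:40#0/1\nTTTTT\n+\n!!!!!\n"
        "@noCoordsHere\nAAAAA\n+\nIIIII\n")
    reader = read_fastq(p, mini_layout)
    recs = list(reader)
    assert reader.encoding_offset == 33  # '!' forces Phred+33
    assert reader.n_records == 3
    assert len(recs) == 2 and reader.n_coordinateless == 1
    assert recs[0].symbols == "ACGTN"
    assert list(recs[1].quals) == [0] * 5
    # x/y re-based against the per-file minimum
    assert (recs[0].coord.x, recs[0].coord.y) == (0, 0)
    assert (recs[1].coord.x, recs[1].coord.y) == (20, 20)


def test_fastq_truncated_is_hard_error(tmp_path):
    p = tmp_path / "t.fastq"
    p.write_text("@M:1:1:10:20\nACGT\n+\n")
    with pytest.raises(FormatError):
        list(read_fastq(p))


def test_fastq_empty_file_is_empty_stream(tmp_path):
    p = tmp_path / "e.fastq"
    p.write_text("")
    assert list(read_fastq(p)) == []


def test_csfasta_qual_pairing(tmp_path):
    cs = tmp_path / "a.csfasta"
    q = tmp_path / "a.qual"
    cs.write_text("# comment\n>1_5_6_F3\nT0123.01\n>2_7_8_F3\nT0000000\n")
    q.write_text("# comment\n>1_5_6_F3\n10 11 12 13 14 15 16\n"
                 ">2_7_8_F3\n9 9 9 9 9 9 9\n")
    recs = list(read_csfasta(cs, q))
    assert len(recs) == 2
    r = recs[0]
    assert r.primer == "T" and r.symbols == "0123.01" and r.colorspace
    assert list(r.quals) == [10, 11, 12, 13, 14, 15, 16]
    assert (r.coord.tile_id, r.coord.x, r.coord.y) == ("1", 5, 6)


def test_csfasta_count_mismatch(tmp_path):
    cs = tmp_path / "a.csfasta"
    q = tmp_path / "a.qual"
    cs.write_text(">1_5_6_F3\nT012\n>2_7_8_F3\nT000\n>3_1_1_F3\nT111\n")
    q.write_text(">1_5_6_F3\n1 2 3\n>2_7_8_F3\n4 5 6\n")
    with pytest.raises(FormatError):
        list(read_csfasta(cs, q))


def test_csfasta_header_mismatch(tmp_path):
    cs = tmp_path / "a.csfasta"
    q = tmp_path / "a.qual"
    cs.write_text(">1_5_6_F3\nT012\n")
    q.write_text(">9_9_9_F3\n1 2 3\n")
    with pytest.raises(FormatError, match="1_5_6_F3"):
        list(read_csfasta(cs, q))


SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"


def test_read_sam_mask_and_uniqueness(tmp_path):
    p = tmp_path / "a.sam"
    p.write_text(
        SAM_HEADER
        + "r1\t0\tchr1\t101\t60\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII\tNM:i:2\tMD:Z:2C4G2\n"
        + "r2\t0\tchr1\t11\t0\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII\tNM:i:0\tMD:Z:10\n"
        + "r2\t256\tchr1\t51\t0\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII\tNM:i:0\tMD:Z:10\n"
        + "r3\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\tIIII\n")
    sam = read_sam(p)
    assert sam.references == {"chr1": 1000}
    h1 = next(h for h in sam.hits if h.read_id == "r1")
    assert h1.mismatches == 2 and h1.unique
    assert h1.mismatch_mask.sum() == 2
    assert list(np.nonzero(h1.mismatch_mask)[0]) == [2, 7]
    assert h1.start == 100  # 0-based
    assert all(not h.unique for h in sam.hits if h.read_id == "r2")
    h3 = next(h for h in sam.hits if h.read_id == "r3")
    assert h3.reference is None
    assert sam.n_unmapped == 1


def test_read_sam_reverse_mask_is_cycle_ordered(tmp_path):
    # mismatch at the last stored base of a reverse alignment = cycle 0
    p = tmp_path / "r.sam"
    p.write_text(SAM_HEADER
                 + "r1\t16\tchr1\t1\t60\t6M\t*\t0\t0\tAAAAAA\tIIIIII\tNM:i:1\tMD:Z:5C0\n")
    sam = read_sam(p)
    mask = sam.hits[0].mismatch_mask
    assert list(np.nonzero(mask)[0]) == [0]


def test_generated_files_parse_losslessly(flat_flowcell, mini_layout):
    """Conservation: records in == records out + counted errors."""
    reader = read_fastq(flat_flowcell.paths["fastq"], mini_layout)
    recs = list(reader)
    assert reader.n_records == len(recs) + reader.n_coordinateless
    assert reader.n_coordinateless == 0
    assert len(recs) == 5000
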