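"""Pair classification, distances and bookkeeping."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surfqc.formats import AlignmentHit, PairConfig
from surfqc.pairs import (PairCategory, classify_pair, pair_distance, pair_up,
                          summarize_pairs)

CFG = PairConfig("e1", "e2", 500, 5000)


def hit(ref="chr1", start=0, strand="+", unique=True, mate=None):
    return AlignmentHit("r", ref, start, strand, 0, unique, mate)


@pytest.mark.parametrize("s1, s2, expected", [
    (100, 600, -500),
    (5000, 100, 4900),
    (250, 250, 0),
])
def test_pair_distance_formula(s1, s2, expected):
    assert pair_distance(hit(start=s1), hit(start=s2)) == expected


def test_pair_distance_needs_same_reference():
    with pytest.raises(ValueError):
        pair_distance(hit(ref="chr1"), hit(ref="chr2"))


@given(st.integers(0, 10**6), st.integers(0, 10**6))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_pair_distance_antisymmetry(a, b):
    assert pair_distance(hit(start=a), hit(start=b)) == -pair_distance(
        hit(start=b), hit(start=a))


@pytest.mark.parametrize("e1, e2, expected", [
    (hit("chr1", 1000, "+"), hit("chr1", 2500, "-"), PairCategory.GOOD_PAIR),
    (hit("chr1"), hit("chr7"), PairCategory.DIFFERENT_CHROMOSOME),
    (hit("chr1", 0, "+"), hit("chr1", 1000, "+"), PairCategory.WRONG_ORIENTATION),
    (hit("chr1", 0, "+"), hit("chr1", 200, "-"), PairCategory.BELOW_RANGE),
    (hit("chr1", 0, "+"), hit("chr1", 6000, "-"), PairCategory.ABOVE_RANGE),
    (hit("chr1", 0, "+"), hit("chr1", 500, "-"), PairCategory.GOOD_PAIR),   # closed
    (hit("chr1", 5000, "+"), hit("chr1", 0, "-"), PairCategory.GOOD_PAIR),  # bounds
    (hit(), None, PairCategory.UNPAIRED_FORWARD),
    (None, hit(), PairCategory.UNPAIRED_REVERSE),
    (hit(), AlignmentHit("r", None), PairCategory.UNPAIRED_FORWARD),
    (hit(unique=False), hit("chr1", 1000, "-"), PairCategory.UNPAIRED_REVERSE),
    (None, None, None),
])
def test_classify_pair_examples(e1, e2, expected):
    assert classify_pair(e1, e2, CFG) is expected


def test_same_orientation_convention():
    e1, e2 = hit("chr1", 0, "+"), hit("chr1", 1000, "+")
    assert classify_pair(e1, e2, CFG, orientation="same") is PairCategory.GOOD_PAIR
    e2b = hit("chr1", 1000, "-")
    assert classify_pair(e1, e2b, CFG, orientation="same") is PairCategory.WRONG_ORIENTATION


# ---- independent decision-table oracle -----------------------------------

_ORACLE = {
    # (end1 usable, end2 usable, same ref, same strand, stratum) -> category
}
for u1, u2 in itertools.product([False, True], repeat=2):
    for same_ref in (False, True):
        for same_strand in (False, True):
            for stratum in ("below", "inside", "above"):
                key = (u1, u2, same_ref, same_strand, stratum)
                if not u1 and not u2:
                    _ORACLE[key] = None
                elif u1 and not u2:
                    _ORACLE[key] = PairCategory.UNPAIRED_FORWARD
                elif u2 and not u1:
                    _ORACLE[key] = PairCategory.UNPAIRED_REVERSE
                elif not same_ref:
                    _ORACLE[key] = PairCategory.DIFFERENT_CHROMOSOME
                elif same_strand:
                    _ORACLE[key] = PairCategory.WRONG_ORIENTATION
                elif stratum == "below":
                    _ORACLE[key] = PairCategory.BELOW_RANGE
                elif stratum == "above":
                    _ORACLE[key] = PairCategory.ABOVE_RANGE
                else:
                    _ORACLE[key] = PairCategory.GOOD_PAIR


def _end_states():
    # mapped/unmapped x unique/multi x 2 refs x 2 strands = 16 states per end
    for kind in ("mapped", "unmapped"):
        for unique in (True, False):
            for ref in ("chrA", "chrB"):
                for strand in ("+", "-"):
                    yield kind, unique, ref, strand


def test_classifier_agrees_with_decision_table_everywhere():
    """Exhaustive agreement with an independent lookup-table oracle
    over all 16 x 16 x 6 = 1536 small configurations."""
    distances = {"zero": 0, "below": 200, "at_min": 500, "inside": 2000,
                 "at_max": 5000, "above": 9000}
    checked = 0
    for st1, st2 in itertools.product(_end_states(), repeat=2):
        for dname, d in distances.items():
            k1, uq1, r1, s1 = st1
            k2, uq2, r2, s2 = st2
            e1 = (AlignmentHit("r", None) if k1 == "unmapped" else
                  AlignmentHit("r", r1, 1000, s1, 0, uq1))
            e2 = (AlignmentHit("r", None) if k2 == "unmapped" else
                  AlignmentHit("r", r2, 1000 + d, s2, 0, uq2))
            u1 = k1 == "mapped" and uq1
            u2 = k2 == "mapped" and uq2
            stratum = ("below" if d < 500 else "above" if d > 5000 else "inside")
            key = (u1, u2,
                   (r1 == r2) if (u1 and u2) else True,
                   (s1 == s2) if (u1 and u2) else True,
                   stratum)
            assert classify_pair(e1, e2, CFG) is _ORACLE[key]
            checked += 1
    assert checked == 1536


def test_every_pair_contributes_exactly_one_category():
    """Fuzz: exhaustiveness and exclusivity over random configurations."""
    rng = np.random.default_rng(7)
    pairs = []
    for _ in range(500):
        ends = []
        for _e in range(2):
            kind = rng.integers(0, 3)
            if kind == 0:
                ends.append(None)
            elif kind == 1:
                ends.append(AlignmentHit("r", None))
            else:
                ends.append(AlignmentHit(
                    "r", rng.choice(["chr1", "chr2"]), int(rng.integers(0, 10_000)),
                    rng.choice(["+", "-"]), 0, bool(rng.integers(0, 2))))
        pairs.append(tuple(ends))
    summary = summarize_pairs(pairs, CFG)
    assert summary.n_classified + summary.both_unmapped == 500


def test_summarize_exact_bookkeeping_and_histograms(tmp_path):
    from surfqc.formats import read_sam
    from surfqc.synthetic import generate_pairs

    counts = {PairCategory.GOOD_PAIR: 700, PairCategory.UNPAIRED_FORWARD: 60,
              PairCategory.UNPAIRED_REVERSE: 40,
              PairCategory.DIFFERENT_CHROMOSOME: 100,
              PairCategory.WRONG_ORIENTATION: 50, PairCategory.BELOW_RANGE: 80,
              PairCategory.ABOVE_RANGE: 70}
    sim = generate_pairs(counts, out_dir=tmp_path, seed=13)
    summary = summarize_pairs(pair_up(read_sam(sim.sam_path).hits).values(),
                              sim.config)
    assert summary.counts == counts
    assert summary.n_classified == 1100
    assert summary.chimera_fraction == pytest.approx(150 / 1100)
    # strand-split totals balanced within binomial bounds (p=1/2, n=700)
    np_, nm = (sum(summary.distance_histogram_plus.values()),
               sum(summary.distance_histogram_minus.values()))
    assert np_ + nm == 700
    assert abs(np_ - 350) < 5 * np.sqrt(700 * 0.25)
    # signs follow the first end's strand by construction
    assert all(k < 0 for k in summary.distance_histogram_plus)
    assert all(k >= 0 for k in summary.distance_histogram_minus)


def test_insert_distribution_recovered(tmp_path):
    from surfqc.formats import read_sam
    from surfqc.synthetic import generate_pairs

    sim = generate_pairs({PairCategory.GOOD_PAIR: 4000}, out_dir=tmp_path,
                         seed=17, insert_mean=2000, insert_sd=300)
    summary = summarize_pairs(pair_up(read_sam(sim.sam_path).hits).values(),
                              sim.config, hist_bin=50)
    d = np.concatenate([
        np.repeat(list(summary.distance_histogram_plus.keys()),
                  list(summary.distance_histogram_plus.values())),
        np.repeat(list(summary.distance_histogram_minus.keys()),
                  list(summary.distance_histogram_minus.values()))])
    mean_abs = np.abs(d + 25).mean()  # bin centers
    assert abs(mean_abs - 2000) < 3 * 300 / np.sqrt(4000) + 50
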