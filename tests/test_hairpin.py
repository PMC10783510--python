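"""Hairpin maximum-pairing DP against an exhaustive-enumeration oracle."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from g4switch import SequenceRecord, max_hairpin_pairs, stem_report

_GC = {("G", "C"), ("C", "G")}
_AT = {("A", "T"), ("T", "A")}


def brute_max_pairs(seq: str, min_loop: int = 1, count_at: bool = False) -> int:
    """Independent oracle: enumerate every nested pairing recursively.

    No memoization and no tabulation — a direct exhaustive walk over all
    non-crossing pairings of the interval, feasible for short sequences.
    """

    def pairable(a, b):
        return (a, b) in _GC or (count_at and (a, b) in _AT)

    def best(i, j):
        if j - i <= min_loop:
            return 0
        top = best(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if pairable(seq[i], seq[k]):
                top = max(top, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return top

    return best(0, len(seq) - 1)


def _valid(fold):
    pairs = fold.pairing
    for i, j in pairs:
        assert i < j and j - i - 1 >= fold.min_loop
        couple = (fold.seq[i], fold.seq[j])
        assert couple in _GC or (fold.count_at and couple in _AT)
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            (i, j), (k, l) = pairs[a], pairs[b]
            assert not (i < k < j < l) and not (k < i < l < j), "crossing pair"
    flat = [x for p in pairs for x in p]
    assert len(flat) == len(set(flat)), "base paired twice"


def test_cebm5_pairing_capacity_is_nine(ceb):
    """CEBm5 can form up to 9 G-C pairs; 9 == its total cytosine count."""
    fold = max_hairpin_pairs(ceb["CEBm5"], min_loop=1)
    assert fold.max_pairs == 9
    assert fold.max_pairs == min(ceb["CEBm5"].seq.count("G"), ceb["CEBm5"].seq.count("C"))
    _valid(fold)  # returned pairing proves attainability


def test_cebm6_pairing_capacity_is_nine(ceb):
    assert max_hairpin_pairs(ceb["CEBm6"], min_loop=1).max_pairs == 9


def test_forced_stem():
    fold = max_hairpin_pairs(SequenceRecord("x", "GGGAAACCC"), min_loop=3)
    assert fold.max_pairs == 3
    assert fold.dot_bracket == "(((...)))"


def test_no_complement_no_pairs():
    fold = max_hairpin_pairs(SequenceRecord("x", "GGGGGG"), min_loop=1)
    assert fold.max_pairs == 0 and fold.dot_bracket == "......"


def test_too_short_sequence_folds_to_zero_pairs():
    assert max_hairpin_pairs(SequenceRecord("x", "GC"), min_loop=3).max_pairs == 0


def test_cebm5_min_loop_three_matches_oracle(ceb):
    seq = ceb["CEBm5"].seq
    fold = max_hairpin_pairs(ceb["CEBm5"], min_loop=3)
    assert fold.max_pairs == brute_max_pairs(seq, min_loop=3)
    assert fold.max_pairs < 9  # the capacity needs the min_loop=1 relaxation


@settings(deadline=None, derandomize=True, max_examples=150)
@given(
    st.text(alphabet="ACGT", min_size=2, max_size=14),
    st.integers(min_value=1, max_value=4),
    st.booleans(),
)
def test_dp_equals_exhaustive_enumeration(seq, min_loop, count_at):
    fold = max_hairpin_pairs(SequenceRecord("s", seq), min_loop=min_loop, count_at=count_at)
    assert fold.max_pairs == brute_max_pairs(seq, min_loop, count_at)
    _valid(fold)


def test_dp_equals_oracle_up_to_length_18():
    rng = random.Random(42)
    for _ in range(40):
        n = rng.randint(15, 18)
        seq = "".join(rng.choice("ACGT") for _ in range(n))
        got = max_hairpin_pairs(SequenceRecord("s", seq), min_loop=1).max_pairs
        assert got == brute_max_pairs(seq, min_loop=1)


def test_gc_rich_oracle_spot_check():
    for seq in ["GCGCGCGCGCGCGCGC", "GGGGCCCCGGGGCCCC", "CCCGGGCCCGGGCCCG"]:
        got = max_hairpin_pairs(SequenceRecord("s", seq), min_loop=1).max_pairs
        assert got == brute_max_pairs(seq, min_loop=1)


@settings(deadline=None, derandomize=True, max_examples=80)
@given(st.text(alphabet="ACGT", min_size=4, max_size=16))
def test_monotone_in_min_loop_and_bounded(seq):
    rec = SequenceRecord("s", seq)
    counts = [max_hairpin_pairs(rec, min_loop=m).max_pairs for m in (1, 2, 3, 4)]
    assert counts == sorted(counts, reverse=True)
    assert counts[0] <= min(seq.count("G"), seq.count("C"))


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.text(alphabet="ACGT", min_size=4, max_size=14), st.text(alphabet="ACGT", min_size=1, max_size=4))
def test_appending_bases_never_decreases_capacity(seq, extra):
    a = max_hairpin_pairs(SequenceRecord("s", seq), min_loop=1).max_pairs
    b = max_hairpin_pairs(SequenceRecord("s", seq + extra), min_loop=1).max_pairs
    assert b >= a


def test_stem_report_simple_hairpin():
    fold = max_hairpin_pairs(SequenceRecord("x", "GGGAAACCC"), min_loop=3)
    report = stem_report(fold)
    assert len(report["stems"]) == 1
    assert report["stems"][0].length == 3
    assert report["hairpin_loops"] == [3]
    assert report["dangling_ends"] == (0, 0)


def test_stem_report_cebm5_capacity_fold(ceb):
    fold = max_hairpin_pairs(ceb["CEBm5"], min_loop=1)
    report = stem_report(fold)
    assert sum(s.length for s in report["stems"]) == 9
    assert [s.length for s in report["stems"]] == [3, 3, 3]


def test_stem_report_empty_pairing():
    fold = max_hairpin_pairs(SequenceRecord("x", "AAAA"), min_loop=1)
    report = stem_report(fold)
    assert report["stems"] == [] and report["hairpin_loops"] == []


def test_dangling_ends_reported():
    fold = max_hairpin_pairs(SequenceRecord("x", "TTGGGAAACCCTT"), min_loop=3)
    assert stem_report(fold)["dangling_ends"] == (2, 2)


def test_min_loop_validation():
    with pytest.raises(ValueError):
        max_hairpin_pairs(SequenceRecord("x", "GAC"), min_loop=0)
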