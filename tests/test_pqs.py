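"""PQS motif detection: class grammars, strand symmetry, planted genomes."""

import random
import warnings

import pytest
from hypothesis import given, settings, strategies as st

from g4switch import (
    FixtureSpec,
    SequenceRecord,
    census,
    find_pqs,
    reverse_complement,
    synth_genome,
)


def test_cebwt_is_a_long_loop_pqs(ceb):
    hits = find_pqs(ceb["CEBwt"], both_strands=False)
    assert len(hits) == 1
    h = hits[0]
    assert h.motif_class == "long_loop"
    assert len(h.tracts) == 4
    assert all(e - s == 3 for s, e in h.tracts)  # four GGG tracts
    assert h.loop_lengths == (1, 9, 1)  # 9-nt central loop


def test_minimal_classical_motif():
    hits = find_pqs(SequenceRecord("x", "GGGTGGGTGGGTGGG"), both_strands=False)
    assert len(hits) == 1
    h = hits[0]
    assert h.motif_class == "classical"
    assert (h.start, h.end) == (0, 15)
    assert h.loop_lengths == (1, 1, 1)


def test_no_g_runs_no_hits():
    assert find_pqs(SequenceRecord("x", "ACGTACGTACGT")) == []


def test_cebm7_still_matches_the_motif_grammar(ceb):
    """Motif classes are sequence-only: CEBm7 is a PQS even though it
    folds as a hairpin — regime assignment is the classifier's job."""
    hits = find_pqs(ceb["CEBm7"], both_strands=False)
    assert [h.motif_class for h in hits] == ["long_loop"]


def test_bulged_motif_detection():
    # fourth tract is GG·G with a 1-nt bulge
    seq = "GGGAGGGAGGGAGGAG"
    hits = find_pqs(SequenceRecord("x", seq), both_strands=False)
    assert [h.motif_class for h in hits] == ["bulged"]
    assert hits[0].end == len(seq)


def test_vacancy_motif_detection():
    seq = "GGGAGGGAGGGAGG"
    hits = find_pqs(SequenceRecord("x", seq), both_strands=False)
    assert [h.motif_class for h in hits] == ["vacancy"]


def test_class_precedence_reports_single_class_per_locus():
    # a classical locus trivially contains vacancy/bulged sub-grammars once
    # extra short G-runs are around; default output keeps one class
    seq = "GGGTGGGTGGGTGGGTTGG"
    hits = find_pqs(SequenceRecord("x", seq), both_strands=False)
    assert len(hits) == 1 and hits[0].motif_class == "classical"


def test_minus_strand_hit_is_c_motif_on_forward(ceb):
    rc = ceb["CEBwt"].reverse_complement()
    hits = find_pqs(rc, both_strands=True)
    assert len(hits) == 1
    assert hits[0].strand == "-"
    assert hits[0].motif_class == "long_loop"
    assert "CCC" in hits[0].seq


def test_relaxing_loop_bound_never_removes_classical_hits():
    rng = random.Random(5)
    for _ in range(50):
        seq = "".join(rng.choice("ACGT") for _ in range(120))
        rec = SequenceRecord("r", seq)
        classical = find_pqs(rec, classes=["classical"], report_all=True)
        both = find_pqs(rec, classes=["classical", "long_loop"], report_all=True)
        spans = {(h.start, h.end, h.strand) for h in both if h.motif_class == "classical"}
        assert all((h.start, h.end, h.strand) in spans for h in classical)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.text(alphabet="ACGT", min_size=20, max_size=120))
def test_strand_symmetry(seq):
    """Plus-only hits on the reverse complement mirror minus hits."""
    rec = SequenceRecord("g", seq)
    fwd = find_pqs(rec, both_strands=True, report_all=True)
    minus = {
        (len(seq) - h.end, len(seq) - h.start, h.motif_class)
        for h in fwd
        if h.strand == "-"
    }
    rc_plus = {
        (h.start, h.end, h.motif_class)
        for h in find_pqs(rec.reverse_complement(), both_strands=False, report_all=True)
    }
    assert minus == rc_plus


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.text(alphabet="ACGT", min_size=15, max_size=100))
def test_every_hit_rematches_its_class(seq):
    for hit in find_pqs(SequenceRecord("g", seq)):
        hit.validate()


def test_planted_genome_recall_and_false_positive_audit():
    spec = FixtureSpec(
        genome_length=30_000,
        planted=(("classical", 5), ("long_loop", 5), ("bulged", 5), ("vacancy", 5)),
        background_gc=0.4,
        seed=11,
    )
    genome, truth = synth_genome(spec)
    hits = find_pqs(genome)
    got = [(h.start, h.end, h.motif_class) for h in hits]
    want = [(s, e, c) for _, s, e, c in truth]
    assert got == want  # 100% recall, zero off-truth hits, classes correct


def test_census_on_ceb_family(ceb):
    hits = []
    for rec in ceb.values():
        hits.extend(find_pqs(rec, both_strands=False))
    assert len(hits) == 10  # every family member is a PQS
    summary = census(hits)
    assert summary.with_ccc_ge1 == 7  # all but CEBwt / CEBm0A / CEBm0T
    # hit slices run tract-to-tract, so 3' extensions are not counted:
    # two CCC runs remain inside CEBm4, CEBm5 and CEBm7 motifs only
    assert summary.with_ccc_ge2 == 3
    assert summary.passing_threshold == 7


def test_census_n_stat_filter(ceb):
    hits = []
    for rec in ceb.values():
        hits.extend(find_pqs(rec, both_strands=False))
    summary = census(hits, n_threshold=2, filter_on="n_stat")
    # hit slices trim the 3' extensions, so the n_stat >= 2 set is the
    # central-loop mutants CEBm4/CEBm5/CEBm7 (CEBm6 keeps N = 1 in-motif)
    assert summary.passing_threshold == 3


def test_census_empty_hit_list():
    summary = census([])
    assert summary.total_pqs == 0
    assert summary.with_ccc_ge1 == 0 and summary.with_ccc_ge2 == 0


def test_census_frequency_per_kb():
    spec = FixtureSpec(genome_length=50_000, planted=(("classical", 24),), seed=3)
    genome, _ = synth_genome(spec)
    hits = find_pqs(genome)
    summary = census(hits, total_bases=genome.length)
    assert summary.frequency_per_kb == pytest.approx(24 / 50_000 * 1000)


def test_census_annotation_breakdown_and_mismatch_warning(ceb):
    hits = find_pqs(ceb["CEBwt"], both_strands=False)
    ann = [("CEBwt", 0, 26, "promoter")]
    summary = census(hits, annotation=ann)
    assert summary.feature_counts == {"promoter": 1}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        summary = census(hits, annotation=[("chrX", 0, 100, "exon")])
    assert summary.feature_counts is None
    assert any("feature breakdown skipped" in str(w.message) for w in caught)
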