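"""Junction extraction, strand handling, deduplication and tallies."""

import warnings

import pytest

from txqc import junctions as jx
from txqc.orf import revcomp
from txqc.seqio import GenomeSequence, TranscriptModel


def build_genome(intron_seq, flank=40):
    """Two 40 bp exons around the given intron; returns (genome, model exons)."""
    seq = "A" * flank + intron_seq + "C" * flank
    exons = ((0, flank), (flank + len(intron_seq), len(seq)))
    return {"c": GenomeSequence("c", seq)}, exons


INTRON_GT = "GTAAGT" + "T" * 20 + "TTCAG"  # canonical GT...AG, 31 nt


def test_plus_strand_canonical_junction():
    genome, exons = build_genome(INTRON_GT)
    model = TranscriptModel("t1", "c", "+", exons)
    (j,) = jx.extract_junctions([model], genome)
    assert (j.donor_dinuc, j.acceptor_dinuc, j.strand) == ("GT", "AG", "+")


def test_minus_strand_dinucleotides_are_reverse_complemented():
    # forward-strand intron CT...GC reads GC-AG after reverse complement
    intron = "CT" + "G" * 27 + "GC"
    genome, exons = build_genome(intron)
    model = TranscriptModel("t1", "c", "-", exons)
    (j,) = jx.extract_junctions([model], genome)
    assert j.donor_dinuc == revcomp(intron[-2:]) == "GC"
    assert j.acceptor_dinuc == revcomp(intron[:2]) == "AG"


def test_shared_intron_counted_once():
    genome, exons = build_genome(INTRON_GT)
    iso1 = TranscriptModel("t1", "c", "+", exons)
    iso2 = TranscriptModel("t2", "c", "+", exons)
    assert len(jx.extract_junctions([iso1, iso2], genome)) == 1


def test_dedup_under_model_duplication(small_bundle):
    genome, models, _, _ = small_bundle
    gd = {genome.name: genome}
    once = jx.extract_junctions(models, gd)
    twice = jx.extract_junctions(list(models) + list(models), gd)
    assert once == twice


def test_short_intron_skipped_with_warning():
    intron = "GT" + "A" * 10 + "AG"  # 14 nt < 30
    genome, exons = build_genome(intron)
    model = TranscriptModel("t1", "c", "+", exons)
    with pytest.warns(UserWarning):
        out = jx.extract_junctions([model], genome)
    assert out == set()


def test_strand_involution_on_reverse_complemented_genome(small_bundle):
    """Mirroring models onto the reverse-complemented genome flips strands
    but leaves every donor/acceptor dinucleotide unchanged."""
    genome, models, _, _ = small_bundle
    n = len(genome)
    mirror_genome = {genome.name: GenomeSequence(genome.name, revcomp(genome.sequence))}
    flipped = []
    for m in models:
        exons = tuple(sorted((n - e, n - s) for s, e in m.exons))
        strand = "+" if m.strand == "-" else "-"
        flipped.append(TranscriptModel(m.transcript_id, m.chrom, strand, exons))
    orig = jx.extract_junctions(models, {genome.name: genome})
    mirrored = jx.extract_junctions(flipped, mirror_genome)
    assert sorted((j.donor_dinuc, j.acceptor_dinuc) for j in orig) == \
        sorted((j.donor_dinuc, j.acceptor_dinuc) for j in mirrored)


def test_classify_bins_and_totals():
    def j(donor, acceptor, start):
        return jx.Junction("c", start, start + 40, "+", donor, acceptor)

    tally = jx.classify({j("GT", "AG", 0), j("GC", "AG", 100), j("GC", "AG", 200)})
    assert tally.donors["GC"] == 2 and tally.donors["GT"] == 1
    assert tally.acceptors["AG"] == tally.total == 3
    assert sum(tally.donors.values()) == sum(tally.acceptors.values()) == tally.total


def test_classify_n_goes_to_other_and_ga_binned():
    def j(donor, acceptor, start):
        return jx.Junction("c", start, start + 40, "+", donor, acceptor)

    tally = jx.classify({j("GA", "AG", 0), j("GN", "AG", 50), j("TT", "NG", 90)})
    assert tally.donors["GA"] == 1
    assert tally.donors["other"] == 2  # GN (contains N) and TT (unbinned)
    assert tally.acceptors["other"] == 1


def test_classify_rejects_empty_set():
    with pytest.raises(ValueError):
        jx.classify(set())


def test_planted_mix_recovered_exactly(small_bundle):
    genome, models, _, truth = small_bundle
    tally = jx.classify(jx.extract_junctions(models, {genome.name: genome}))
    assert tally.donors["GC"] == truth["donor_counts"]["GC"]
    assert tally.donors["GT"] == truth["donor_counts"]["GT"]
    assert tally.donors["GA"] == truth["donor_counts"]["GA"]
    assert tally.acceptors["AG"] == tally.total == truth["n_introns"]


def test_ag_acceptor_filter():
    def j(donor, acceptor, start):
        return jx.Junction("c", start, start + 40, "+", donor, acceptor)

    mixed = {j("GT", "AG", 0), j("GT", "AC", 50), j("GC", "AG", 100)}
    kept = jx.filter_ag_acceptors(mixed)
    assert kept == {x for x in mixed if x.acceptor_dinuc == "AG"}
    assert jx.filter_ag_acceptors(kept) == kept  # identity on all-AG input


def test_infer_strand_by_acceptor():
    genome, exons = build_genome(INTRON_GT)
    fwd = TranscriptModel("t1", "c", "?", exons)
    assert jx.infer_strand_by_acceptor(fwd, genome) == "+"

    intron_rev = "CT" + "G" * 27 + "GC"  # revcomp-AG start
    genome2, exons2 = build_genome(intron_rev)
    rev = TranscriptModel("t2", "c", "?", exons2)
    assert jx.infer_strand_by_acceptor(rev, genome2) == "-"


def test_infer_strand_tie_is_unknown():
    # one intron ends AG read forward, the other starts CT: one vote each way
    seq = "A" * 30 + INTRON_GT + "C" * 30 + "CT" + "G" * 27 + "GC" + "A" * 30
    flank1 = (0, 30)
    mid = (30 + len(INTRON_GT), 30 + len(INTRON_GT) + 30)
    last = (mid[1] + 31, len(seq))
    genome = {"c": GenomeSequence("c", seq)}
    model = TranscriptModel("t", "c", "?", (flank1, mid, last))
    assert jx.infer_strand_by_acceptor(model, genome) == "?"


def test_unknown_strand_model_oriented_before_extraction():
    genome, exons = build_genome(INTRON_GT)
    model = TranscriptModel("t1", "c", "?", exons)
    (j,) = jx.extract_junctions([model], genome)
    assert (j.strand, j.donor_dinuc, j.acceptor_dinuc) == ("+", "GT", "AG")
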