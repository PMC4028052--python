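"""Local alignment vs exhaustive DP oracle; presence checks; collection stats."""

import numpy as np
import pytest

from txqc import qc, synth
from txqc.qc import Scoring, align_local, presence_check
from txqc.seqio import GenomeSequence

from _oracles import dp_local_score
from conftest import random_dna


def gs(name, seq):
    return GenomeSequence(name, seq)


def test_identical_sequences_score_their_length(rng):
    for n in (199, 200, 250):
        s = random_dna(rng, n)
        hit = align_local(gs("q", s), gs("t", s))
        assert hit.score == hit.matches == n
        assert hit.mismatches == hit.q_gap_count == hit.t_gap_count == 0
        assert hit.identity == 1.0


def test_score_formula_holds():
    q = gs("q", "ACGTACGTAC" * 5)
    t = gs("t", "ACGTACGTAC" * 3 + "TTTTT" + "ACGTACGTAC" * 2)
    hit = align_local(q, t)
    assert hit.score == hit.matches - hit.mismatches - hit.q_gap_count - hit.t_gap_count


def test_mixed_alphabets_rejected():
    with pytest.raises(ValueError):
        align_local(gs("q", "ACGT"), gs("t", "MKLV"))


def test_planted_homology_matches_dp_oracle(rng):
    """A shared block with point mutations and scattered deletions: the
    engine's score equals the exhaustive Gotoh optimum."""
    block = random_dna(rng, 250)
    mutated = list(block)
    for pos in rng.choice(250, size=30, replace=False):
        mutated[pos] = rng.choice([c for c in "ACGT" if c != mutated[pos]])
    for pos in sorted(rng.choice(240, size=5, replace=False), reverse=True):
        del mutated[pos]
    q = random_dna(rng, 120) + block + random_dna(rng, 130)
    t = random_dna(rng, 100) + "".join(mutated) + random_dna(rng, 150)
    hit = align_local(gs("q", q), gs("t", t))
    assert hit.score == dp_local_score(q, t)


def test_random_pairs_match_dp_oracle(rng):
    for _ in range(40):
        n, m = rng.integers(20, 200, size=2)
        q, t = random_dna(rng, int(n), gc=0.65), random_dna(rng, int(m), gc=0.65)
        assert align_local(gs("q", q), gs("t", t)).score == dp_local_score(q, t)


def test_align_local_is_deterministic(rng):
    q, t = random_dna(rng, 150), random_dna(rng, 150)
    hits = [align_local(gs("q", q), gs("t", t)) for _ in range(3)]
    assert hits[0] == hits[1] == hits[2]


# --- presence -------------------------------------------------------------

def test_identical_member_is_found_and_absent_is_missing(rng):
    ref = gs("gene1", random_dna(rng, 300))
    other = gs("gene2", random_dna(rng, 300))
    report = presence_check([ref, other], {"c": [gs("tx1", ref.sequence)]})
    assert report.status.loc["gene1", "c"] == qc.FOUND
    assert report.status.loc["gene2", "c"] == qc.MISSING
    assert report.found_counts()["c"] == 1


def test_presence_monotone_in_min_score(rng):
    spec = synth.SynthSpec(seed=21)
    gold, _, coll, _ = synth.generate_gold_fixture(spec, n_gold=8)
    found_prev = None
    for threshold in (100, 200, 300, 450):
        rep = presence_check(gold, {"c": coll}, min_score=threshold)
        n = int(rep.found_counts()["c"])
        if found_prev is not None:
            assert n <= found_prev
        found_prev = n


def test_planted_defect_fixture_dna_vs_protein():
    """17 intact + 2 frameshifted + 1 absent: DNA level finds 19 (frameshift
    is invisible to DNA alignment), protein level finds only the 17 intact."""
    spec = synth.SynthSpec(seed=42)
    gold, gold_pep, coll, truth = synth.generate_gold_fixture(spec)
    dna = presence_check(gold, {"c": coll}, level="dna", min_score=200)
    assert int(dna.found_counts()["c"]) == 19
    peptides = qc.translate_collection(coll)
    pro = presence_check(gold_pep, {"c": peptides}, level="protein")
    assert int(pro.found_counts()["c"]) == 17
    # the genes lost at protein level are exactly the planted frameshifts
    lost = set(dna.membership.index[dna.membership["c"] & ~pro.membership["c"]])
    assert lost == {g for g, r in truth["roles"].items() if r == "frameshift"}


def test_membership_matrix_venn_counts(rng):
    genes = [gs(f"g{i}", random_dna(rng, 280)) for i in range(4)]
    colls = {
        "a": [gs("a0", genes[0].sequence), gs("a1", genes[1].sequence)],
        "b": [gs("b1", genes[1].sequence), gs("b2", genes[2].sequence)],
    }
    rep = presence_check(genes, colls)
    venn = rep.venn_counts()
    assert venn[("a",)] == 1 and venn[("b",)] == 1
    assert venn[("a", "b")] == 1 and venn[()] == 1
    assert (rep.membership.sum(axis=1) == [1, 2, 1, 0]).all()


def test_eligibility_mask_marks_no_input_support(rng):
    genes = [gs("g0", random_dna(rng, 280)), gs("g1", random_dna(rng, 280))]
    rep = presence_check(
        genes, {"c": [gs("t0", genes[0].sequence), gs("t1", genes[1].sequence)]},
        eligibility={"c": ["g0"]},
    )
    assert rep.status.loc["g0", "c"] == qc.FOUND
    assert rep.status.loc["g1", "c"] == qc.NO_INPUT_SUPPORT
    assert not rep.membership.loc["g1", "c"]


def test_empty_collection_warns_and_reports_missing(rng):
    genes = [gs("g0", random_dna(rng, 280))]
    with pytest.warns(UserWarning):
        rep = presence_check(genes, {"c": []})
    assert rep.status.loc["g0", "c"] == qc.MISSING


# --- characterization -----------------------------------------------------

def test_characterize_length_bins_and_median(rng):
    recs = [gs("a", random_dna(rng, 400)), gs("b", random_dna(rng, 800)),
            gs("c", random_dna(rng, 1600))]
    stats = qc.characterize_collection(recs)
    assert stats.length_hist == {"1-500": 1, "501-1000": 1, ">1000": 1}
    assert stats.median_length == 800


def test_characterize_full_orf_collection():
    spec = synth.SynthSpec(seed=30)
    rng = np.random.default_rng(1)
    recs = []
    for i in range(5):
        aa = int(rng.integers(60, 120))
        t = synth.make_transcript(rng, 3 * aa + 6, aa, pad5=0)
        # drop the leading stop codon so the ORF interval spans everything
        recs.append(gs(f"t{i}", t.sequence[3:]))
    stats = qc.characterize_collection(recs)
    assert stats.coverage_hist["0.9-1.0"] == 5
    assert stats.median_orf_coverage == 1.0


def test_characterize_histogram_equals_brute_tally(rng):
    lengths = rng.integers(301, 3000, size=60)
    recs = [gs(f"t{i}", random_dna(rng, int(n))) for i, n in enumerate(lengths)]
    stats = qc.characterize_collection(recs)
    assert stats.length_hist["1-500"] == int((lengths <= 500).sum())
    assert stats.length_hist["501-1000"] == int(((lengths > 500) & (lengths <= 1000)).sum())
    assert stats.length_hist[">1000"] == int((lengths > 1000).sum())
    assert sum(stats.coverage_hist.values()) == 60
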