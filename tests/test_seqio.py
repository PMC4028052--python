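"""FASTA/GTF/coverage I/O: round trips, coordinate conversion, validation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from txqc import seqio
from txqc.seqio import GenomeSequence, SeqioError, TranscriptModel

from _oracles import paint_coverage

names = st.text(st.characters(whitelist_categories=("Lu", "Ll", "Nd")), min_size=1, max_size=8)
dna = st.text(st.sampled_from("ACGTN"), min_size=1, max_size=120)


def test_fasta_read_uppercases_and_preserves_order(tmp_path):
    p = tmp_path / "in.fasta"
    p.write_text(">a\nacgt\n>b desc text\nNNGG\n")
    recs = seqio.read_fasta(p)
    assert [(r.name, r.sequence) for r in recs] == [("a", "ACGT"), ("b", "NNGG")]


@pytest.mark.parametrize(
    "content", [">a\nACGT\n>a\nGGGG\n", ">a\n\n>b\nACGT\n"],
    ids=["duplicate-id", "empty-sequence"],
)
def test_fasta_errors(tmp_path, content):
    p = tmp_path / "bad.fasta"
    p.write_text(content)
    with pytest.raises(SeqioError):
        seqio.read_fasta(p)


@given(st.lists(st.tuples(names, dna), min_size=1, max_size=6,
                unique_by=lambda t: t[0]))
def test_fasta_roundtrip_is_identity(tmp_path_factory, records):
    """write_fasta then read_fasta reproduces any valid collection."""
    p = tmp_path_factory.mktemp("fa") / "rt.fasta"
    collection = [GenomeSequence(n, s) for n, s in records]
    seqio.write_fasta(collection, p)
    back = seqio.read_fasta(p)
    assert [(r.name, r.sequence) for r in back] == records


GTF_LINE = 'chr1\tsrc\texon\t{}\t{}\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'


def test_gtf_coordinates_convert_to_half_open(tmp_path):
    p = tmp_path / "m.gtf"
    p.write_text(GTF_LINE.format(100, 200) + GTF_LINE.format(300, 400))
    (model,) = seqio.read_gtf(p)
    assert model.exons == ((99, 200), (299, 400))
    assert model.introns == [(200, 299)]
    assert model.introns[0][1] - model.introns[0][0] == 99


def test_gtf_invariant_under_exon_line_permutation(tmp_path):
    fwd = tmp_path / "fwd.gtf"
    rev = tmp_path / "rev.gtf"
    lines = [GTF_LINE.format(100, 200), GTF_LINE.format(300, 400),
             GTF_LINE.format(500, 620)]
    fwd.write_text("".join(lines))
    rev.write_text("".join(reversed(lines)))
    assert seqio.read_gtf(fwd) == seqio.read_gtf(rev)


def test_gtf_roundtrip_via_write_gtf(tmp_path, small_bundle):
    _, models, _, _ = small_bundle
    p = tmp_path / "rt.gtf"
    seqio.write_gtf(models, p)
    assert seqio.read_gtf(p) == list(models)


def test_gtf_overlapping_exons_rejected(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text(GTF_LINE.format(100, 300) + GTF_LINE.format(250, 400))
    with pytest.raises(SeqioError):
        seqio.read_gtf(p)


def test_transcript_model_rejects_unsorted_or_empty_exons():
    with pytest.raises(SeqioError):
        TranscriptModel("t", "c", "+", ((10, 10),))
    with pytest.raises(SeqioError):
        TranscriptModel("t", "c", "*", ((0, 10),))


def test_spliced_sequence_reverse_complements_minus_strand():
    genome = {"c": GenomeSequence("c", "AAACCCGGGTTT")}
    model = TranscriptModel("t", "c", "-", ((0, 3), (9, 12)))
    assert model.spliced_sequence(genome) == "AAATTT"


def test_bedgraph_paints_exact_positions(tmp_path):
    genome = {"chr1": GenomeSequence("chr1", "A" * 30)}
    p = tmp_path / "cov.bedgraph"
    p.write_text("chr1\t10\t13\t50\n")
    track = seqio.read_coverage(p, genome)
    assert track["chr1"][9] == 0
    assert list(track["chr1"][10:13]) == [50, 50, 50]
    assert track["chr1"][13] == 0
    assert track.total() == 150


def test_empty_coverage_file_is_all_zero(tmp_path):
    genome = {"chr1": GenomeSequence("chr1", "A" * 10)}
    p = tmp_path / "cov.bedgraph"
    p.write_text("")
    assert seqio.read_coverage(p, genome).total() == 0


@pytest.mark.parametrize(
    "line", ["chrX\t0\t5\t3", "chr1\t0\t5\t-3", "chr1\t5\t25\t3"],
    ids=["unknown-chrom", "negative-depth", "beyond-end"],
)
def test_bedgraph_errors(tmp_path, line):
    genome = {"chr1": GenomeSequence("chr1", "A" * 20)}
    p = tmp_path / "cov.bedgraph"
    p.write_text(line + "\n")
    with pytest.raises(SeqioError):
        seqio.read_coverage(p, genome)


def test_overlapping_bedgraph_records_rejected(tmp_path):
    genome = {"chr1": GenomeSequence("chr1", "A" * 20)}
    p = tmp_path / "cov.bedgraph"
    p.write_text("chr1\t0\t6\t3\nchr1\t5\t9\t2\n")
    with pytest.raises(SeqioError):
        seqio.read_coverage(p, genome)


def test_coverage_matches_brute_force_painting(tmp_path, rng):
    """Random non-overlapping records equal base-by-base painting, and the
    track total equals sum(depth x length)."""
    length = 500
    genome = {"chr1": GenomeSequence("chr1", "A" * length)}
    cuts = np.sort(rng.choice(np.arange(1, length), size=40, replace=False))
    bounds = [0, *cuts.tolist(), length]
    records = []
    for s, e in zip(bounds, bounds[1:]):
        if rng.random() < 0.5:
            records.append((s, e, int(rng.integers(1, 100))))
    p = tmp_path / "cov.bedgraph"
    p.write_text("".join(f"chr1\t{s}\t{e}\t{d}\n" for s, e, d in records))
    track = seqio.read_coverage(p, genome)
    assert np.array_equal(track["chr1"], paint_coverage(length, records))
    assert track.total() == sum(d * (e - s) for s, e, d in records)


def test_write_bedgraph_roundtrip(tmp_path, small_spec, small_bundle):
    from txqc import synth
    genome, models, _, _ = small_bundle
    track, _ = synth.generate_coverage(small_spec, models, genome)
    p = tmp_path / "cov.bedgraph"
    seqio.write_bedgraph(track, p)
    back = seqio.read_coverage(p, {genome.name: genome})
    assert np.array_equal(back[genome.name], track[genome.name])


def test_fixedstep_wiggle(tmp_path):
    genome = {"chr1": GenomeSequence("chr1", "A" * 20)}
    p = tmp_path / "cov.wig"
    p.write_text("fixedStep chrom=chr1 start=3 step=1\n5\n6\n7\n")
    track = seqio.read_coverage(p, genome)
    # wiggle start is 1-based: values land on 0-based positions 2,3,4
    assert list(track["chr1"][2:5]) == [5, 6, 7]
    assert track.total() == 18
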