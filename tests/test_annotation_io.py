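import pytest
from hypothesis import given, strategies as st

from circscreen.annotation_io import (
    AnnotationError,
    CircRNAModel,
    GenomeSequence,
    TranscriptModel,
    circular_sequence,
    read_circrnas,
    read_de_table,
    read_genome,
    read_transcripts,
    revcomp,
    spliced_sequence,
    three_prime_utr_sequence,
    write_circrnas,
    write_transcripts_gtf,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def oracle_revcomp(seq):
    # independent character-wise complement, then reverse
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    return "".join(comp[c] for c in seq)[::-1]


@given(dna)
def test_revcomp_matches_oracle_and_is_involutive(seq):
    assert revcomp(seq) == oracle_revcomp(seq)
    assert revcomp(revcomp(seq)) == seq


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def test_read_genome_uppercases(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">chr1\nacgt\n")
    assert dict(read_genome(p).sequences) == {"chr1": "ACGT"}


def test_read_genome_u_to_t(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">c\nACGU\n")
    assert read_genome(p)["c"] == "ACGT"


def test_read_genome_duplicate_header(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">c\nAC\n>c\nGT\n")
    with pytest.raises(AnnotationError, match="duplicate"):
        read_genome(p)


def test_read_genome_bad_char_names_line(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">c\nACGT\nACXT\n")
    with pytest.raises(AnnotationError, match=":3"):
        read_genome(p)


def test_read_genome_data_before_header(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text("ACGT\n")
    with pytest.raises(AnnotationError, match=":1"):
        read_genome(p)


def test_genome_missing_chrom_error():
    g = GenomeSequence({"chr1": "ACGT"})
    with pytest.raises(AnnotationError, match="absent"):
        g["chr2"]


# ---------------------------------------------------------------------------
# Spliced / circular sequences
# ---------------------------------------------------------------------------


def test_spliced_plus_strand_two_exons():
    # GTF 1-based closed [1,4] and [7,9] on ATGCCCTAG -> "ATGC" + "TAG"
    g = GenomeSequence({"c": "ATGCCCTAG"})
    t = TranscriptModel("t1", "g1", "c", "+", exons=((0, 4), (6, 9)))
    assert spliced_sequence(t, g) == "ATGCTAG"


def test_spliced_minus_strand_single_exon():
    g = GenomeSequence({"c": "ATGCAAAA"})
    t = TranscriptModel("t1", "g1", "c", "-", exons=((0, 4),))
    assert spliced_sequence(t, g) == "GCAT"


def test_empty_exon_list_rejected():
    with pytest.raises(AnnotationError, match="empty exon"):
        TranscriptModel("t1", "g1", "c", "+", exons=())


def test_circular_sequence_plus_identity():
    g = GenomeSequence({"c": "AAAAATTTTT"})
    c = CircRNAModel("circ1", "c", "+", 0, 10)
    assert circular_sequence(c, g) == "AAAAATTTTT"


def test_circular_sequence_minus_is_revcomp():
    g = GenomeSequence({"c": "AAAAATTTTT"})
    c = CircRNAModel("circ1", "c", "-", 0, 10)
    assert circular_sequence(c, g) == oracle_revcomp("AAAAATTTTT")


def test_circular_sequence_two_exons_hand_concat():
    chrom = "ACGTACGTAATTGGCCAAGG"  # 20 nt
    g = GenomeSequence({"c": chrom})
    c = CircRNAModel("circ1", "c", "+", 2, 18, exons=((2, 8), (12, 18)))
    assert circular_sequence(c, g) == chrom[2:8] + chrom[12:18]


def test_circular_equals_spliced_of_equivalent_transcript(locus, minus_locus):
    for loc in (locus, minus_locus):
        c = loc.circs[0]
        t = TranscriptModel(c.circ_id, c.circ_id, c.chrom, c.strand, c.exons)
        assert circular_sequence(c, loc.genome) == spliced_sequence(t, loc.genome)


def test_synth_locus_truth_matches_circular_sequence(locus, minus_locus):
    for loc in (locus, minus_locus):
        c = loc.circs[0]
        assert circular_sequence(c, loc.genome) == loc.truth[c.circ_id]


# ---------------------------------------------------------------------------
# circRNA BED I/O
# ---------------------------------------------------------------------------


def test_read_circrnas_bed6(tmp_path):
    p = tmp_path / "c.bed"
    p.write_text("chr1\t100\t200\tcircA\t0\t+\n")
    (c,) = read_circrnas(p)
    assert (c.circ_id, c.start, c.end, c.strand) == ("circA", 100, 200, "+")
    assert c.exons == ((100, 200),)


def test_read_circrnas_bed12_blocks(tmp_path):
    p = tmp_path / "c.bed"
    p.write_text(
        "chr1\t100\t200\tcircA\t0\t+\t100\t200\t0\t2\t30,40\t0,60\n"
    )
    (c,) = read_circrnas(p)
    assert c.exons == ((100, 130), (160, 200))


def test_read_circrnas_degenerate_interval(tmp_path):
    p = tmp_path / "c.bed"
    p.write_text("chr1\t200\t100\tcircA\t0\t+\n")
    with pytest.raises(AnnotationError, match="end"):
        read_circrnas(p)


def test_read_circrnas_missing_strand(tmp_path):
    p = tmp_path / "c.bed"
    p.write_text("chr1\t100\t200\tcircA\t0\t.\n")
    with pytest.raises(AnnotationError, match="strand"):
        read_circrnas(p)


@given(
    start=st.integers(0, 1000),
    length=st.integers(2, 500),
    strand=st.sampled_from("+-"),
)
def test_bed_round_trip(tmp_path_factory, start, length, strand):
    c = CircRNAModel("circX", "chr9", strand, start, start + length)
    path = tmp_path_factory.mktemp("bed") / "rt.bed"
    write_circrnas([c], path)
    (back,) = read_circrnas(path)
    assert back == c


def test_bed12_round_trip(tmp_path):
    c = CircRNAModel(
        "circX", "chr9", "-", 10, 110, exons=((10, 40), (60, 110))
    )
    path = tmp_path / "rt.bed"
    write_circrnas([c], path)
    assert read_circrnas(path) == [c]


@given(st.integers(0, 10**6), st.integers(1, 10**4))
def test_bed_gtf_coordinate_conversion_identity(start, length):
    end = start + length
    gtf_start, gtf_end = start + 1, end  # half-open -> 1-based closed
    assert (gtf_start - 1, gtf_end) == (start, end)


# ---------------------------------------------------------------------------
# GTF round trip and 3' UTR derivation
# ---------------------------------------------------------------------------


def test_gtf_round_trip(tmp_path, locus, minus_locus):
    for loc in (locus, minus_locus):
        path = tmp_path / f"{loc.transcripts[0].strand}.gtf"
        write_transcripts_gtf(loc.transcripts, path)
        assert tuple(read_transcripts(path)) == loc.transcripts


def test_three_prime_utr_plus_strand():
    g = GenomeSequence({"c": "ATGAAACCCGGGTTTACG"})
    t = TranscriptModel("t", "g", "c", "+", exons=((0, 18),), cds_end=12)
    utr, flagged = three_prime_utr_sequence(t, g)
    assert utr == "TTTACG" and not flagged


def test_three_prime_utr_minus_strand():
    g = GenomeSequence({"c": "ATGAAACCCGGGTTTACG"})
    t = TranscriptModel("t", "g", "c", "-", exons=((0, 18),), cds_end=6)
    utr, flagged = three_prime_utr_sequence(t, g)
    # UTR bases are genomic [0, 6), read in minus orientation as a suffix
    assert utr == oracle_revcomp("ATGAAA") and not flagged


def test_three_prime_utr_spans_exon_boundary():
    g = GenomeSequence({"c": "ATGAAACCCGGGTTTACG"})
    t = TranscriptModel("t", "g", "c", "+", exons=((0, 6), (9, 18)), cds_end=12)
    utr, _ = three_prime_utr_sequence(t, g)
    assert utr == "TTTACG"


def test_three_prime_utr_no_cds_flagged():
    g = GenomeSequence({"c": "ATGAAACCC"})
    t = TranscriptModel("t", "g", "c", "+", exons=((0, 9),))
    utr, flagged = three_prime_utr_sequence(t, g)
    assert utr == "ATGAAACCC" and flagged


def test_utr_is_suffix_of_spliced(locus):
    t = locus.transcripts[0]
    utr, flagged = three_prime_utr_sequence(t, locus.genome)
    assert not flagged and utr
    assert spliced_sequence(t, locus.genome).endswith(utr)


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------


def test_read_de_table_na_handling(tmp_path):
    p = tmp_path / "de.tsv"
    p.write_text(
        "gene_id\tlog2fc\tpvalue\tpadj\n"
        "g1\t0.5\t0.01\t0.04\n"
        "g2\t-1.2\tNA\tNA\n"
    )
    df = read_de_table(p)
    assert df.loc[df.gene_id == "g2", "padj"].isna().all()
    assert df.loc[df.gene_id == "g1", "padj"].iloc[0] == 0.04


def test_read_de_table_duplicate_gene(tmp_path):
    p = tmp_path / "de.tsv"
    p.write_text(
        "gene_id\tlog2fc\tpvalue\tpadj\ng1\t0.5\t0.01\t0.04\ng1\t0.1\t0.2\t0.3\n"
    )
    with pytest.raises(AnnotationError, match="duplicate"):
        read_de_table(p)


def test_read_de_table_p_out_of_range(tmp_path):
    p = tmp_path / "de.tsv"
    p.write_text("gene_id\tlog2fc\tpvalue\tpadj\ng1\t0.5\t1.5\t0.04\n")
    with pytest.raises(AnnotationError, match="pvalue"):
        read_de_table(p)
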