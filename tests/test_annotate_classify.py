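import numpy as np
import pytest

from lncflora.annotate_classify import (
    ClassCode,
    ReferenceIndex,
    assign_class_code,
    chromosome_density,
    classify_all,
    exonic_overlap_bp,
)
from lncflora.io_formats import GenomicInterval, TranscriptModel


def _tx(tid, chrom, strand, exon_coords, gene=None):
    return TranscriptModel(
        tid,
        gene or f"{tid}_g",
        chrom,
        strand,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_coords),
    )


# ---------------------------------------------------------------------------
# exonic overlap


def test_exonic_overlap_examples():
    q = _tx("q", "chr1", "+", [(100, 200)])
    s = _tx("s", "chr1", "+", [(150, 250)])
    assert exonic_overlap_bp(q, s) == 50
    assert exonic_overlap_bp(s, q) == 50  # symmetric
    far = _tx("f", "chr1", "+", [(5000, 5100)])
    assert exonic_overlap_bp(q, far) == 0
    other = _tx("o", "chr2", "+", [(100, 200)])
    assert exonic_overlap_bp(q, other) == 0  # different chromosome, not an error
    assert exonic_overlap_bp(q, q) == q.length


# ---------------------------------------------------------------------------
# class codes: the spec'd textbook cases


@pytest.fixture
def small_reference():
    return [
        _tx("r1", "chr1", "+", [(1000, 1200), (1800, 2000)], gene="G1"),
    ]


def test_intergenic(small_reference):
    idx = ReferenceIndex(small_reference)
    code = assign_class_code(_tx("q", "chr1", "+", [(5000, 5500)]), idx)
    assert code == ClassCode("u")


def test_antisense_overlap(small_reference):
    idx = ReferenceIndex(small_reference)
    code = assign_class_code(_tx("q", "chr1", "-", [(1100, 1300)]), idx)
    assert code.code == "x" and code.subject_gene_id == "G1"


def test_intronic_same_strand(small_reference):
    idx = ReferenceIndex(small_reference)
    code = assign_class_code(_tx("q", "chr1", "+", [(1300, 1700)]), idx)
    assert code.code == "i" and code.subject_gene_id == "G1"


def test_sense_overlap(small_reference):
    idx = ReferenceIndex(small_reference)
    code = assign_class_code(_tx("q", "chr1", "+", [(1100, 1300)]), idx)
    assert code.code == "o" and code.subject_gene_id == "G1"


def test_exact_match_multiexon(small_reference):
    idx = ReferenceIndex(small_reference)
    # same intron chain, slightly different terminal ends: still '='
    code = assign_class_code(_tx("q", "chr1", "+", [(950, 1200), (1800, 2100)]), idx)
    assert code.code == "="


def test_sense_outranks_antisense():
    ref = [
        _tx("r+", "chr1", "+", [(1000, 2000)], gene="Gp"),
        _tx("r-", "chr1", "-", [(1500, 2500)], gene="Gm"),
    ]
    idx = ReferenceIndex(ref)
    code = assign_class_code(_tx("q", "chr1", "+", [(1600, 1900)]), idx)
    assert code.code == "o"


def test_unstranded_query_rejected(small_reference):
    idx = ReferenceIndex(small_reference)
    with pytest.raises(ValueError, match="unstranded"):
        assign_class_code(_tx("q", "chr1", ".", [(1, 10)]), idx)


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_class(q, refs):
    """All-pairs classifier without any interval index (the oracle)."""

    def overlap(a, b):
        if a.chrom != b.chrom:
            return 0
        return sum(
            max(0, min(x.end, y.end) - max(x.start, y.start))
            for x in a.exons
            for y in b.exons
        )

    same = [r for r in refs if r.chrom == q.chrom and r.strand == q.strand]
    opposite = [r for r in refs if r.chrom == q.chrom and r.strand != q.strand]
    for r in same:
        if q.n_exons > 1 and r.n_exons > 1:
            qi = [(a.end, b.start) for a, b in zip(q.exons, q.exons[1:])]
            ri = [(a.end, b.start) for a, b in zip(r.exons, r.exons[1:])]
            if qi == ri:
                return "="
        if q.n_exons == 1 and r.n_exons == 1:
            if (q.start, q.end) == (r.start, r.end):
                return "="
    if any(overlap(q, r) > 0 for r in same):
        return "o"
    for r in same:
        for a, b in zip(r.exons, r.exons[1:]):
            if a.end <= q.start and q.end <= b.start:
                return "i"
    if any(overlap(q, r) > 0 for r in opposite):
        return "x"
    return "u"


def test_oracle_equivalence_on_synthetic_annotation(bundle):
    """Index-based classification matches the brute-force all-pairs oracle."""
    codes = classify_all(bundle.novel_transcripts, bundle.ref_transcripts)
    assert len(codes) >= 200
    for q in bundle.novel_transcripts:
        assert codes[q.transcript_id].code == brute_force_class(
            q, bundle.ref_transcripts
        ), q.transcript_id


def test_codes_partition_the_input(bundle):
    codes = classify_all(bundle.novel_transcripts, bundle.ref_transcripts)
    per_code = {c: 0 for c in "=uxio"}
    for code in codes.values():
        per_code[code.code] += 1
    assert sum(per_code.values()) == len(bundle.novel_transcripts)


def test_u_transcripts_touch_no_reference_gene(bundle):
    """'u' calls have zero exonic overlap and zero gene-span containment."""
    codes = classify_all(bundle.novel_transcripts, bundle.ref_transcripts)
    u_transcripts = [
        t for t in bundle.novel_transcripts if codes[t.transcript_id].code == "u"
    ]
    assert u_transcripts
    for q in u_transcripts:
        for r in bundle.ref_transcripts:
            assert exonic_overlap_bp(q, r) == 0
            if r.chrom == q.chrom:
                assert not (r.start <= q.start and q.end <= r.end)


# ---------------------------------------------------------------------------
# density


def test_density_examples():
    feats = [
        GenomicInterval("chr1", 0, 10),
        GenomicInterval("chr1", 10, 20),
        GenomicInterval("chr1", 1_000_000, 1_000_010),
    ]
    df = chromosome_density(feats, {"chr1": 2_000_000}, 1_000_000)
    assert list(df["count"]) == [2, 1]
    empty = chromosome_density([], {"chr1": 2_000_000}, 1_000_000)
    assert empty["count"].sum() == 0


def test_density_total_matches_feature_count():
    rng = np.random.default_rng(0)
    feats = [
        GenomicInterval("chr1", int(s), int(s) + 5)
        for s in rng.integers(0, 1_999_000, size=100)
    ]
    df = chromosome_density(feats, {"chr1": 2_000_000}, 250_000)
    assert df["count"].sum() == 100


def test_density_unknown_chromosome_excluded():
    feats = [GenomicInterval("chrX", 0, 10), GenomicInterval("chr1", 0, 10)]
    df = chromosome_density(feats, {"chr1": 1_000_000}, 1_000_000)
    assert df["count"].sum() == 1
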