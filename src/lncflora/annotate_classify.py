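"""Positional classification of assembled transcripts against a reference.

Each novel transcript is assigned one class code describing its relation to
the reference annotation:

* ``=`` complete match of an annotated transcript (same strand, identical
  intron chain; identical exon coordinates for monoexonics),
* ``o`` same-strand exonic overlap (sense),
* ``i`` fully contained in an intron of a same-strand reference transcript,
* ``x`` opposite-strand exonic overlap (antisense),
* ``u`` none of the above (intergenic).

When several relations hold, precedence is ``=`` > ``o`` > ``i`` > ``x`` >
``u``: sense overlap outranks antisense so a transcript touching exons on
both strands is not mislabelled antisense.  Strandedness is required (the
pipeline assumes stranded libraries); unstranded queries are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomicInterval, TranscriptModel

log = logging.getLogger(__name__)

CLASS_CODES = ("=", "u", "x", "i", "o")

__all__ = [
    "ClassCode",
    "ReferenceIndex",
    "exonic_overlap_bp",
    "assign_class_code",
    "classify_all",
    "chromosome_density",
]


@dataclass(frozen=True)
class ClassCode:
    """Positional relation of a transcript to the reference annotation."""

    code: str
    subject_gene_id: str = ""

    def __post_init__(self) -> None:
        if self.code not in CLASS_CODES:
            raise ValueError(f"unknown class code {self.code!r}")
        if (self.code == "u") != (self.subject_gene_id == ""):
            raise ValueError("subject_gene_id must be empty iff code == 'u'")


def exonic_overlap_bp(query: TranscriptModel, subject: TranscriptModel) -> int:
    """Total bp of exon-chain intersection between two transcripts.

    Symmetric in its arguments; transcripts on different chromosomes overlap
    by 0 bp (not an error).  Strand is deliberately ignored here — callers
    decide which strand combination they are probing.
    """
    if query.chrom != subject.chrom:
        return 0
    total = 0
    for qe in query.exons:
        for se in subject.exons:
            total += qe.overlap(se)
    return total


def _intron_chain(t: TranscriptModel) -> tuple[tuple[int, int], ...]:
    return tuple((a.end, b.start) for a, b in zip(t.exons, t.exons[1:]))


class ReferenceIndex:
    """Interval indexes over a reference annotation for class-code queries."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: list[TranscriptModel] = list(transcripts)
        self._exons: dict[str, IntervalTree] = {}
        self._introns: dict[str, IntervalTree] = {}
        self._spans: dict[str, IntervalTree] = {}
        # exact-match lookups
        self._multi_chains: dict[tuple, list[TranscriptModel]] = {}
        self._mono_coords: dict[tuple, list[TranscriptModel]] = {}
        for t in self.transcripts:
            ex = self._exons.setdefault(t.chrom, IntervalTree())
            for e in t.exons:
                ex.addi(e.start, e.end, t)
            intr = self._introns.setdefault(t.chrom, IntervalTree())
            for i in t.introns():
                intr.addi(i.start, i.end, t)
            self._spans.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t)
            if t.n_exons > 1:
                key = (t.chrom, t.strand, _intron_chain(t))
                self._multi_chains.setdefault(key, []).append(t)
            else:
                key = (t.chrom, t.strand, (t.start, t.end))
                self._mono_coords.setdefault(key, []).append(t)

    def overlapping_exon_transcripts(self, query: TranscriptModel) -> set[TranscriptModel]:
        tree = self._exons.get(query.chrom)
        if tree is None:
            return set()
        found: set[TranscriptModel] = set()
        for e in query.exons:
            for iv in tree.overlap(e.start, e.end):
                found.add(iv.data)
        return found

    def containing_introns(self, query: TranscriptModel) -> set[TranscriptModel]:
        """Reference transcripts with an intron fully containing the query span."""
        tree = self._introns.get(query.chrom)
        if tree is None:
            return set()
        out: set[TranscriptModel] = set()
        for iv in tree.overlap(query.start, query.end):
            if iv.begin <= query.start and iv.end >= query.end:
                out.add(iv.data)
        return out

    def exact_matches(self, query: TranscriptModel) -> list[TranscriptModel]:
        if query.n_exons > 1:
            key = (query.chrom, query.strand, _intron_chain(query))
            return self._multi_chains.get(key, [])
        key = (query.chrom, query.strand, (query.start, query.end))
        return self._mono_coords.get(key, [])


def assign_class_code(query: TranscriptModel, ref: ReferenceIndex) -> ClassCode:
    """Assign the class code of ``query`` relative to the reference index."""
    if query.strand not in ("+", "-"):
        raise ValueError(
            f"{query.transcript_id}: unstranded transcript cannot be classified"
        )

    matches = ref.exact_matches(query)
    if matches:
        return ClassCode("=", matches[0].gene_id)

    overlapping = ref.overlapping_exon_transcripts(query)
    same = [t for t in overlapping if t.strand == query.strand]
    if same:
        best = max(same, key=lambda t: (exonic_overlap_bp(query, t), t.gene_id))
        return ClassCode("o", best.gene_id)

    intronic = [t for t in ref.containing_introns(query) if t.strand == query.strand]
    if intronic:
        return ClassCode("i", min(t.gene_id for t in intronic))

    anti = [t for t in overlapping if t.strand != query.strand and t.strand in "+-"]
    if anti:
        best = max(anti, key=lambda t: (exonic_overlap_bp(query, t), t.gene_id))
        return ClassCode("x", best.gene_id)

    # Contained in an opposite-strand gene span without exon overlap falls
    # through to 'u'; log it, since the call is convention-dependent.
    opp_introns = [t for t in ref.containing_introns(query) if t.strand != query.strand]
    if opp_introns:
        log.info(
            "%s: contained in opposite-strand intron of %s; classified 'u'",
            query.transcript_id,
            opp_introns[0].gene_id,
        )
    return ClassCode("u")


def classify_all(
    queries: Sequence[TranscriptModel], reference: Sequence[TranscriptModel]
) -> dict[str, ClassCode]:
    """Classify every query transcript; returns transcript_id -> ClassCode."""
    index = ReferenceIndex(reference)
    return {q.transcript_id: assign_class_code(q, index) for q in queries}


def chromosome_density(
    features: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    bin_size: int,
) -> pd.DataFrame:
    """Count features per fixed-size bin along each chromosome.

    Each feature is counted once, in the bin containing its start.  Features
    on chromosomes absent from ``chrom_sizes`` are excluded with a warning.
    Returns a DataFrame with columns chrom, bin_start, count.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    rows = []
    counts: dict[tuple[str, int], int] = {}
    for chrom, size in chrom_sizes.items():
        for b in range(0, size, bin_size):
            counts[(chrom, b)] = 0
    for f in features:
        if f.chrom not in chrom_sizes:
            log.warning("feature on unknown chromosome %s excluded", f.chrom)
            continue
        b = (f.start // bin_size) * bin_size
        counts[(f.chrom, b)] += 1
    for (chrom, b), n in sorted(counts.items()):
        rows.append({"chrom": chrom, "bin_start": b, "count": n})
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "count"])
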