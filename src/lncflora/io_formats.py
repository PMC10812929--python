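"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are 0-based half-open throughout the package; GTF I/O
converts from/to the 1-based inclusive convention at this boundary and
nowhere else.  Counts are integers; FPKM is always derived downstream,
never read from disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "ExpressionMatrix",
    "HomologyHit",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_counts",
    "read_blast_tab",
]


class GtfParseError(ValueError):
    """Raised for malformed GTF lines; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval: ``start`` 0-based inclusive, ``end`` exclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Length in bp of the intersection with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, multi-exon transcript; the unit flowing through the pipeline."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        for e in exons:
            if e.chrom != self.chrom:
                raise ValueError(f"{self.transcript_id}: exon on wrong chromosome")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"{self.transcript_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        """Spliced transcript length in nt (sum of exon lengths)."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        """Genomic locus span from first exon start to last exon end."""
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        )


@dataclass
class ExpressionMatrix:
    """Integer read counts per feature x sample, with library sizes and groups.

    ``counts`` is a features-by-samples DataFrame of non-negative integers.
    ``library_sizes`` are total mapped reads per sample (defaults to column
    sums when no sidecar is supplied).  ``group_labels`` assigns each sample
    a condition (e.g. FB / FF).
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    group_labels: pd.Series

    def __post_init__(self) -> None:
        samples = list(self.counts.columns)
        if list(self.library_sizes.index) != samples:
            self.library_sizes = self.library_sizes.reindex(samples)
        if list(self.group_labels.index) != samples:
            self.group_labels = self.group_labels.reindex(samples)
        if self.library_sizes.isna().any():
            raise ValueError("library size missing for some sample")
        if self.group_labels.isna().any():
            raise ValueError("group label missing for some sample")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be > 0")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class HomologyHit:
    """One BLAST outfmt-6 HSP, optionally annotated with its query length."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    query_length: int | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if self.alignment_length < 1:
            raise ValueError("alignment length must be >= 1")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent identity outside [0, 100]")

    @property
    def coverage(self) -> float:
        """Alignment length as a fraction of the query length."""
        if self.query_length is None:
            raise ValueError(f"query length not attached for {self.query_id}")
        return self.alignment_length / self.query_length


# ---------------------------------------------------------------------------
# GTF


def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF file into TranscriptModels (exon features only).

    1-based inclusive GTF coordinates become 0-based half-open internally.
    Exons are grouped by transcript_id and sorted; transcripts without any
    exon record are not emitted.  Malformed lines raise :class:`GtfParseError`
    naming the line number.
    """
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"line {lineno}: expected >= 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields[:9]
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise GtfParseError(f"line {lineno}: end < start ({end1} < {start1})")
            if strand not in VALID_STRANDS:
                raise GtfParseError(f"line {lineno}: unknown strand {strand!r}")
            attrs = _parse_gtf_attributes(attr_s, lineno)
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise GtfParseError(
                    f"line {lineno}: exon without transcript_id/gene_id attributes"
                )
            tx = attrs["transcript_id"]
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if tx not in meta:
                meta[tx] = (attrs["gene_id"], chrom, strand)
                order.append(tx)
            exons_by_tx.setdefault(tx, []).append(iv)
    out = []
    for tx in order:
        gene, chrom, strand = meta[tx]
        out.append(
            TranscriptModel(tx, gene, chrom, strand, tuple(sorted(exons_by_tx[tx])))
        )
    return out


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write TranscriptModels as GTF exon records (round-trips with read_gtf)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for e in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "lncflora",
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase-sequence map.

    The id is the first whitespace-delimited header token.  Duplicate ids and
    empty sequences are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.upper()), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# count matrices


def read_counts(
    path: str | Path,
    library_sizes: Mapping[str, float] | pd.Series | None = None,
    group_labels: Mapping[str, str] | pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a TSV count matrix (rows features, columns samples).

    When ``library_sizes`` is absent it defaults to per-sample column sums.
    When ``group_labels`` is absent every sample is assigned group "all".
    Negative or non-numeric counts are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        counts = df.astype("int64")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-integer count in {path}") from exc
    if not (df.values == counts.values).all():
        raise ValueError(f"non-integer count in {path}")
    if (counts.values < 0).any():
        raise ValueError(f"negative count in {path}")
    if library_sizes is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = pd.Series(dict(library_sizes), dtype=float).reindex(counts.columns)
    if group_labels is None:
        groups = pd.Series("all", index=counts.columns)
    else:
        groups = pd.Series(dict(group_labels)).reindex(counts.columns)
    return ExpressionMatrix(counts, lib, groups)


def read_samples_sheet(path: str | Path) -> tuple[pd.Series, pd.Series]:
    """Read a sample sidecar TSV with columns sample, group, library_size."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})
    df = df.set_index("sample")
    return df["library_size"].astype(float), df["group"]


# ---------------------------------------------------------------------------
# BLAST tabular


_BLAST_COLS = 12


def read_blast_tab(
    path: str | Path,
    query_lengths: Mapping[str, int] | None = None,
) -> list[HomologyHit]:
    """Read 12-column BLAST outfmt-6 rows into HomologyHits.

    ``query_lengths`` (id -> nt), typically from the query FASTA, is attached
    to each hit; an unknown query id raises an error listing the id.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _BLAST_COLS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {_BLAST_COLS} columns, "
                    f"got {len(fields)}"
                )
            (qid, sid, pident, alen, mism, gaps, qs, qe, ss, se, ev, bits) = fields
            qlen = None
            if query_lengths is not None:
                if qid not in query_lengths:
                    raise ValueError(f"unknown query id {qid!r} when attaching length")
                qlen = int(query_lengths[qid])
            hits.append(
                HomologyHit(
                    query_id=qid,
                    subject_id=sid,
                    percent_identity=float(pident),
                    alignment_length=int(alen),
                    mismatches=int(mism),
                    gap_opens=int(gaps),
                    qstart=int(qs),
                    qend=int(qe),
                    sstart=int(ss),
                    send=int(se),
                    evalue=float(ev),
                    bitscore=float(bits),
                    query_length=qlen,
                )
            )
    return hits


def write_blast_tab(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.qstart),
                        str(h.qend),
                        str(h.sstart),
                        str(h.send),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )
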