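"""Candidate filter cascade and lncRNA categorisation.

Novel transcripts survive four ordered steps: (0) keep only unannotated
positional classes {u, x, i, o}; (1) drop transcripts shorter than 200 nt or
without an exon record; (2) drop transcripts whose maximum FPKM across all
samples is below 0.5; (3) keep only transcripts the coding-potential
ensemble calls non-coding.  Every step is recorded in an audit trail, and
survivors are categorised by class code (u -> lincRNA, x -> antisense,
o -> sense, i -> intronic) and renamed with stable TCONS serials in genomic
sort order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotate_classify import ClassCode
from .coding_potential import CodingVerdict
from .io_formats import TranscriptModel

UNANNOTATED_CODES = frozenset({"u", "x", "i", "o"})

CATEGORY_BY_CODE = {
    "u": "lincRNA",
    "x": "antisense",
    "o": "sense",
    "i": "intronic",
}

__all__ = [
    "FilterParams",
    "LncRNARecord",
    "FilterStep",
    "FilterAudit",
    "filter_candidates",
    "categorize_and_name",
]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the candidate filter cascade."""

    min_length: int = 200
    min_exons: int = 1
    min_fpkm: float = 0.5
    require_unannotated: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 0 or self.min_exons < 0 or self.min_fpkm < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class LncRNARecord:
    """One surviving lncRNA with its category and (eventually) stable name."""

    transcript_id: str
    class_code: str
    category: str
    transcript: TranscriptModel
    lncrna_id: str = ""

    def __post_init__(self) -> None:
        expected = CATEGORY_BY_CODE.get(self.class_code)
        if expected is None:
            raise ValueError(f"unknown class code {self.class_code!r}")
        if self.category != expected:
            raise ValueError(
                f"category {self.category!r} does not match class code "
                f"{self.class_code!r}"
            )


@dataclass(frozen=True)
class FilterStep:
    name: str
    n_input: int
    n_removed: int
    n_surviving: int


@dataclass
class FilterAudit:
    """Ordered per-step accounting of the filter cascade."""

    steps: list[FilterStep] = field(default_factory=list)
    params: FilterParams = field(default_factory=FilterParams)

    def add(self, name: str, n_input: int, n_surviving: int) -> None:
        step = FilterStep(name, n_input, n_input - n_surviving, n_surviving)
        if self.steps and self.steps[-1].n_surviving != n_input:
            raise ValueError("audit chain broken: input != previous surviving")
        self.steps.append(step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.name,
                    "input": s.n_input,
                    "removed": s.n_removed,
                    "surviving": s.n_surviving,
                }
                for s in self.steps
            ]
        )


def filter_candidates(
    transcripts: Sequence[TranscriptModel],
    class_codes: Mapping[str, ClassCode],
    fpkm: pd.DataFrame,
    verdicts: Mapping[str, CodingVerdict],
    params: FilterParams = FilterParams(),
) -> tuple[list[LncRNARecord], FilterAudit]:
    """Apply the filter cascade; returns surviving records plus the audit.

    ``fpkm`` is a features-by-samples matrix covering (at least) every
    transcript that reaches step 2; a transcript missing from it is an
    error naming the transcript.  Coding verdicts are only required for
    transcripts that reach step 3.
    """
    audit = FilterAudit(params=params)
    current = list(transcripts)
    for t in current:
        if t.transcript_id not in class_codes:
            raise ValueError(f"transcript {t.transcript_id} has no class code")

    n0 = len(current)
    if params.require_unannotated:
        current = [
            t
            for t in current
            if class_codes[t.transcript_id].code in UNANNOTATED_CODES
        ]
    audit.add("unannotated_class", n0, len(current))

    n1 = len(current)
    current = [
        t
        for t in current
        if t.length >= params.min_length and t.n_exons >= params.min_exons
    ]
    audit.add("length_and_exons", n1, len(current))

    n2 = len(current)
    kept2 = []
    for t in current:
        if t.transcript_id not in fpkm.index:
            raise ValueError(f"transcript {t.transcript_id} missing from FPKM matrix")
        if float(fpkm.loc[t.transcript_id].max()) >= params.min_fpkm:
            kept2.append(t)
    current = kept2
    audit.add("min_fpkm", n2, len(current))

    n3 = len(current)
    kept3 = []
    for t in current:
        if t.transcript_id not in verdicts:
            raise ValueError(f"no coding verdict for {t.transcript_id}")
        if verdicts[t.transcript_id].is_noncoding:
            kept3.append(t)
    current = kept3
    audit.add("noncoding", n3, len(current))

    records = [
        LncRNARecord(
            transcript_id=t.transcript_id,
            class_code=class_codes[t.transcript_id].code,
            category=CATEGORY_BY_CODE[class_codes[t.transcript_id].code],
            transcript=t,
        )
        for t in current
    ]
    return records, audit


def categorize_and_name(
    records: Sequence[LncRNARecord], prefix: str = "TCONS_"
) -> list[LncRNARecord]:
    """Assign stable serial names in genomic sort order (chrom, start, id).

    Deterministic for a fixed input set: re-running on the same records
    yields the same names.  Returns the records sorted in naming order.
    """
    ordered = sorted(
        records,
        key=lambda r: (r.transcript.chrom, r.transcript.start, r.transcript_id),
    )
    for serial, rec in enumerate(ordered, start=1):
        rec.lncrna_id = f"{prefix}{serial:08d}"
    return ordered


_RECORD_COLUMNS = [
    "lncrna_id", "transcript_id", "category", "class_code",
    "chrom", "start", "end", "strand", "length", "n_exons",
]


def records_to_frame(records: Sequence[LncRNARecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": r.lncrna_id,
                "transcript_id": r.transcript_id,
                "category": r.category,
                "class_code": r.class_code,
                "chrom": r.transcript.chrom,
                "start": r.transcript.start,
                "end": r.transcript.end,
                "strand": r.transcript.strand,
                "length": r.transcript.length,
                "n_exons": r.transcript.n_exons,
            }
            for r in records
        ],
        columns=_RECORD_COLUMNS,
    )
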