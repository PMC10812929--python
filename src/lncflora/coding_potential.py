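"""Coding-potential assessment with three built-in predictors.

The predictors stand in for the external tool trio a practitioner would run
(an ORF-based classifier, a TESTCODE-style statistic, a hexamer-usage
score).  A transcript is accepted as non-coding only when *all three*
predictors agree it is non-coding — the intersection rule.  Real external
tool outputs (CPC2 / CNCI / Pfam tables) can be ingested instead of the
built-ins.

All scores are pure functions of the sequence (and, for the hexamer
log-likelihood ratio, of two trained hexamer models).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import fickett_tables as _ft

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

__all__ = [
    "OrfResult",
    "CodingVerdict",
    "Thresholds",
    "HexamerModel",
    "longest_orf",
    "fickett_score",
    "train_hexamer_model",
    "background_hexamer_model",
    "hexamer_llr",
    "ensemble_noncoding_vote",
    "score_transcripts",
    "ingest_external_predictions",
]


@dataclass(frozen=True)
class OrfResult:
    """Longest sense-strand open reading frame of a transcript."""

    start: int
    length: int
    frame: int
    has_stop: bool

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("ORF length must be >= 0")
        if self.has_stop and self.length % 3 != 0:
            raise ValueError("complete ORF length must be a multiple of 3")


@dataclass(frozen=True)
class Thresholds:
    """Per-predictor coding-call thresholds.

    Defaults follow the conventions of the tools the predictors emulate:
    an ORF of >= 300 nt (100 codons), a TESTCODE score in the
    "probably coding" region (>= 0.95), and any positive hexamer
    log-likelihood ratio.
    """

    min_orf_nt: int = 300
    min_fickett: float = 0.95
    min_hexamer_llr: float = 0.0


@dataclass
class CodingVerdict:
    """Per-predictor scores and calls for one transcript, plus the vote."""

    transcript_id: str
    orf_length: int
    fickett: float
    hexamer_llr: float
    orf_call_coding: bool
    fickett_call_coding: bool
    hexamer_call_coding: bool
    is_noncoding: bool
    warnings: tuple[str, ...] = ()

    @property
    def calls(self) -> tuple[bool, bool, bool]:
        return (self.orf_call_coding, self.fickett_call_coding, self.hexamer_call_coding)


def longest_orf(seq: str) -> OrfResult:
    """Longest ATG..stop span on the sense strand, scanning 3 frames.

    The reported length includes the stop codon.  If an ATG has no
    downstream in-frame stop, the open-ended span to the last complete codon
    is a candidate with ``has_stop=False``.  Ties break toward the smaller
    start, then the lower frame.
    """
    seq = seq.upper()
    best = OrfResult(0, 0, 0, False)

    def better(cand: OrfResult, cur: OrfResult) -> bool:
        if cand.length != cur.length:
            return cand.length > cur.length
        if cand.start != cur.start:
            return cand.start < cur.start
        return cand.frame < cur.frame

    for frame in range(3):
        open_start: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if open_start is None and codon == "ATG":
                open_start = pos
            elif open_start is not None and codon in STOP_CODONS:
                cand = OrfResult(open_start, pos + 3 - open_start, frame, True)
                if better(cand, best):
                    best = cand
                open_start = None
        if open_start is not None:
            n_codons = (len(seq) - open_start) // 3
            cand = OrfResult(open_start, 3 * n_codons, frame, False)
            if better(cand, best):
                best = cand
    return best


def _lookup(value: float, thresholds: Sequence[float], probs: Sequence[float]) -> float:
    for t, p in zip(thresholds, probs):
        if value >= t:
            return p
    return probs[-1]


def fickett_score(seq: str) -> float:
    """TESTCODE statistic: weighted sum of 8 table-binned parameters.

    Four positional asymmetries (max/min+1 of per-frame base counts) and
    four base-content fractions, each mapped through the published lookup
    tables.  Deterministic; bases other than ACGT are ignored in the counts.
    """
    seq = seq.upper()
    if not seq:
        return 0.0
    pos_counts = {b: [0, 0, 0] for b in "ACGT"}
    content = {b: 0 for b in "ACGT"}
    for i, base in enumerate(seq):
        if base in content:
            content[base] += 1
            pos_counts[base][i % 3] += 1
    total = sum(content.values())
    if total == 0:
        return 0.0
    score = 0.0
    for base in "ACGT":
        c = pos_counts[base]
        position_value = max(c) / (min(c) + 1)
        score += (
            _lookup(position_value, _ft.POSITION_THRESHOLDS, _ft.POSITION_PROBABILITY[base])
            * _ft.POSITION_WEIGHT[base]
        )
        content_value = content[base] / total
        score += (
            _lookup(content_value, _ft.CONTENT_THRESHOLDS, _ft.CONTENT_PROBABILITY[base])
            * _ft.CONTENT_WEIGHT[base]
        )
    return score


# ---------------------------------------------------------------------------
# hexamer model


def _hexamer_index(hexamer: str) -> int | None:
    idx = 0
    for base in hexamer:
        b = _BASE_INDEX.get(base)
        if b is None:
            return None
        idx = idx * 4 + b
    return idx


@dataclass
class HexamerModel:
    """Multinomial model over the 4096 hexamers (natural-log probabilities)."""

    log_probs: np.ndarray  # shape (4096,)

    def __post_init__(self) -> None:
        if self.log_probs.shape != (4096,):
            raise ValueError("hexamer model needs 4096 entries")

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_probs)


def train_hexamer_model(seqs: Iterable[str], pseudocount: float = 1.0) -> HexamerModel:
    """Count overlapping hexamers (step 1) over a corpus, with pseudocounts.

    Probabilities are (count + pseudocount) / (total + 4096 * pseudocount);
    invariant to sequence order.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    counts = np.zeros(4096, dtype=np.float64)
    n_seqs = 0
    for seq in seqs:
        n_seqs += 1
        seq = seq.upper()
        for i in range(len(seq) - 5):
            idx = _hexamer_index(seq[i : i + 6])
            if idx is not None:
                counts[idx] += 1
    if n_seqs == 0:
        raise ValueError("empty training corpus")
    probs = (counts + pseudocount) / (counts.sum() + 4096 * pseudocount)
    return HexamerModel(np.log(probs))


def background_hexamer_model(seqs: Iterable[str]) -> HexamerModel:
    """Zero-order background: P(hexamer) from corpus mononucleotide frequencies.

    The analytic equivalent of training on an (infinitely) shuffled corpus —
    it keeps base composition and discards all codon/word structure, and is
    fully deterministic.
    """
    base_counts = np.zeros(4, dtype=np.float64)
    n_seqs = 0
    for seq in seqs:
        n_seqs += 1
        for base, idx in _BASE_INDEX.items():
            base_counts[idx] += seq.upper().count(base)
    if n_seqs == 0 or base_counts.sum() == 0:
        raise ValueError("empty training corpus")
    log_base = np.log(base_counts / base_counts.sum())
    log_probs = np.zeros(4096)
    for idx in range(4096):
        rem, lp = idx, 0.0
        for _ in range(6):
            lp += log_base[rem % 4]
            rem //= 4
        log_probs[idx] = lp
    return HexamerModel(log_probs)


def hexamer_llr(seq: str, coding: HexamerModel, noncoding: HexamerModel) -> float:
    """Mean log(P_coding/P_noncoding) over in-frame (step-3) hexamers.

    Returns 0.0 (with a log note) for sequences shorter than one hexamer;
    identical models give exactly 0 and swapping the models negates the
    score.
    """
    seq = seq.upper()
    if len(seq) < 6:
        log.debug("sequence shorter than 6 nt; hexamer LLR set to 0")
        return 0.0
    diffs = coding.log_probs - noncoding.log_probs
    total = 0.0
    n = 0
    for i in range(0, len(seq) - 5, 3):
        idx = _hexamer_index(seq[i : i + 6])
        if idx is not None:
            total += diffs[idx]
            n += 1
    return total / n if n else 0.0


# ---------------------------------------------------------------------------
# ensemble


def ensemble_noncoding_vote(
    transcript_id: str,
    seq: str,
    coding_model: HexamerModel,
    noncoding_model: HexamerModel,
    thresholds: Thresholds = Thresholds(),
) -> CodingVerdict:
    """Score one transcript with the three built-ins and take the vote.

    ``is_noncoding`` is true iff *all three* predictors call non-coding.
    Sequences with >10% N and sequences shorter than 200 nt are flagged
    (low-confidence scores), not rejected.
    """
    seq = seq.upper()
    warnings: list[str] = []
    n_frac = seq.count("N") / len(seq) if seq else 0.0
    if n_frac > 0.10:
        warnings.append("n_fraction_gt_10pct")
    if len(seq) < 200:
        warnings.append("short_sequence")
    orf = longest_orf(seq)
    fick = fickett_score(seq)
    llr = hexamer_llr(seq, coding_model, noncoding_model)
    orf_coding = orf.length >= thresholds.min_orf_nt
    fick_coding = fick >= thresholds.min_fickett
    hex_coding = llr > thresholds.min_hexamer_llr
    return CodingVerdict(
        transcript_id=transcript_id,
        orf_length=orf.length,
        fickett=fick,
        hexamer_llr=llr,
        orf_call_coding=orf_coding,
        fickett_call_coding=fick_coding,
        hexamer_call_coding=hex_coding,
        is_noncoding=not (orf_coding or fick_coding or hex_coding),
        warnings=tuple(warnings),
    )


def score_transcripts(
    seqs: Mapping[str, str],
    coding_model: HexamerModel,
    noncoding_model: HexamerModel,
    thresholds: Thresholds = Thresholds(),
) -> dict[str, CodingVerdict]:
    """Run the built-in ensemble over an id -> sequence map."""
    return {
        tid: ensemble_noncoding_vote(tid, s, coding_model, noncoding_model, thresholds)
        for tid, s in seqs.items()
    }


def verdicts_to_frame(verdicts: Mapping[str, CodingVerdict]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": v.transcript_id,
            "orf_length": v.orf_length,
            "fickett": v.fickett,
            "hexamer_llr": v.hexamer_llr,
            "orf_call_coding": v.orf_call_coding,
            "fickett_call_coding": v.fickett_call_coding,
            "hexamer_call_coding": v.hexamer_call_coding,
            "is_noncoding": v.is_noncoding,
        }
        for v in verdicts.values()
    ]
    return pd.DataFrame(rows).set_index("transcript_id")


# ---------------------------------------------------------------------------
# external predictor ingestion


def ingest_external_predictions(
    cpc2_table: str | Path | pd.DataFrame,
    cnci_table: str | Path | pd.DataFrame,
    pfam_hits: str | Path | pd.DataFrame,
) -> dict[str, CodingVerdict]:
    """Combine CPC2 / CNCI / Pfam tool outputs under the intersection rule.

    CPC2: a ``label`` column with 'coding'/'noncoding' per transcript.
    CNCI: a ``score`` (index) column; score >= 0 means coding.
    Pfam: any row naming a transcript means that transcript is coding.
    Transcripts absent from CPC2 or CNCI are excluded with a warning; Pfam
    absence simply means "no domain hit" (non-coding by that predictor).
    """

    def _load(obj, **kw) -> pd.DataFrame:
        if isinstance(obj, pd.DataFrame):
            return obj
        return pd.read_csv(obj, sep="\t", **kw)

    cpc2 = _load(cpc2_table)
    cnci = _load(cnci_table)
    pfam = _load(pfam_hits)

    def _id_col(df: pd.DataFrame) -> str:
        return df.columns[0]

    cpc2_calls: dict[str, bool] = {}
    for _, row in cpc2.iterrows():
        label = str(row["label"]).strip().lower()
        tid = str(row[_id_col(cpc2)])
        if label not in ("coding", "noncoding"):
            raise ValueError(f"unparseable CPC2 label {label!r} for {tid}")
        cpc2_calls[tid] = label == "coding"

    cnci_calls: dict[str, bool] = {}
    for _, row in cnci.iterrows():
        tid = str(row[_id_col(cnci)])
        try:
            score = float(row["score"])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unparseable CNCI score for {tid}") from exc
        cnci_calls[tid] = score >= 0

    pfam_coding = set(pfam[_id_col(pfam)].astype(str)) if len(pfam) else set()

    shared = set(cpc2_calls) & set(cnci_calls)
    dropped = (set(cpc2_calls) | set(cnci_calls)) - shared
    for tid in sorted(dropped):
        log.warning("%s absent from some predictor table; excluded", tid)

    out: dict[str, CodingVerdict] = {}
    for tid in sorted(shared):
        calls = (cpc2_calls[tid], cnci_calls[tid], tid in pfam_coding)
        out[tid] = CodingVerdict(
            transcript_id=tid,
            orf_length=-1,
            fickett=math.nan,
            hexamer_llr=math.nan,
            orf_call_coding=calls[0],
            fickett_call_coding=calls[1],
            hexamer_call_coding=calls[2],
            is_noncoding=not any(calls),
        )
    return out
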