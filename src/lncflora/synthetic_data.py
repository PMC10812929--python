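"""Seeded generator for every input the pipeline consumes, with ground truth.

The generator emulates the study design the pipeline is built for: a
chromosome-level genome with a multi-exon reference annotation, novel
transcripts planted in each positional class (intergenic / antisense /
intronic / sense / annotated copies), transcript sequences with planted
coding or non-coding character, negative-binomial counts for two
conditions (FB vs FF, three replicates each) with planted fold changes,
fabricated cross-species homology tables with planted reciprocal best
hits, and a term map for enrichment.  Alongside the inputs it emits truth
tables for every planted property, so each pipeline stage can be verified
by recovery.

Everything is a pure function of :class:`SynthConfig`; the same seed gives
byte-identical outputs.

Design notes
------------
* Coding sequences embed a long ORF (>= 300 nt) built from a fixed
  position-biased codon sampler; non-coding sequences are i.i.d. draws at
  the same base composition, rejection-sampled until the three built-in
  coding predictors all score them non-coding.  The planted classes are
  therefore separable exactly, by construction, which is what makes exact
  end-to-end recovery a meaningful test.
* Homology E-values come from a fixed monotone formula of alignment length
  and identity; no aligner runs.  The conservation stage only consumes the
  table, so the formula's realism is irrelevant to its correctness.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from .coding_potential import (
    HexamerModel,
    background_hexamer_model,
    fickett_score,
    hexamer_llr,
    longest_orf,
    train_hexamer_model,
)
from .io_formats import GenomicInterval, HomologyHit, TranscriptModel

__all__ = ["SynthConfig", "Bundle", "generate_bundle", "write_bundle"]

SPECIES_POOL = (
    "Arabidopsis_thaliana",
    "Solanum_lycopersicum",
    "Cucumis_sativus",
    "Oryza_sativa",
    "Vitis_vinifera",
    "Brassica_napus",
    "Medicago_truncatula",
    "Zea_mays",
)

# Position-specific nucleotide preferences of the codon sampler (A, C, G, T).
# Chosen to give strong 3-periodicity while averaging to ~50% GC so coding
# and non-coding sequences share base composition.
_CODON_POS_PROBS = np.array(
    [
        [0.35, 0.15, 0.35, 0.15],
        [0.30, 0.20, 0.20, 0.30],
        [0.20, 0.30, 0.30, 0.20],
    ]
)
_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_BG_PROBS = _CODON_POS_PROBS.mean(axis=0)  # i.i.d. composition for non-coding


@dataclass(frozen=True)
class SynthConfig:
    """Everything the generator needs; defaults are the standard conditions."""

    seed: int = 1
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_ref_genes: int = 100
    n_novel: Mapping[str, int] = field(
        default_factory=lambda: {"u": 190, "x": 80, "i": 40, "o": 60, "=": 30}
    )
    coding_fraction: float = 0.25
    short_fraction: float = 0.05  # non-coding candidates planted below 200 nt
    low_expression_fraction: float = 0.10
    # lncRNA-like: ~800 nt mean, mostly 1-2 exons; mRNA-like: ~2.9 kb, ~5 exons
    lnc_len_log_mean: float = math.log(650.0)
    lnc_len_log_sd: float = 0.55
    mrna_len_log_mean: float = math.log(2500.0)
    mrna_len_log_sd: float = 0.45
    n_samples: int = 3
    group_labels: tuple[str, str] = ("FB", "FF")
    mean_expression: float = 50.0
    expr_log_sd: float = 0.8
    dispersion: float = 0.1
    de_fraction: float = 0.15
    de_log2fc: float = 2.0
    nominal_library_size: float = 2.0e7
    size_factors: tuple[float, ...] | None = None  # None -> all 1.0
    n_species: int = 5
    n_planted_homologs: int = 30
    n_oneway_homologs: int = 10
    n_decoy_homologs: int = 100
    homolog_mutation_rate: float = 0.10
    n_trans_pairs: int = 20
    n_terms: int = 15

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_novel.values()):
            raise ValueError("class counts must be >= 0")
        if not (0.0 <= self.coding_fraction <= 1.0):
            raise ValueError("coding_fraction outside [0, 1]")
        if self.homolog_mutation_rate >= 0.5:
            raise ValueError("mutation rate >= 0.5 makes planted pairs unrecoverable")
        if self.n_species > len(SPECIES_POOL):
            raise ValueError(f"at most {len(SPECIES_POOL)} species supported")

    @property
    def species(self) -> tuple[str, ...]:
        return SPECIES_POOL[: self.n_species]

    @property
    def samples(self) -> list[str]:
        return [
            f"{g}{i + 1}" for g in self.group_labels for i in range(self.n_samples)
        ]

    @property
    def sample_groups(self) -> list[str]:
        return [g for g in self.group_labels for _ in range(self.n_samples)]


@dataclass
class Bundle:
    """In-memory result of a full generation run."""

    config: SynthConfig
    chrom_sizes: dict[str, int]
    ref_transcripts: list[TranscriptModel]
    novel_transcripts: list[TranscriptModel]
    ref_sequences: dict[str, str]
    novel_sequences: dict[str, str]
    counts: pd.DataFrame
    library_sizes: pd.Series
    groups: pd.Series
    feature_lengths: pd.Series
    species_sequences: dict[str, dict[str, str]]
    forward_hits: dict[str, list[HomologyHit]]
    reverse_hits: dict[str, list[HomologyHit]]
    term_map: pd.DataFrame
    truth_transcripts: pd.DataFrame
    truth_expression: pd.DataFrame
    truth_rbh: pd.DataFrame
    truth_oneway: pd.DataFrame
    truth_cis: pd.DataFrame
    truth_trans: pd.DataFrame


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[list[TranscriptModel], dict[str, int]]:
    """Place non-overlapping multi-exon genes on both strands of each chromosome."""
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)
    }
    chroms = list(chrom_sizes)
    transcripts: list[TranscriptModel] = []
    cursors = {c: 10_000 for c in chroms}
    for g in range(config.n_ref_genes):
        chrom = chroms[g % len(chroms)]
        n_exons = 2 + int(rng.poisson(3))
        exon_lens = np.clip(
            rng.lognormal(math.log(300.0), 0.5, size=n_exons), 100, 2000
        ).astype(int)
        intron_lens = rng.integers(500, 4000, size=n_exons - 1)
        start = cursors[chrom] + int(rng.integers(3000, 12000))
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        if pos > chrom_sizes[chrom] - 10_000:
            raise ValueError(
                f"gene {g} does not fit on {chrom}; enlarge chrom_length or "
                "reduce n_ref_genes"
            )
        cursors[chrom] = pos
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"JSG{g + 1:05d}"
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gid}.t1",
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
            )
        )
    return transcripts, chrom_sizes


# ---------------------------------------------------------------------------
# novel transcripts


def _sample_lnc_length(config: SynthConfig, rng: np.random.Generator) -> int:
    return int(np.clip(rng.lognormal(config.lnc_len_log_mean, config.lnc_len_log_sd), 210, 3000))


def _sample_mrna_length(config: SynthConfig, rng: np.random.Generator) -> int:
    return int(
        np.clip(rng.lognormal(config.mrna_len_log_mean, config.mrna_len_log_sd), 500, 8000)
    )


def _lnc_exon_count(rng: np.random.Generator) -> int:
    return int(rng.choice([1, 2, 3], p=[0.77, 0.18, 0.05]))


def _build_exon_chain(
    chrom: str,
    strand: str,
    start: int,
    total_len: int,
    n_exons: int,
    rng: np.random.Generator,
) -> tuple[GenomicInterval, ...]:
    """Split total_len over n_exons and insert introns; returns sorted exons."""
    if n_exons == 1:
        return (GenomicInterval(chrom, start, start + total_len, strand),)
    cuts = np.sort(rng.choice(np.arange(1, total_len), size=n_exons - 1, replace=False))
    lens = np.diff(np.concatenate([[0], cuts, [total_len]]))
    lens = np.maximum(lens, 30)
    introns = rng.integers(200, 2000, size=n_exons - 1)
    exons = []
    pos = start
    for i, el in enumerate(lens):
        exons.append(GenomicInterval(chrom, pos, pos + int(el), strand))
        pos += int(el)
        if i < n_exons - 1:
            pos += int(introns[i])
    return tuple(exons)


def generate_novel_transcripts(
    config: SynthConfig,
    reference: Sequence[TranscriptModel],
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Construct transcripts that satisfy each planted positional class."""
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in reference:
        by_chrom.setdefault(t.chrom, []).append(t)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t.start)

    # intergenic gaps with 500 bp margins
    gaps: list[tuple[str, int, int]] = []
    for chrom, size in chrom_sizes.items():
        spans = [(t.start, t.end) for t in by_chrom.get(chrom, [])]
        prev = 1000
        for s, e in spans:
            if s - 500 - prev > 1000:
                gaps.append((chrom, prev, s - 500))
            prev = e + 500
        if size - 1000 - prev > 1000:
            gaps.append((chrom, prev, size - 1000))

    # per-gene clamp window: stay clear of neighbouring genes
    windows: dict[str, tuple[int, int]] = {}
    for chrom, genes in by_chrom.items():
        for i, t in enumerate(genes):
            lo = genes[i - 1].end + 500 if i > 0 else 1000
            hi = (
                genes[i + 1].start - 500
                if i + 1 < len(genes)
                else chrom_sizes[chrom] - 1000
            )
            windows[t.transcript_id] = (lo, hi)

    novels: list[TranscriptModel] = []
    rows: list[dict] = []
    serial = 0

    def _add(t: TranscriptModel, klass: str, coding: bool) -> None:
        novels.append(t)
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "planted_class": klass,
                "planted_coding": coding,
                "length": t.length,
                "n_exons": t.n_exons,
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
            }
        )

    def _next_ids() -> tuple[str, str]:
        nonlocal serial
        serial += 1
        return f"NOVT{serial:05d}", f"NOVG{serial:05d}"

    flip = {"+": "-", "-": "+"}

    for klass, n in config.n_novel.items():
        for _ in range(n):
            coding = bool(rng.random() < config.coding_fraction) and klass != "="
            if klass == "=":
                src = reference[int(rng.integers(len(reference)))]
                tid, gid = _next_ids()
                _add(
                    TranscriptModel(tid, gid, src.chrom, src.strand, src.exons),
                    "=",
                    True,
                )
                continue
            if klass == "u":
                if coding:
                    total = _sample_mrna_length(config, rng)
                    n_ex = 1 + int(rng.poisson(4))
                else:
                    total = _sample_lnc_length(config, rng)
                    if rng.random() < config.short_fraction:
                        total = int(rng.integers(120, 200))
                    n_ex = _lnc_exon_count(rng)
                span_budget = total + (n_ex - 1) * 2000 + 50
                eligible = [g for g in gaps if g[2] - g[1] > span_budget]
                if not eligible:
                    raise ValueError(
                        "could not place intergenic transcript; enlarge genome"
                    )
                room = np.array([hi - lo - span_budget for _, lo, hi in eligible], float)
                chrom, lo, hi = eligible[int(rng.choice(len(eligible), p=room / room.sum()))]
                start = int(rng.integers(lo, hi - span_budget))
                exons = _build_exon_chain(
                    chrom, "+" if rng.random() < 0.5 else "-", start, total, n_ex, rng
                )
                tid, gid = _next_ids()
                _add(
                    TranscriptModel(tid, gid, chrom, exons[0].strand, exons),
                    "u",
                    coding,
                )
                continue
            if klass in ("x", "o"):
                for _try in range(200):
                    g = reference[int(rng.integers(len(reference)))]
                    lo, hi = windows[g.transcript_id]
                    exon = g.exons[int(rng.integers(g.n_exons))]
                    total = max(
                        _sample_mrna_length(config, rng) if coding else _sample_lnc_length(config, rng),
                        400 if coding else 210,
                    )
                    total = min(total, hi - lo - 20)
                    if total < 200:
                        continue
                    # anchor so the single exon overlaps `exon` by >= 50 bp
                    anchor_lo = max(lo, exon.start - total + 50)
                    anchor_hi = min(hi - total, exon.end - 50)
                    if anchor_hi <= anchor_lo:
                        continue
                    start = int(rng.integers(anchor_lo, anchor_hi))
                    strand = g.strand if klass == "o" else flip[g.strand]
                    tid, gid = _next_ids()
                    _add(
                        TranscriptModel(
                            tid,
                            gid,
                            g.chrom,
                            strand,
                            (GenomicInterval(g.chrom, start, start + total, strand),),
                        ),
                        klass,
                        coding,
                    )
                    break
                else:
                    raise ValueError(f"could not place class-{klass} transcript")
                continue
            if klass == "i":
                for _try in range(400):
                    g = reference[int(rng.integers(len(reference)))]
                    introns = g.introns()
                    if not introns:
                        continue
                    intr = introns[int(rng.integers(len(introns)))]
                    total = max(
                        400 if coding else _sample_lnc_length(config, rng), 250
                    )
                    if len(intr) <= total + 40:
                        continue
                    start = int(rng.integers(intr.start + 20, intr.end - total - 20))
                    tid, gid = _next_ids()
                    _add(
                        TranscriptModel(
                            tid,
                            gid,
                            g.chrom,
                            g.strand,
                            (
                                GenomicInterval(
                                    g.chrom, start, start + total, g.strand
                                ),
                            ),
                        ),
                        "i",
                        coding,
                    )
                    break
                else:
                    raise ValueError("could not place intronic transcript")
                continue
            raise ValueError(f"unknown planted class {klass!r}")

    truth = pd.DataFrame(rows)
    return novels, truth


# ---------------------------------------------------------------------------
# sequences


def _sample_codons(n: int, rng: np.random.Generator) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        codon = "".join(
            _BASES[rng.choice(4, p=_CODON_POS_PROBS[i])] for i in range(3)
        )
        if codon not in _STOPS:
            out.append(codon)
    return out


def _iid_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.choice(4, p=_BG_PROBS, size=n)])


def _coding_seq(length: int, rng: np.random.Generator, min_orf: int = 300) -> str:
    """Sequence of ``length`` nt with an embedded codon-biased ORF >= min_orf."""
    orf_len = min(length - 60, int(0.7 * length))
    orf_len -= orf_len % 3
    if orf_len < min_orf:
        orf_len = min(min_orf, length - length % 3)  # truncated-ORF edge case
    n_codons = orf_len // 3
    body = "".join(_sample_codons(max(0, n_codons - 2), rng))
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(3))]
    orf = "ATG" + body + stop
    rest = length - len(orf)
    u5 = int(rng.integers(0, rest + 1)) if rest > 0 else 0
    return _iid_seq(u5, rng) + orf + _iid_seq(rest - u5, rng)


def _noncoding_seq(
    length: int,
    rng: np.random.Generator,
    coding_model: HexamerModel,
    screen_model: HexamerModel,
    max_orf: int = 300,
    max_tries: int = 500,
) -> str:
    """I.i.d. sequence screened so all three built-in predictors say non-coding."""
    for _ in range(max_tries):
        seq = _iid_seq(length, rng)
        if longest_orf(seq).length >= max_orf:
            continue
        if fickett_score(seq) >= 0.95:
            continue
        if length >= 6 and hexamer_llr(seq, coding_model, screen_model) >= -0.02:
            continue
        return seq
    raise RuntimeError(f"could not draw a non-coding sequence of length {length}")


def generate_sequences(
    config: SynthConfig,
    ref_transcripts: Sequence[TranscriptModel],
    novel_transcripts: Sequence[TranscriptModel],
    truth_transcripts: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, str]]:
    """Sequences for reference (all coding-style) and novel transcripts."""
    ref_seqs = {
        t.transcript_id: _coding_seq(t.length, rng) for t in ref_transcripts
    }
    # screen against the exact models the pipeline will rebuild from this corpus
    coding_model = train_hexamer_model(ref_seqs.values())
    screen_model = background_hexamer_model(ref_seqs.values())
    flags = truth_transcripts.set_index("transcript_id")["planted_coding"]
    novel_seqs: dict[str, str] = {}
    for t in novel_transcripts:
        if bool(flags[t.transcript_id]):
            novel_seqs[t.transcript_id] = _coding_seq(t.length, rng)
        else:
            novel_seqs[t.transcript_id] = _noncoding_seq(
                t.length, rng, coding_model, screen_model
            )
    return ref_seqs, novel_seqs


# ---------------------------------------------------------------------------
# counts


def _nb_draw(
    mean: np.ndarray, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson draw of NB(mean, phi); Poisson when phi == 0."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    lam = rng.gamma(shape, mean * phi)
    return rng.poisson(lam)


def generate_counts(
    config: SynthConfig,
    ref_transcripts: Sequence[TranscriptModel],
    novel_transcripts: Sequence[TranscriptModel],
    truth_transcripts: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series, pd.DataFrame, pd.DataFrame]:
    """NB counts for PCGs (gene ids) and novel transcripts, with DE/trans truth."""
    samples = config.samples
    groups = pd.Series(config.sample_groups, index=samples)
    sf = (
        np.asarray(config.size_factors, dtype=float)
        if config.size_factors is not None
        else np.ones(len(samples))
    )
    if len(sf) != len(samples):
        raise ValueError("size_factors length must equal the number of samples")

    tinfo = truth_transcripts.set_index("transcript_id")
    feature_ids = [t.gene_id for t in ref_transcripts] + [
        t.transcript_id for t in novel_transcripts
    ]
    feature_types = ["PCG"] * len(ref_transcripts) + ["novel"] * len(novel_transcripts)
    lengths = pd.Series(
        [t.length for t in ref_transcripts] + [t.length for t in novel_transcripts],
        index=feature_ids,
        name="length",
    )

    n_feat = len(feature_ids)
    mu = np.clip(
        rng.lognormal(math.log(config.mean_expression), config.expr_log_sd, n_feat),
        2.0,
        5000.0,
    )

    is_novel = np.array([ft == "novel" for ft in feature_types])
    is_lnc_candidate = np.zeros(n_feat, dtype=bool)
    for i, fid in enumerate(feature_ids):
        if is_novel[i]:
            row = tinfo.loc[fid]
            is_lnc_candidate[i] = (
                (not bool(row["planted_coding"]))
                and row["planted_class"] in ("u", "x", "i", "o")
                and int(row["length"]) >= 200
            )

    # low-expression plants among non-coding candidates (exercise the FPKM filter)
    low_expr = np.zeros(n_feat, dtype=bool)
    cand_idx = np.where(is_lnc_candidate)[0]
    n_low = int(round(config.low_expression_fraction * len(cand_idx)))
    if n_low:
        chosen = rng.choice(cand_idx, size=n_low, replace=False)
        low_expr[chosen] = True
        mu[low_expr] = rng.uniform(0.02, 0.5, size=n_low)

    # planted DE among everything expressed
    de_lfc = np.zeros(n_feat)
    eligible = np.where(~low_expr)[0]
    n_de = int(round(config.de_fraction * len(eligible)))
    de_idx = rng.choice(eligible, size=n_de, replace=False) if n_de else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=len(de_idx))
    de_lfc[de_idx] = signs * config.de_log2fc

    # planted trans pairs: strongly stage-regulated lncRNA drives a PCG copy
    trans_lnc_pool = [
        i for i in cand_idx if not low_expr[i]
    ]
    pcg_pool = [i for i in range(n_feat) if feature_types[i] == "PCG"]
    n_trans = min(config.n_trans_pairs, len(trans_lnc_pool), len(pcg_pool))
    trans_lnc = rng.choice(trans_lnc_pool, size=n_trans, replace=False)
    trans_gene = rng.choice(pcg_pool, size=n_trans, replace=False)
    trans_sign = rng.choice([-1, 1], size=n_trans)
    for i in trans_lnc:
        mu[i] = 4.0 * config.mean_expression
        if de_lfc[i] == 0.0:
            de_lfc[i] = float(rng.choice([-1.0, 1.0])) * config.de_log2fc

    group_arr = np.array(config.sample_groups)
    contrast = group_arr == config.group_labels[1]
    means = np.outer(mu, sf)
    means[:, contrast] *= np.power(2.0, de_lfc)[:, None]
    counts = np.vstack(
        [_nb_draw(means[i], config.dispersion, rng) for i in range(n_feat)]
    ).astype(np.int64)

    # overwrite trans-partner PCG counts with an exact (anti)linear map
    linked = np.zeros(n_feat, dtype=bool)
    trans_rows = []
    for i, j, s in zip(trans_lnc, trans_gene, trans_sign):
        x = counts[i]
        if s > 0:
            counts[j] = 2 * x
        else:
            counts[j] = 2 * (x.max() + 5 - x)
        linked[j] = True
        trans_rows.append(
            {
                "lncrna_id": feature_ids[i],
                "gene_id": feature_ids[j],
                "sign": int(s),
            }
        )

    counts_df = pd.DataFrame(counts, index=feature_ids, columns=samples)
    library_sizes = pd.Series(
        config.nominal_library_size * sf, index=samples, name="library_size"
    )
    fpkm = counts_df.div(lengths, axis=0).div(library_sizes, axis=1) * 1e9
    status = np.where(de_lfc > 0, "up", np.where(de_lfc < 0, "down", "ns"))
    status = np.where(linked, "linked", status)
    truth_expr = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "feature_type": feature_types,
            "planted_mean": mu,
            "planted_lfc": de_lfc,
            "planted_status": status,
            "low_expression": low_expr,
            "max_fpkm": fpkm.max(axis=1).values,
        }
    )
    truth_trans = pd.DataFrame(trans_rows, columns=["lncrna_id", "gene_id", "sign"])
    return counts_df, library_sizes, groups, lengths, truth_expr, truth_trans


# ---------------------------------------------------------------------------
# homology


def _fabricated_hit(
    qid: str,
    sid: str,
    qlen: int,
    aln_len: int,
    pident: float,
    mismatches: int,
    query_length: int | None = None,
) -> HomologyHit:
    bits = max(0.0, aln_len * (pident / 100.0 - 0.25) * 1.6)
    evalue = min(10.0, max(1e-180, qlen * 1e3 * 2.0 ** (-bits)))
    return HomologyHit(
        query_id=qid,
        subject_id=sid,
        percent_identity=round(pident, 2),
        alignment_length=aln_len,
        mismatches=mismatches,
        gap_opens=0,
        qstart=1,
        qend=aln_len,
        sstart=1,
        send=aln_len,
        evalue=evalue,
        bitscore=round(bits, 1),
        query_length=query_length,
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    arr = np.array(list(seq))
    hits = np.where(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr), len(hits)


def generate_homology(
    config: SynthConfig,
    lnc_sequences: Mapping[str, str],
    rng: np.random.Generator,
) -> tuple[
    dict[str, dict[str, str]],
    dict[str, list[HomologyHit]],
    dict[str, list[HomologyHit]],
    pd.DataFrame,
    pd.DataFrame,
]:
    """Fabricate per-species sequence sets and reciprocal hit tables.

    Planted pairs are full-length mutated copies whose fabricated hits pass
    the default filters in both directions; one-way homologs pass forward
    only (their reverse best points to a different query); decoys never
    pass.
    """
    ids = [i for i, s in sorted(lnc_sequences.items()) if len(s) >= 300]
    species_seqs: dict[str, dict[str, str]] = {}
    fwd: dict[str, list[HomologyHit]] = {}
    rev: dict[str, list[HomologyHit]] = {}
    rbh_rows, oneway_rows = [], []
    rate = config.homolog_mutation_rate
    for sp in config.species:
        seqs: dict[str, str] = {}
        f_hits: list[HomologyHit] = []
        r_hits: list[HomologyHit] = []
        picked = rng.choice(
            len(ids),
            size=min(len(ids), config.n_planted_homologs + config.n_oneway_homologs),
            replace=False,
        )
        planted = [ids[i] for i in picked[: config.n_planted_homologs]]
        oneway = [ids[i] for i in picked[config.n_planted_homologs :]]
        for k, qid in enumerate(planted):
            src = lnc_sequences[qid]
            mut, n_sub = _mutate(src, rate, rng)
            sid = f"{sp}_h{k + 1:03d}"
            seqs[sid] = mut
            pident = 100.0 * (1 - n_sub / len(src))
            f_hits.append(
                _fabricated_hit(qid, sid, len(src), len(src), pident, n_sub, len(src))
            )
            r_hits.append(
                _fabricated_hit(sid, qid, len(mut), len(mut), pident, n_sub, len(mut))
            )
            rbh_rows.append({"species": sp, "query_id": qid, "subject_id": sid})
        for k, qid in enumerate(oneway):
            src = lnc_sequences[qid]
            mut, n_sub = _mutate(src, rate, rng)
            sid = f"{sp}_w{k + 1:03d}"
            seqs[sid] = mut
            pident = 100.0 * (1 - n_sub / len(src))
            f_hits.append(
                _fabricated_hit(qid, sid, len(src), len(src), pident, n_sub, len(src))
            )
            # reverse best points at a different (planted) query, breaking RBH
            other = planted[k % len(planted)] if planted else qid
            if other != qid:
                r_hits.append(
                    _fabricated_hit(
                        sid, other, len(mut), len(mut), min(99.9, pident + 1.0),
                        n_sub, len(mut)
                    )
                )
            oneway_rows.append({"species": sp, "query_id": qid, "subject_id": sid})
        for k in range(config.n_decoy_homologs):
            sid = f"{sp}_d{k + 1:03d}"
            seqs[sid] = _iid_seq(int(rng.integers(300, 1500)), rng)
            qid = ids[int(rng.integers(len(ids)))]
            qlen = len(lnc_sequences[qid])
            aln = max(20, int(0.1 * qlen))  # coverage < 0.3 and weak E-value
            f_hits.append(
                _fabricated_hit(qid, sid, qlen, aln, 70.0, int(0.3 * aln), qlen)
            )
            r_hits.append(
                _fabricated_hit(
                    sid, qid, len(seqs[sid]), aln, 70.0, int(0.3 * aln), len(seqs[sid])
                )
            )
        species_seqs[sp] = seqs
        fwd[sp] = f_hits
        rev[sp] = r_hits
    truth_rbh = pd.DataFrame(rbh_rows, columns=["species", "query_id", "subject_id"])
    truth_oneway = pd.DataFrame(
        oneway_rows, columns=["species", "query_id", "subject_id"]
    )
    return species_seqs, fwd, rev, truth_rbh, truth_oneway


# ---------------------------------------------------------------------------
# cis truth and term map


def _cis_truth(
    novel: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    window: int = 100_000,
) -> pd.DataFrame:
    """Brute-force list of novel-transcript/gene pairs within the window."""
    rows = []
    for t in novel:
        for g in reference:
            if t.chrom != g.chrom:
                continue
            if t.start < g.end and g.start < t.end:
                gap = 0
            else:
                gap = max(g.start - t.end, t.start - g.end)
            if gap <= window:
                rows.append(
                    {
                        "transcript_id": t.transcript_id,
                        "gene_id": g.gene_id,
                        "distance": gap,
                    }
                )
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "distance"])


def _term_map(
    config: SynthConfig,
    ref_transcripts: Sequence[TranscriptModel],
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    for t in ref_transcripts:
        n = 1 + int(rng.integers(3))
        terms = rng.choice(config.n_terms, size=n, replace=False)
        for k in sorted(terms):
            rows.append(
                {
                    "term_id": f"T{k + 1:03d}",
                    "term_name": f"term_{k + 1:03d}",
                    "gene_id": t.gene_id,
                }
            )
    return pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"])


# ---------------------------------------------------------------------------
# bundle


def generate_bundle(config: SynthConfig) -> Bundle:
    """Run every generator stage off one seed; pure function of the config."""
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(6)]
    ref, chrom_sizes = generate_annotation(config, rngs[0])
    novel, truth_tx = generate_novel_transcripts(config, ref, chrom_sizes, rngs[1])
    ref_seqs, novel_seqs = generate_sequences(config, ref, novel, truth_tx, rngs[2])
    counts, libs, groups, lengths, truth_expr, truth_trans = generate_counts(
        config, ref, novel, truth_tx, rngs[3]
    )
    # homologs come from non-coding candidate sequences
    tinfo = truth_tx.set_index("transcript_id")
    lnc_like = {
        tid: seq
        for tid, seq in novel_seqs.items()
        if not bool(tinfo.loc[tid, "planted_coding"])
        and tinfo.loc[tid, "planted_class"] in ("u", "x", "i", "o")
    }
    species_seqs, fwd, rev, truth_rbh, truth_oneway = generate_homology(
        config, lnc_like, rngs[4]
    )
    terms = _term_map(config, ref, rngs[5])
    truth_cis = _cis_truth(novel, ref)
    return Bundle(
        config=config,
        chrom_sizes=chrom_sizes,
        ref_transcripts=ref,
        novel_transcripts=novel,
        ref_sequences=ref_seqs,
        novel_sequences=novel_seqs,
        counts=counts,
        library_sizes=libs,
        groups=groups,
        feature_lengths=lengths,
        species_sequences=species_seqs,
        forward_hits=fwd,
        reverse_hits=rev,
        term_map=terms,
        truth_transcripts=truth_tx,
        truth_expression=truth_expr,
        truth_rbh=truth_rbh,
        truth_oneway=truth_oneway,
        truth_cis=truth_cis,
        truth_trans=truth_trans,
    )


def write_bundle(bundle: Bundle, outdir: str | Path) -> Path:
    """Write the bundle in the exact formats the pipeline readers consume."""
    out = Path(outdir)
    (out / "homology").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    iof.write_gtf(bundle.ref_transcripts, out / "reference.gtf")
    iof.write_gtf(bundle.novel_transcripts, out / "novel.gtf")
    with open(out / "chrom_sizes.tsv", "w") as fh:
        for chrom, size in bundle.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    iof.write_fasta(bundle.ref_sequences, out / "ref_transcripts.fasta")
    iof.write_fasta(bundle.novel_sequences, out / "novel_transcripts.fasta")

    bundle.counts.to_csv(out / "counts.tsv", sep="\t", index_label="feature_id")
    samples = pd.DataFrame(
        {
            "sample": bundle.counts.columns,
            "group": bundle.groups.values,
            "library_size": bundle.library_sizes.values,
        }
    )
    samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    bundle.term_map.to_csv(out / "terms.tsv", sep="\t", index=False)

    for sp in bundle.config.species:
        iof.write_fasta(bundle.species_sequences[sp], out / "homology" / f"{sp}.fasta")
        iof.write_blast_tab(
            bundle.forward_hits[sp], out / "homology" / f"{sp}_forward.tsv"
        )
        iof.write_blast_tab(
            bundle.reverse_hits[sp], out / "homology" / f"{sp}_reverse.tsv"
        )

    kw = {"sep": "\t", "index": False, "float_format": "%.6g"}
    bundle.truth_transcripts.to_csv(out / "truth" / "transcripts.tsv", **kw)
    bundle.truth_expression.to_csv(out / "truth" / "expression.tsv", **kw)
    bundle.truth_rbh.to_csv(out / "truth" / "rbh.tsv", **kw)
    bundle.truth_oneway.to_csv(out / "truth" / "oneway.tsv", **kw)
    bundle.truth_cis.to_csv(out / "truth" / "cis_pairs.tsv", **kw)
    bundle.truth_trans.to_csv(out / "truth" / "trans_pairs.tsv", **kw)

    manifest = {
        "reference_gtf": "reference.gtf",
        "novel_gtf": "novel.gtf",
        "chrom_sizes": "chrom_sizes.tsv",
        "ref_fasta": "ref_transcripts.fasta",
        "novel_fasta": "novel_transcripts.fasta",
        "counts": "counts.tsv",
        "samples": "samples.tsv",
        "terms": "terms.tsv",
        "species": list(bundle.config.species),
        "homology_dir": "homology",
        "group_labels": list(bundle.config.group_labels),
        "config": {
            k: (list(v) if isinstance(v, tuple) else dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(bundle.config).items()
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out
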