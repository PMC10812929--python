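"""Cis / trans target inference and term enrichment for lncRNAs.

A protein-coding gene is a *cis* target when the gap between its locus span
and the lncRNA's locus span is at most a fixed window (100 kb by default,
strand-agnostic; 0 for overlap).  A *trans* target is a gene whose
expression profile across samples correlates with the lncRNA's (Pearson
|r| above a threshold with a significant two-sided t-test p).  Target gene
sets are tested for term enrichment with a one-sided hypergeometric test
and BH correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_de import bh_adjust
from .io_formats import TranscriptModel

log = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 100_000
DEFAULT_MIN_ABS_R = 0.95
DEFAULT_TRANS_ALPHA = 0.05

__all__ = [
    "TargetPair",
    "EnrichmentResult",
    "interval_gap",
    "cis_targets",
    "pearson",
    "trans_targets",
    "enrich",
    "export_network",
]


@dataclass(frozen=True)
class TargetPair:
    """One lncRNA -> PCG association, cis (distance) or trans (correlation)."""

    lncrna_id: str
    gene_id: str
    mode: str  # cis / trans
    distance: int | None = None
    r: float | None = None
    r_pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise ValueError(f"bad mode {self.mode!r}")
        if self.mode == "cis" and self.distance is None:
            raise ValueError("cis pair needs a distance")
        if self.mode == "trans" and (self.r is None or self.r_pvalue is None):
            raise ValueError("trans pair needs r and p")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # selected genes carrying the term
    K: int  # universe genes carrying the term
    n: int  # selected set size
    N: int  # universe size
    pvalue: float
    qvalue: float = float("nan")
    significant: bool = False


def interval_gap(
    chrom_a: str, start_a: int, end_a: int, chrom_b: str, start_b: int, end_b: int
) -> int | None:
    """Gap in bp between two locus spans; 0 when overlapping, None across chroms."""
    if chrom_a != chrom_b:
        return None
    if start_a < end_b and start_b < end_a:
        return 0
    return max(start_b - end_a, start_a - end_b)


def cis_targets(
    lncrnas: Sequence[TranscriptModel],
    genes: Sequence[TranscriptModel],
    window: int = DEFAULT_CIS_WINDOW,
) -> list[TargetPair]:
    """Genes whose locus span lies within ``window`` bp of an lncRNA span."""
    if window < 0:
        raise ValueError("window must be >= 0")
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs = []
    for lnc in lncrnas:
        for g in by_chrom.get(lnc.chrom, []):
            gap = interval_gap(lnc.chrom, lnc.start, lnc.end, g.chrom, g.start, g.end)
            if gap is not None and gap <= window:
                pairs.append(
                    TargetPair(
                        lncrna_id=lnc.transcript_id,
                        gene_id=g.gene_id,
                        mode="cis",
                        distance=gap,
                    )
                )
    return pairs


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment r with a two-sided t-test p (n - 2 df).

    Both vectors need length >= 3 and nonzero variance; a constant vector
    raises an undefined-correlation error (callers skip the pair).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("vectors must share length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def trans_targets(
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    min_abs_r: float = DEFAULT_MIN_ABS_R,
    alpha: float = DEFAULT_TRANS_ALPHA,
) -> list[TargetPair]:
    """Expression-correlated lncRNA-gene pairs over shared sample columns.

    Kept iff |r| >= min_abs_r (non-strict) and p < alpha.  Zero-variance
    features are skipped with a warning.  Correlations are computed
    vectorised; p-values follow the t transform with n - 2 df.
    """
    if list(lnc_expr.columns) != list(gene_expr.columns):
        raise ValueError("expression matrices must share sample columns")
    n = lnc_expr.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples")
    lx = lnc_expr.values.astype(float)
    gx = gene_expr.values.astype(float)
    l_sd = lx.std(axis=1)
    g_sd = gx.std(axis=1)
    l_ok = l_sd > 0
    g_ok = g_sd > 0
    for fid in lnc_expr.index[~l_ok]:
        log.warning("lncRNA %s has zero variance; skipped in trans inference", fid)
    for fid in gene_expr.index[~g_ok]:
        log.warning("gene %s has zero variance; skipped in trans inference", fid)
    lz = (lx - lx.mean(axis=1, keepdims=True))
    gz = (gx - gx.mean(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (lz @ gz.T) / (n * np.outer(l_sd, g_sd))
    corr = np.clip(corr, -1.0, 1.0)
    pairs = []
    df = n - 2
    for i, lnc_id in enumerate(lnc_expr.index):
        if not l_ok[i]:
            continue
        for j, gene_id in enumerate(gene_expr.index):
            if not g_ok[j]:
                continue
            r = corr[i, j]
            if abs(r) < min_abs_r:
                continue
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt(df / (1.0 - r * r))
                p = 2.0 * stats.t.sf(abs(t), df)
            if p < alpha:
                pairs.append(
                    TargetPair(
                        lncrna_id=str(lnc_id),
                        gene_id=str(gene_id),
                        mode="trans",
                        r=float(r),
                        r_pvalue=float(p),
                    )
                )
    return pairs


def enrich(
    selected_genes: set[str],
    universe_genes: set[str],
    term_map: Mapping[str, set[str]],
    q_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail term enrichment with BH correction.

    For each term with at least one universe gene: p = P(X >= k) under
    Hypergeometric(N, K, n), where N is the universe size, K the term's
    universe genes, n the selected set size and k the overlap.
    """
    if not selected_genes <= universe_genes:
        raise ValueError("selected genes must be a subset of the universe")
    N = len(universe_genes)
    n = len(selected_genes)
    rows = []
    for term_id in sorted(term_map):
        term_genes = term_map[term_id] & universe_genes
        K = len(term_genes)
        if K < 1:
            continue
        k = len(term_genes & selected_genes)
        # P(X >= k); sf(k-1) is the upper tail including k
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(1.0, max(p, 0.0))
        rows.append((term_id, k, K, p))
    if not rows:
        return []
    qvals = bh_adjust(np.array([r[3] for r in rows]))
    return [
        EnrichmentResult(
            term_id=term_id,
            k=k,
            K=K,
            n=n,
            N=N,
            pvalue=p,
            qvalue=float(q),
            significant=bool(q < q_threshold),
        )
        for (term_id, k, K, p), q in zip(rows, qvals)
    ]


def read_term_map(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a TSV term map (term_id, term_name, gene_id) into sets + names."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    term_map: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for _, row in df.iterrows():
        term_map.setdefault(row["term_id"], set()).add(row["gene_id"])
        names[row["term_id"]] = row.get("term_name", row["term_id"])
    return term_map, names


def export_network(
    pairs: Sequence[TargetPair],
    de_status: Mapping[str, str],
    path: str | Path,
) -> pd.DataFrame:
    """Write a generic edge table (one row per pair) importable by Cytoscape.

    Columns: source (lncRNA), target (gene), mode, distance, r, plus the DE
    status of each endpoint ('na' when unknown).  Returns the DataFrame.
    """
    rows = [
        {
            "source": p.lncrna_id,
            "target": p.gene_id,
            "mode": p.mode,
            "distance": "" if p.distance is None else p.distance,
            "r": "" if p.r is None else f"{p.r:.4f}",
            "source_de": de_status.get(p.lncrna_id, "na"),
            "target_de": de_status.get(p.gene_id, "na"),
        }
        for p in pairs
    ]
    df = pd.DataFrame(
        rows,
        columns=["source", "target", "mode", "distance", "r", "source_de", "target_de"],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
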