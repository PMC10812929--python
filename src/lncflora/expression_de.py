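"""FPKM computation and negative-binomial differential expression.

Differential expression between two conditions is called with an in-house
NB exact test: counts are scaled to a common effective library size, pooled
within groups (a sum of n iid NB(mu, phi) variables is NB(n*mu, phi/n)),
and the two-sided p-value is the total conditional probability of all
splits of the pooled sum no more likely than the observed one.  Dispersion
comes from a pooled within-group method-of-moments estimate with a small
floor and no empirical-Bayes shrinkage.  Benjamini-Hochberg controls the
FDR, and features with |log2FC| > 1 and q < 0.05 are flagged up/down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

DISPERSION_FLOOR = 1e-6
LOG2FC_PSEUDOCOUNT = 0.5

__all__ = [
    "DEResult",
    "fpkm",
    "estimate_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "call_de",
    "de_analysis",
]


@dataclass(frozen=True)
class DEResult:
    """Per-feature differential-expression call between two conditions."""

    feature_id: str
    base_mean_a: float
    base_mean_b: float
    log2fc: float
    pvalue: float
    qvalue: float
    status: str  # up / down / ns

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 and 0.0 <= self.qvalue <= 1.0):
            raise ValueError("p/q outside [0, 1]")
        if self.status not in ("up", "down", "ns"):
            raise ValueError(f"bad status {self.status!r}")


def fpkm(
    counts: pd.DataFrame,
    transcript_lengths: pd.Series,
    library_sizes: pd.Series,
) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads.

    FPKM[f, s] = counts[f, s] * 1e9 / (length[f] * library_size[s]).
    """
    lengths = transcript_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index[0]
        raise ValueError(f"no length for feature {missing}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be > 0")
    libs = library_sizes.reindex(counts.columns)
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("library sizes must be present and > 0")
    return counts.div(lengths, axis=0).div(libs, axis=1) * 1e9


def _normalized_counts(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Counts rescaled to the mean library size (common effective depth)."""
    libs = library_sizes.reindex(counts.columns).astype(float)
    return counts * (libs.mean() / libs)


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series,
    library_sizes: pd.Series | None = None,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Pooled within-group method-of-moments NB dispersion per feature.

    On library-size-normalized counts, each group contributes
    (s^2 - mu) against mu^2, weighted by its degrees of freedom; the pooled
    ratio is floored at ``floor``.  All-zero features sit at the floor.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    norm = _normalized_counts(counts, library_sizes)
    group_names = groups.unique()
    num = np.zeros(len(norm), dtype=float)
    den = np.zeros(len(norm), dtype=float)
    for g in group_names:
        cols = groups.index[groups == g]
        if len(cols) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
        sub = norm[cols].values
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        w = len(cols) - 1
        num += w * (s2 - mu)
        den += w * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    phi = np.maximum(phi, floor)
    return pd.Series(phi, index=counts.index, name="dispersion")


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    """log pmf of NB with mean/dispersion parameterisation (Poisson at phi=0)."""
    if mean <= 0:
        # degenerate at zero
        return np.where(k == 0, 0.0, -np.inf)
    if phi <= 0:
        return stats.poisson.logpmf(k, mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def nb_exact_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    phi: float,
    library_sizes: np.ndarray | None = None,
) -> float:
    """Two-sided NB exact test conditioning on the pooled count sum.

    Counts are first equalized to a common library size (pseudo-counts,
    rounded); the group sums are then NB with dispersion phi/n, and the
    p-value sums the conditional probabilities of every split of the total
    whose probability does not exceed the observed split's.  With phi = 0
    this reduces to the exact binomial split test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if not (np.all(a == np.floor(a)) and np.all(b == np.floor(b))):
        raise ValueError("counts must be integers")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    n_a, n_b = len(a), len(b)
    if library_sizes is not None:
        libs = np.asarray(library_sizes, dtype=float)
        if len(libs) != n_a + n_b:
            raise ValueError("library_sizes length mismatch")
        common = np.exp(np.mean(np.log(libs)))
        scaled = np.concatenate([a, b]) * (common / libs)
        a = np.round(scaled[:n_a])
        b = np.round(scaled[n_a:])
    sum_a = int(round(a.sum()))
    sum_b = int(round(b.sum()))
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    k = np.arange(total + 1)
    logp = _nb_logpmf(k, n_a * mu, phi / n_a) + _nb_logpmf(
        total - k, n_b * mu, phi / n_b
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[sum_a]
    p = probs[probs <= observed * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def call_de(
    log2fc: float, qvalue: float, lfc_threshold: float = 1.0, q_threshold: float = 0.05
) -> str:
    """Status from strict |log2FC| and q thresholds: 'up', 'down' or 'ns'."""
    if qvalue < q_threshold and log2fc > lfc_threshold:
        return "up"
    if qvalue < q_threshold and log2fc < -lfc_threshold:
        return "down"
    return "ns"


def de_analysis(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Full two-group DE table: log2FC(B/A), exact-test p, BH q, status.

    log2FC compares library-size-normalized group means with a pseudo-count
    of 0.5; group A is the baseline (e.g. FB), group B the contrast (FF).
    """
    groups = matrix.group_labels
    cols_a = list(groups.index[groups == group_a])
    cols_b = list(groups.index[groups == group_b])
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    counts = matrix.counts[cols_a + cols_b]
    libs = matrix.library_sizes[cols_a + cols_b]
    sub_groups = groups[cols_a + cols_b]
    if dispersion is None:
        dispersion = estimate_dispersion(counts, sub_groups, libs)
    norm = _normalized_counts(counts, libs)
    mean_a = norm[cols_a].mean(axis=1)
    mean_b = norm[cols_b].mean(axis=1)
    log2fc = np.log2((mean_b + LOG2FC_PSEUDOCOUNT) / (mean_a + LOG2FC_PSEUDOCOUNT))
    libs_arr = libs.values
    pvals = np.empty(len(counts))
    a_vals = counts[cols_a].values
    b_vals = counts[cols_b].values
    for i in range(len(counts)):
        pvals[i] = nb_exact_test(
            a_vals[i], b_vals[i], float(dispersion.iloc[i]), libs_arr
        )
    qvals = bh_adjust(pvals)
    status = [
        call_de(lfc, q, lfc_threshold, q_threshold)
        for lfc, q in zip(log2fc.values, qvals)
    ]
    return pd.DataFrame(
        {
            "base_mean_a": mean_a,
            "base_mean_b": mean_b,
            "log2fc": log2fc,
            "dispersion": dispersion.values,
            "pvalue": pvals,
            "qvalue": qvals,
            "status": status,
        },
        index=counts.index,
    )
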