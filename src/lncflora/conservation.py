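"""Cross-species lncRNA conservation from tabular homology hits.

A query is *conserved* in a species when it retains at least one hit after
the E-value / query-coverage filter (E < 1e-10, coverage >= 0.30 by
default), and *highly conserved* when it forms a reciprocal best hit: each
member is the unique best (bitscore, then E-value, then subject id) hit of
the other in the filtered tables of both directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import HomologyHit

DEFAULT_MAX_EVALUE = 1e-10
DEFAULT_MIN_COVERAGE = 0.30

__all__ = [
    "RBHPair",
    "filter_hits",
    "best_hit_per_query",
    "reciprocal_best_hits",
    "conservation_summary",
    "sharing_matrix",
]


@dataclass(frozen=True)
class RBHPair:
    """A reciprocal-best-hit pair between a jasmine lncRNA and another species."""

    query_id: str
    subject_id: str
    species: str
    forward_bitscore: float
    reverse_bitscore: float


def filter_hits(
    hits: Iterable[HomologyHit],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[HomologyHit]:
    """Keep hits with evalue < max_evalue and coverage >= min_coverage.

    The E-value inequality is strict and the coverage one is not; coverage
    is alignment length over the query length, which must be attached.
    """
    kept = []
    for h in hits:
        if h.query_length is None:
            raise ValueError(f"query length missing for {h.query_id}")
        if h.evalue < max_evalue and h.coverage >= min_coverage:
            kept.append(h)
    return kept


def best_hit_per_query(hits: Iterable[HomologyHit]) -> dict[str, HomologyHit]:
    """Deterministic best hit per query: max bitscore, min E-value, min subject id."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (-h.bitscore, h.evalue, h.subject_id)
        key_cur = (-cur.bitscore, cur.evalue, cur.subject_id)
        if key_new < key_cur:
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    forward_best: Mapping[str, HomologyHit],
    reverse_best: Mapping[str, HomologyHit],
    species: str,
) -> list[RBHPair]:
    """(q, s) is an RBH pair iff forward[q] == s and reverse[s] == q."""
    pairs = []
    for q, fh in sorted(forward_best.items()):
        s = fh.subject_id
        rh = reverse_best.get(s)
        if rh is not None and rh.subject_id == q:
            pairs.append(
                RBHPair(
                    query_id=q,
                    subject_id=s,
                    species=species,
                    forward_bitscore=fh.bitscore,
                    reverse_bitscore=rh.bitscore,
                )
            )
    return pairs


def conservation_summary(
    kept_forward: Mapping[str, Sequence[HomologyHit]],
    rbh: Mapping[str, Sequence[RBHPair]],
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Per-species conserved / highly-conserved counts plus sharing sets.

    ``kept_forward`` maps species -> filtered one-way hits (jasmine queries);
    ``rbh`` maps species -> RBH pairs.  Returns a summary table (species,
    n_conserved, n_highly_conserved) and, for sharing analysis, a map
    query_id -> set of species it is conserved in.
    """
    rows = []
    membership: dict[str, set[str]] = {}
    for species in sorted(kept_forward):
        conserved_ids = {h.query_id for h in kept_forward[species]}
        for qid in conserved_ids:
            membership.setdefault(qid, set()).add(species)
        n_rbh = len(rbh.get(species, []))
        if n_rbh > len(conserved_ids):
            raise ValueError(
                f"{species}: more RBH pairs than conserved queries"
            )
        rows.append(
            {
                "species": species,
                "n_conserved": len(conserved_ids),
                "n_highly_conserved": n_rbh,
            }
        )
    return pd.DataFrame(rows, columns=["species", "n_conserved", "n_highly_conserved"]), membership


def sharing_matrix(membership: Mapping[str, set[str]], species: Sequence[str]) -> pd.DataFrame:
    """Boolean query x species membership matrix (for upset-style plots)."""
    rows = {
        qid: {sp: sp in present for sp in species}
        for qid, present in sorted(membership.items())
    }
    return pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(species)).fillna(False)
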