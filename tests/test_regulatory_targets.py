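import math

import numpy as np
import pandas as pd
import pytest

from lncflora.io_formats import GenomicInterval, TranscriptModel
from lncflora.regulatory_targets import (
    cis_targets,
    enrich,
    export_network,
    interval_gap,
    pearson,
    trans_targets,
)


def _tx(tid, start, end, chrom="chr1", strand="+", gene=None):
    return TranscriptModel(
        tid,
        gene or tid,
        chrom,
        strand,
        (GenomicInterval(chrom, start, end, strand),),
    )


# ---------------------------------------------------------------------------
# cis targets


def test_cis_window_examples():
    lnc = _tx("L1", 200_000, 201_000)
    near = _tx("gN", 250_000, 252_000, gene="gN")
    far = _tx("gF", 350_000, 352_000, gene="gF")
    overlapping = _tx("gO", 200_500, 202_000, gene="gO")
    pairs = cis_targets([lnc], [near, far, overlapping], window=100_000)
    by_gene = {p.gene_id: p.distance for p in pairs}
    assert by_gene == {"gN": 49_000, "gO": 0}


def test_cis_gap_is_symmetric():
    assert interval_gap("c", 100, 200, "c", 500, 600) == interval_gap(
        "c", 500, 600, "c", 100, 200
    )
    assert interval_gap("c1", 0, 10, "c2", 0, 10) is None


def test_cis_window_monotone():
    rng = np.random.default_rng(4)
    lncs = [_tx(f"L{i}", int(s), int(s) + 500) for i, s in
            enumerate(rng.integers(0, 900_000, 20))]
    genes = [_tx(f"g{i}", int(s), int(s) + 2000, gene=f"g{i}") for i, s in
             enumerate(rng.integers(0, 900_000, 50))]
    small = {(p.lncrna_id, p.gene_id) for p in cis_targets(lncs, genes, 10_000)}
    large = {(p.lncrna_id, p.gene_id) for p in cis_targets(lncs, genes, 100_000)}
    assert small <= large


# ---------------------------------------------------------------------------
# correlation


def test_pearson_perfect_lines():
    r, p = pearson([1, 2, 3], [2, 4, 6])
    assert r == pytest.approx(1.0)
    r, _ = pearson([1, 2, 3], [6, 4, 2])
    assert r == pytest.approx(-1.0)


def test_pearson_constant_vector_raises():
    with pytest.raises(ValueError, match="zero-variance"):
        pearson([1, 2, 3], [5, 5, 5])


def test_trans_targets_linear_pair_kept_and_boundary_inclusive():
    samples = [f"s{i}" for i in range(6)]
    x = np.array([1.0, 5.0, 2.0, 8.0, 3.0, 9.0])
    lnc = pd.DataFrame([x], index=["L1"], columns=samples)
    genes = pd.DataFrame(
        [2 * x, 10 - x, np.array([4.0, 4.1, 3.9, 4.0, 4.2, 3.8])],
        index=["gPos", "gNeg", "gFlat"],
        columns=samples,
    )
    pairs = trans_targets(lnc, genes, min_abs_r=1.0, alpha=0.05)
    kept = {(p.lncrna_id, p.gene_id): p.r for p in pairs}
    # |r| == min_abs_r exactly is kept (non-strict >=), sign retained
    assert kept[("L1", "gPos")] == pytest.approx(1.0)
    assert kept[("L1", "gNeg")] == pytest.approx(-1.0)
    assert ("L1", "gFlat") not in kept


def test_trans_targets_skips_zero_variance_and_checks_columns():
    samples = [f"s{i}" for i in range(4)]
    lnc = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["L1"], columns=samples)
    genes = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g1"], columns=samples)
    assert trans_targets(lnc, genes, 0.5, 0.5) == []
    with pytest.raises(ValueError, match="sample columns"):
        trans_targets(lnc, genes[reversed(samples)], 0.5, 0.5)


def test_planted_coexpression_recovered(bundle):
    """All planted pairs found; decoy gene acceptance stays below 5%."""
    from lncflora.expression_de import fpkm

    fpkm_df = fpkm(bundle.counts, bundle.feature_lengths, bundle.library_sizes)
    planted = bundle.truth_trans
    lnc_ids = sorted(planted["lncrna_id"])
    gene_ids = [t.gene_id for t in bundle.ref_transcripts]
    pairs = trans_targets(fpkm_df.loc[lnc_ids], fpkm_df.loc[gene_ids], 0.95, 0.05)
    got = {(p.lncrna_id, p.gene_id) for p in pairs}
    want = set(map(tuple, planted[["lncrna_id", "gene_id"]].values))
    assert want <= got
    decoy_accepted = got - want
    n_decoy_pairs = len(lnc_ids) * len(gene_ids) - len(want)
    assert len(decoy_accepted) / n_decoy_pairs <= 0.05


# ---------------------------------------------------------------------------
# enrichment


def test_hypergeometric_examples():
    universe = {f"g{i}" for i in range(20)}
    term = {f"g{i}" for i in range(5)}
    selected = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(10, 15)}
    (res,) = enrich(selected, universe, {"T1": term})
    assert (res.k, res.K, res.n, res.N) == (5, 5, 10, 20)
    assert res.pvalue == pytest.approx(3003 / 184756)


def test_enrich_edge_cases():
    universe = {f"g{i}" for i in range(10)}
    term = {"g0", "g1"}
    # k = 0 -> upper tail covers the whole support -> p = 1
    (res,) = enrich({"g5", "g6"}, universe, {"T1": term})
    assert res.k == 0 and res.pvalue == pytest.approx(1.0)
    # selected == universe -> k == K, p == 1 for every term
    (res,) = enrich(universe, universe, {"T1": term})
    assert res.k == res.K and res.pvalue == pytest.approx(1.0)
    with pytest.raises(ValueError, match="subset"):
        enrich({"gX"}, universe, {"T1": term})


def test_hypergeometric_matches_enumeration_small_universes():
    """Spot-check p against explicit combinatorial enumeration."""
    rng = np.random.default_rng(9)
    for _ in range(40):
        N = int(rng.integers(2, 16))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        k_max = min(K, n)
        k = int(rng.integers(max(0, K + n - N), k_max + 1))
        universe = {f"g{i}" for i in range(N)}
        term = {f"g{i}" for i in range(K)}
        selected = {f"g{i}" for i in range(k)} | {
            f"g{i}" for i in range(K, K + n - k)
        }
        (res,) = enrich(selected, universe, {"T": term})
        oracle = sum(
            math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, k_max + 1)
        ) / math.comb(N, n)
        assert res.pvalue == pytest.approx(oracle, rel=1e-9)


# ---------------------------------------------------------------------------
# network export


def test_export_network_rows(tmp_path):
    from lncflora.regulatory_targets import TargetPair

    pairs = [
        TargetPair("L1", "g1", "cis", distance=1234),
        TargetPair("L1", "g2", "trans", r=0.99, r_pvalue=0.001),
    ]
    path = tmp_path / "edges.tsv"
    df = export_network(pairs, {"L1": "up", "g1": "down"}, path)
    assert len(df) == len(pairs)
    back = pd.read_csv(path, sep="\t")
    assert list(back["mode"]) == ["cis", "trans"]
    assert back.loc[0, "source_de"] == "up" and back.loc[1, "target_de"] == "na"


def test_export_network_empty(tmp_path):
    path = tmp_path / "edges.tsv"
    export_network([], {}, path)
    assert pd.read_csv(path, sep="\t").empty
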