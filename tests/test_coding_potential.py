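import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lncflora.coding_potential import (
    HexamerModel,
    Thresholds,
    background_hexamer_model,
    ensemble_noncoding_vote,
    fickett_score,
    hexamer_llr,
    ingest_external_predictions,
    longest_orf,
    score_transcripts,
    train_hexamer_model,
)
from lncflora.synthetic_data import _coding_seq

# ---------------------------------------------------------------------------
# ORF finder


def brute_force_longest_orf(seq):
    """Enumerate every (ATG, stop) pair in 3 frames; the independent oracle."""
    seq = seq.upper()
    stops = {"TAA", "TAG", "TGA"}
    best = (0, 0, 0, False)  # length, -start preference handled below
    candidates = []
    for frame in range(3):
        codons = [
            (pos, seq[pos : pos + 3]) for pos in range(frame, len(seq) - 2, 3)
        ]
        for i, (pos, codon) in enumerate(codons):
            if codon != "ATG":
                continue
            closed = False
            for j in range(i + 1, len(codons)):
                if codons[j][1] in stops:
                    candidates.append((codons[j][0] + 3 - pos, pos, frame, True))
                    closed = True
                    break
            if not closed:
                candidates.append((3 * (len(codons) - i), pos, frame, False))
    if not candidates:
        return (0, 0, 0, False)
    return max(candidates, key=lambda c: (c[0], -c[1], -c[2]))


@pytest.mark.parametrize(
    "seq,length,start,has_stop",
    [
        ("ATGGCCTAA", 9, 0, True),
        ("CCCCCC", 0, 0, False),
        ("ATGATGTAA", 9, 0, True),  # outer frame-0 ORF subsumes the inner one
        ("", 0, 0, False),
        ("ATGAAA", 6, 0, False),  # open-ended, no stop
    ],
)
def test_longest_orf_examples(seq, length, start, has_stop):
    orf = longest_orf(seq)
    assert (orf.length, orf.start, orf.has_stop) == (length, start, has_stop)


def test_longest_orf_matches_brute_force_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(150):
        n = int(rng.integers(0, 120))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        got = longest_orf(seq)
        exp_len, exp_start, _frame, exp_stop = brute_force_longest_orf(seq)
        assert got.length == exp_len
        if exp_len:
            assert (got.start, got.has_stop) == (exp_start, exp_stop)


# ---------------------------------------------------------------------------
# TESTCODE statistic


def test_fickett_deterministic():
    seq = "ATGGCGTACGATCGTAGCTAGCTAGCATCGATCG" * 6
    assert fickett_score(seq) == fickett_score(seq)


def test_fickett_homopolymer_frozen_value():
    """Hand application of the published tables to A*60.

    Per-frame A counts are (20, 20, 20), so the positional ratio 20/21 falls
    into the lowest bin; C/G/T have zero counts everywhere.  A-content 1.0
    takes the top content bin, the rest the bottom one.  The weighted sum of
    the tabulated probabilities is 0.3066.
    """
    assert fickett_score("A" * 60) == pytest.approx(0.3066, abs=1e-10)


def test_fickett_separates_coding_from_dinucleotide_shuffle():
    """A codon-biased CDS outscores its dinucleotide-shuffled self >= 95%."""
    rng = np.random.default_rng(42)
    wins = 0
    for _ in range(200):
        cds = _coding_seq(300, rng)
        pairs = [cds[i : i + 2] for i in range(0, len(cds) - 1, 2)]
        rng.shuffle(pairs)
        wins += fickett_score(cds) > fickett_score("".join(pairs))
    assert wins >= 190


# ---------------------------------------------------------------------------
# hexamer model


def test_hexamer_training_single_observation():
    m = train_hexamer_model(["AAAAAA"], pseudocount=1)
    probs = m.probs
    assert probs[0] == pytest.approx(2 / 4097)
    assert probs[1] == pytest.approx(1 / 4097)
    assert probs.sum() == pytest.approx(1.0)


def test_hexamer_training_order_invariant():
    seqs = ["ACGTACGTAC", "GGGCCCAAATTT", "ATATATATAT"]
    a = train_hexamer_model(seqs)
    b = train_hexamer_model(list(reversed(seqs)))
    np.testing.assert_allclose(a.log_probs, b.log_probs)


def test_hexamer_training_empty_corpus_raises():
    with pytest.raises(ValueError, match="empty"):
        train_hexamer_model([])


def test_hexamer_llr_identical_models_and_antisymmetry():
    m = train_hexamer_model(["ACGTACGTACGTAAACCCGGGTTT"])
    n = train_hexamer_model(["AAAATTTTCCCCGGGGACGTACGT"])
    seq = "ACGTAAACCCGGGTTTACGT"
    assert hexamer_llr(seq, m, m) == 0.0
    assert hexamer_llr(seq, m, n) == pytest.approx(-hexamer_llr(seq, n, m))
    assert hexamer_llr("ACG", m, n) == 0.0  # too short -> 0 with a note


def test_hexamer_llr_closed_form_enrichment():
    """A sequence made of one hexamer enriched 2x scores exactly log 2."""
    uniform = np.full(4096, math.log(1 / 4096))
    enriched = uniform.copy()
    enriched[0] += math.log(2)  # AAAAAA
    coding = HexamerModel(enriched)
    noncoding = HexamerModel(uniform)
    assert hexamer_llr("A" * 30, coding, noncoding) == pytest.approx(math.log(2))


def test_background_model_is_zero_order():
    m = background_hexamer_model(["ACGT" * 50])
    # uniform composition -> every hexamer at (1/4)^6
    np.testing.assert_allclose(m.probs, 1 / 4096, rtol=1e-9)


# ---------------------------------------------------------------------------
# ensemble


def _verdict(calls):
    """Drive each predictor's call through rigged thresholds on a fixed seq."""
    uniform = np.full(4096, math.log(1 / 4096))
    coding = HexamerModel(uniform + np.linspace(-0.01, 0.01, 4096))
    noncoding = HexamerModel(uniform)
    seq = "ATGGCC" * 20 + "TAA"  # known ORF of 123 nt, llr != 0
    base = ensemble_noncoding_vote("t", seq, coding, noncoding)
    orf_c, fick_c, hex_c = calls
    th = Thresholds(
        min_orf_nt=base.orf_length if orf_c else base.orf_length + 1,
        min_fickett=base.fickett if fick_c else base.fickett + 1,
        min_hexamer_llr=base.hexamer_llr - 0.1 if hex_c else base.hexamer_llr + 0.1,
    )
    v = ensemble_noncoding_vote("t", seq, coding, noncoding, th)
    assert v.calls == calls
    return v


@pytest.mark.parametrize(
    "calls,expect_noncoding",
    [
        ((False, False, False), True),
        ((False, False, True), False),
        ((True, False, False), False),
        ((True, True, True), False),
    ],
)
def test_intersection_rule(calls, expect_noncoding):
    assert _verdict(calls).is_noncoding == expect_noncoding


@given(
    st.tuples(st.booleans(), st.booleans(), st.booleans()),
    st.integers(0, 2),
)
def test_ensemble_monotonicity(calls, flip_idx):
    """Turning any call to 'coding' never turns is_noncoding back on."""
    before = not any(calls)
    stricter = list(calls)
    stricter[flip_idx] = True
    after = not any(stricter)
    assert not (after and not before)


def test_ensemble_recovers_planted_labels(bundle):
    """Built-in trio vs generator truth: accuracy and false-coding bounds."""
    coding_model = train_hexamer_model(bundle.ref_sequences.values())
    noncoding_model = background_hexamer_model(bundle.ref_sequences.values())
    verdicts = score_transcripts(
        bundle.novel_sequences, coding_model, noncoding_model
    )
    truth = bundle.truth_transcripts.set_index("transcript_id")["planted_coding"]
    n_correct = sum(
        verdicts[tid].is_noncoding != bool(truth[tid]) for tid in truth.index
    )
    accuracy = n_correct / len(truth)
    assert accuracy >= 0.90
    lnc_ids = truth.index[~truth]
    false_coding = sum(not verdicts[t].is_noncoding for t in lnc_ids) / len(lnc_ids)
    assert false_coding <= 0.15


def test_short_and_ny_sequences_flagged():
    m = HexamerModel(np.full(4096, math.log(1 / 4096)))
    v = ensemble_noncoding_vote("t", "ACGT" * 10, m, m)
    assert "short_sequence" in v.warnings
    v2 = ensemble_noncoding_vote("t", "N" * 100 + "ACGT" * 100, m, m)
    assert "n_fraction_gt_10pct" in v2.warnings


# ---------------------------------------------------------------------------
# external predictor ingestion


def test_ingest_external_tables():
    cpc2 = pd.DataFrame({"id": ["t1", "t2", "t3"], "label": ["noncoding", "coding", "noncoding"]})
    cnci = pd.DataFrame({"id": ["t1", "t2", "t3"], "score": [-0.5, 0.2, -0.1]})
    pfam = pd.DataFrame({"id": ["t2"]})
    verdicts = ingest_external_predictions(cpc2, cnci, pfam)
    assert verdicts["t1"].is_noncoding
    assert not verdicts["t2"].is_noncoding  # coding in all three
    assert verdicts["t3"].is_noncoding  # no Pfam hit == non-coding there


def test_ingest_absent_transcript_excluded():
    cpc2 = pd.DataFrame({"id": ["t1", "t2"], "label": ["noncoding", "noncoding"]})
    cnci = pd.DataFrame({"id": ["t1"], "score": [-1.0]})
    pfam = pd.DataFrame({"id": []})
    verdicts = ingest_external_predictions(cpc2, cnci, pfam)
    assert set(verdicts) == {"t1"}


def test_ingest_bad_label_raises():
    cpc2 = pd.DataFrame({"id": ["t1"], "label": ["maybe"]})
    cnci = pd.DataFrame({"id": ["t1"], "score": [0.0]})
    with pytest.raises(ValueError, match="t1"):
        ingest_external_predictions(cpc2, cnci, pd.DataFrame({"id": []}))
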