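import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from lncflora.expression_de import (
    DISPERSION_FLOOR,
    bh_adjust,
    call_de,
    de_analysis,
    estimate_dispersion,
    fpkm,
    nb_exact_test,
)
from lncflora.io_formats import ExpressionMatrix

# ---------------------------------------------------------------------------
# FPKM


@pytest.mark.parametrize(
    "count,length,lib,expected",
    [(100, 2000, 1e7, 5.0), (0, 2000, 1e7, 0.0), (10, 1000, 1e6, 10.0)],
)
def test_fpkm_formula(count, length, lib, expected):
    counts = pd.DataFrame({"s1": {"f1": count}})
    out = fpkm(counts, pd.Series({"f1": length}), pd.Series({"s1": lib}))
    assert out.loc["f1", "s1"] == pytest.approx(expected)


def test_fpkm_zero_length_raises():
    counts = pd.DataFrame({"s1": {"f1": 5}})
    with pytest.raises(ValueError, match="> 0"):
        fpkm(counts, pd.Series({"f1": 0}), pd.Series({"s1": 1e6}))


# ---------------------------------------------------------------------------
# dispersion


def _one_group(values):
    df = pd.DataFrame([values], index=["f1"],
                      columns=[f"s{i}" for i in range(len(values))])
    groups = pd.Series("A", index=df.columns)
    libs = pd.Series(1.0, index=df.columns)  # normalization is the identity
    return estimate_dispersion(df, groups, libs).iloc[0]


def test_dispersion_poisson_like_hits_floor():
    # mean 10, sample variance 1 -> negative moment estimate -> floor
    assert _one_group([9, 10, 11]) == DISPERSION_FLOOR


def test_dispersion_moment_formula():
    # mean 10, sample variance 25: phi = (25 - 10) / 100 = 0.15
    assert _one_group([5, 10, 15]) == pytest.approx(0.15)


def test_dispersion_all_zero_feature_at_floor():
    assert _one_group([0, 0, 0]) == DISPERSION_FLOOR


def test_dispersion_recovered_from_nb_simulation():
    """Median moment estimate lands near the simulated dispersion."""
    rng = np.random.default_rng(7)
    phi, mu, n = 0.2, 100.0, 6
    lam = rng.gamma(1 / phi, mu * phi, size=(2000, n))
    counts = pd.DataFrame(rng.poisson(lam), columns=[f"s{i}" for i in range(n)])
    groups = pd.Series("A", index=counts.columns)
    libs = pd.Series(1e7, index=counts.columns)
    est = estimate_dispersion(counts, groups, libs)
    assert 0.1 <= est.median() <= 0.4


# ---------------------------------------------------------------------------
# NB exact test


def test_exact_test_identical_groups_p_one():
    assert nb_exact_test([5, 5], [5, 5], 0.3) == pytest.approx(1.0)


def test_exact_test_binomial_closed_form():
    # phi = 0, equal libraries: (0) vs (10) -> 2 * (1/2)^10
    assert nb_exact_test([0], [10], 0.0) == pytest.approx(2 * 0.5**10)


def test_exact_test_group_swap_symmetry():
    rng = np.random.default_rng(5)
    for _ in range(20):
        a = rng.poisson(40, 3)
        b = rng.poisson(60, 3)
        assert nb_exact_test(a, b, 0.1) == pytest.approx(
            nb_exact_test(b, a, 0.1), rel=1e-12
        )


def test_exact_test_agrees_with_binomial_split_oracle():
    """At phi = 0 the conditional law is exactly binomial (oracle check)."""
    rng = np.random.default_rng(3)
    for _ in range(30):
        a = rng.poisson(80, 3)
        b = rng.poisson(80, 3)
        p_impl = nb_exact_test(a, b, 0.0)
        total = a.sum() + b.sum()
        pmf = stats.binom.pmf(np.arange(total + 1), total, 0.5)
        p_oracle = pmf[pmf <= pmf[a.sum()] * (1 + 1e-12)].sum()
        assert abs(p_impl - p_oracle) < 1e-6


def test_exact_test_unequal_libraries_shift_the_null():
    # the same counts are unremarkable once library sizes explain them
    p_equal = nb_exact_test([10], [40], 0.0)
    p_scaled = nb_exact_test([10], [40], 0.0, library_sizes=[1e6, 4e6])
    assert p_scaled > p_equal


def test_exact_test_input_validation():
    with pytest.raises(ValueError, match="integer"):
        nb_exact_test([1.5], [2], 0.1)
    with pytest.raises(ValueError, match="non-negative"):
        nb_exact_test([-1], [2], 0.1)
    with pytest.raises(ValueError, match="dispersion"):
        nb_exact_test([1], [2], -0.1)
    assert nb_exact_test([0, 0], [0, 0], 0.1) == 1.0


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_step_up_hand_example():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_trivial_cases():
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
)
def test_bh_matches_step_up_formula_and_dominates_p(pvals):
    """Independent implementation of the step-up formula as oracle."""
    p = np.array(pvals)
    q = bh_adjust(p)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    expected = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        expected[idx] = running
    np.testing.assert_allclose(q, expected, atol=1e-12)
    assert np.all(q >= p - 1e-12)


# ---------------------------------------------------------------------------
# DE calls


@pytest.mark.parametrize(
    "lfc,q,status",
    [
        (2.0, 0.01, "up"),
        (-2.0, 0.01, "down"),
        (0.5, 0.001, "ns"),
        (1.0, 0.001, "ns"),  # strict inequality on |lfc|
        (2.0, 0.05, "ns"),  # strict inequality on q
    ],
)
def test_call_de_thresholds(lfc, q, status):
    assert call_de(lfc, q) == status


def test_de_analysis_swap_negates_log2fc():
    rng = np.random.default_rng(2)
    counts = pd.DataFrame(
        rng.poisson([[50], [200]], size=(2, 6)),
        index=["f1", "f2"],
        columns=[f"s{i}" for i in range(6)],
    )
    m = ExpressionMatrix(
        counts,
        pd.Series(1e7, index=counts.columns),
        pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns),
    )
    ab = de_analysis(m, "A", "B")
    ba = de_analysis(m, "B", "A")
    np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"])
    np.testing.assert_allclose(ab["pvalue"], ba["pvalue"])


def test_de_analysis_detects_a_planted_change():
    rng = np.random.default_rng(8)
    n = 60
    means = np.full((n, 6), 100.0)
    means[0, 3:] *= 8  # one strongly induced feature
    counts = pd.DataFrame(
        rng.poisson(means),
        index=[f"f{i}" for i in range(n)],
        columns=[f"s{i}" for i in range(6)],
    )
    m = ExpressionMatrix(
        counts,
        pd.Series(1e7, index=counts.columns),
        pd.Series(["FB"] * 3 + ["FF"] * 3, index=counts.columns),
    )
    res = de_analysis(m, "FB", "FF")
    assert res.loc["f0", "status"] == "up"
    assert (res["status"] == "ns").sum() >= n - 3
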