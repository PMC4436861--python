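"""Binomial family-level tests: tails, classification, G-test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import brute_binomial_tails
from saltrait.diversity import (
    FamilyRecord,
    binomial_tails,
    classify_family,
    classify_table,
    g_test_fit,
    overall_proportion,
)


def test_overall_proportion_survey_totals():
    # 2852 halophyte species over 276,000 across two pseudo-families
    records = [
        FamilyRecord("a", 200_000, 2000),
        FamilyRecord("b", 76_000, 852),
    ]
    assert overall_proportion(records) == pytest.approx(2852 / 276_000)
    assert overall_proportion(records) == pytest.approx(0.010333, abs=1e-6)


def test_overall_proportion_edge_cases():
    assert overall_proportion([FamilyRecord("a", 10, 0)]) == 0.0
    assert overall_proportion([FamilyRecord("a", 10, 10)]) == 1.0
    with pytest.raises(ValueError):
        overall_proportion([])


def test_binomial_tails_closed_forms():
    p_more, p_fewer = binomial_tails(0, 50, 0.3)
    assert p_more == 1.0
    p_more, _ = binomial_tails(10, 10, 0.5)
    assert p_more == pytest.approx(0.5**10)
    with pytest.raises(ValueError):
        binomial_tails(11, 10, 0.5)


@pytest.mark.parametrize(
    "k,n,p",
    [(5, 12, 0.3), (0, 20, 0.1), (20, 20, 0.9), (7, 100, 0.05), (250, 500, 0.5)],
)
def test_binomial_tails_match_brute_force(k, n, p):
    expect = brute_binomial_tails(k, n, p)
    got = binomial_tails(k, n, p)
    assert got[0] == pytest.approx(expect[0], rel=1e-9, abs=1e-12)
    assert got[1] == pytest.approx(expect[1], rel=1e-9, abs=1e-12)


@given(n=st.integers(1, 400), k_frac=st.floats(0, 1), p=st.floats(0.001, 0.999))
@settings(max_examples=80, deadline=None, derandomize=True)
def test_tail_conservation(n, k_frac, p):
    """P(X>=k) + P(X<=k) - P(X=k) == 1 to near machine precision."""
    k = min(n, int(k_frac * (n + 1)))
    p_more, p_fewer = binomial_tails(k, n, p)
    pmf = stats.binom.pmf(k, n, p)
    assert p_more + p_fewer - pmf == pytest.approx(1.0, abs=1e-12)


def test_classification_published_like_records():
    p_hat = 2852 / 276_000
    tam = classify_family(FamilyRecord("Tamaricaceae", 90, 55), p_hat)
    assert tam.classification == "more"
    aca = classify_family(FamilyRecord("Acanthaceae", 4000, 18), p_hat)
    assert aca.classification == "fewer"
    # count right at the expectation: neither strict tail fires
    mid = classify_family(FamilyRecord("mid", 1000, 10), 0.01)
    assert mid.classification == "expected"
    assert mid.expected_k == pytest.approx(10.0)


def test_classification_monotone_in_k():
    order = {"fewer": 0, "expected": 1, "more": 2}
    codes = [
        order[classify_family(FamilyRecord("f", 100, k), 0.05).classification]
        for k in range(101)
    ]
    assert codes == sorted(codes)


def test_classification_strict_inequality_at_alpha():
    # engineer p_fewer exactly at alpha: P(X <= k) compared with alpha=itself
    rec = FamilyRecord("edge", 10, 0)
    p_more, p_fewer = binomial_tails(0, 10, 0.5)
    verdict = classify_family(rec, 0.5, alpha=p_fewer)
    assert verdict.classification == "expected"  # ties are not significant


def test_g_test_perfect_fit_and_hand_value():
    perfect = [FamilyRecord("a", 100, 10), FamilyRecord("b", 300, 30)]
    res = g_test_fit(perfect)
    assert res.G == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    # [[10,90],[30,70]]: G = 2 sum O ln(O/E) with margin expecteds
    table = [FamilyRecord("a", 100, 10), FamilyRecord("b", 100, 30)]
    obs = np.array([[10, 90], [30, 70]], dtype=float)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    g_hand = 2 * (obs * np.log(obs / expected)).sum()
    res = g_test_fit(table)
    assert res.G == pytest.approx(g_hand)
    assert res.df == 1


def test_g_test_matches_scipy_log_likelihood_route():
    rng = np.random.default_rng(11)
    sizes = rng.integers(50, 2000, size=12)
    ks = rng.binomial(sizes, 0.08)
    records = [
        FamilyRecord(f"f{i}", int(n), int(k)) for i, (n, k) in enumerate(zip(sizes, ks))
    ]
    res = g_test_fit(records)
    table = np.array([[r.k_halophytes, r.n_species - r.k_halophytes] for r in records])
    g2, p2, df2, _ = stats.chi2_contingency(table, correction=False,
                                            lambda_="log-likelihood")
    assert res.G == pytest.approx(float(g2))
    assert res.df == int(df2)
    assert res.p_value == pytest.approx(float(p2))


def test_g_test_input_validation():
    with pytest.raises(ValueError):
        g_test_fit([FamilyRecord("only", 10, 1)])


def test_g_test_null_rejection_rate():
    """Under binomial-null tables the G-test rejects near the nominal 5%.

    Family sizes are heavy-tailed, so some expected cell counts are small
    and the chi-square reference is mildly anticonservative; the band
    [0.02, 0.09] allows that documented approximation slack plus
    Monte-Carlo error at 1000 replicates.
    """
    from saltrait.synthetic import generate_family_table

    reps = 1000
    rejections = sum(
        g_test_fit(generate_family_table(60, 0.2, 50_000 + r)).p_value < 0.05
        for r in range(reps)
    )
    assert 0.02 <= rejections / reps <= 0.09


def test_record_invariants():
    with pytest.raises(ValueError):
        FamilyRecord("bad", 10, 11)
    with pytest.raises(ValueError):
        FamilyRecord("bad", 0, 0)


def test_classify_table_uses_table_proportion():
    records = [FamilyRecord(f"f{i}", 100, 1) for i in range(10)]
    verdicts = classify_table(records)
    assert all(v.classification == "expected" for v in verdicts)
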