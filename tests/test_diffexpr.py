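"""Differential expression: normalisation arithmetic, the exact
conditional count test against a rational-arithmetic oracle, and
power/type-I behaviour on simulated counts."""

import math
import random

import numpy as np
import pytest
from scipy.stats import kstest

from bovmir.config import PipelineConfig
from bovmir.diffexpr import (
    audic_claverie_p,
    classify_expression,
    conditional_log_pmf,
    de_summary,
    de_table,
    fold_change,
    normalize,
    ratio_ne,
)
from oracles import exact_conditional_pmf, exact_two_sided_p


# --- normalisation and fold change ---------------------------------------


@pytest.mark.parametrize(
    "count,total,ne",
    [(100, 10**6, 100.0), (0, 10**6, 0.0), (10**6, 10**6, 10**6)],
)
def test_normalize_tpm(count, total, ne):
    assert normalize(count, total) == pytest.approx(ne)


def test_zero_count_pseudo_tpm_for_ratios_only():
    assert normalize(0, 10**6) == 0.0
    assert ratio_ne(0, 10**6) == 0.01


def test_normalize_rejects_zero_total():
    with pytest.raises(ValueError):
        normalize(5, 0)


def test_fold_change_identities():
    assert fold_change(50.0, 50.0) == 0.0
    assert fold_change(200.0, 50.0) == pytest.approx(2.0)
    assert fold_change(50.0, 200.0) == pytest.approx(-2.0)


@pytest.mark.parametrize(
    "fc,cls", [(math.log2(3), "up"), (0.0, "unchanged"), (-1.0, "down"), (1.0, "unchanged")]
)
def test_expression_classes_with_boundaries(fc, cls):
    # ratio 3 -> up; ratio 1 -> unchanged; ratio exactly 1/2 -> down;
    # ratio exactly 2 -> unchanged (the class is ">2-fold")
    assert classify_expression(fc) == cls


# --- the exact conditional test ------------------------------------------


def test_pmf_of_zero_given_zero_is_half():
    assert math.exp(conditional_log_pmf(0, 0, 10**6, 10**6)) == pytest.approx(0.5)


def test_pmf_symmetry_at_equal_depths():
    for x, y in [(0, 5), (3, 7), (40, 11)]:
        a = conditional_log_pmf(y, x, 10**6, 10**6)
        b = conditional_log_pmf(x, y, 10**6, 10**6)
        assert a == pytest.approx(b, rel=1e-12)


def test_pvalue_matches_exact_oracle_to_ten_digits():
    """Log-gamma evaluation vs exact rational summation of the same series
    over a grid of counts and depth ratios."""
    rng = random.Random(2024)
    grid = [(x, y) for x in (0, 1, 5, 20, 80, 200) for y in (0, 1, 7, 50, 200)]
    grid += [(rng.randint(0, 200), rng.randint(0, 200)) for _ in range(20)]
    for n1, n2 in [(10**6, 5 * 10**5), (10**6, 10**6), (10**6, 2 * 10**6)]:
        for x, y in grid:
            got = audic_claverie_p(x, y, n1, n2)
            want = float(exact_two_sided_p(x, y, n1, n2))
            assert got == pytest.approx(want, rel=5e-11), (x, y, n1, n2)


def test_pmf_normalises_to_one():
    from scipy.special import logsumexp

    from bovmir.diffexpr import _log_pmf

    for x, r in [(0, 1.0), (17, 0.5), (120, 2.0)]:
        n1 = 10**6
        ks = np.arange(0, 20000, dtype=float)
        total = float(np.exp(logsumexp(_log_pmf(ks, x, n1, r * n1))))
        assert total == pytest.approx(1.0, abs=1e-10)


def test_library_swap_duality():
    """Swapping (x, N1) with (y, N2) maps the lower tail onto the upper
    tail (N1*p(y|x) = N2*p(x|y) pointwise) and negates the fold change."""
    for x, y, n1, n2 in [(5, 50, 10**6, 10**6), (12, 3, 2 * 10**6, 10**6)]:
        direct = math.exp(conditional_log_pmf(y, x, n1, n2))
        swapped = math.exp(conditional_log_pmf(x, y, n2, n1))
        assert n2 * direct == pytest.approx(n1 * swapped, rel=1e-10)
        # which tail is the small one flips with the swap
        c = sum(exact_conditional_pmf(k, x, n1, n2) for k in range(y + 1))
        c_swapped = sum(exact_conditional_pmf(k, y, n2, n1) for k in range(x + 1))
        assert (c > 0.5) != (c_swapped > 0.5)
        f1 = fold_change(ratio_ne(x, n1), ratio_ne(y, n2))
        f2 = fold_change(ratio_ne(y, n2), ratio_ne(x, n1))
        assert f1 == pytest.approx(-f2)


def test_rejects_non_integer_counts():
    with pytest.raises(ValueError):
        audic_claverie_p(1.5, 2, 10**6, 10**6)
    with pytest.raises(ValueError):
        audic_claverie_p(-1, 2, 10**6, 10**6)


def test_null_pvalues_near_uniform():
    """Under the null (equal true rates), the p-values are close to uniform
    apart from discreteness at finite counts."""
    rng = np.random.default_rng(77)
    lam = 200
    n = 10_000
    xs = rng.poisson(lam, n)
    ys = rng.poisson(lam, n)
    ps = np.array([audic_claverie_p(int(x), int(y), 10**6, 10**6) for x, y in zip(xs, ys)])
    stat = kstest(ps, "uniform").statistic
    assert stat < 0.1


# --- table level ----------------------------------------------------------


def test_de_table_power_and_false_positives():
    """20 planted 4-fold miRNAs among 200 nulls at 1e5 reads/library:
    at least 18 detected at BH-adjusted p <= 0.01, few false positives."""
    rng = np.random.default_rng(42)
    n1 = n2 = 10**5
    counts1, counts2 = {}, {}
    truth = set()
    for i in range(220):
        mid = f"m{i:03d}"
        base = float(rng.lognormal(math.log(200), 0.5))
        if i < 20:
            truth.add(mid)
            counts1[mid] = int(rng.poisson(4 * base))
            counts2[mid] = int(rng.poisson(base))
        else:
            counts1[mid] = int(rng.poisson(base))
            counts2[mid] = int(rng.poisson(base))
    table = de_table(counts1, counts2, n1, n2, PipelineConfig(alpha=0.01))
    detected = set(table[table["significant"]].index)
    assert len(truth & detected) >= 18
    assert len(detected - truth) <= 4
    summary = de_summary(table)
    assert summary["significant"] == len(detected)


def test_all_null_counts_control_type_one_error():
    rng = np.random.default_rng(7)
    n1 = n2 = 10**5
    counts1 = {f"m{i}": int(rng.poisson(100)) for i in range(2000)}
    counts2 = {f"m{i}": int(rng.poisson(100)) for i in range(2000)}
    table = de_table(counts1, counts2, n1, n2, PipelineConfig(alpha=0.05))
    raw_rate = float((table["p_value"] <= 0.05).mean())
    assert raw_rate <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / len(table))
    assert int(table["significant"].sum()) <= 5  # BH on top of an exact test


def test_unobserved_mirna_excluded():
    table = de_table({"a": 10, "b": 0}, {"a": 5, "b": 0}, 10**6, 10**6)
    assert list(table.index) == ["a"]
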