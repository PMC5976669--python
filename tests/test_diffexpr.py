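"""Exact NB test, scaling, TPM, fold change, FDR and ddCt utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from degradome.diffexpr import (
    bh_fdr,
    call_de,
    compute_tpm,
    ddct_fold_change,
    de_analysis,
    estimate_common_dispersion,
    exact_nb_test,
    normalize_libraries,
    rank_sum_test,
    signed_fold_change,
)
from degradome.io import ExpressionMatrix, ValidationError
from degradome.simulate import simulate_two_group_counts

GROUPS_44 = {f"A{i}": "A" for i in range(1, 5)} | {f"B{i}": "B" for i in range(1, 5)}


def _matrix(rows, n_a=4, n_b=4):
    cols = [f"A{i}" for i in range(1, n_a + 1)] + [f"B{i}" for i in range(1, n_b + 1)]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# TPM


def test_tpm_single_transcript_is_a_million():
    tpm = compute_tpm(pd.DataFrame({"s": [17]}, index=["t"]), {"t": 500})
    assert tpm.loc["t", "s"] == pytest.approx(1e6)


def test_tpm_length_scaling_and_hand_table():
    counts = pd.DataFrame({"s": [100, 100]}, index=["a", "b"])
    tpm = compute_tpm(counts, {"a": 1000, "b": 2000})
    assert tpm.loc["a", "s"] / tpm.loc["b", "s"] == pytest.approx(2.0)

    counts5 = pd.DataFrame({"x": [10, 20, 0, 5, 40]}, index=list("abcde"))
    lens = {"a": 100, "b": 200, "c": 300, "d": 400, "e": 500}
    rates = np.array([10 / 100, 20 / 200, 0, 5 / 400, 40 / 500])
    expected = rates / rates.sum() * 1e6
    tpm5 = compute_tpm(counts5, lens)
    np.testing.assert_allclose(tpm5["x"].to_numpy(), expected)
    assert tpm5["x"].sum() == pytest.approx(1e6, rel=1e-9)


def test_tpm_missing_length_names_transcript():
    with pytest.raises(ValidationError, match="tX"):
        compute_tpm(pd.DataFrame({"s": [1]}, index=["tX"]), {})


# ---------------------------------------------------------------------------
# Library scaling


def test_identical_columns_give_unit_factors():
    counts = pd.DataFrame({"s1": [5, 9, 2], "s2": [5, 9, 2], "s3": [5, 9, 2]})
    np.testing.assert_allclose(normalize_libraries(counts).to_numpy(), 1.0)


def test_doubled_column_gives_factor_ratio_two():
    counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
    f = normalize_libraries(counts)
    assert f["s2"] / f["s1"] == pytest.approx(2.0)
    assert np.exp(np.log(f.to_numpy()).mean()) == pytest.approx(1.0)


def test_factors_match_bruteforce_trimmed_log_ratio(rng):
    counts = pd.DataFrame(
        rng.integers(1, 1000, size=(50, 4)), columns=list("wxyz")
    )
    f = normalize_libraries(counts, trim=0.3)
    # independent brute force: per-sample trimmed mean of log ratios to the
    # per-gene geometric mean, computed by explicit sort-and-slice
    x = counts.to_numpy(dtype=float)
    ref = np.exp(np.log(x).mean(axis=1))
    expected = []
    for j in range(4):
        lr = np.sort(np.log2(x[:, j] / ref))
        k = int(0.3 * lr.size)
        expected.append(np.mean(lr[k : lr.size - k]))
    expected = np.array(expected)
    expected -= expected.mean()
    np.testing.assert_allclose(np.log2(f.to_numpy()), expected, atol=1e-9)


def test_all_zero_sample_is_named():
    counts = pd.DataFrame({"ok": [1, 2], "bad": [0, 0]})
    with pytest.raises(ValidationError, match="bad"):
        normalize_libraries(counts)


# ---------------------------------------------------------------------------
# Dispersion


def test_dispersion_estimates_converge_to_truth(rng):
    counts, groups = simulate_two_group_counts(5000, depth=2e5, phi=0.0, rng=rng)
    assert estimate_common_dispersion(counts, groups) < 0.02
    counts, groups = simulate_two_group_counts(5000, depth=2e5, phi=0.4, rng=rng)
    assert 0.3 <= estimate_common_dispersion(counts, groups) <= 0.5


def test_all_zero_matrix_returns_zero_with_warning():
    counts = _matrix(np.zeros((5, 8), dtype=int))
    with pytest.warns(UserWarning):
        assert estimate_common_dispersion(counts, GROUPS_44, lib_sizes=pd.Series(1.0, index=counts.columns)) == 0.0


def test_single_group_rejected():
    counts = _matrix(np.ones((3, 8), dtype=int))
    with pytest.raises(ValidationError):
        estimate_common_dispersion(counts, {c: "A" for c in counts.columns})


# ---------------------------------------------------------------------------
# Exact NB test


def _equal_libs(counts):
    return pd.Series(1e6, index=counts.columns)


def test_balanced_split_gives_p_one():
    counts = _matrix([[10, 10, 10, 10, 10, 10, 10, 10]])
    p = exact_nb_test(counts, GROUPS_44, 0.2, _equal_libs(counts))
    assert p.iloc[0] == pytest.approx(1.0)


def test_poisson_limit_matches_exact_binomial():
    counts = _matrix([[0, 0, 0, 0, 5, 5, 5, 5], [100, 100, 100, 100, 100, 100, 100, 100]])
    p = exact_nb_test(counts, GROUPS_44, 0.0, _equal_libs(counts))
    # two-sided exact binomial: both extreme splits of 20 at p=1/2
    expected = 2 * stats.binom.pmf(0, 20, 0.5)
    assert p.iloc[0] == pytest.approx(expected, rel=1e-10)


def _brute_force_p(sa, sb, na, nb, phi):
    """Linear-space enumeration of all splits, weighted by NB probabilities."""
    s = sa + sb
    mu = s / (na + nb)

    def pmf(k, mean, ph):
        if ph == 0:
            return stats.poisson.pmf(k, mean)
        r = 1.0 / ph
        return stats.nbinom.pmf(k, r, r / (r + mean))

    w = np.array([pmf(a, na * mu, phi / na) * pmf(s - a, nb * mu, phi / nb) for a in range(s + 1)])
    w = w / w.sum()
    return min(1.0, w[w <= w[sa] * (1 + 1e-12)].sum())


@pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
def test_exact_test_matches_enumeration_small_totals(phi, rng):
    for _ in range(30):
        total = int(rng.integers(1, 31))
        sa = int(rng.integers(0, total + 1))
        row = np.zeros(8, dtype=int)
        row[0], row[4] = sa, total - sa
        counts = _matrix([row])
        p = exact_nb_test(counts, GROUPS_44, phi, _equal_libs(counts)).iloc[0]
        assert p == pytest.approx(_brute_force_p(sa, total - sa, 4, 4, phi), abs=1e-10)


def test_negative_dispersion_rejected():
    counts = _matrix([[1] * 8])
    with pytest.raises(ValidationError):
        exact_nb_test(counts, GROUPS_44, -0.5)


# ---------------------------------------------------------------------------
# Fold change


@pytest.mark.parametrize(
    "a,b,expected", [(10, 30, 3.0), (30, 10, -3.0), (5, 5, 1.0), (0, 0, 1.0)]
)
def test_signed_fold_change_examples(a, b, expected):
    assert signed_fold_change(a, b, 0.0) == pytest.approx(expected)


def test_zero_vs_positive_is_infinite_sentinel():
    assert signed_fold_change(0.0, 3.0) == np.inf
    assert signed_fold_change(3.0, 0.0) == -np.inf
    assert signed_fold_change(0.0, 3.0, pseudocount=1.0) == pytest.approx(4.0)
    with pytest.raises(ValidationError):
        signed_fold_change(1, 2, pseudocount=-1)


# ---------------------------------------------------------------------------
# FDR


def test_bh_hand_computation():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert bh_fdr([0.2])[0] == pytest.approx(0.2)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_is_monotone_and_dominates_p(p):
    q = bh_fdr(p)
    assert (q >= np.asarray(p) - 1e-12).all() and (q <= 1).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# Calling


def test_call_de_printed_cases_and_boundaries():
    table = pd.DataFrame(
        {
            "id": ["atrogin-1", "mid", "let-7j", "boundary", "weak_p"],
            "fold_change": [377.71, 2.9, -1056.3, 3.0, 8.0],
            "p": [0.0, 0.0, 0.0, 0.0, 0.5],
            "fdr": [6.909e-16, 1e-9, 0.00069, 1e-9, 0.5],
        }
    )
    out = call_de(table, fc_threshold=3, fdr_threshold=0.01)
    assert list(out["call"]) == ["up", "not-DE", "down", "not-DE", "not-DE"]


def test_de_analysis_null_and_power(rng):
    counts, groups = simulate_two_group_counts(400, depth=4e5, phi=0.1, rng=rng)
    tab = de_analysis(ExpressionMatrix(counts, groups=groups))
    assert (tab["call"] != "not-DE").mean() <= 0.02

    folds = {i: (8.0 if i % 2 else -8.0) for i in range(40)}
    counts, groups = simulate_two_group_counts(400, depth=4e5, phi=0.1, folds=folds, rng=rng)
    tab = de_analysis(ExpressionMatrix(counts, groups=groups))
    planted = tab.iloc[:40]
    assert (planted["call"] != "not-DE").mean() >= 0.9
    # direction: even indices were planted down (negative fold), odd up
    assert (planted["call"].to_numpy()[1::2] == "up").mean() >= 0.9


# ---------------------------------------------------------------------------
# qPCR


@pytest.mark.parametrize(
    "cts,expected",
    [((20, 15, 24, 15), 16.0), ((20, 20, 20, 20), 1.0), ((17, 20, 20, 20), 8.0)],
)
def test_ddct_examples(cts, expected):
    assert ddct_fold_change(*cts) == pytest.approx(expected)


def test_rank_sum_exact_for_small_n():
    case = [5.1, 5.3, 5.2, 5.4]
    ctrl = [1.0, 1.2, 1.1, 1.3]
    p = rank_sum_test(case, ctrl)
    # exact two-sided Mann-Whitney at n=m=4, complete separation
    assert p == pytest.approx(2 / 70, rel=1e-9)
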