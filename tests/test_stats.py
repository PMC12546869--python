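"""Statistical kernels: BH FDR, t-test, enrichment, ordinal regression,
DE classification."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy import special
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

from stressomics.stats import (
    bh_fdr,
    classify_de,
    filter_low_counts,
    hypergeometric_enrichment,
    one_sample_t,
    proportional_odds_fit,
)


# --- Benjamini-Hochberg --------------------------------------------------

def bh_brute_force(p):
    """Literal step-up definition: q_(i) = min_{j >= i} p_(j) * m / j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_index, i in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_index, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q


def test_bh_hand_example():
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_trivial_cases():
    assert bh_fdr([0.5]) == pytest.approx([0.5])
    assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)
    assert bh_fdr([]).size == 0


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_bh_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = rng.integers(1, 40)
        p = rng.uniform(size=n)
        if rng.random() < 0.3:
            p[rng.integers(0, n)] = p[0]  # ties
        assert bh_fdr(p) == pytest.approx(bh_brute_force(list(p)))


def test_bh_matches_statsmodels():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=500)
    _, q_sm, _, _ = multipletests(p, method="fdr_bh")
    assert bh_fdr(p) == pytest.approx(q_sm)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_order_preserving_and_bounded(p):
    q = bh_fdr(p)
    assert np.all((q >= 0) & (q <= 1))
    assert np.all(q >= np.asarray(p) - 1e-12)
    # monotone in sorted p
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


# --- one-sample t --------------------------------------------------------

def test_t_symmetric_values_give_p_one():
    t, p = one_sample_t([-1.0, 1.0], mu0=0.0)
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_t_hand_computed_value():
    t, p = one_sample_t([0.9, 1.1, 1.0], mu0=0.0)
    assert t == pytest.approx(17.3205, abs=1e-3)


def test_t_degenerate_inputs():
    with pytest.raises(ValueError):
        one_sample_t([1.0])
    with pytest.warns(UserWarning, match="zero-variance"):
        t, p = one_sample_t([1.0, 1.0, 1.0])
    assert math.isnan(t) and math.isnan(p)


# --- hypergeometric enrichment -------------------------------------------

def hypergeom_tail_enumeration(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of the hypergeometric pmf."""
    total = 0.0
    for j in range(k, min(n, K) + 1):
        total += (
            math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
        )
    return total


def _universe(N, K, n, k):
    background = [f"g{i}" for i in range(N)]
    term_genes = background[:K]
    study = background[: k] + background[K: K + (n - k)]
    return study, background, {"T": term_genes}


def test_enrichment_hand_example():
    study, background, ann = _universe(50, 10, 5, 3)
    res = hypergeometric_enrichment(study, background, ann)
    assert res[0].p_value == pytest.approx(0.04826, abs=1e-4)
    assert (res[0].k, res[0].n, res[0].K, res[0].N) == (3, 5, 10, 50)


def test_enrichment_certain_event():
    study, background, ann = _universe(20, 20, 20, 20)
    res = hypergeometric_enrichment(study, background, ann)
    assert res[0].p_value == pytest.approx(1.0)


def test_enrichment_skips_zero_hit_terms():
    study, background, _ = _universe(50, 10, 5, 3)
    ann = {"EMPTY": background[40:45]}
    assert hypergeometric_enrichment(study[:3], background, ann) == []


def test_enrichment_rejects_stray_study_gene():
    with pytest.raises(ValueError, match="absent from background"):
        hypergeometric_enrichment(["zzz"], ["g1"], {"T": ["g1"]})


def test_enrichment_matches_enumeration_small_universes():
    rng = np.random.default_rng(3)
    for _ in range(50):
        N = int(rng.integers(5, 61))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        k_max = min(n, K)
        k = int(rng.integers(1, k_max + 1))
        if k > n or (n - k) > (N - K):
            continue
        study, background, ann = _universe(N, K, n, k)
        res = hypergeometric_enrichment(study, background, ann)
        assert res[0].p_value == pytest.approx(
            hypergeom_tail_enumeration(N, K, n, k), rel=1e-9
        )


# --- proportional odds ---------------------------------------------------

def simulate_ordinal(beta, cutpoints, n, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 1))
    cdf = special.expit(np.asarray(cutpoints)[None, :] - x * beta)
    y = (rng.uniform(size=n)[:, None] > cdf).sum(axis=1)
    return y, x


def test_po_matches_statsmodels_ordered_model():
    y, x = simulate_ordinal(1.0, [-1.0, 0.0, 1.0], n=400, seed=5)
    ours = proportional_odds_fit(y, x)
    theirs = OrderedModel(y, x, distr="logit").fit(method="bfgs", disp=0)
    assert ours.converged
    assert ours.coefficients[0] == pytest.approx(theirs.params[0], abs=1e-4)
    assert ours.log_likelihood == pytest.approx(theirs.llf, abs=1e-6)
    assert np.all(np.diff(ours.cutpoints) > 0)


def test_po_two_states_reduces_to_logistic_regression():
    y, x = simulate_ordinal(0.8, [0.0], n=300, seed=6)
    ours = proportional_odds_fit(y, x)
    logit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    assert ours.coefficients[0] == pytest.approx(logit.params[1], abs=1e-6)
    # cutpoint equals the negated logistic intercept
    assert ours.cutpoints[0] == pytest.approx(-logit.params[0], abs=1e-6)


def test_po_null_beta_within_two_se():
    inside = 0
    n_sims = 40
    for s in range(n_sims):
        y, x = simulate_ordinal(0.0, [-1.0, 0.0, 1.0], n=200, seed=100 + s)
        fit = proportional_odds_fit(y, x)
        if abs(fit.coefficients[0]) <= 2 * fit.beta_se[0]:
            inside += 1
    assert inside >= 0.9 * n_sims


def test_po_fractional_weights_equal_count_expansion():
    y = np.array([0, 1, 2, 0, 1, 2])
    x = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]])
    w = np.array([4.0, 2.0, 1.0, 1.0, 2.0, 4.0])
    weighted = proportional_odds_fit(y, x, weights=w)
    y_exp = np.repeat(y, w.astype(int))
    x_exp = np.repeat(x, w.astype(int), axis=0)
    expanded = proportional_odds_fit(y_exp, x_exp)
    assert weighted.coefficients[0] == pytest.approx(
        expanded.coefficients[0], abs=1e-6
    )
    # downscaled fractional weights give the same point estimate
    scaled = proportional_odds_fit(y, x, weights=w / w.sum())
    assert scaled.coefficients[0] == pytest.approx(
        expanded.coefficients[0], abs=1e-5
    )


def test_po_wald_test_detects_strong_effect():
    y, x = simulate_ordinal(2.0, [-1.0, 1.0], n=500, seed=9)
    fit = proportional_odds_fit(y, x)
    z, p = fit.wald_test()
    assert p[0] < 1e-6


# --- DE classification and count filtering -------------------------------

@pytest.mark.parametrize(
    "fc, p, expected",
    [
        (-0.8, 0.049, "down"),    # inclusive fold-change boundary
        (-0.79, 0.01, "unchanged"),
        (2.0, 0.05, "unchanged"),  # strict p boundary
        (0.8, 0.049, "up"),
        (0.0, 0.001, "unchanged"),
    ],
)
def test_classify_de_thresholds(fc, p, expected):
    table = pd.DataFrame({"gene_id": ["g"], "log2_fc": [fc], "adj_p": [p]})
    assert classify_de(table)["call"].iloc[0] == expected


def test_classify_de_missing_p_warns_unchanged():
    table = pd.DataFrame({
        "gene_id": ["a", "b"],
        "log2_fc": [2.0, 2.0],
        "adj_p": [np.nan, 0.01],
    })
    with pytest.warns(UserWarning, match="missing adjusted p"):
        out = classify_de(table)
    assert list(out["call"]) == ["unchanged", "up"]


def test_classify_de_threshold_monotone():
    rng = np.random.default_rng(8)
    table = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(100)],
        "log2_fc": rng.normal(0, 1.5, 100),
        "adj_p": rng.uniform(size=100),
    })
    loose = classify_de(table, fc_threshold=0.8)
    strict = classify_de(table, fc_threshold=1.6)
    changed_loose = set(loose[loose["call"] != "unchanged"]["gene_id"])
    changed_strict = set(strict[strict["call"] != "unchanged"]["gene_id"])
    assert changed_strict <= changed_loose


def test_filter_low_counts_boundary():
    counts = pd.DataFrame(
        [[0, 1, 0], [1, 1, 0], [0, 0, 0]],
        index=["sum1", "sum2", "sum0"],
        columns=["s1", "s2", "s3"],
    )
    out = filter_low_counts(counts)
    assert list(out.index) == ["sum2"]


def test_filter_low_counts_all_zero_and_negative():
    empty = filter_low_counts(pd.DataFrame(np.zeros((3, 2), dtype=int)))
    assert len(empty) == 0
    with pytest.raises(ValueError, match="negative"):
        filter_low_counts(pd.DataFrame([[-1, 2]]))
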