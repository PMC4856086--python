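"""Statistics core against independent oracles: hand-computed closed forms,
direct log-pmf summation, statsmodels GLM / multipletests, pydeseq2 size
factors, and parameter-recovery simulations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cistrans import nbcore
from cistrans.nbcore import (
    CountMatrix,
    GlmError,
    bh_adjust,
    estimate_dispersions,
    estimate_size_factors,
    filter_low_counts,
    fit_nb_glm,
    nb_loglik,
    wald_test,
)

# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------


def test_size_factors_hand_example():
    # rows (2,4) and (6,12): geometric means sqrt(8), sqrt(72); both ratio
    # columns are (1/sqrt2, sqrt2)
    m = pd.DataFrame({"c1": [2, 6], "c2": [4, 12]})
    sf = estimate_size_factors(m)
    assert sf.to_numpy() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])


def test_size_factors_identical_columns_and_scale_equivariance():
    rng = np.random.default_rng(0)
    base = rng.integers(1, 500, size=(50, 4))
    m = pd.DataFrame(base, columns=list("abcd"))
    sf = estimate_size_factors(m)
    assert estimate_size_factors(pd.DataFrame({"x": base[:, 0], "y": base[:, 0]})).to_numpy() == pytest.approx([1, 1])
    # scale equivariance: multiplying one column by 10 multiplies its factor
    # relative to every other column by 10 (the geometric-mean reference
    # rescales all factors by a common constant, here 10^(1/4))
    scaled = m.copy()
    scaled["b"] = scaled["b"] * 10
    sf2 = estimate_size_factors(scaled)
    assert sf2["b"] / sf2["a"] == pytest.approx(10 * sf["b"] / sf["a"])
    assert (sf2[["a", "c", "d"]] / sf[["a", "c", "d"]]).to_numpy() == pytest.approx(
        np.full(3, 10 ** (-1 / 4))
    )


def test_size_factors_row_permutation_invariant():
    rng = np.random.default_rng(1)
    m = pd.DataFrame(rng.integers(1, 300, size=(40, 5)))
    perm = m.sample(frac=1.0, random_state=2)
    assert estimate_size_factors(m).to_numpy() == pytest.approx(
        estimate_size_factors(perm).to_numpy()
    )


def test_size_factors_requires_positive_feature_unless_fallback():
    m = pd.DataFrame({"c1": [0, 5], "c2": [3, 0]})
    with pytest.raises(ValueError, match="positive-subset"):
        estimate_size_factors(m)
    sf = estimate_size_factors(m, fallback="positive-subset")
    assert (sf > 0).all()


def test_size_factors_match_pydeseq2():
    pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
    rng = np.random.default_rng(3)
    counts = rng.negative_binomial(10, 0.05, size=(200, 6))
    _, ref = pydeseq2.deseq2_norm(counts.T)  # samples x genes convention
    mine = estimate_size_factors(pd.DataFrame(counts))
    assert mine.to_numpy() == pytest.approx(np.asarray(ref), rel=1e-10)


# ---------------------------------------------------------------------------
# NB likelihood and GLM
# ---------------------------------------------------------------------------


def test_nb_loglik_equals_direct_logpmf_summation():
    rng = np.random.default_rng(4)
    for _ in range(25):
        n = rng.integers(3, 15)
        mu = rng.uniform(0.5, 2000, size=n)
        alpha = rng.uniform(1e-4, 2.0)
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
        r = 1.0 / alpha
        direct = float(stats.nbinom.logpmf(y, r, r / (r + mu)).sum())
        assert abs(nb_loglik(y, mu, alpha) - direct) < 1e-8


def test_saturated_two_group_mle_equals_ratio_of_means():
    """With unit size factors, the two-group NB MLE log2FC is exactly the
    log2 ratio of group mean counts."""
    rng = np.random.default_rng(5)
    groups = np.array(["a"] * 4 + ["b"] * 4)
    X, names = nbcore.two_group_design(groups, "a")
    for _ in range(10):
        y = rng.integers(1, 400, size=8).astype(float)
        fit = fit_nb_glm(y, np.ones(8), 0.1, X, names)
        l2fc, *_ = wald_test(fit, "b_vs_a")
        expected = np.log2(y[4:].mean() / y[:4].mean())
        assert l2fc == pytest.approx(expected, abs=1e-8)


@pytest.mark.parametrize(
    "counts,expected",
    [([100, 100, 100, 100, 100, 100], 0.0), ([10, 10, 10, 40, 40, 40], 2.0)],
)
def test_two_group_fixed_examples(counts, expected):
    groups = np.array(["a"] * 3 + ["b"] * 3)
    X, names = nbcore.two_group_design(groups, "a")
    fit = fit_nb_glm(np.array(counts, dtype=float), np.ones(6), 0.05, X, names)
    l2fc, *_ = wald_test(fit, "b_vs_a")
    assert l2fc == pytest.approx(expected, abs=1e-9)


def test_glm_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(6)
    groups = np.array(["a"] * 3 + ["b"] * 3)
    X, names = nbcore.two_group_design(groups, "a")
    y = rng.negative_binomial(20, 20 / (20 + np.array([100.0, 120, 80, 300, 310, 290])))
    sf = np.array([0.9, 1.0, 1.1, 0.95, 1.05, 1.0])
    fit = fit_nb_glm(y, sf, 0.05, X, names)
    ref = sm.GLM(
        y, X, family=sm.families.NegativeBinomial(alpha=0.05), offset=np.log(sf)
    ).fit()
    assert fit.beta == pytest.approx(np.asarray(ref.params), abs=1e-6)
    assert np.sqrt(np.diag(fit.cov)) == pytest.approx(np.asarray(ref.bse), rel=1e-4)


def test_interaction_recovery():
    """2x2 factorial NB data with a true interaction of 1.5 log2: the mean
    estimate over 1000 features is within +-0.05."""
    rng = np.random.default_rng(7)
    is_p = np.repeat([0.0, 1.0], 6)
    is_b = np.tile([0.0, 1.0], 6)
    X = np.column_stack([np.ones(12), is_p, is_b, is_p * is_b])
    names = ["intercept", "typeP", "alleleB", "typeP:alleleB"]
    true = 1.5
    mu = 500 * 2.0 ** (0.3 * is_p + 0.2 * is_b + true * is_p * is_b)
    alpha = 0.05
    estimates = []
    for _ in range(1000):
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
        fit = fit_nb_glm(y.astype(float), np.ones(12), alpha, X, names)
        estimates.append(wald_test(fit, "typeP:alleleB")[0])
    assert np.mean(estimates) == pytest.approx(true, abs=0.05)


def test_glm_failures():
    groups = np.array(["a"] * 3 + ["b"] * 3)
    X, names = nbcore.two_group_design(groups, "a")
    with pytest.raises(GlmError):
        fit_nb_glm(np.zeros(6), np.ones(6), 0.05, X, names)
    with pytest.raises(GlmError):  # one group entirely zero -> separation
        fit_nb_glm(np.array([50.0, 60, 55, 0, 0, 0]), np.ones(6), 0.05, X, names)
    bad = np.column_stack([np.ones(6), np.ones(6)])
    with pytest.raises(GlmError):
        fit_nb_glm(np.array([5.0, 6, 7, 8, 9, 10]), np.ones(6), 0.05, bad, ["a", "b"])


def test_wald_examples():
    X, names = nbcore.two_group_design(np.array(["a", "a", "b", "b"]), "a")
    fit = fit_nb_glm(np.array([30.0, 30, 30, 30]), np.ones(4), 0.05, X, names)
    fit.beta = np.array([np.log(30), 0.0])
    fit.cov = np.eye(2)
    l2fc, se, z, p = wald_test(fit, "b_vs_a")
    assert (l2fc, z, p) == pytest.approx((0.0, 0.0, 1.0))
    fit.beta = np.array([0.0, 1.959964])
    assert wald_test(fit, "b_vs_a")[3] == pytest.approx(0.05, abs=1e-6)
    fit.cov = np.zeros((2, 2))
    with pytest.raises(GlmError):
        wald_test(fit, "b_vs_a")
    with pytest.raises(KeyError):
        wald_test(fit, "no_such_coef")


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def test_bh_worked_examples():
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    out = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(out[1]) and out[0] == pytest.approx(0.02)


def test_bh_matches_statsmodels():
    multitest = pytest.importorskip("statsmodels.stats.multitest")
    rng = np.random.default_rng(8)
    p = rng.uniform(size=200)
    ref = multitest.multipletests(p, method="fdr_bh")[1]
    assert bh_adjust(p) == pytest.approx(ref)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
def test_bh_properties(pvals):
    p = np.array(pvals)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in p
    perm = np.random.default_rng(0).permutation(len(p))
    assert bh_adjust(p[perm]) == pytest.approx(adj[perm])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# filtering and dispersions
# ---------------------------------------------------------------------------


def test_filter_low_counts():
    rng = np.random.default_rng(9)
    counts = pd.DataFrame(rng.integers(50, 150, size=(7, 4)))
    low = pd.DataFrame([[0, 0, 0, 0], [1, 0, 1, 0], [2, 1, 0, 1]], columns=counts.columns,
                       index=[7, 8, 9])
    m = pd.concat([counts, low])
    sf = pd.Series(1.0, index=m.columns)
    kept, removed = filter_low_counts(m, sf, threshold=5.0)
    assert len(kept) == 7 and set(removed) == {7, 8, 9}
    kept0, removed0 = filter_low_counts(m, sf, threshold=0.0)
    assert len(kept0) == 10 and len(removed0) == 0
    _, removed1 = filter_low_counts(m, sf, threshold=1.0)
    assert 7 in removed1  # all-zero feature goes at any positive threshold


def test_dispersion_recovery_constant_alpha():
    rng = np.random.default_rng(10)
    n, cols, alpha = 2000, 12, 0.05
    mu = 500 * np.exp(rng.normal(0, 0.5, size=n))
    counts = pd.DataFrame(
        rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu[:, None]), size=(n, cols))
    )
    sf = estimate_size_factors(counts, fallback="positive-subset")
    X = np.ones((cols, 1))
    ds = estimate_dispersions(counts, sf, X)
    assert 0.04 <= ds.final.median() <= 0.06


def test_dispersion_poisson_limit():
    # tested at a mean where dispersion is statistically resolvable:
    # at mu=2000 the sampling noise of alpha-hat is well below 1e-3
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(rng.poisson(2000.0, size=(500, 12)))
    sf = estimate_size_factors(counts, fallback="positive-subset")
    ds = estimate_dispersions(counts, sf, np.ones((12, 1)))
    assert ds.final.median() <= 1e-3


def test_dispersion_fixed_alpha_passthrough():
    counts = pd.DataFrame([[10, 12, 9, 11]], index=["f1"])
    sf = pd.Series(1.0, index=counts.columns)
    ds = estimate_dispersions(counts, sf, np.ones((4, 1)), fixed_alpha=0.2)
    assert float(ds.final["f1"]) == 0.2 and float(ds.genewise["f1"]) == 0.2


def test_dispersion_needs_residual_df():
    counts = pd.DataFrame([[10, 12, 9]])
    sf = pd.Series(1.0, index=counts.columns)
    with pytest.raises(ValueError, match="fixed_alpha"):
        estimate_dispersions(counts, sf, np.eye(3)[:, :2])


# ---------------------------------------------------------------------------
# CountMatrix container
# ---------------------------------------------------------------------------


def test_count_matrix_validation_and_roundtrip(tmp_path):
    counts = pd.DataFrame([[1, 2], [3, 4]], columns=["s1", "s2"], index=["f1", "f2"])
    meta = pd.DataFrame({"population": ["AUS", "TIM"]}, index=["s1", "s2"])
    cm = CountMatrix(counts, meta)
    cm.to_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
    back = CountMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
    pd.testing.assert_frame_equal(back.counts, counts.rename_axis("feature"))
    with pytest.raises(ValueError):
        CountMatrix(counts * -1, meta)
    with pytest.raises(ValueError):
        CountMatrix(counts, meta.iloc[::-1])
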