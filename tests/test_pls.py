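"""PLS decompositions against brute-force SVD oracles, closed-form rank-1
cases, the literal permutation-p rule, and bootstrap reliability output."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connfit.pls import (
    BehavioralPLS,
    MeanCenteredPLS,
    behavioral_pls,
    compare_saliences,
    mean_centering_pls,
    salience_z_difference,
)


def make_groups(sizes):
    return np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])


def mc_matrix_oracle(X, groups):
    """Grand-mean-centered group-mean matrix, written out longhand."""
    labels = np.unique(groups)
    M = np.vstack([X[groups == g].mean(axis=0) for g in labels])
    return M - M.mean(axis=0)


def behav_matrix_oracle(X, Y, groups):
    labels = np.unique(groups)
    blocks = []
    for g in labels:
        Xg, Yg = X[groups == g], Y[groups == g]
        q, p = Yg.shape[1], Xg.shape[1]
        R = np.empty((q, p))
        for i in range(q):
            for j in range(p):
                R[i, j] = np.corrcoef(Yg[:, i], Xg[:, j])[0, 1]
        blocks.append(R)
    return np.vstack(blocks)


# ------------------------------------------------------- mean-centering PLS

def test_two_group_mean_difference_is_a_rank_one_contrast():
    """With two groups the cross-block is +/- half the mean difference, so
    d1 = ||mean difference|| / sqrt(2) and the brain salience is its unit
    vector; all further singular values vanish."""
    rng = np.random.default_rng(0)
    X = rng.standard_normal((40, 5)) * 0.001
    groups = make_groups([20, 20])
    X[groups == 1] += [1.0, 2.0, 0.0, -2.0, 0.0]
    est = MeanCenteredPLS(n_perm=0, n_boot=0).fit(X, groups)
    diff = X[groups == 1].mean(axis=0) - X[groups == 0].mean(axis=0)
    assert est.singular_values_[0] == pytest.approx(
        np.linalg.norm(diff) / np.sqrt(2), rel=1e-10
    )
    assert est.singular_values_[1] == pytest.approx(0.0, abs=1e-12)
    v = est.brain_saliences_[:, 0]
    assert np.allclose(np.abs(v), np.abs(diff) / np.linalg.norm(diff), atol=1e-6)
    assert est.covariance_explained_[0] == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_mean_centering_singular_values_match_direct_svd(seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((24, 6))
    groups = make_groups([8, 8, 8])
    est = MeanCenteredPLS(n_perm=0, n_boot=0).fit(X, groups)
    R = mc_matrix_oracle(X, groups)
    s = np.linalg.svd(R, compute_uv=False)
    assert np.allclose(est.singular_values_, s[: len(est.singular_values_)],
                       rtol=1e-10)
    # covariance conservation: sum d^2 = ||R||_F^2
    assert np.sum(est.singular_values_**2) == pytest.approx(
        np.sum(R**2), rel=1e-10
    )


def test_brain_salience_columns_are_orthonormal():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((30, 7))
    est = MeanCenteredPLS(n_perm=0, n_boot=0).fit(X, make_groups([10, 10, 10]))
    V = est.brain_saliences_
    assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)
    # scores are the projection onto the saliences
    assert np.allclose(est.brain_scores_, X @ V)
    assert np.allclose(est.transform(X), X @ V)


def test_sign_convention_largest_element_positive():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((20, 5))
    est = MeanCenteredPLS(n_perm=0, n_boot=0).fit(X, make_groups([10, 10]))
    V = est.brain_saliences_
    for k in range(V.shape[1] - 1):  # last column of a 2-group fit is ~0
        assert V[np.argmax(np.abs(V[:, k])), k] > 0


def test_single_group_rejected():
    X = np.random.default_rng(0).standard_normal((10, 3))
    with pytest.raises(ValueError, match="2 groups"):
        MeanCenteredPLS().fit(X, np.zeros(10, dtype=int))


def test_group_length_mismatch_rejected():
    X = np.random.default_rng(0).standard_normal((10, 3))
    with pytest.raises(ValueError, match="groups"):
        MeanCenteredPLS().fit(X, make_groups([5, 4]))


# ---------------------------------------------------------- behavioural PLS

def test_single_brain_single_behavior_reduces_to_pearson_r():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((50, 1))
    y = 0.5 * x[:, 0] + 0.3 * rng.standard_normal(50)
    est = BehavioralPLS(n_perm=0, n_boot=0).fit(x, y)
    r = np.corrcoef(x[:, 0], y)[0, 1]
    assert est.singular_values_[0] == pytest.approx(abs(r), rel=1e-10)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_behavioral_cross_block_matches_longhand_correlations(seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((30, 4))
    Y = rng.standard_normal((30, 2))
    groups = make_groups([15, 15])
    est = BehavioralPLS(n_perm=0, n_boot=0).fit(X, Y, groups=groups)
    R = behav_matrix_oracle(X, Y, groups)
    s = np.linalg.svd(R, compute_uv=False)
    assert np.allclose(est.singular_values_, s[: len(est.singular_values_)],
                       rtol=1e-10)


def test_constant_behavior_column_rejected_with_group_context():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((12, 3))
    Y = np.column_stack([rng.standard_normal(12), np.full(12, 2.0)])
    with pytest.raises(ValueError, match=r"behaviour column\(s\) \[1\]"):
        BehavioralPLS(n_perm=0, n_boot=0).fit(X, Y)


# -------------------------------------------------------------- permutation

def test_perm_p_is_the_literal_exceedance_proportion():
    """A planted overwhelming effect yields p = 0 under the proportion rule."""
    rng = np.random.default_rng(3)
    X = rng.standard_normal((40, 4)) * 0.01
    groups = make_groups([20, 20])
    X[groups == 1, 0] += 10.0
    est = MeanCenteredPLS(n_perm=50, n_boot=0, random_state=1).fit(X, groups)
    assert est.perm_pvalues_[0] == 0.0


def test_perm_correction_option_uses_add_one_rule():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((40, 4)) * 0.01
    groups = make_groups([20, 20])
    X[groups == 1, 0] += 10.0
    est = MeanCenteredPLS(
        n_perm=49, n_boot=0, random_state=1, perm_correction=True
    ).fit(X, groups)
    assert est.perm_pvalues_[0] == pytest.approx(1 / 50)


def test_null_data_gives_large_p():
    rng = np.random.default_rng(8)
    X = rng.standard_normal((30, 4))
    est = MeanCenteredPLS(n_perm=100, n_boot=0, random_state=2).fit(
        X, make_groups([15, 15])
    )
    assert est.perm_pvalues_[0] > 0.05


# ---------------------------------------------------------------- bootstrap

def test_bootstrap_flags_the_planted_variable():
    rng = np.random.default_rng(5)
    n = 60
    X = rng.standard_normal((n, 5))
    y = 1.5 * X[:, 2] + 0.5 * rng.standard_normal(n)
    est = BehavioralPLS(n_perm=0, n_boot=200, random_state=3).fit(X, y)
    bsr = est.bootstrap_ratios_[:, 0]
    assert np.abs(bsr[2]) > 2.0
    assert np.argmax(np.abs(bsr)) == 2
    lo, hi = est.brain_salience_ci_[0, 2, 0], est.brain_salience_ci_[1, 2, 0]
    assert lo * hi > 0  # CI for the planted salience excludes zero


def test_bootstrap_output_shapes():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((24, 5))
    est = MeanCenteredPLS(n_perm=0, n_boot=50, random_state=0).fit(
        X, make_groups([12, 12])
    )
    k = est.singular_values_.size
    assert est.bootstrap_ratios_.shape == (5, k)
    assert est.salience_ci_.shape == (2, 2, k)
    assert est.brain_salience_ci_.shape == (2, 5, k)


def test_functional_wrappers_return_populated_results():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((20, 4))
    res = mean_centering_pls(X, make_groups([10, 10]), n_perm=20, n_boot=20)
    assert res.perm_p is not None and res.bootstrap_ratios is not None
    y = rng.standard_normal(20)
    res_b = behavioral_pls(X, y, n_perm=20, n_boot=20)
    assert res_b.singular_values.size >= 1


def test_fits_are_reproducible_across_calls():
    rng = np.random.default_rng(11)
    X = rng.standard_normal((24, 4))
    g = make_groups([12, 12])
    a = MeanCenteredPLS(n_perm=30, n_boot=30, random_state=5).fit(X, g)
    b = MeanCenteredPLS(n_perm=30, n_boot=30, random_state=5).fit(X, g)
    assert np.array_equal(a.perm_pvalues_, b.perm_pvalues_)
    assert np.array_equal(a.bootstrap_ratios_, b.bootstrap_ratios_)


# -------------------------------------------------------- salience contrast

def test_compare_saliences_cosine_and_fisher_z():
    r, z = compare_saliences([1.0, 0.0], [1.0, 0.0], n_effective=28)
    assert r == pytest.approx(1.0)
    assert z > 10  # atanh saturates near perfect similarity
    r2, z2 = compare_saliences([1.0, 0.0], [0.0, 1.0], n_effective=28)
    assert r2 == pytest.approx(0.0, abs=1e-12)
    assert z2 == pytest.approx(0.0, abs=1e-9)
    r3, _ = compare_saliences([1.0, 0.0], [-1.0, 0.0])
    assert r3 == pytest.approx(-1.0)


def test_compare_saliences_validation():
    with pytest.raises(ValueError, match="length"):
        compare_saliences([1.0, 0.0], [1.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="zero-norm"):
        compare_saliences([0.0, 0.0], [1.0, 0.0])


def test_salience_z_difference_is_antisymmetric_and_zero_at_equality():
    assert salience_z_difference(0.5, 0.5, 30) == pytest.approx(0.0)
    z = salience_z_difference(0.8, 0.3, 30)
    assert z > 0
    assert salience_z_difference(0.3, 0.8, 30) == pytest.approx(-z)
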