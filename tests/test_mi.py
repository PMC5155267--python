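import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import micluster.mi as mi_mod
from micluster import (HistogramSpec, InputError, MutualInformationDissimilarity,
                       auto_delta_max, column_entropy, default_n_bins,
                       dissimilarity_from_mi, estimate_mi,
                       independence_mi_floor, mi_matrix)

LOG2 = math.log(2.0)


# ---------------------------------------------------------------------------
# worked cases with hand-computed oracles

def test_identical_binary_vectors_give_log2():
    x = np.array([0.0, 0.0, 1.0, 1.0])
    assert estimate_mi(x, x, n_bins=2) == pytest.approx(LOG2, abs=1e-15)


def test_independent_balanced_vectors_give_zero():
    x = np.array([0.0, 0.0, 1.0, 1.0])
    y = np.array([0.0, 1.0, 0.0, 1.0])
    assert estimate_mi(x, y, n_bins=2) == 0.0


def test_entropy_of_skewed_binary_split():
    # 5 values on [0, 4], 2 equal-width bins with right-closed interior edge
    # at 2: {0, 1, 2} fall in the lower bin, {3, 4} in the upper.
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    expected = -(0.6 * math.log(0.6) + 0.4 * math.log(0.4))
    assert column_entropy(x, HistogramSpec(n_bins=2)) == pytest.approx(
        expected, abs=1e-15)


def test_deterministic_monotone_relation_has_high_mi():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(1000)
    assert estimate_mi(x, x ** 2) > 5 * independence_mi_floor(1000, 14)


# ---------------------------------------------------------------------------
# invariants (property-based)

finite_pairs = hnp.arrays(np.float64, (40,),
                          elements=st.floats(-50, 50, allow_nan=False))


@given(finite_pairs, finite_pairs)
def test_mi_symmetric_and_nonnegative(x, y):
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    a = estimate_mi(x, y, n_bins=4)
    b = estimate_mi(y, x, n_bins=4)
    assert a == pytest.approx(b, abs=1e-12)
    assert a >= 0.0


@given(finite_pairs, finite_pairs)
def test_mi_bounded_by_min_entropy(x, y):
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    spec = HistogramSpec(n_bins=4)
    m = estimate_mi(x, y, spec)
    bound = min(column_entropy(x, spec), column_entropy(y, spec))
    assert m <= bound + 1e-12


def test_bits_are_nats_over_log2(rng):
    x, y = rng.standard_normal(500), rng.standard_normal(500)
    nats = estimate_mi(x, y, base="nats")
    bits = estimate_mi(x, y, base="bits")
    assert bits == pytest.approx(nats / LOG2, rel=1e-12)


def test_entropy_bounded_by_log_bins(rng):
    x = rng.standard_normal(300)
    assert column_entropy(x, HistogramSpec(n_bins=8)) <= math.log(8) + 1e-12


def test_mi_invariant_to_affine_rescaling(rng):
    x, y = rng.standard_normal(400), rng.standard_normal(400)
    a = estimate_mi(x, y, n_bins=6)
    b = estimate_mi(3.0 * x - 7.0, 0.5 * y + 2.0, n_bins=6)
    assert a == pytest.approx(b, abs=1e-12)


def test_independence_bias_shrinks_with_sample_size():
    # mean plug-in MI of independent normals decreases as N_s grows at fixed B
    means = []
    for n_s in (100, 1000, 10000):
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            vals.append(estimate_mi(r.standard_normal(n_s),
                                    r.standard_normal(n_s), n_bins=8))
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]
    # first-order bias formula tracks the measured means within a factor of 2
    for n_s, m in zip((100, 1000, 10000), means):
        assert m < 2.0 * independence_mi_floor(n_s, 8)


# ---------------------------------------------------------------------------
# binning rule and derived constants

def test_default_n_bins_rule():
    assert default_n_bins(1000) == 14
    assert default_n_bins(20) == 2          # clamped from below
    assert default_n_bins(100_000) == 50    # clamped from above
    with pytest.raises(InputError):
        default_n_bins(1)


def test_independence_floor_and_auto_cap_algebra():
    floor = independence_mi_floor(1000, 14)
    assert floor == pytest.approx(169 / 2000)
    assert auto_delta_max(1000, 14) == pytest.approx(1.0 / floor)
    # tiny floor -> hard cap kicks in
    assert auto_delta_max(10**9, 2) == 1e3


# ---------------------------------------------------------------------------
# matrix-level behavior

def test_mi_matrix_symmetric_with_entropy_diagonal(rng):
    X = rng.standard_normal((300, 4))
    spec = HistogramSpec(n_bins=6)
    M = mi_matrix(X, spec)
    assert np.allclose(M.values, M.values.T)
    for j in range(4):
        assert M.values[j, j] == pytest.approx(
            column_entropy(X[:, j], spec), abs=1e-12)
    assert M.values[0, 1] == pytest.approx(
        estimate_mi(X[:, 0], X[:, 1], spec), abs=1e-12)


def test_mi_matrix_computes_each_pair_once(rng, monkeypatch):
    calls = {"n": 0}
    orig = mi_mod._mi_from_indices

    def counting(ix, iy, b):
        calls["n"] += 1
        return orig(ix, iy, b)

    monkeypatch.setattr(mi_mod, "_mi_from_indices", counting)
    n_vars = 7
    mi_matrix(rng.standard_normal((200, n_vars)))
    assert calls["n"] == n_vars * (n_vars - 1) // 2


def test_dissimilarity_reciprocal_cap_and_zero_diagonal():
    M = pd.DataFrame([[2.0, 0.5, 1e-9],
                      [0.5, 2.0, 4.0],
                      [1e-9, 4.0, 2.0]],
                     index=list("abc"), columns=list("abc"))
    D = dissimilarity_from_mi(M, delta_max=100.0)
    assert np.allclose(np.diag(D.values), 0.0)
    assert D.loc["a", "b"] == pytest.approx(2.0)
    assert D.loc["b", "c"] == pytest.approx(0.25)
    assert D.loc["a", "c"] == 100.0  # capped
    assert list(D.index) == list("abc")


def test_dissimilarity_monotone_decreasing_in_mi():
    lo = dissimilarity_from_mi(np.array([[1.0, 0.2], [0.2, 1.0]]))
    hi = dissimilarity_from_mi(np.array([[1.0, 0.8], [0.8, 1.0]]))
    assert hi.values[0, 1] < lo.values[0, 1]


def test_dissimilarity_input_validation():
    with pytest.raises(InputError):
        dissimilarity_from_mi(np.array([[1.0, -0.5], [-0.5, 1.0]]))
    with pytest.raises(InputError):
        dissimilarity_from_mi(np.eye(2), delta_max=0.0)
    with pytest.raises(InputError):
        dissimilarity_from_mi(np.ones((2, 3)))


# ---------------------------------------------------------------------------
# error handling

def test_estimate_mi_input_validation():
    with pytest.raises(InputError):
        estimate_mi([1.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(InputError):
        estimate_mi([1.0], [2.0])
    with pytest.raises(InputError):
        estimate_mi([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])


def test_constant_vector_handling(rng):
    x = rng.standard_normal(100)
    c = np.full(100, 3.14)
    with pytest.raises(InputError):
        estimate_mi(x, c)
    assert estimate_mi(x, c, on_constant="zero") == 0.0
    X = np.column_stack([x, c])
    with pytest.raises(InputError):
        mi_matrix(X)
    M = mi_matrix(X, HistogramSpec(on_constant="zero"))
    assert M.values[0, 1] == 0.0


def test_histogram_spec_validation():
    with pytest.raises(InputError):
        HistogramSpec(n_bins=1)
    with pytest.raises(InputError):
        HistogramSpec(base="decibels")
    with pytest.raises(InputError):
        HistogramSpec(on_constant="ignore")


# ---------------------------------------------------------------------------
# estimator wrapper

def test_estimator_fit_sets_attributes(rng):
    X = rng.standard_normal((500, 3))
    est = MutualInformationDissimilarity().fit(X)
    assert est.n_bins_ == default_n_bins(500)
    assert est.delta_max_ == pytest.approx(auto_delta_max(500, est.n_bins_))
    assert est.mi_matrix_.shape == (3, 3)
    assert est.dissimilarity_.shape == (3, 3)
    assert est.names_ == ["v1", "v2", "v3"]


def test_estimator_explicit_cap_and_fit_transform(rng):
    X = rng.standard_normal((200, 3))
    est = MutualInformationDissimilarity(delta_max=50.0)
    D = est.fit_transform(X)
    assert est.delta_max_ == 50.0
    assert D.values.max() <= 50.0
    pd.testing.assert_frame_equal(D, est.dissimilarity_)
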