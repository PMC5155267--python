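import numpy as np
import pytest

from micluster import (ClassificationReport, InputError, SparseGroupLogistic,
                       evaluate, fit_group_enet, logistic_loglik,
                       predict_proba, tune_group_enet)


@pytest.fixture
def fixture_100x6():
    rng = np.random.default_rng(42)
    W = rng.standard_normal((100, 6))
    beta = np.array([1.0, -0.5, 0.8, 0.0, 0.3, -1.2])
    z = (rng.random(100) < 1 / (1 + np.exp(-(0.2 + W @ beta)))).astype(int)
    groups = np.array([0, 0, 1, 1, 2, 2])
    return W, z, groups


# ---------------------------------------------------------------------------
# log likelihood

def test_loglik_matches_naive_formula(rng):
    W = rng.standard_normal((30, 3))
    z = (rng.random(30) < 0.5).astype(int)
    beta = np.array([0.5, -1.0, 0.2])
    h = 1 / (1 + np.exp(-(W @ beta + 0.3)))
    naive = np.sum(z * np.log(h) + (1 - z) * np.log1p(-h))
    assert logistic_loglik(beta, 0.3, W, z) == pytest.approx(naive, abs=1e-10)
    assert logistic_loglik(beta, 0.3, W, z) <= 0.0


def test_loglik_stable_at_extreme_linear_predictor():
    W = np.array([[1000.0], [-1000.0]])
    z = np.array([1, 0])
    val = logistic_loglik(np.array([1.0]), 0.0, W, z)
    assert np.isfinite(val)
    assert val == pytest.approx(0.0, abs=1e-10)


def test_loglik_shape_validation(rng):
    with pytest.raises(InputError):
        logistic_loglik([1.0], 0.0, rng.standard_normal((5, 2)),
                        [0, 1, 0, 1, 0])


# ---------------------------------------------------------------------------
# solver

def test_unpenalized_fit_matches_statsmodels(fixture_100x6):
    sm = pytest.importorskip("statsmodels.api")
    W, z, groups = fixture_100x6
    m = fit_group_enet(W, z, groups, 0.0, 0.0, max_iter=100_000, tol=1e-12)
    oracle = sm.Logit(z, sm.add_constant(W)).fit(disp=0)
    assert m.intercept == pytest.approx(oracle.params[0], abs=1e-4)
    assert np.allclose(m.beta, oracle.params[1:], atol=1e-4)


def test_objective_trace_monotone_nonincreasing(fixture_100x6):
    W, z, groups = fixture_100x6
    m = fit_group_enet(W, z, groups, 0.5, 0.1)
    assert np.all(np.diff(m.objective_trace) <= 1e-10)
    assert m.converged


def test_huge_l1_zeroes_all_slopes(fixture_100x6):
    W, z, groups = fixture_100x6
    m = fit_group_enet(W, z, groups, 0.0, 1e6)
    assert np.all(m.beta == 0.0)
    # intercept still fits the base rate
    assert predict_proba(m, W)[0] == pytest.approx(z.mean(), abs=0.05)


def test_huge_group_penalty_zeroes_all_slopes(fixture_100x6):
    W, z, groups = fixture_100x6
    m = fit_group_enet(W, z, groups, 1e6, 0.0)
    assert np.all(m.beta == 0.0)


def test_singleton_groups_reduce_group_penalty_to_l1(fixture_100x6):
    W, z, _ = fixture_100x6
    singles = np.arange(6)
    a = fit_group_enet(W, z, singles, 2.0, 0.0, max_iter=50_000, tol=1e-12)
    b = fit_group_enet(W, z, singles, 0.0, 2.0, max_iter=50_000, tol=1e-12)
    assert np.allclose(a.beta, b.beta, atol=1e-6)
    assert a.intercept == pytest.approx(b.intercept, abs=1e-6)


def test_warm_start_agrees_with_cold_start(fixture_100x6):
    W, z, groups = fixture_100x6
    cold = fit_group_enet(W, z, groups, 0.5, 0.1, max_iter=100_000, tol=1e-12)
    rng = np.random.default_rng(9)
    warm = fit_group_enet(W, z, groups, 0.5, 0.1, max_iter=100_000, tol=1e-12,
                          beta0=0.5 * rng.standard_normal(6), intercept0=1.0)
    assert np.allclose(cold.beta, warm.beta, atol=1e-6)
    assert cold.intercept == pytest.approx(warm.intercept, abs=1e-6)


def test_penalized_objective_never_better_than_unpenalized_loglik(fixture_100x6):
    W, z, groups = fixture_100x6
    free = fit_group_enet(W, z, groups, 0.0, 0.0, max_iter=50_000, tol=1e-12)
    pen = fit_group_enet(W, z, groups, 1.0, 0.5)
    assert logistic_loglik(pen.beta, pen.intercept, W, z) <= \
        logistic_loglik(free.beta, free.intercept, W, z) + 1e-8


def test_solver_input_validation(fixture_100x6):
    W, z, groups = fixture_100x6
    with pytest.raises(InputError):
        fit_group_enet(W, z, groups, -1.0, 0.0)
    with pytest.raises(InputError):
        fit_group_enet(W, z[:-1], groups, 0.0, 0.0)
    with pytest.raises(InputError):
        fit_group_enet(W, z, groups[:-1], 0.0, 0.0)
    with pytest.raises(InputError):
        fit_group_enet(W, np.arange(100), groups, 0.0, 0.0)  # not binary


def test_model_serialization_roundtrip(fixture_100x6):
    W, z, groups = fixture_100x6
    m = fit_group_enet(W, z, groups, 0.5, 0.1)
    doc = m.to_dict()
    assert doc["lambda"] == 0.1 and doc["gamma"] == 0.5
    assert np.allclose(doc["beta"], m.beta)
    assert doc["group_index"] == groups.tolist()


# ---------------------------------------------------------------------------
# prediction and evaluation

def test_predict_proba_formula_and_validation(fixture_100x6):
    W, z, groups = fixture_100x6
    m = fit_group_enet(W, z, groups, 0.1, 0.01)
    p = predict_proba(m, W)
    assert np.all((p > 0) & (p < 1))
    manual = 1 / (1 + np.exp(-(W @ m.beta + m.intercept)))
    assert np.allclose(p, manual, atol=1e-12)
    with pytest.raises(InputError):
        predict_proba(m, W[:, :4])


def test_classification_report_counts():
    pred = np.array([1, 1, 0, 0, 1, 0])
    z = np.array([1, 0, 0, 1, 1, 0])
    rep = evaluate(pred, z)
    assert (rep.tp, rep.tn, rep.fp, rep.fn) == (2, 2, 1, 1)
    assert rep.accuracy == pytest.approx(100 * 4 / 6)
    assert rep.sensitivity == pytest.approx(100 * 2 / 3)
    assert rep.specificity == pytest.approx(100 * 2 / 3)
    d = rep.to_dict()
    assert d["accuracy"] == round(rep.accuracy, 2)
    with pytest.raises(InputError):
        evaluate(np.array([0, 2]), np.array([0, 1]))


# ---------------------------------------------------------------------------
# cross-validation tuning

def test_tuning_is_deterministic_and_returns_grid_values(fixture_100x6):
    W, z, groups = fixture_100x6
    g_grid, l_grid = [1.0, 0.1], [0.5, 0.05]
    a = tune_group_enet(W, z, groups, g_grid, l_grid, n_splits=4, seed=3)
    b = tune_group_enet(W, z, groups, g_grid, l_grid, n_splits=4, seed=3)
    assert a[:2] == b[:2]
    assert a[0] in g_grid and a[1] in l_grid
    assert len(a[2]) == 4
    assert a[2] == b[2]


def test_tuning_ties_resolve_to_larger_penalty(rng):
    # pure-noise design: all penalty pairs tie (or nearly), so the scan
    # order (largest penalties first, strict improvement required) keeps
    # the sparsest model
    W = rng.standard_normal((60, 4))
    z = np.repeat([0, 1], 30)
    groups = np.array([0, 0, 1, 1])
    gamma, lam, table = tune_group_enet(W, z, groups, [100.0, 0.0],
                                        [100.0, 0.0], n_splits=3, seed=0)
    accs = [row["cv_accuracy"] for row in table]
    if accs.count(max(accs)) > 1:
        assert (gamma, lam) == (100.0, 100.0)


def test_tuning_needs_both_classes():
    W = np.random.default_rng(0).standard_normal((20, 2))
    with pytest.raises(InputError):
        tune_group_enet(W, np.ones(20, dtype=int), np.array([0, 1]),
                        [1.0], [1.0])


# ---------------------------------------------------------------------------
# estimator wrapper

def test_sparse_group_logistic_estimator(fixture_100x6):
    W, z, groups = fixture_100x6
    est = SparseGroupLogistic(gamma=0.1, lam=0.01, groups=groups).fit(W, z)
    pred = est.predict(W)
    assert set(np.unique(pred)) <= {0, 1}
    assert np.mean(pred == z) > 0.7
    proba = est.predict_proba(W)
    assert proba.shape == (100, 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
    assert np.array_equal(pred, (proba[:, 1] >= 0.5).astype(int))
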