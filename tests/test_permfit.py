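"""Permutation-importance contracts: scores, variance, tests, selection."""

import numpy as np
import pytest

from hdfit import (
    ImportanceResult,
    PermutationPlan,
    importance_score,
    importance_variance,
    permfit_test,
    permute_feature,
    select_features,
)
from hdfit.permfit import read_importance_tsv, write_importance_tsv


# ---------------------------------------------------------- permute_feature
def test_permute_feature_contracts():
    M = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
    out = permute_feature(M, 0, seed=3)
    # multiset of the permuted column is preserved, other columns untouched
    np.testing.assert_array_equal(np.sort(out[:, 0]), np.array([1.0, 2.0, 3.0]))
    np.testing.assert_array_equal(out[:, 1], M[:, 1])
    # reproducible under the same seed
    np.testing.assert_array_equal(out, permute_feature(M, 0, seed=3))
    # a constant column is invariant
    Mc = np.column_stack([np.full(3, 7.0), M[:, 1]])
    np.testing.assert_array_equal(permute_feature(Mc, 0, seed=1), Mc)
    with pytest.raises(IndexError):
        permute_feature(M, 2)


def test_permute_feature_draws_uniform_permutations():
    """Each of the 6 orderings of a 3-vector appears with frequency ~1/6."""
    M = np.array([[1.0], [2.0], [3.0]])
    seen = {}
    for seed in range(600):
        key = tuple(permute_feature(M, 0, seed=seed)[:, 0])
        seen[key] = seen.get(key, 0) + 1
    freqs = np.array(list(seen.values())) / 600
    assert len(seen) == 6
    assert np.all(np.abs(freqs - 1 / 6) < 0.06)


# --------------------------------------------------------- importance_score
def test_score_zero_for_ignored_feature(oracle_model_cls):
    model = oracle_model_cls(beta=[1.0, 0.0])
    rng = np.random.default_rng(0)
    X = rng.standard_normal((50, 2))
    y = model.predict(X)
    lam, per_sample = importance_score(model, X, y, j=1, n_perm=4, seed=1)
    assert lam == 0.0
    np.testing.assert_array_equal(per_sample, np.zeros(50))


def test_score_two_sample_hand_example(oracle_model_cls):
    """y=[0,1], base predictions [0,1], swapped predictions [1,0] -> scores [1,1]."""
    model = oracle_model_cls(beta=[1.0])
    X = np.array([[0.0], [1.0]])
    y = np.array([0.0, 1.0])
    swap_seed = next(
        s for s in range(50)
        if np.array_equal(np.random.default_rng(s).permutation(2), [1, 0])
    )
    lam, per_sample = importance_score(model, X, y, j=0, n_perm=1, seed=swap_seed)
    np.testing.assert_array_equal(per_sample, [1.0, 1.0])
    assert lam == 1.0


def test_score_recovers_closed_form_for_linear_oracle(oracle_model_cls):
    """E[score] = ((n-1)/n) * 2 a^2 Var(X_j) for an independent linear feature."""
    a = 2.0
    n = 100_000
    model = oracle_model_cls(beta=[a, 0.5])
    rng = np.random.default_rng(42)
    X = rng.standard_normal((n, 2))
    y = model.predict(X) + rng.standard_normal(n)
    lam, per_sample = importance_score(model, X, y, j=0, n_perm=2, seed=7)
    expected = (n - 1) / n * 2 * a**2
    mc_se = per_sample.std(ddof=1) / np.sqrt(n)
    assert abs(lam - expected) < 3 * mc_se


# ------------------------------------------------------ importance_variance
def test_variance_hand_examples():
    v, se = importance_variance([3.0, 3.0, 3.0])
    assert v == 0.0 and se == 0.0
    v, se = importance_variance([0.0, 2.0])
    assert v == pytest.approx(0.5)  # per-sample variance 1, / n_V=2
    assert se == pytest.approx(np.sqrt(0.5))
    v4, _ = importance_variance([0.0, 4.0])
    assert v4 == pytest.approx(4 * v)  # doubling scores quadruples variance
    vp, _ = importance_variance([0.0, 2.0], convention="printed")
    assert vp == pytest.approx(1.0)
    with pytest.raises(ValueError):
        importance_variance([1.0])


# -------------------------------------------------------------- permfit_test
def test_select_features_strict_cutoff():
    mk = lambda i, p: ImportanceResult(i, f"f{i}", 1.0, 1.0, 1.0, p, p < 0.1)
    results = [mk(0, 0.09), mk(1, 0.11)]
    np.testing.assert_array_equal(select_features(results, 0.1), [0])
    np.testing.assert_array_equal(select_features(results, 1.0), [0, 1])
    np.testing.assert_array_equal(select_features(results, 0.0), [])


def test_permfit_degenerate_inputs(oracle_model_cls):
    X = np.random.default_rng(0).standard_normal((30, 2))
    with pytest.raises(ValueError, match="zero variance"):
        permfit_test(oracle_model_cls([1.0, 1.0]), X, np.zeros(30), prefit=True)
    assert permfit_test(oracle_model_cls([]), np.empty((30, 0)), X[:, 0], prefit=True) == []


def test_permfit_power_on_strong_linear_feature():
    """A unit-coefficient feature at n=500 is detected essentially always."""
    rng = np.random.default_rng(1)
    hits = 0
    reps = 25
    for rep in range(reps):
        X = rng.standard_normal((500, 5))
        y = X[:, 0] + rng.standard_normal(500)
        res = permfit_test(
            "lasso", X, y,
            plan=PermutationPlan(n_perm=3, n_folds=5, seed=rep),
            alpha=0.1,
        )
        hits += res[0].selected
    assert hits / reps > 0.9


def test_permfit_type_one_error_smoke(oracle_model_cls):
    """Null features are rejected at roughly the nominal rate (reduced scale)."""
    rng = np.random.default_rng(9)
    model = oracle_model_cls(beta=[0.7, -0.4, 0.2, 0.0, 0.3])
    rates = []
    for rep in range(120):
        X = rng.standard_normal((300, 5))
        y = rng.standard_normal(300)  # independent of X: every feature is null
        res = permfit_test(
            model, X, y,
            plan=PermutationPlan(n_perm=3, seed=rep), alpha=0.1, prefit=True,
        )
        rates.append(np.mean([r.selected for r in res]))
    rate = float(np.mean(rates))
    assert abs(rate - 0.10) < 0.05


def test_duplicated_feature_dilutes_importance(oracle_model_cls):
    """Splitting a signal across two identical copies lowers each copy's score."""
    rng = np.random.default_rng(4)
    x = rng.standard_normal(4000)
    y = x + 0.5 * rng.standard_normal(4000)
    solo = importance_score(
        oracle_model_cls([1.0]), x[:, None], y, 0, n_perm=4, seed=0
    )[0]
    X2 = np.column_stack([x, x])
    dup_model = oracle_model_cls([0.5, 0.5])  # same fit, signal shared across copies
    dup0 = importance_score(dup_model, X2, y, 0, n_perm=4, seed=0)[0]
    dup1 = importance_score(dup_model, X2, y, 1, n_perm=4, seed=0)[0]
    assert dup0 < solo and dup1 < solo


def test_importance_tsv_round_trip(tmp_path):
    results = [
        ImportanceResult(0, "age", 0.52, 0.11, 4.7, 1.2e-6, True),
        ImportanceResult(1, "z17", -0.02, 0.05, -0.4, 0.66, False),
    ]
    path = tmp_path / "importance.tsv"
    write_importance_tsv(results, path)
    back = read_importance_tsv(path)
    assert [r.name for r in back] == ["age", "z17"]
    assert back[0].selected and not back[1].selected
    assert back[1].lambda_hat == pytest.approx(-0.02)


def test_single_split_plan_holds_out_half():
    plan = PermutationPlan(n_perm=1, n_folds=1, seed=3)
    (val,) = plan.folds(100)
    assert val.size == 50
    # k-fold partitions cover every index exactly once
    plan5 = PermutationPlan(n_perm=1, n_folds=5, seed=3)
    folds = plan5.folds(103)
    np.testing.assert_array_equal(np.sort(np.concatenate(folds)), np.arange(103))
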