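"""Bagged-ensemble contracts: OOB scoring, ranking, retention, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hdfit
from hdfit import BaggedEnsemble, NetArchitecture, fit_bagged, fit_tdnn, oob_score, select_q_opt
from hdfit.ensemble import _q_opt_from_ranked_preds


class ConstantPredictor:
    def __init__(self, value_fn):
        self._fn = value_fn

    def predict(self, X):
        return self._fn(np.asarray(X))


def _stub_ensemble(predict_fns, q_opt=1):
    members = [ConstantPredictor(f) for f in predict_fns]
    K = len(members)
    return BaggedEnsemble(
        members=members,
        oob_sets=[np.array([0]) for _ in range(K)],
        scores=np.arange(K, 0, -1, dtype=float),
        ranking=np.arange(K),
        q_opt=q_opt,
    )


# ---------------------------------------------------------------- oob_score
def test_oob_score_hand_examples():
    y = np.array([1.0, 2.0, 3.0])
    # baseline predictor: constant at the OOB mean scores zero
    assert oob_score(y, np.full(3, y.mean())) == pytest.approx(0.0)
    # perfect predictor: the OOB population variance
    assert oob_score(y, y) == pytest.approx(np.var(y))
    # direct evaluation: ((1-2)^2-(1-1.5)^2 + 0-0 + (3-2)^2-(3-2.5)^2)/3 = 1.5/3
    assert oob_score(y, [1.5, 2.0, 2.5]) == pytest.approx(0.5)


@given(
    shift=st.floats(-50, 50),
    y=st.lists(st.floats(-10, 10), min_size=2, max_size=8),
)
@settings(max_examples=50, deadline=None)
def test_oob_score_invariant_to_common_shift(shift, y):
    y = np.asarray(y)
    yhat = y * 0.5 + 1.0
    a = oob_score(y, yhat)
    b = oob_score(y + shift, yhat + shift)
    assert a == pytest.approx(b, rel=1e-9, abs=1e-9)


def test_oob_score_empty_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        oob_score([], [])


# ------------------------------------------------------------- select_q_opt
def test_q_opt_one_when_members_identical():
    ens = _stub_ensemble([lambda X: X[:, 0]] * 4)
    X = np.linspace(0, 1, 10)[:, None]
    assert select_q_opt(ens, X, X[:, 0]) == 1


def test_q_opt_prefers_exact_top_member_over_offset_average():
    # top member reproduces y; second is offset by +c, so averaging hurts
    c = 2.0
    ens = _stub_ensemble([lambda X: X[:, 0], lambda X: X[:, 0] + c])
    X = np.arange(8, dtype=float)[:, None]
    y = X[:, 0]
    assert select_q_opt(ens, X, y) == 1
    # enumerate losses by hand: q=1 -> 0, q=2 -> n * (c/2)^2
    _, losses = _q_opt_from_ranked_preds(np.vstack([y, y + c]), y)
    np.testing.assert_allclose(losses, [0.0, 8 * (c / 2) ** 2])


def test_q_opt_picks_best_average_when_errors_cancel():
    # two members with opposite offsets: their average is exact
    ens = _stub_ensemble([lambda X: X[:, 0] + 1.0, lambda X: X[:, 0] - 1.0], q_opt=2)
    X = np.arange(6, dtype=float)[:, None]
    assert select_q_opt(ens, X, X[:, 0]) == 2


# ------------------------------------------------------------------ predict
def test_predict_averages_retained_members():
    ens = _stub_ensemble(
        [lambda X: np.full(len(X), 1.0), lambda X: np.full(len(X), 3.0)], q_opt=2
    )
    np.testing.assert_allclose(ens.predict(np.zeros((4, 1))), np.full(4, 2.0))
    ens1 = _stub_ensemble(
        [lambda X: np.full(len(X), 1.0), lambda X: np.full(len(X), 3.0)], q_opt=1
    )
    np.testing.assert_allclose(ens1.predict(np.zeros((4, 1))), np.full(4, 1.0))


def test_predict_equals_member_when_all_identical():
    fn = lambda X: 2.0 * X[:, 0] - 1.0
    ens = _stub_ensemble([fn] * 5, q_opt=5)
    X = np.linspace(-2, 2, 9)[:, None]
    np.testing.assert_allclose(ens.predict(X), fn(X), rtol=0, atol=1e-12)


def test_ranking_must_be_permutation():
    with pytest.raises(ValueError, match="permutation"):
        BaggedEnsemble(
            members=[ConstantPredictor(lambda X: X[:, 0])] * 2,
            oob_sets=[np.array([0])] * 2,
            scores=np.array([1.0, 0.0]),
            ranking=np.array([0, 0]),
            q_opt=1,
        )


# --------------------------------------------------------------- fit_bagged
@pytest.fixture(scope="module")
def small_fit(fast_arch):
    rng = np.random.default_rng(5)
    X = rng.standard_normal((60, 4))
    y = X @ np.array([1.0, -1.0, 0.5, 0.0]) + 0.2 * rng.standard_normal(60)
    ens = fit_bagged(X, y, K=6, arch=fast_arch, seed=9)
    return X, y, ens


def test_fit_bagged_contracts(small_fit, fast_arch):
    X, y, ens = small_fit
    # ranking is a permutation sorted by descending score
    assert sorted(ens.ranking.tolist()) == list(range(6))
    ranked = ens.scores[ens.ranking]
    assert np.all(np.diff(ranked) <= 0)
    assert 1 <= ens.q_opt <= 6
    # OOB sets are disjoint from their bootstrap supports by construction;
    # each nonempty and within range
    for oob in ens.oob_sets:
        assert np.all((oob >= 0) & (oob < 60))
    # filtered training loss never exceeds the full-bag loss (argmin property)
    assert ens.q_losses[ens.q_opt - 1] <= ens.q_losses[-1] + 1e-9
    # determinism: same inputs and seed reproduce scores and q_opt
    ens2 = fit_bagged(X, y, K=6, arch=fast_arch, seed=9)
    np.testing.assert_array_equal(ens.scores, ens2.scores)
    assert ens.q_opt == ens2.q_opt
    np.testing.assert_allclose(ens.predict(X[:5]), ens2.predict(X[:5]))


def test_fit_bagged_k1(fast_arch):
    rng = np.random.default_rng(0)
    X = rng.standard_normal((25, 2))
    y = X[:, 0]
    ens = fit_bagged(X, y, K=1, arch=fast_arch, seed=1)
    assert ens.n_members == 1 and ens.q_opt == 1


def test_fit_bagged_input_validation(fast_arch):
    X = np.full((30, 2), np.nan)
    with pytest.raises(ValueError, match="non-finite"):
        fit_bagged(X, np.zeros(30), K=1, arch=fast_arch)
    with pytest.raises(ValueError, match="at least 20"):
        fit_bagged(np.zeros((5, 2)), np.zeros(5), K=1, arch=fast_arch)


def test_predict_rejects_feature_mismatch(small_fit):
    _, _, ens = small_fit
    with pytest.raises(ValueError, match="features"):
        ens.predict(np.zeros((3, 7)))


def test_column_swap_fast_path_matches_materialized(small_fit):
    X, _, ens = small_fit
    rng = np.random.default_rng(3)
    cols = np.vstack([X[rng.permutation(60), 1] for _ in range(3)])
    fast = ens.predict_column_swaps(X, 1, cols)
    naive = np.vstack(
        [ens.predict(np.column_stack([X[:, :1], c, X[:, 2:]])) for c in cols]
    )
    np.testing.assert_allclose(fast, naive, rtol=2e-4, atol=1e-5)


def test_ensemble_round_trips_through_bundle(small_fit, tmp_path):
    X, _, ens = small_fit
    path = tmp_path / "ensemble.joblib"
    ens.save(path)
    back = BaggedEnsemble.load(path)
    assert back.q_opt == ens.q_opt
    np.testing.assert_array_equal(back.ranking, ens.ranking)
    np.testing.assert_allclose(back.predict(X[:7]), ens.predict(X[:7]))


# ------------------------------------------------------------------- tdnn
def test_tdnn_deterministic_and_learns_constant(fast_arch):
    rng = np.random.default_rng(2)
    X = rng.standard_normal((40, 3))
    y = X[:, 0] + 0.1 * rng.standard_normal(40)
    a = fit_tdnn(X, y, arch=fast_arch, seed=4)
    b = fit_tdnn(X, y, arch=fast_arch, seed=4)
    np.testing.assert_array_equal(a.predict(X), b.predict(X))
    # zero-variance outcome: the network learns (approximately) the constant
    c = fit_tdnn(X, np.full(40, 5.0), arch=fast_arch, seed=4)
    np.testing.assert_allclose(c.predict(X), np.full(40, 5.0), atol=0.1)


def test_bagging_beats_single_network_on_average(fast_arch):
    """Filtered bagging should not predict worse than one net, on average."""
    rng = np.random.default_rng(12)
    gains = []
    for rep in range(6):
        n, p = 120, 8
        X = rng.standard_normal((n + 50, p))
        beta = rng.standard_normal(p)
        y = X @ beta + rng.standard_normal(n + 50)
        Xtr, ytr, Xte, yte = X[:n], y[:n], X[n:], y[n:]
        ens = fit_bagged(Xtr, ytr, K=8, arch=fast_arch, seed=rep)
        net = fit_tdnn(Xtr, ytr, arch=fast_arch, seed=rep)
        m_ens = np.mean((yte - ens.predict(Xte)) ** 2)
        m_net = np.mean((yte - net.predict(Xte)) ** 2)
        gains.append(m_net - m_ens)
    assert np.mean(gains) > 0
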