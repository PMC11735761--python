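"""Uniform fit/predict wrappers over the supported regressors.

The permutation-importance test and the pipeline are generic over any object
exposing ``fit(X, y, seed) -> self`` and ``predict(X) -> array``; this module
provides the built-in choices:

* ``stable-dnn`` — the stability-filtered bagged network (the method's own
  learner),
* ``tdnn``       — a plain single network, same architecture,
* ``rf``         — random forest (1000 trees by default),
* ``lasso``      — L1-regularized linear regression with cross-validated
  penalty.

Comparator learners are delegated to scikit-learn: they are baselines, not
the contribution.  A user-supplied object with the same surface is accepted
anywhere a learner name is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV

from .ensemble import BaggedEnsemble, NetArchitecture, fit_bagged, fit_tdnn

__all__ = ["LEARNERS", "make_learner", "StableDNNLearner", "TDNNLearner", "RFLearner", "LassoLearner"]


@dataclass
class StableDNNLearner:
    """Stability-filtered bagged network with ``K`` bootstrap members."""

    arch: NetArchitecture = field(default_factory=NetArchitecture)
    K: int = 100
    ensemble_: BaggedEnsemble | None = None

    def fit(self, X, y, seed: int = 0):
        self.ensemble_ = fit_bagged(X, y, K=self.K, arch=self.arch, seed=seed)
        return self

    def predict(self, X):
        return self.ensemble_.predict(X)

    def predict_column_swaps(self, X, j, new_columns):
        return self.ensemble_.predict_column_swaps(X, j, new_columns)

    def predict_many_column_swaps(self, X, swaps):
        return self.ensemble_.predict_many_column_swaps(X, swaps)


@dataclass
class TDNNLearner:
    arch: NetArchitecture = field(default_factory=NetArchitecture)
    net_: object = None

    def fit(self, X, y, seed: int = 0):
        self.net_ = fit_tdnn(X, y, arch=self.arch, seed=seed)
        return self

    def predict(self, X):
        return self.net_.predict(X)

    def predict_column_swaps(self, X, j, new_columns):
        return self.net_.predict_column_swaps(X, j, new_columns)

    def predict_many_column_swaps(self, X, swaps):
        return self.net_.predict_many_column_swaps(X, swaps)


@dataclass
class RFLearner:
    n_trees: int = 1000
    model_: RandomForestRegressor | None = None

    def fit(self, X, y, seed: int = 0):
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_trees, random_state=int(seed) % (2**31), n_jobs=1
        )
        self.model_.fit(X, y)
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X))


@dataclass
class LassoLearner:
    cv: int = 5
    model_: LassoCV | None = None

    def fit(self, X, y, seed: int = 0):
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        self.model_ = LassoCV(cv=self.cv, random_state=int(seed) % (2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.model_.fit(X, y)
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X))


LEARNERS = {
    "stable-dnn": StableDNNLearner,
    "tdnn": TDNNLearner,
    "rf": RFLearner,
    "lasso": LassoLearner,
}


def make_learner(spec, *, arch: NetArchitecture | None = None, K: int = 100, rf_trees: int = 1000):
    """Instantiate a learner from a name, or pass through a fit/predict object."""
    if not isinstance(spec, str):
        if not (hasattr(spec, "fit") and hasattr(spec, "predict")):
            raise TypeError("learner object must expose fit(X, y, seed) and predict(X)")
        return spec
    if spec not in LEARNERS:
        raise ValueError(f"unknown learner {spec!r}; choose from {sorted(LEARNERS)}")
    if spec == "stable-dnn":
        return StableDNNLearner(arch=arch or NetArchitecture(), K=K)
    if spec == "tdnn":
        return TDNNLearner(arch=arch or NetArchitecture())
    if spec == "rf":
        return RFLearner(n_trees=rf_trees)
    return LassoLearner()
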