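"""Permutation-based feature importance testing with cross-fitting.

The importance of feature ``j`` for a regression function
``xi(x) = E[Y | X = x]`` is defined as the expected increase in squared
prediction error when column ``j`` is replaced by a random permutation of
itself:

    Lambda_j = E[ xi(X) - xi(X^(j)) ]^2,

which is zero exactly when ``xi`` does not depend on ``X_j`` given the other
covariates.  Empirically, with a fitted ``xi_hat`` and a validation sample of
size ``n_V`` disjoint from the training data (cross-fitting), the per-sample
score

    L_ij = (y_i - xi_hat(x_i^(j)))^2 - (y_i - xi_hat(x_i))^2

has mean ``(n_V - 1)/n_V * Lambda_j`` under independent features, and the
studentized mean gives a one-sided z-test of ``H0: Lambda_j = 0``.

Per-sample scores are averaged over ``n_perm`` independent permutations
before the variance is computed (reducing permutation noise without
inflating ``n_V``), and pooled across the cross-fitting folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import check_aligned, check_matrix, check_vector, child_seed
from .learners import make_learner

__all__ = [
    "PermutationPlan",
    "ImportanceResult",
    "permute_feature",
    "importance_score",
    "importance_variance",
    "permfit_test",
    "select_features",
    "write_importance_tsv",
    "read_importance_tsv",
]

# cap on elements materialized at once by the generic (no fast path) predictor
_CHUNK_ELEMENTS = 20_000_000


@dataclass(frozen=True)
class PermutationPlan:
    """Cross-fitting and permutation settings for one importance run.

    ``variance_convention`` selects the denominator of the variance of the
    mean score: ``"sem"`` (default) divides the per-sample variance by
    ``n_V`` so the test statistic is standard normal under the null;
    ``"printed"`` keeps the bare per-sample variance.
    """

    n_perm: int = 200
    n_folds: int = 5
    seed: int = 0
    variance_convention: str = "sem"

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")
        if self.variance_convention not in ("sem", "printed"):
            raise ValueError("variance_convention must be 'sem' or 'printed'")

    def folds(self, n: int) -> list[np.ndarray]:
        """Deterministic validation folds over ``range(n)``.

        With ``n_folds >= 2`` this is a k-fold partition (every sample is
        validated exactly once).  ``n_folds=1`` performs a single 50/50
        train/validation split: only the held-out half contributes scores.
        """
        idx = np.random.default_rng(child_seed(self.seed, "folds")).permutation(n)
        if self.n_folds == 1:
            return [np.sort(idx[n // 2 :])]
        return [np.sort(f) for f in np.array_split(idx, self.n_folds)]


@dataclass
class ImportanceResult:
    """Importance estimate and test for one feature."""

    index: int
    name: str
    lambda_hat: float
    se: float
    statistic: float
    p_value: float
    selected: bool


def permute_feature(M, j: int, seed: int = 0) -> np.ndarray:
    """Return a copy of ``M`` with column ``j`` replaced by a uniform random
    permutation of its own entries (all other columns untouched)."""
    M = np.asarray(M, dtype=float)
    if not (0 <= j < M.shape[1]):
        raise IndexError(f"column {j} out of range for matrix with {M.shape[1]} columns")
    rng = np.random.default_rng(seed)
    out = M.copy()
    out[:, j] = M[rng.permutation(M.shape[0]), j]
    return out


def _permuted_columns(col: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n) stack of independent permutations of one column."""
    return np.vstack([col[rng.permutation(col.size)] for _ in range(n_perm)])


def _predict_swaps(model, X_val: np.ndarray, j: int, perm_cols: np.ndarray) -> np.ndarray:
    """Predictions on copies of ``X_val`` with column ``j`` swapped.

    Uses the model's rank-one fast path when available, otherwise
    materializes the permuted matrices in memory-bounded chunks.
    """
    if hasattr(model, "predict_column_swaps"):
        return model.predict_column_swaps(X_val, j, perm_cols)
    n_perm, n = perm_cols.shape
    p = X_val.shape[1]
    rows_per_chunk = max(1, _CHUNK_ELEMENTS // max(p, 1) // max(n, 1))
    out = np.empty((n_perm, n))
    for start in range(0, n_perm, rows_per_chunk):
        stop = min(start + rows_per_chunk, n_perm)
        block = np.repeat(X_val[None, :, :], stop - start, axis=0)
        block[:, :, j] = perm_cols[start:stop]
        out[start:stop] = model.predict(block.reshape(-1, p)).reshape(stop - start, n)
    return out


def importance_score(
    model,
    X_val,
    y_val,
    j: int,
    n_perm: int = 1,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Estimate ``Lambda_j`` on a validation set for a fitted model.

    Returns the mean importance estimate and the per-sample scores (one per
    validation sample, already averaged over the ``n_perm`` permutations).
    The model must have been fitted on data disjoint from ``(X_val, y_val)``.
    """
    X_val = check_matrix(X_val, "X_val")
    y_val = check_vector(y_val, "y_val")
    check_aligned(X_val, y_val, "X_val", "y_val")
    if X_val.shape[0] == 0:
        raise ValueError("empty validation set")
    if not (0 <= j < X_val.shape[1]):
        raise IndexError(f"column {j} out of range")
    base_err = (y_val - np.asarray(model.predict(X_val))) ** 2
    per_sample = _per_sample_scores(model, X_val, y_val, j, n_perm, seed, base_err)
    return float(per_sample.mean()), per_sample


def _per_sample_scores(model, X_val, y_val, j, n_perm, seed, base_err) -> np.ndarray:
    rng = np.random.default_rng(seed)
    perm_cols = _permuted_columns(X_val[:, j], n_perm, rng)
    perm_pred = _predict_swaps(model, X_val, j, perm_cols)
    perm_err = (y_val[None, :] - perm_pred) ** 2
    return perm_err.mean(axis=0) - base_err


def importance_variance(
    per_sample_scores, convention: str = "sem"
) -> tuple[float, float]:
    """Variance of the mean importance score and its square root.

    ``"sem"`` divides the per-sample sample variance by ``n_V`` (standard
    error of the mean); ``"printed"`` returns the bare per-sample variance.
    """
    s = check_vector(per_sample_scores, "per_sample_scores")
    if s.size < 2:
        raise ValueError("need at least 2 per-sample scores")
    v = float(np.mean((s - s.mean()) ** 2))
    if convention == "sem":
        v = v / s.size
    elif convention != "printed":
        raise ValueError("convention must be 'sem' or 'printed'")
    return v, float(np.sqrt(v))


def permfit_test(
    estimator,
    X,
    y,
    plan: PermutationPlan | None = None,
    alpha: float = 0.1,
    feature_names: list[str] | None = None,
    *,
    prefit: bool = False,
    **learner_kwargs,
) -> list[ImportanceResult]:
    """Cross-fitted permutation importance test for every column of ``X``.

    ``estimator`` is a learner name (``"stable-dnn"``, ``"rf"``, ...) or an
    object with ``fit(X, y, seed)``/``predict(X)``.  With ``prefit=True`` the
    supplied model is used as-is on the full sample (appropriate when the
    regression function is known or was fitted on independent data).

    For each fold, the learner is fitted on the complement and per-sample
    scores are computed on the fold; scores are pooled over folds, and each
    feature gets a one-sided upper-tail z-test of zero importance.
    """
    X = check_matrix(X)
    y = check_vector(y)
    check_aligned(X, y)
    plan = plan or PermutationPlan()
    n, p = X.shape
    if p == 0:
        return []
    if np.std(y) == 0:
        raise ValueError("outcome has zero variance; importance test undefined")
    if feature_names is None:
        feature_names = [f"f{j + 1}" for j in range(p)]
    if len(feature_names) != p:
        raise ValueError("feature_names length mismatch")

    pooled: list[list[np.ndarray]] = [[] for _ in range(p)]
    if prefit:
        fold_sets = [np.arange(n)]
    else:
        fold_sets = plan.folds(n)
        learner = make_learner(estimator, **learner_kwargs)
    for f, val_idx in enumerate(fold_sets):
        if prefit:
            model = estimator
        else:
            train_idx = np.setdiff1d(np.arange(n), val_idx)
            if train_idx.size == 0 or val_idx.size == 0:
                raise ValueError("fold with empty training or validation part")
            model = learner.fit(
                X[train_idx], y[train_idx], seed=child_seed(plan.seed, "fit", f)
            )
        Xv, yv = X[val_idx], y[val_idx]
        base_err = (yv - np.asarray(model.predict(Xv))) ** 2
        if hasattr(model, "predict_many_column_swaps"):
            # batched path: the model reuses its first-layer state across
            # features, so group features into memory-bounded chunks
            n_v = val_idx.size
            chunk = max(1, 400_000 // max(plan.n_perm * n_v, 1))
            for start in range(0, p, chunk):
                js = range(start, min(start + chunk, p))
                swaps = [
                    (
                        j,
                        _permuted_columns(
                            Xv[:, j],
                            plan.n_perm,
                            np.random.default_rng(child_seed(plan.seed, "perm", f, j)),
                        ),
                    )
                    for j in js
                ]
                preds = model.predict_many_column_swaps(Xv, swaps)
                for (j, _), pred in zip(swaps, preds):
                    perm_err = (yv[None, :] - pred) ** 2
                    pooled[j].append(perm_err.mean(axis=0) - base_err)
        else:
            for j in range(p):
                s = _per_sample_scores(
                    model, Xv, yv, j, plan.n_perm,
                    child_seed(plan.seed, "perm", f, j), base_err,
                )
                pooled[j].append(s)
    pooled = [np.concatenate(chunks) for chunks in pooled]

    results = []
    for j in range(p):
        s = pooled[j]
        lam = float(s.mean())
        _, se = importance_variance(s, plan.variance_convention)
        if se > 0:
            stat = lam / se
            pval = float(stats.norm.sf(stat))
        else:  # all per-sample scores identical (e.g. model constant in j)
            stat = 0.0 if lam <= 0 else np.inf
            pval = 1.0 if lam <= 0 else 0.0
        results.append(
            ImportanceResult(
                index=j,
                name=feature_names[j],
                lambda_hat=lam,
                se=se,
                statistic=stat,
                p_value=pval,
                selected=bool(pval < alpha),
            )
        )
    return results


def select_features(results: list[ImportanceResult], alpha: float) -> np.ndarray:
    """Indices of features with ``p_value < alpha``, in original column order."""
    return np.array(sorted(r.index for r in results if r.p_value < alpha), dtype=int)


def results_to_frame(results: list[ImportanceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.name for r in results],
            "lambda_hat": [r.lambda_hat for r in results],
            "se": [r.se for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "selected": [r.selected for r in results],
        }
    )


def write_importance_tsv(results: list[ImportanceResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_importance_tsv(path) -> list[ImportanceResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        ImportanceResult(
            index=i,
            name=str(row.feature),
            lambda_hat=float(row.lambda_hat),
            se=float(row.se),
            statistic=float(row.statistic),
            p_value=float(row.p_value),
            selected=bool(row.selected),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]
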