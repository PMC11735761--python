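"""Per-biomarker relevance scores and top-K retention (the "Hd" stage).

When the biomarker count rivals or exceeds the sample size, importance
testing with flexible learners degrades: the learner is poorly trained and
the search space is dominated by noise columns.  Screening assigns each
biomarker ``Z_k`` a cheap relevance score ``delta_k`` computed on training
samples only, and retains the ``K_keep`` top-scoring columns:

* ``logmean``      — unsupervised: mean of ``log Z_k`` (log of the geometric
  mean); appropriate for positive, right-skewed abundance data where highly
  expressed markers are a priori more informative.
* ``correlation``  — absolute Pearson correlation with the outcome.
* ``regression``   — absolute t-statistic of the biomarker main effect in an
  OLS fit of ``y`` on ``[1, Z*_k, X, X * Z*_k]``, adjusting for the
  low-dimensional confounders and their interactions with the biomarker.
* ``random``       — a uniformly random subset; a negative control
  quantifying the value of informed screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import check_aligned, check_matrix, check_vector

__all__ = [
    "ScreeningResult",
    "logmean_score",
    "correlation_score",
    "regression_score",
    "screen_top_k",
    "random_screen",
    "screen",
]

METHODS = ("logmean", "correlation", "regression", "random")


@dataclass
class ScreeningResult:
    """Scores, retained index set, and provenance of one screening run."""

    method: str
    scores: np.ndarray            # delta_k per biomarker; -inf for degenerate/unscored
    retained: np.ndarray          # indices sorted by descending score, ties by index
    k_keep: int
    transform: str = "standardize"

    def to_frame(self, names: list[str] | None = None) -> pd.DataFrame:
        p = self.scores.size
        names = names or [f"z{k + 1}" for k in range(p)]
        rank = np.full(p, -1)
        order = _order_descending(self.scores)
        rank[order] = np.arange(p)
        kept = np.zeros(p, dtype=bool)
        kept[self.retained] = True
        return pd.DataFrame(
            {"biomarker": names, "score": self.scores, "rank": rank + 1, "retained": kept}
        )


def logmean_score(Z_k) -> float:
    """Mean of the log-transformed measurements (log geometric mean)."""
    Z_k = check_vector(Z_k, "Z_k")
    if np.any(Z_k <= 0):
        raise ValueError(
            "logmean_score requires strictly positive measurements; "
            "use the correlation or regression score for signed data"
        )
    return float(np.mean(np.log(Z_k)))


def correlation_score(y, Z_k) -> float:
    """Absolute Pearson correlation between the outcome and the biomarker."""
    y = check_vector(y, "y")
    Z_k = check_vector(Z_k, "Z_k")
    check_aligned(y[:, None], Z_k, "y", "Z_k")
    if np.std(y) == 0 or np.std(Z_k) == 0:
        raise ValueError("correlation_score undefined for a constant vector")
    return float(abs(np.corrcoef(y, Z_k)[0, 1]))


def _transform_column(z: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log":
        if np.any(z <= 0):
            raise ValueError("log transform requires strictly positive measurements")
        return np.log(z)
    if transform == "standardize":
        sd = z.std()
        if sd == 0:
            raise ValueError("cannot standardize a constant column")
        return (z - z.mean()) / sd
    if transform == "none":
        return z
    raise ValueError(f"unknown transform {transform!r}")


def _screening_design(
    z_star: np.ndarray, X: np.ndarray, quadratic: bool, interactions: bool
) -> np.ndarray:
    n = z_star.size
    cols = [np.ones(n), z_star]
    if X.shape[1]:
        cols.append(X)
        if interactions:
            cols.append(X * z_star[:, None])
    if quadratic:
        cols.append(z_star[:, None] ** 2)
        if X.shape[1]:
            cols.append(X**2)
    return np.column_stack(cols)


def regression_score(
    y,
    Z_k,
    X=None,
    transform: str = "standardize",
    quadratic: bool = False,
    interactions: bool = True,
    name: str = "Z_k",
) -> float:
    """Confounder-adjusted OLS t-statistic score for one biomarker.

    Fits ``y = a0 + a_z z* + a_X X + a_XZ (X * z*) + eps`` by ordinary least
    squares on the training samples and returns ``|a_z| / SE(a_z)`` with the
    classical homoskedastic standard error.  ``z*`` is the log- or
    z-score-transformed biomarker; ``X`` is standardized before interaction
    columns are formed.  ``interactions=False`` drops the ``X * z*`` block
    (adjusting for the linear confounder terms only) and ``quadratic=True``
    adds squared columns.
    """
    y = check_vector(y, "y")
    Z_k = check_vector(Z_k, "Z_k")
    check_aligned(y[:, None], Z_k, "y", "Z_k")
    if X is None:
        X = np.empty((y.size, 0))
    X = check_matrix(X, "X")
    check_aligned(X, y)
    z_star = _transform_column(Z_k, transform)
    Xs = X.copy()
    if X.shape[1]:
        sd = Xs.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("confounder matrix X has a constant column")
        Xs = (Xs - Xs.mean(axis=0)) / sd
    A = _screening_design(z_star, Xs, quadratic, interactions)
    m, ncol = A.shape
    if m <= ncol:
        raise ValueError(
            f"need more than {ncol} training samples for the screening regression, got {m}"
        )
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < ncol:
        raise ValueError(
            f"screening design matrix is rank deficient for biomarker {name}; "
            "the biomarker may be collinear with a confounder"
        )
    resid = y - A @ coef
    sigma2 = float(resid @ resid) / (m - ncol)
    AtA_inv = np.linalg.inv(A.T @ A)
    se = np.sqrt(sigma2 * AtA_inv[1, 1])
    if se == 0:
        return float(np.inf)
    return float(abs(coef[1]) / se)


def _order_descending(scores: np.ndarray) -> np.ndarray:
    return np.lexsort((np.arange(scores.size), -scores))


def screen_top_k(scores, k_keep: int) -> np.ndarray:
    """Indices of the ``k_keep`` largest scores (ties by ascending index)."""
    scores = np.asarray(scores, dtype=float)
    if k_keep < 1:
        raise ValueError("k_keep must be >= 1")
    return _order_descending(scores)[: min(k_keep, scores.size)]


def random_screen(p_high: int, k_keep: int, seed: int = 0) -> np.ndarray:
    """Uniform random subset of ``k_keep`` distinct biomarker indices."""
    if k_keep > p_high:
        raise ValueError(f"cannot retain {k_keep} of {p_high} biomarkers")
    rng = np.random.default_rng(seed)
    return rng.choice(p_high, size=k_keep, replace=False)


def screen(
    y,
    Z,
    X=None,
    method: str = "regression",
    k_keep: int = 80,
    transform: str | None = None,
    quadratic: bool = False,
    interactions: bool = True,
    seed: int = 0,
) -> ScreeningResult:
    """Score every biomarker column of ``Z`` and retain the top ``k_keep``.

    ``transform`` defaults to ``"log"`` when all measurements are strictly
    positive and ``"standardize"`` otherwise.  Degenerate (zero-variance)
    columns score ``-inf`` and are never retained ahead of scored columns.
    Call with training rows only: screening must not see test data.
    """
    Z = check_matrix(Z, "Z")
    p_high = Z.shape[1]
    if method not in METHODS:
        raise ValueError(f"unknown screening method {method!r}; choose from {METHODS}")
    if method == "random":
        retained = random_screen(p_high, min(k_keep, p_high), seed=seed)
        scores = np.full(p_high, -np.inf)
        scores[retained] = 0.0
        return ScreeningResult("random", scores, retained, k_keep, transform="none")

    y = check_vector(y, "y")
    check_aligned(Z, y, "Z", "y")
    if transform is None:
        transform = "log" if np.all(Z > 0) else "standardize"
    scores = np.empty(p_high)
    for k in range(p_high):
        z = Z[:, k]
        if np.std(z) == 0:
            scores[k] = -np.inf
            continue
        if method == "logmean":
            scores[k] = logmean_score(z)
        elif method == "correlation":
            scores[k] = correlation_score(y, z)
        else:
            scores[k] = regression_score(
                y, z, X, transform=transform, quadratic=quadratic,
                interactions=interactions, name=f"column {k}",
            )
    retained = screen_top_k(scores, k_keep)
    return ScreeningResult(method, scores, retained, k_keep, transform=transform)
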