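"""Synthetic data generators for the two Monte-Carlo study scenarios.

Both scenarios draw every feature i.i.d. standard normal: an ``n x 20``
low-dimensional block ``X`` of behavioral/clinical covariates (10 informative)
and an ``n x (p_total - 20)`` high-dimensional biomarker block ``Z``
(10 informative, the rest pure nuisance).  The continuous outcome is

* scenario 1 (linear):       y = a0 + sum a_z z_q + sum a_x x_q + eps
* scenario 2 (nonlinear):    scenario 1 + sum a_qz z_q^2 + sum a_qx x_q^2
                             + sum a_int x_q z_q + eps

with ``eps ~ N(0, 1)`` and every coefficient drawn once from N(0, 1) from a
dedicated coefficient seed, then held fixed across Monte-Carlo replicates.
By convention the informative columns are the first 10 of X and the first 10
of Z; the convention is recorded explicitly in the returned truth object so
downstream code never relies on position implicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._utils import check_vector

__all__ = [
    "ScenarioSpec",
    "Truth",
    "SimulatedDataset",
    "draw_coefficients",
    "generate",
    "make_fixture",
]

N_LOW = 20          # behavioral/clinical block width
N_INFORMATIVE = 10  # informative columns within each block


@dataclass(frozen=True)
class ScenarioSpec:
    """Study-condition description for one simulation scenario.

    Parameters
    ----------
    scenario
        1 for the linear response, 2 for quadratic + interaction terms.
    n
        Sample size per replicate.
    p_total
        Total observed covariates (low-dimensional 20 + biomarkers).
        Must be at least 40 so the biomarker block can host the 10
        informative columns plus a minimum of 10 nuisance columns.
    noise_sd
        Standard deviation of the additive Gaussian error (1 in the study).
    coefficient_seed, data_seed
        Separate streams: coefficients are drawn once per study and reused
        across replicates; data are redrawn per replicate.
    """

    scenario: int = 1
    n: int = 500
    p_total: int = 500
    noise_sd: float = 1.0
    coefficient_seed: int = 0
    data_seed: int = 0

    def __post_init__(self):
        if self.scenario not in (1, 2):
            raise ValueError(f"scenario must be 1 or 2, got {self.scenario}")
        if self.p_total < 2 * N_LOW:
            raise ValueError(
                f"p_total must be >= {2 * N_LOW} "
                f"(20 low-dim + 10 informative + >=10 nuisance biomarkers), got {self.p_total}"
            )

    @property
    def p_high(self) -> int:
        return self.p_total - N_LOW


@dataclass
class Truth:
    """Ground-truth coefficients and informative-index bookkeeping."""

    scenario: int
    alpha0: float
    alpha_z: np.ndarray          # (10,) linear biomarker effects
    alpha_x: np.ndarray          # (10,) linear low-dim effects
    alpha_quad_z: np.ndarray | None = None
    alpha_quad_x: np.ndarray | None = None
    alpha_int: np.ndarray | None = None
    informative_x: np.ndarray = field(default_factory=lambda: np.arange(N_INFORMATIVE))
    informative_z: np.ndarray = field(default_factory=lambda: np.arange(N_INFORMATIVE))

    def n_coefficients(self) -> int:
        n = 1 + self.alpha_z.size + self.alpha_x.size
        for a in (self.alpha_quad_z, self.alpha_quad_x, self.alpha_int):
            if a is not None:
                n += a.size
        return n

    def signal(self, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """Deterministic part of the response, E[y | X, Z]."""
        xs = X[:, self.informative_x]
        zs = Z[:, self.informative_z]
        out = self.alpha0 + zs @ self.alpha_z + xs @ self.alpha_x
        if self.scenario == 2:
            out = (
                out
                + (zs**2) @ self.alpha_quad_z
                + (xs**2) @ self.alpha_quad_x
                + (xs * zs) @ self.alpha_int
            )
        return out

    def to_dict(self) -> dict:
        d = {
            "scenario": self.scenario,
            "alpha0": self.alpha0,
            "alpha_z": self.alpha_z.tolist(),
            "alpha_x": self.alpha_x.tolist(),
            "informative_x": self.informative_x.tolist(),
            "informative_z": self.informative_z.tolist(),
        }
        for key in ("alpha_quad_z", "alpha_quad_x", "alpha_int"):
            a = getattr(self, key)
            d[key] = None if a is None else a.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Truth":
        def arr(v):
            return None if v is None else np.asarray(v, dtype=float)

        return cls(
            scenario=int(d["scenario"]),
            alpha0=float(d["alpha0"]),
            alpha_z=np.asarray(d["alpha_z"], dtype=float),
            alpha_x=np.asarray(d["alpha_x"], dtype=float),
            alpha_quad_z=arr(d.get("alpha_quad_z")),
            alpha_quad_x=arr(d.get("alpha_quad_x")),
            alpha_int=arr(d.get("alpha_int")),
            informative_x=np.asarray(d["informative_x"], dtype=int),
            informative_z=np.asarray(d["informative_z"], dtype=int),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Truth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SimulatedDataset:
    """Sample-aligned container for one simulated replicate."""

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    truth: Truth
    x_names: list[str] = field(default_factory=list)
    z_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.x_names:
            self.x_names = [f"x{q + 1}" for q in range(self.X.shape[1])]
        if not self.z_names:
            self.z_names = [f"z{k + 1}" for k in range(self.Z.shape[1])]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def features(self) -> np.ndarray:
        """Full feature matrix [X | Z]."""
        return np.hstack([self.X, self.Z])

    @property
    def feature_names(self) -> list[str]:
        return self.x_names + self.z_names


def draw_coefficients(spec: ScenarioSpec) -> Truth:
    """Draw all response coefficients from N(0, 1) using the coefficient seed."""
    rng = np.random.default_rng(spec.coefficient_seed)
    alpha0 = float(rng.standard_normal())
    alpha_z = rng.standard_normal(N_INFORMATIVE)
    alpha_x = rng.standard_normal(N_INFORMATIVE)
    if spec.scenario == 1:
        return Truth(1, alpha0, alpha_z, alpha_x)
    return Truth(
        2,
        alpha0,
        alpha_z,
        alpha_x,
        alpha_quad_z=rng.standard_normal(N_INFORMATIVE),
        alpha_quad_x=rng.standard_normal(N_INFORMATIVE),
        alpha_int=rng.standard_normal(N_INFORMATIVE),
    )


def generate(spec: ScenarioSpec, truth: Truth | None = None) -> SimulatedDataset:
    """Generate one replicate under the given scenario specification."""
    if truth is None:
        truth = draw_coefficients(spec)
    if truth.scenario != spec.scenario:
        raise ValueError("truth was drawn for a different scenario")
    rng = np.random.default_rng(spec.data_seed)
    X = rng.standard_normal((spec.n, N_LOW))
    Z = rng.standard_normal((spec.n, spec.p_high))
    eps = spec.noise_sd * rng.standard_normal(spec.n)
    y = truth.signal(X, Z) + eps
    return SimulatedDataset(X=X, Z=Z, y=y, truth=truth)


def make_fixture(
    n: int,
    p_low: int,
    p_high: int,
    *,
    alpha0: float = 0.0,
    alpha_x: Sequence[float] = (),
    alpha_z: Sequence[float] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SimulatedDataset:
    """Tiny deterministic dataset with user-pinned linear coefficients.

    Intended for exact hand-checkable unit tests: with ``noise_sd=0`` the
    outcome is an exact linear function of the named informative columns
    (the first ``len(alpha_x)`` of X and first ``len(alpha_z)`` of Z).
    """
    alpha_x = np.asarray(list(alpha_x), dtype=float)
    alpha_z = np.asarray(list(alpha_z), dtype=float)
    if alpha_x.size > p_low or alpha_z.size > p_high:
        raise ValueError("more coefficients than columns")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p_low))
    Z = rng.standard_normal((n, p_high))
    truth = Truth(
        scenario=1,
        alpha0=alpha0,
        alpha_z=alpha_z,
        alpha_x=alpha_x,
        informative_x=np.arange(alpha_x.size),
        informative_z=np.arange(alpha_z.size),
    )
    y = truth.signal(X, Z)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(n)
    y = check_vector(y)
    return SimulatedDataset(X=X, Z=Z, y=y, truth=truth)
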