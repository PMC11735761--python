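"""End-to-end orchestration: screen -> importance test -> refit -> predict.

The pipeline composes the three stages on a train/test split:

1. biomarkers are screened on training rows only, retaining ``k_keep``;
2. the permutation importance test runs on the concatenation of the
   low-dimensional features (which always bypass screening) and the retained
   biomarkers;
3. the chosen learner is refitted on the selected features and evaluated on
   the held-out rows with MSPE and Pearson correlation.

Named "arms" reproduce the benchmark variants: plain learners, importance
testing without screening, informed screening, and a random-screening
negative control.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from ._utils import check_aligned, check_matrix, check_vector, child_seed
from .ensemble import NetArchitecture
from .learners import make_learner
from .permfit import PermutationPlan, permfit_test, results_to_frame, select_features
from .screening import ScreeningResult, screen
from . import simdata

logger = logging.getLogger("hdfit")

__all__ = [
    "Dataset",
    "RunConfig",
    "RunReport",
    "TractabilityError",
    "ARMS",
    "mspe",
    "pcc",
    "run_hdfit",
    "run_benchmark",
    "scaled_sim_config",
]


class TractabilityError(RuntimeError):
    """Raised when an unscreened flexible learner is asked to fit too many features."""


def mspe(y, yhat) -> float:
    """Mean squared prediction error on held-out samples."""
    y = check_vector(y, "y")
    yhat = check_vector(yhat, "yhat")
    if y.size == 0:
        raise ValueError("empty vectors")
    check_aligned(y[:, None], yhat, "y", "yhat")
    return float(np.mean((y - yhat) ** 2))


def pcc(y, yhat) -> float:
    """Pearson correlation between observed and predicted outcomes."""
    y = check_vector(y, "y")
    yhat = check_vector(yhat, "yhat")
    check_aligned(y[:, None], yhat, "y", "yhat")
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(np.corrcoef(y, yhat)[0, 1])


@dataclass
class Dataset:
    """Sample-aligned container: low-dim block X, biomarker block Z, outcome y."""

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    x_names: list[str] = field(default_factory=list)
    z_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size or self.Z.shape[0] != self.y.size:
            raise ValueError("X, Z and y must agree on the number of samples")
        if not self.x_names:
            self.x_names = [f"x{q + 1}" for q in range(self.X.shape[1])]
        if not self.z_names:
            self.z_names = [f"z{k + 1}" for k in range(self.Z.shape[1])]

    @property
    def n(self) -> int:
        return self.y.size

    def features(self) -> np.ndarray:
        return np.hstack([self.X, self.Z])

    @property
    def feature_names(self) -> list[str]:
        return self.x_names + self.z_names


@dataclass(frozen=True)
class RunConfig:
    """All tunables of one pipeline run; serialized with every report.

    Every random operation derives its seed deterministically from
    ``seed`` via named streams, so a config fully determines a run.
    """

    learner: str = "stable-dnn"
    screening: str = "regression"       # or correlation / logmean / random / none
    screening_interactions: bool = True  # X * Z_k columns in the screening OLS
    k_keep: int = 80
    importance: bool = True
    alpha: float = 0.1
    n_perm: int = 200
    n_folds: int = 5
    variance_convention: str = "sem"
    arch: NetArchitecture = field(default_factory=NetArchitecture)
    K: int = 100
    rf_trees: int = 1000
    test_size: int = 50
    tractability_bound: int = 2000
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arch"]["hidden_sizes"] = list(d["arch"]["hidden_sizes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        arch = d.pop("arch", None)
        if arch is not None:
            arch = NetArchitecture(**{**arch, "hidden_sizes": tuple(arch["hidden_sizes"])})
            d["arch"] = arch
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    """Outputs and provenance of one pipeline run."""

    config: RunConfig
    screening_result: ScreeningResult | None
    importance: list
    selected_features: list[str]
    test_mspe: float | None
    test_pcc: float | None
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "config_hash": self.config.hash(),
            "selected_features": self.selected_features,
            "test_mspe": self.test_mspe,
            "test_pcc": self.test_pcc,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "importance": None
            if not self.importance
            else results_to_frame(self.importance).to_dict(orient="list"),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# arm name -> (learner, screening, importance test?)
ARMS: dict[str, dict] = {
    "lasso": dict(learner="lasso", screening="none", importance=False),
    "rf": dict(learner="rf", screening="none", importance=False),
    "tdnn": dict(learner="tdnn", screening="none", importance=False),
    "dnn": dict(learner="stable-dnn", screening="none", importance=False),
    "permfit-rf": dict(learner="rf", screening="none", importance=True),
    "permfit-dnn": dict(learner="stable-dnn", screening="none", importance=True),
    "control-rf": dict(learner="rf", screening="random", importance=True),
    "control-dnn": dict(learner="stable-dnn", screening="random", importance=True),
    "hdfit-rf": dict(learner="rf", screening="regression", importance=True),
    "hdfit-dnn": dict(learner="stable-dnn", screening="regression", importance=True),
}


def _learner_kwargs(config: RunConfig) -> dict:
    return dict(arch=config.arch, K=config.K, rf_trees=config.rf_trees)


def run_hdfit(
    dataset,
    config: RunConfig,
    train_idx=None,
    test_idx=None,
    evaluate: bool = True,
) -> RunReport:
    """Run the full screen -> test -> refit -> predict pipeline.

    ``dataset`` is any object with ``X``, ``Z``, ``y``, ``x_names`` and
    ``z_names`` attributes.  Training rows are the only rows any stage sees
    before the final evaluation; with ``evaluate=False`` the test rows are
    never read at all.
    """
    n = dataset.y.shape[0]
    if train_idx is None or test_idx is None:
        rng = np.random.default_rng(child_seed(config.seed, "split"))
        perm = rng.permutation(n)
        test_idx = np.sort(perm[: config.test_size])
        train_idx = np.sort(perm[config.test_size :])
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices overlap")

    p_low = dataset.X.shape[1]
    p_high = dataset.Z.shape[1]
    p_total = p_low + p_high

    Xtr = check_matrix(dataset.X[train_idx], "X[train]")
    Ztr = check_matrix(dataset.Z[train_idx], "Z[train]")
    ytr = check_vector(dataset.y[train_idx], "y[train]")

    # -- stage 1: screening (training rows only) --------------------------
    if config.screening == "none":
        if config.learner in ("stable-dnn", "tdnn", "rf") and p_total > config.tractability_bound:
            raise TractabilityError(
                f"{config.learner} without screening refuses p={p_total} features "
                f"(> tractability bound {config.tractability_bound}); "
                "enable screening or raise the bound"
            )
        screening_result = None
        retained = np.arange(p_high)
    else:
        screening_result = screen(
            ytr,
            Ztr,
            Xtr,
            method=config.screening,
            k_keep=config.k_keep,
            interactions=config.screening_interactions,
            seed=child_seed(config.seed, "screen"),
        )
        retained = screening_result.retained

    feat_names = list(dataset.x_names) + [dataset.z_names[k] for k in retained]
    Ftr = np.hstack([Xtr, Ztr[:, retained]])

    # -- stage 2: permutation importance test -----------------------------
    if config.importance:
        plan = PermutationPlan(
            n_perm=config.n_perm,
            n_folds=config.n_folds,
            seed=child_seed(config.seed, "permfit"),
            variance_convention=config.variance_convention,
        )
        importance = permfit_test(
            config.learner,
            Ftr,
            ytr,
            plan=plan,
            alpha=config.alpha,
            feature_names=feat_names,
            **_learner_kwargs(config),
        )
        sel = select_features(importance, config.alpha)
        if sel.size == 0:
            logger.warning(
                "no feature passed the importance test at alpha=%.3g; "
                "refitting on all %d post-screening features",
                config.alpha,
                Ftr.shape[1],
            )
            sel = np.arange(Ftr.shape[1])
    else:
        importance = []
        sel = np.arange(Ftr.shape[1])

    # -- stage 3: refit on selected features and evaluate ------------------
    learner = make_learner(config.learner, **_learner_kwargs(config))
    learner.fit(Ftr[:, sel], ytr, seed=child_seed(config.seed, "refit"))

    test_mspe = test_pcc = None
    if evaluate:
        Xte = np.asarray(dataset.X[test_idx], dtype=float)
        Zte = np.asarray(dataset.Z[test_idx], dtype=float)
        yte = np.asarray(dataset.y[test_idx], dtype=float)
        Fte = np.hstack([Xte, Zte[:, retained]])
        yhat = learner.predict(Fte[:, sel])
        test_mspe = mspe(yte, yhat)
        test_pcc = pcc(yte, yhat)

    return RunReport(
        config=config,
        screening_result=screening_result,
        importance=importance,
        selected_features=[feat_names[int(j)] for j in sel],
        test_mspe=test_mspe,
        test_pcc=test_pcc,
        n_train=train_idx.size,
        n_test=test_idx.size,
    )


def scaled_sim_config(seed: int = 0, **overrides) -> RunConfig:
    """The reduced-scale simulation configuration used by the benchmark suite.

    Bootstrap count, cross-fitting depth, permutation count and optimizer
    are scaled down from the package defaults so a full multi-arm
    Monte-Carlo sweep runs on a single CPU in minutes; see docs/methods.md.
    """
    cfg = RunConfig(
        arch=NetArchitecture(solver="lbfgs", max_iter=200),
        K=20,
        n_folds=1,
        n_perm=5,
        rf_trees=300,
        screening_interactions=False,  # simulations adjust for linear X terms only
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def run_benchmark(
    scenario: int,
    p_total: int,
    arms: list[str],
    n_reps: int,
    seed: int = 0,
    n: int = 500,
    base_config: RunConfig | None = None,
) -> pd.DataFrame:
    """Monte-Carlo benchmark over the named arms.

    Coefficients are drawn once from the seed and held fixed across the
    ``n_reps`` replicates; each replicate draws fresh data, reserves
    ``test_size`` samples for testing, and runs every arm on the same split.
    Returns one row per arm with mean MSPE/PCC, Monte-Carlo standard errors,
    and the replicate count (NaN metrics with ``n_reps = 0`` for arms that
    refuse the dimensionality).
    """
    unknown = set(arms) - set(ARMS)
    if unknown:
        raise ValueError(f"unknown arms: {sorted(unknown)}")
    base = base_config or scaled_sim_config()
    coef_seed = child_seed(seed, "coefficients")
    spec0 = simdata.ScenarioSpec(
        scenario=scenario, n=n, p_total=p_total, coefficient_seed=coef_seed
    )
    truth = simdata.draw_coefficients(spec0)

    records: dict[str, list[tuple[float, float]]] = {a: [] for a in arms}
    skipped: dict[str, str] = {}
    for rep in range(n_reps):
        spec = replace(spec0, data_seed=child_seed(seed, "data", rep))
        ds = simdata.generate(spec, truth)
        split_rng = np.random.default_rng(child_seed(seed, "split", rep))
        perm = split_rng.permutation(n)
        test_idx = np.sort(perm[: base.test_size])
        train_idx = np.sort(perm[base.test_size :])
        for arm in arms:
            if arm in skipped:
                continue
            cfg = replace(
                base,
                **ARMS[arm],
                seed=child_seed(seed, "run", rep, arm),
            )
            try:
                rep_report = run_hdfit(ds, cfg, train_idx=train_idx, test_idx=test_idx)
            except TractabilityError as exc:
                skipped[arm] = str(exc)
                logger.warning("arm %s skipped: %s", arm, exc)
                continue
            records[arm].append((rep_report.test_mspe, rep_report.test_pcc))

    rows = []
    for arm in arms:
        vals = records[arm]
        if not vals or arm in skipped:
            rows.append(
                dict(arm=arm, p_total=p_total, mspe=np.nan, pcc=np.nan,
                     mspe_se=np.nan, pcc_se=np.nan, n_reps=0)
            )
            continue
        m = np.array([v[0] for v in vals])
        c = np.array([v[1] for v in vals])
        rows.append(
            dict(
                arm=arm,
                p_total=p_total,
                mspe=float(m.mean()),
                pcc=float(c.mean()),
                mspe_se=float(m.std(ddof=1) / np.sqrt(m.size)) if m.size > 1 else np.nan,
                pcc_se=float(c.std(ddof=1) / np.sqrt(c.size)) if c.size > 1 else np.nan,
                n_reps=int(m.size),
            )
        )
    return pd.DataFrame(rows)
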