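"""Gaze -> posture coupling model.

A bootstrap forest of regression trees is built explicitly (one bootstrap
sample per tree, random feature subsets per split) so that each tree's
out-of-bag cases are available. Feature importance follows the ratio rule

    Imp_i = mean(d_i) / sd(d_i)

where d_i is, for every tree whose splits use feature i, the change in
out-of-bag squared error after randomly permuting feature i (sd with one
delta degree of freedom; a zero or undefined sd yields Imp_i = 0). The
protocol runs the importance estimate five times with derived seeds and
selects features whose lower quartile of the five values exceeds the
threshold (strict inequality, linear-interpolation quantile).

Prediction quality is assessed by leave-one-out cross-validation with the
root-mean-square error normalized by the 100-point score range, reported
both on all subjects and after excluding the single largest residual.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .types import InvalidInputError


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    features_per_split: int | None = None  # default ceil(p / 3)
    min_leaf: int = 2
    seed: int = 0

    def validate(self, n_features: int) -> int:
        if self.n_trees < 1:
            raise InvalidInputError("n_trees must be >= 1")
        mf = self.features_per_split
        if mf is None:
            mf = math.ceil(n_features / 3)
        if not 1 <= mf <= n_features:
            raise InvalidInputError("features_per_split out of range")
        return mf


@dataclass
class _Forest:
    trees: list[DecisionTreeRegressor]
    oob_indices: list[np.ndarray]
    used_features: list[np.ndarray]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float32)
        preds = np.zeros(len(X))
        for tree in self.trees:
            preds += tree.predict(X, check_input=False)
        return preds / len(self.trees)


def _fit_forest(X: np.ndarray, y: np.ndarray, cfg: ForestConfig, rng: np.random.Generator) -> _Forest:
    n, p = X.shape
    mf = cfg.validate(p)
    trees, oobs, used = [], [], []
    for _ in range(cfg.n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeRegressor(
            max_features=mf,
            min_samples_leaf=cfg.min_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        trees.append(tree)
        oobs.append(oob)
        used.append(np.unique(tree.tree_.feature[tree.tree_.feature >= 0]))
    return _Forest(trees=trees, oob_indices=oobs, used_features=used)


def importance_ratio(d: np.ndarray) -> float:
    """mean/sd of the per-tree error changes; 0 when sd is 0 or undefined."""
    d = np.asarray(d, dtype=float)
    if len(d) < 2:
        return 0.0
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        return 0.0
    return float(np.mean(d) / sd)


@dataclass
class ImportanceResult:
    feature_names: tuple[str, ...]
    imp_runs: np.ndarray  # (n_features, n_runs)
    d_mean: np.ndarray  # (n_features, n_runs)
    d_sd: np.ndarray  # (n_features, n_runs)
    quartile25: np.ndarray  # (n_features,)
    selected: np.ndarray  # bool (n_features,)
    threshold: float

    def selected_names(self) -> list[str]:
        return [n for n, s in zip(self.feature_names, self.selected) if s]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.imp_runs,
            index=list(self.feature_names),
            columns=[f"imp_run{r + 1}" for r in range(self.imp_runs.shape[1])],
        )
        df.index.name = "feature"
        df["quartile25"] = self.quartile25
        df["selected"] = self.selected
        return df.reset_index()


def _one_run_importance(
    X: np.ndarray, y: np.ndarray, cfg: ForestConfig, run_seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(run_seed)
    forest = _fit_forest(X, y, cfg, rng)
    p = X.shape[1]
    d_lists: list[list[float]] = [[] for _ in range(p)]
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    for tree, oob, used in zip(forest.trees, forest.oob_indices, forest.used_features):
        if len(oob) == 0 or len(used) == 0:
            continue
        Xo = X32[oob]
        base = float(np.mean((tree.predict(Xo, check_input=False) - y[oob]) ** 2))
        for f in used:
            Xp = Xo.copy()
            Xp[:, f] = Xp[rng.permutation(len(oob)), f]
            err = float(np.mean((tree.predict(Xp, check_input=False) - y[oob]) ** 2))
            d_lists[f].append(err - base)
    imp = np.array([importance_ratio(np.array(d)) for d in d_lists])
    dm = np.array([np.mean(d) if d else 0.0 for d in d_lists])
    ds = np.array([np.std(d, ddof=1) if len(d) > 1 else 0.0 for d in d_lists])
    return imp, dm, ds


def oob_permutation_importance(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    cfg: ForestConfig = ForestConfig(),
    n_runs: int = 5,
    threshold: float = 0.1,
    feature_names: tuple[str, ...] | None = None,
) -> ImportanceResult:
    """Repeated out-of-bag permutation importance with quartile selection."""
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < 5:
        raise InvalidInputError("need at least 5 subjects")
    if np.any(~np.isfinite(X)):
        raise InvalidInputError("missing feature values must be imputed before modeling")
    if np.ptp(y) == 0:
        raise InvalidInputError("degenerate target: postural scores are constant")
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    p = X.shape[1]
    imp_runs = np.empty((p, n_runs))
    d_mean = np.empty((p, n_runs))
    d_sd = np.empty((p, n_runs))
    for r in range(n_runs):
        imp_runs[:, r], d_mean[:, r], d_sd[:, r] = _one_run_importance(X, y, cfg, cfg.seed + r)
    q25 = np.quantile(imp_runs, 0.25, axis=1)  # linear-interpolation quantile
    return ImportanceResult(
        feature_names=feature_names,
        imp_runs=imp_runs,
        d_mean=d_mean,
        d_sd=d_sd,
        quartile25=q25,
        selected=q25 > threshold,
        threshold=threshold,
    )


def select_features(imp: ImportanceResult, threshold: float = 0.1) -> list[str]:
    """Features whose lower quartile of importance strictly exceeds the threshold."""
    q25 = np.quantile(imp.imp_runs, 0.25, axis=1)
    return [n for n, q in zip(imp.feature_names, q25) if q > threshold]


def normalized_rmse(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float, int]:
    """(rmse/100, rmse/100 after dropping the largest |residual|, its index).

    Ties on the largest residual resolve to the first index.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    resid = predicted - observed
    rmse = float(np.sqrt(np.mean(resid**2)) / 100.0)
    worst = int(np.argmax(np.abs(resid)))
    keep = np.arange(len(resid)) != worst
    rmse_excl = float(np.sqrt(np.mean(resid[keep] ** 2)) / 100.0)
    return rmse, rmse_excl, worst


@dataclass
class PredictionResult:
    subject_ids: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    rmse_norm: float
    rmse_norm_excl: float
    excluded_subject: str
    clipped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "observed": self.observed,
                "predicted": self.predicted,
                "residual": self.predicted - self.observed,
            }
        )


def loo_predict(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    cfg: ForestConfig = ForestConfig(),
    feature_subset: list[str] | None = None,
    subject_ids: list[str] | None = None,
) -> PredictionResult:
    """Leave-one-out forest prediction with normalized RMSE.

    ``rmse_norm`` divides by the 100-point score range; ``rmse_norm_excl``
    recomputes it after dropping the largest absolute residual (first
    index on ties). Per-fold seeds derive from ``cfg.seed`` and the fold
    index only, so changing a held-out label cannot leak into its own
    prediction.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        if feature_subset is not None:
            unknown = [f for f in feature_subset if f not in names]
            if unknown:
                raise InvalidInputError(f"unknown features in subset: {unknown}")
            X = X[list(feature_subset)]
        X = X.to_numpy(dtype=float)
    elif feature_subset is not None:
        raise InvalidInputError("feature_subset requires a DataFrame input")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(X)
    if n < 3:
        raise InvalidInputError("need at least 3 subjects for leave-one-out")
    if subject_ids is None:
        subject_ids = [str(i) for i in range(n)]
    preds = np.empty(n)
    clipped: list[str] = []
    for i in range(n):
        rest = np.arange(n) != i
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, i)))
        forest = _fit_forest(X[rest], y[rest], cfg, rng)
        pred = float(forest.predict(X[i : i + 1])[0])
        if pred < 0.0 or pred > 100.0:
            clipped.append(subject_ids[i])
            pred = float(np.clip(pred, 0.0, 100.0))
        preds[i] = pred
    rmse_norm, rmse_excl, worst = normalized_rmse(y, preds)
    return PredictionResult(
        subject_ids=list(subject_ids),
        observed=y,
        predicted=preds,
        rmse_norm=rmse_norm,
        rmse_norm_excl=rmse_excl,
        excluded_subject=subject_ids[worst],
        clipped=clipped,
    )
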