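"""Breast-muscle weight regression: RFE feature selection + linear SVR.

Candidate predictors are live weight plus the 15 mask shape descriptors.
Features are z-scored (the target stays in grams, so the SVR epsilon-tube of
0.3 g is meaningful); an epsilon-insensitive linear SVR with C=10 is ranked
recursively: the feature with the smallest |coefficient| is eliminated at
each step, the 5-fold cross-validated R^2 of every nested subset is recorded,
and the subset with the highest CV R^2 is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from . import shape_features
from .shape_features import FEATURE_NAMES

#: the 16 candidate predictor columns
CANDIDATE_FEATURES = ("live_weight", *FEATURE_NAMES)
TARGET_COLUMN = "breast_muscle_weight"


@dataclass(frozen=True)
class SVRConfig:
    kernel: str = "linear"
    C: float = 10.0
    epsilon: float = 0.3
    tol: float = 1e-4

    def __post_init__(self):
        if self.C <= 0 or self.epsilon < 0:
            raise ValueError("require C > 0 and epsilon >= 0")

    def make(self) -> SVR:
        return SVR(kernel=self.kernel, C=self.C, epsilon=self.epsilon,
                   tol=self.tol)


@dataclass(frozen=True)
class RFEConfig:
    cv_folds: int = 5
    seed: int = 0
    subset_sizes: tuple[int, ...] | None = None  # default: every size 1..n

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class RegressionMetrics:
    r2: float
    rmse: float   # grams
    mae: float    # grams
    mre: float    # percent


@dataclass
class WeightPredictionModel:
    selected_features: list[str]
    scaler: StandardScaler
    svr: SVR
    svr_config: SVRConfig

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.selected_features].to_numpy(dtype=np.float64)
        return self.svr.predict(self.scaler.transform(x))


def regression_metrics(actual, predicted) -> RegressionMetrics:
    """R^2, RMSE, MAE (grams) and MRE (percent) of predictions."""
    y = np.asarray(actual, dtype=np.float64)
    yhat = np.asarray(predicted, dtype=np.float64)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("actual and predicted must be equal-length, nonempty")
    err = yhat - y
    ss_res = float((err ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else
                                                   -np.inf)
    rmse = float(np.sqrt((err ** 2).mean()))
    mae = float(np.abs(err).mean())
    if (y == 0).any():
        warnings.warn("actual weight of 0 g encountered; MRE is undefined "
                      "and reported as NaN")
        mre = float("nan")
    else:
        mre = float(np.abs(err / y).mean() * 100.0)
    return RegressionMetrics(r2=r2, rmse=rmse, mae=mae, mre=mre)


def build_predictor_table(features: pd.DataFrame,
                          manifest: pd.DataFrame) -> pd.DataFrame:
    """Join shape features with the per-animal manifest on sample_id."""
    table = features.merge(
        manifest.rename(columns={"live_weight_g": "live_weight",
                                 "breast_muscle_weight_g": TARGET_COLUMN}),
        on="sample_id", validate="one_to_one")
    missing = [c for c in (*CANDIDATE_FEATURES, TARGET_COLUMN)
               if c not in table.columns]
    if missing:
        raise ValueError(f"predictor table is missing columns {missing}")
    if table[list(CANDIDATE_FEATURES) + [TARGET_COLUMN]].isna().any().any():
        raise ValueError("predictor table contains missing values")
    return table


def _cv_r2(x: np.ndarray, y: np.ndarray, svr_cfg: SVRConfig, folds: int,
           seed: int) -> float:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in kf.split(x):
        scaler = StandardScaler().fit(x[tr])
        svr = svr_cfg.make().fit(scaler.transform(x[tr]), y[tr])
        pred = svr.predict(scaler.transform(x[te]))
        scores.append(regression_metrics(y[te], pred).r2)
    return float(np.mean(scores))


@dataclass(frozen=True)
class RFEResult:
    selected: tuple[str, ...]
    cv_scores: dict[int, float]          # subset size -> mean CV R^2
    elimination_order: tuple[str, ...]   # first eliminated first
    subsets: dict[int, tuple[str, ...]]  # subset size -> nested subset


def rfe_select(table: pd.DataFrame, rfe_cfg: RFEConfig | None = None,
               svr_cfg: SVRConfig | None = None,
               features: tuple[str, ...] = CANDIDATE_FEATURES,
               target: str = TARGET_COLUMN) -> RFEResult:
    """Recursive feature elimination with linear-SVR coefficient ranking.

    At each step the linear SVR is refit on the standardized remaining
    features and the feature with the smallest |coefficient| is removed (ties
    broken toward the later column).  Every nested subset's k-fold CV R^2 is
    recorded; the subset with the maximum CV R^2 is returned (ties toward the
    smaller subset).
    """
    rfe_cfg = rfe_cfg or RFEConfig()
    svr_cfg = svr_cfg or SVRConfig()
    y = table[target].to_numpy(dtype=np.float64)
    if len(y) < 2 * rfe_cfg.cv_folds:
        raise ValueError("need at least 2 rows per CV fold")

    remaining = [f for f in features]
    for f in features:
        if table[f].nunique() <= 1:
            warnings.warn(f"dropping constant feature column {f!r}")
            remaining.remove(f)
    sizes = (set(rfe_cfg.subset_sizes) if rfe_cfg.subset_sizes is not None
             else set(range(1, len(remaining) + 1)))

    cv_scores: dict[int, float] = {}
    subsets: dict[int, tuple[str, ...]] = {}
    eliminated: list[str] = []
    while remaining:
        x = table[remaining].to_numpy(dtype=np.float64)
        if len(remaining) in sizes:
            cv_scores[len(remaining)] = _cv_r2(x, y, svr_cfg,
                                               rfe_cfg.cv_folds, rfe_cfg.seed)
            subsets[len(remaining)] = tuple(remaining)
        if len(remaining) == 1:
            break
        scaler = StandardScaler().fit(x)
        svr = svr_cfg.make().fit(scaler.transform(x), y)
        coefs = np.abs(np.ravel(svr.coef_))
        ties = np.flatnonzero(coefs == coefs.min())
        drop = int(ties.max())  # later column loses on exact ties
        eliminated.append(remaining.pop(drop))

    if not cv_scores:
        raise ValueError("no subset size was evaluated")
    best_size = max(sorted(cv_scores), key=lambda s: (cv_scores[s], -s))
    return RFEResult(selected=subsets[best_size], cv_scores=cv_scores,
                     elimination_order=tuple(eliminated), subsets=subsets)


def fit(table: pd.DataFrame, selected, svr_cfg: SVRConfig | None = None,
        target: str = TARGET_COLUMN) -> WeightPredictionModel:
    """Fit the z-scoring scaler and linear SVR on the given rows."""
    svr_cfg = svr_cfg or SVRConfig()
    selected = list(selected)
    if len(table) < 2:
        raise ValueError("need at least 2 rows to fit")
    x = table[selected].to_numpy(dtype=np.float64)
    if (x.std(axis=0) == 0).any():
        bad = [f for f, s in zip(selected, x.std(axis=0)) if s == 0]
        raise ValueError(f"zero-variance selected feature(s): {bad}")
    y = table[target].to_numpy(dtype=np.float64)
    scaler = StandardScaler().fit(x)
    svr = svr_cfg.make().fit(scaler.transform(x), y)
    return WeightPredictionModel(selected_features=selected, scaler=scaler,
                                 svr=svr, svr_config=svr_cfg)


def cross_validate(table: pd.DataFrame, selected,
                   svr_cfg: SVRConfig | None = None, k: int = 5,
                   seed: int = 0, target: str = TARGET_COLUMN
                   ) -> tuple[list[RegressionMetrics], RegressionMetrics]:
    """Seeded k-fold CV; scaler and SVR are refit on each training fold only.

    Returns the per-fold metrics and their arithmetic mean.
    """
    svr_cfg = svr_cfg or SVRConfig()
    selected = list(selected)
    n = len(table)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available rows")
    x = table[selected].to_numpy(dtype=np.float64)
    y = table[target].to_numpy(dtype=np.float64)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics = []
    for tr, te in kf.split(x):
        scaler = StandardScaler().fit(x[tr])
        svr = svr_cfg.make().fit(scaler.transform(x[tr]), y[tr])
        pred = svr.predict(scaler.transform(x[te]))
        fold_metrics.append(regression_metrics(y[te], pred))
    mean = RegressionMetrics(
        r2=float(np.mean([m.r2 for m in fold_metrics])),
        rmse=float(np.mean([m.rmse for m in fold_metrics])),
        mae=float(np.mean([m.mae for m in fold_metrics])),
        mre=float(np.mean([m.mre for m in fold_metrics])),
    )
    return fold_metrics, mean


def predict_weight(mask: np.ndarray, live_weight: float,
                   model: WeightPredictionModel) -> float:
    """Mask + live weight -> breast-muscle weight in grams."""
    feats = shape_features.extract_features(mask)
    feats["live_weight"] = float(live_weight)
    missing = [f for f in model.selected_features if f not in feats]
    if missing:
        raise ValueError(f"model requires unavailable feature(s) {missing}")
    row = pd.DataFrame([feats])
    return float(model.predict(row)[0])
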