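"""The eight-regressor suite under a single fit/predict/weights contract.

Linear-family members (svm_linear, pcr, pls) expose per-feature coefficient
vectors, which downstream feed the predicted-mortality-rate formula
PMR_n = sum_k W_k C_kn + intercept.  Tree/ensemble/NN members are adapters
over established implementations; their internals are not the point here and
they expose no weights.

Hyperparameters are chosen by internal k-fold resampling minimizing RMSE over
``tune_length`` candidates; the linear-SVR cost C is searched over random
log-uniform draws, following the original tuning convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import BaggingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "MODEL_NAMES",
    "LINEAR_FAMILY",
    "RegressorSpec",
    "FittedModel",
    "fit",
    "predict",
    "extract_weights",
]

MODEL_NAMES = ("knn", "pcr", "pls", "svm_linear", "rf", "treebag", "xgb", "brnn")
LINEAR_FAMILY = frozenset({"svm_linear", "pcr", "pls"})

_CV_FOLDS = 3


@dataclass(frozen=True)
class RegressorSpec:
    """A named regressor with its tuning budget.

    ``grid`` overrides the default candidate set, e.g.
    ``RegressorSpec("knn", grid={"n_neighbors": [1]})`` for a deliberate 1-NN.
    """

    name: str
    tune_length: int = 10
    seed: int = 0
    grid: dict[str, Any] | None = field(default=None, hash=False)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.name!r}; expected one of {MODEL_NAMES}"
            )
        if self.tune_length < 1:
            raise ValueError("tune_length must be >= 1")


@dataclass
class FittedModel:
    spec: RegressorSpec
    estimator: Any
    feature_names: list[str]
    chosen: dict[str, Any]
    cv_rmse: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return predict(self, X)

    @property
    def is_linear(self) -> bool:
        return self.spec.name in LINEAR_FAMILY

    def linear_form(self) -> tuple[pd.Series, float]:
        """(weights, intercept) such that prediction = X @ weights + intercept
        for the linear family; raises for other models."""
        w = extract_weights(self)
        # the intercept of any affine predictor is its value at the origin
        origin = np.zeros((1, len(self.feature_names)))
        b = float(np.ravel(self.estimator.predict(origin))[0])
        return w, b


def _grid_to_candidates(grid: dict[str, Any]) -> list[dict[str, Any]]:
    keys = list(grid)
    lists = [v if isinstance(v, (list, tuple, np.ndarray)) else [v] for v in
             (grid[k] for k in keys)]
    out: list[dict[str, Any]] = [{}]
    for k, vals in zip(keys, lists):
        out = [{**d, k: v} for d in out for v in vals]
    return out


def _default_candidates(
    name: str, tl: int, n: int, p: int, seed: int
) -> list[dict[str, Any]]:
    rng = np.random.default_rng(seed)
    if name == "knn":
        ks = np.unique(np.linspace(1, max(3, min(n - 1, 2 * tl + 1)), tl).astype(int))
        return [{"n_neighbors": int(k)} for k in ks]
    if name in {"pcr", "pls"}:
        cmax = min(tl, p, n - 1)
        return [{"n_components": c} for c in range(1, cmax + 1)]
    if name == "svm_linear":
        # random search for C, log-uniform over [1e-3, 1e2]
        cs = 10.0 ** rng.uniform(-3, 2, size=tl)
        return [{"C": float(c)} for c in cs]
    if name == "rf":
        mf = np.unique(np.linspace(1, p, min(tl, p)).astype(int))
        return [{"max_features": int(m)} for m in mf]
    if name == "treebag":
        return [{}]
    if name == "xgb":
        ns = np.unique(np.linspace(50, 50 + 25 * (tl - 1), tl).astype(int))
        return [{"n_estimators": int(e)} for e in ns]
    if name == "brnn":
        return [{"hidden": h} for h in range(1, tl + 1)]
    raise AssertionError(name)


def _build(name: str, params: dict[str, Any], seed: int, y_sd: float) -> Any:
    if name == "knn":
        return KNeighborsRegressor(n_neighbors=params["n_neighbors"])
    if name == "pcr":
        from sklearn.pipeline import Pipeline

        return Pipeline(
            [
                ("pca", PCA(n_components=params["n_components"], svd_solver="full")),
                ("lr", LinearRegression()),
            ]
        )
    if name == "pls":
        return PLSRegression(n_components=params["n_components"], scale=False)
    if name == "svm_linear":
        eps = params.get("epsilon", 0.1 * y_sd)
        return SVR(kernel="linear", C=params["C"], epsilon=eps)
    if name == "rf":
        return RandomForestRegressor(
            n_estimators=200,
            max_features=params["max_features"],
            random_state=seed,
            n_jobs=1,
        )
    if name == "treebag":
        return BaggingRegressor(
            estimator=DecisionTreeRegressor(random_state=seed),
            n_estimators=50,
            random_state=seed,
            n_jobs=1,
        )
    if name == "xgb":
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=params["n_estimators"],
            learning_rate=0.1,
            max_depth=3,
            subsample=0.8,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    if name == "brnn":
        return MLPRegressor(
            hidden_layer_sizes=(params["hidden"],),
            alpha=0.1,
            solver="lbfgs",
            max_iter=2000,
            random_state=seed,
        )
    raise AssertionError(name)


def fit(spec: RegressorSpec, X: pd.DataFrame, y: Sequence[float]) -> FittedModel:
    """Fit one regressor, selecting hyperparameters by internal 3-fold CV RMSE
    over the candidate set (ties keep the first candidate); fully seeded."""
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < _CV_FOLDS:
        raise ValueError(f"need at least {_CV_FOLDS} rows for internal CV, got {n}")
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    y_sd = float(y.std(ddof=1)) if n > 1 else 1.0
    if spec.grid is not None:
        candidates = _grid_to_candidates(spec.grid)
    else:
        candidates = _default_candidates(spec.name, spec.tune_length, n, p, spec.seed)

    Xv = X.to_numpy(dtype=float)
    if len(candidates) == 1:
        best_params, best_rmse = candidates[0], float("nan")
    else:
        kf = KFold(n_splits=_CV_FOLDS, shuffle=True, random_state=spec.seed)
        folds = list(kf.split(Xv))
        scores = []
        for params in candidates:
            sq = 0.0
            m = 0
            for tr, va in folds:
                est = _build(spec.name, params, spec.seed, y_sd)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    est.fit(Xv[tr], y[tr])
                pred = np.ravel(est.predict(Xv[va]))
                sq += float(((pred - y[va]) ** 2).sum())
                m += len(va)
            scores.append(math.sqrt(sq / m))
        best_idx = int(np.argmin(scores))
        best_params, best_rmse = candidates[best_idx], scores[best_idx]

    est = _build(spec.name, best_params, spec.seed, y_sd)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(Xv, y)
    return FittedModel(
        spec=spec,
        estimator=est,
        feature_names=list(X.columns),
        chosen=dict(best_params),
        cv_rmse=best_rmse,
    )


def predict(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Predictions on the training outcome scale, one per row of X."""
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing:
        raise KeyError(f"feature(s) missing from prediction input: {missing}")
    if len(X) == 0:
        return np.empty(0)
    Xv = X[model.feature_names].to_numpy(dtype=float)
    return np.ravel(model.estimator.predict(Xv))


def extract_weights(model: FittedModel) -> pd.Series:
    """Signed per-feature coefficients for linear-family models.

    svm_linear: the primal weight vector of the linear SVR; pcr: principal
    components back-projected through the regression coefficients; pls: the
    regression coefficients in original feature space.
    """
    name = model.spec.name
    if name not in LINEAR_FAMILY:
        raise ValueError(f"weights undefined for model {name!r}")
    if name == "svm_linear":
        w = np.ravel(np.asarray(model.estimator.coef_))
    elif name == "pcr":
        pca: PCA = model.estimator["pca"]
        lr: LinearRegression = model.estimator["lr"]
        w = pca.components_.T @ lr.coef_
    else:  # pls
        w = np.ravel(np.asarray(model.estimator.coef_))
    return pd.Series(w, index=model.feature_names, name=f"{name}_weight")
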