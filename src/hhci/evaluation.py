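"""Model discrimination and validation: RMSE, blocked repeated cross-
validation, train/external error proportionality, overfit/underfit
classification, model selection and calibration-plot data.

Proportionality is RMSE_train / RMSE_external: values near 1 mean the model
generalizes; values far below 1 flag overfitting (the training error is
deceptively small).  Underfitting is flagged when external predictions are
nearly constant (coefficient of variation below a floor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import FittedModel, RegressorSpec, fit

__all__ = [
    "ModelEvaluation",
    "rmse",
    "blocked_cv",
    "proportionality",
    "classify_fit",
    "select_model",
    "evaluate_models",
    "calibration_data",
]

PROP_FLOOR = 0.7
SPREAD_FLOOR = 0.05


@dataclass
class ModelEvaluation:
    name: str
    rmse_train: float
    rmse_ext_2014: float
    rmse_ext_2015: float
    proportionality_2014: float
    proportionality_2015: float
    pred_spread_cv: float      # coefficient of variation of external predictions
    fit_class: str = "ok"      # ok | overfit | underfit

    def as_row(self) -> dict:
        return {
            "model": self.name,
            "rmse_train": self.rmse_train,
            "rmse_2014": self.rmse_ext_2014,
            "rmse_2015": self.rmse_ext_2015,
            "prop_2014": self.proportionality_2014,
            "prop_2015": self.proportionality_2015,
            "fit_class": self.fit_class,
        }


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root mean squared error sqrt(mean((P_i - O_i)^2))."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def blocked_cv(
    spec: RegressorSpec,
    X: pd.DataFrame,
    y: Sequence[float],
    k: int = 3,
    repeats: int = 5,
    seed: int = 0,
    scheme: str = "all_blocks",
) -> dict:
    """Repeated k-block cross-validation.

    Default scheme ``all_blocks``: each repeat draws a fresh random partition
    into k near-equal blocks and every block serves once as the validation
    set, giving repeats*k validation runs (5 x 3 = 15 by default).  Scheme
    ``one_block``: each repeat validates on a single randomly chosen block
    (repeats runs in total).  Returns mean train/validation RMSE and the
    per-run values.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if scheme not in {"all_blocks", "one_block"}:
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    train_rmses, val_rmses, blocks_log = [], [], []
    for rep in range(repeats):
        perm = rng.permutation(n)
        blocks = np.array_split(perm, k)
        chosen = range(k) if scheme == "all_blocks" else [rng.integers(k)]
        for b in chosen:
            va = np.sort(blocks[b])
            tr = np.sort(np.concatenate([blocks[q] for q in range(k) if q != b]))
            model = fit(spec, X.iloc[tr], y[tr])
            train_rmses.append(rmse(model.predict(X.iloc[tr]), y[tr]))
            val_rmses.append(rmse(model.predict(X.iloc[va]), y[va]))
            blocks_log.append([len(b) for b in blocks])
    return {
        "train_rmse": float(np.mean(train_rmses)),
        "val_rmse": float(np.mean(val_rmses)),
        "train_rmses": train_rmses,
        "val_rmses": val_rmses,
        "block_sizes": blocks_log[0] if blocks_log else [],
        "n_runs": len(val_rmses),
    }


def proportionality(rmse_train: float, rmse_external: float) -> float:
    """Train/external RMSE ratio; close to 1 = stable, well below 1 = the
    external error dwarfs the training error (overfitting)."""
    if rmse_external <= 0:
        raise ValueError("external RMSE must be positive")
    return rmse_train / rmse_external


def classify_fit(
    ev: ModelEvaluation,
    prop_floor: float = PROP_FLOOR,
    cv_pred_spread_floor: float = SPREAD_FLOOR,
) -> str:
    """overfit if proportionality (2014 analog) falls below the floor;
    underfit if external predictions are nearly constant; else ok.  Overfit is
    checked first so the two flags cannot co-occur."""
    if ev.proportionality_2014 < prop_floor:
        return "overfit"
    if ev.pred_spread_cv < cv_pred_spread_floor:
        return "underfit"
    return "ok"


def select_model(evaluations: Sequence[ModelEvaluation]) -> str:
    """Best prediction among models that generalize.

    The fit classification is the gate (overfit and underfit models are out);
    among the remaining models the one with the lowest external RMSE on the
    penultimate-year analog wins — prediction quality decides, proportionality
    only disqualifies.  Ties break by the final-year external RMSE, then by
    name order.
    """
    ok = [e for e in evaluations if e.fit_class == "ok"]
    if not ok:
        table = pd.DataFrame([e.as_row() for e in evaluations]).to_string(index=False)
        raise ValueError(f"no model classified ok; full table:\n{table}")
    ranked = sorted(ok, key=lambda e: (e.rmse_ext_2014, e.rmse_ext_2015, e.name))
    return ranked[0].name


def evaluate_models(
    specs: Sequence[RegressorSpec],
    X: pd.DataFrame,
    y_train: Sequence[float],
    y_2014: Sequence[float],
    y_2015: Sequence[float],
    prop_floor: float = PROP_FLOOR,
    cv_pred_spread_floor: float = SPREAD_FLOOR,
) -> tuple[list[ModelEvaluation], dict[str, FittedModel]]:
    """Fit every spec on the training outcome and score it against the
    training series and the two external single-year series (same covariates,
    later outcomes), mirroring the discrimination/validation table design."""
    y_train = np.asarray(y_train, dtype=float)
    evaluations, fitted = [], {}
    for spec in specs:
        model = fit(spec, X, y_train)
        pred = model.predict(X)
        r_tr = rmse(pred, y_train)
        r_14 = rmse(pred, y_2014)
        r_15 = rmse(pred, y_2015)
        mean_pred = float(np.mean(pred))
        spread = float(np.std(pred) / abs(mean_pred)) if mean_pred != 0 else np.inf
        ev = ModelEvaluation(
            name=spec.name,
            rmse_train=r_tr,
            rmse_ext_2014=r_14,
            rmse_ext_2015=r_15,
            proportionality_2014=proportionality(r_tr, r_14),
            proportionality_2015=proportionality(r_tr, r_15),
            pred_spread_cv=spread,
        )
        ev.fit_class = classify_fit(ev, prop_floor, cv_pred_spread_floor)
        evaluations.append(ev)
        fitted[spec.name] = model
    return evaluations, fitted


def calibration_data(
    model: FittedModel,
    X: pd.DataFrame,
    y: Sequence[float],
    grid_size: int = 256,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Observed/predicted pairs ordered by observed value, plus a kernel
    density estimate of the residuals on a fixed grid (integrates to ~1)."""
    y = np.asarray(y, dtype=float)
    pred = model.predict(X)
    order = np.argsort(y, kind="stable")
    pairs = pd.DataFrame({"observed": y[order], "predicted": pred[order]})
    resid = pred - y
    spread = resid.std()
    if spread < 1e-12:
        # degenerate residuals: a narrow Gaussian spike at the common value
        c = float(resid.mean())
        width = max(1e-6, abs(c) * 1e-3 + 1e-6)
        grid = np.linspace(c - 6 * width, c + 6 * width, grid_size)
        density = stats.norm.pdf(grid, loc=c, scale=width)
    else:
        lo, hi = resid.min(), resid.max()
        pad = 3 * spread
        grid = np.linspace(lo - pad, hi + pad, grid_size)
        density = stats.gaussian_kde(resid)(grid)
    return pairs, grid, density
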