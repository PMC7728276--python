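"""The Heart Health Care Index (HHCI).

The selected model's predicted mortality rate PMR_n is min-max scaled to
MR_adj in [0, 1] and complemented: I_n = 1 - MR_adj.  The municipality with
the highest predicted rate gets index 0 (highest risk) and the one with the
lowest predicted rate gets index 1 (lowest risk).  Municipal risk strata are
quantile classes of the index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .models import FittedModel
from .spatial import quantile_classes

__all__ = [
    "HHCIResult",
    "predicted_rates",
    "minmax_adjust",
    "index",
    "risk_strata",
    "compute_hhci",
]


@dataclass
class HHCIResult:
    ids: list[str]
    pmr: np.ndarray          # predicted rate per 100,000
    mr_adj: np.ndarray       # min-max-scaled predicted rate in [0, 1]
    index: np.ndarray        # I_n = 1 - mr_adj
    risk_stratum: np.ndarray  # quantile class, 0 = lowest index (highest risk)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "pmr": self.pmr,
                "mr_adj": self.mr_adj,
                "index": self.index,
                "stratum": self.risk_stratum,
            }
        )


def predicted_rates(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """One predicted mortality rate per municipality; for linear-family
    models this equals the weighted covariate sum plus intercept."""
    return model.predict(X)


def minmax_adjust(pmr: Sequence[float]) -> np.ndarray:
    """(PMR - min) / (max - min); constant input degenerates to all 0 (read
    as uniformly lowest relative risk) with a loud warning."""
    v = np.asarray(pmr, dtype=float)
    if v.size == 0:
        raise ValueError("empty prediction vector")
    if v.size < 2:
        raise ValueError("need at least two municipalities to scale")
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn(
            "all predicted rates identical; MR_adj set to 0 everywhere "
            "(index will be 1 everywhere)"
        )
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def index(mr_adj: Sequence[float]) -> np.ndarray:
    """I_n = 1 - MR_adj, elementwise; input must lie in [0, 1]."""
    v = np.asarray(mr_adj, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("MR_adj values must lie within [0, 1]")
    return 1.0 - v


def risk_strata(index_values: Sequence[float], k: int = 5) -> np.ndarray:
    """Quantile risk classes of the index (0 = lowest index / highest risk)."""
    return quantile_classes(index_values, k=k)


def compute_hhci(
    model: FittedModel,
    X: pd.DataFrame,
    ids: Sequence[str] | None = None,
    k: int = 5,
) -> HHCIResult:
    """Full index computation: predict, min-max adjust, complement, stratify."""
    pmr = predicted_rates(model, X)
    mr_adj = minmax_adjust(pmr)
    idx = index(mr_adj)
    strata = risk_strata(idx, k=k)
    if ids is None:
        ids = [str(i) for i in (X.index if X.index is not None else range(len(pmr)))]
    return HHCIResult(
        ids=list(ids), pmr=pmr, mr_adj=mr_adj, index=idx, risk_stratum=strata
    )
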