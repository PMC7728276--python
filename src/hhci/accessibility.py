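"""Two-step floating catchment area (2SFCA) accessibility, normalized to the
0-1 index scale.

Step 1 computes each provider's supply-to-demand ratio over the population
within a fixed travel-time catchment (binary, no distance decay); step 2 sums
those ratios over the providers reachable from each municipality.  The raw
score is then min-max normalized so 0 marks the poorest and 1 the ideal
accessibility in the study region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["AccessibilityResult", "two_step_fca", "accessibility_suite"]


@dataclass
class AccessibilityResult:
    a_raw: np.ndarray    # providers per person summed over reachable sites
    a_norm: np.ndarray   # min-max normalized to [0, 1]
    d0: float            # catchment threshold, minutes


def two_step_fca(
    populations: Sequence[float],
    capacities: Sequence[float],
    travel_times: np.ndarray,
    d0: float = 60.0,
) -> AccessibilityResult:
    """Binary-catchment 2SFCA scores.

    ``travel_times`` is municipalities x providers in minutes.  A provider
    whose catchment holds no population gets ratio 0 (with a warning); a
    municipality with no provider within ``d0`` scores 0.  Normalization is
    (A - min)/(max - min); if every raw score is equal the normalized score is
    all 1.0 (equal access read as ideal-relative) unless that constant is 0,
    in which case it stays all 0 — both degenerate cases warn.
    """
    P = np.asarray(populations, dtype=float)
    S = np.asarray(capacities, dtype=float)
    T = np.asarray(travel_times, dtype=float)
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    if np.any(P <= 0):
        raise ValueError("populations must be positive")
    if np.any(~np.isfinite(T)) or np.any(T < 0):
        raise ValueError("travel times must be finite and non-negative")
    if T.shape != (len(P), len(S)):
        raise ValueError(
            f"travel-time matrix shape {T.shape} does not match "
            f"{len(P)} municipalities x {len(S)} providers"
        )
    reach = T <= d0
    demand = P @ reach  # population within each provider's catchment
    empty = demand == 0
    if np.any(empty):
        warnings.warn(
            f"{int(empty.sum())} provider(s) with empty catchment get ratio 0"
        )
    R = np.zeros_like(S)
    np.divide(S, demand, out=R, where=~empty)
    a_raw = reach @ R

    lo, hi = a_raw.min(), a_raw.max()
    if hi == lo:
        if hi == 0.0:
            warnings.warn("no municipality reaches any provider; scores all 0")
            a_norm = np.zeros_like(a_raw)
        else:
            warnings.warn("all raw scores equal; normalized scores set to 1")
            a_norm = np.ones_like(a_raw)
    else:
        a_norm = (a_raw - lo) / (hi - lo)
    return AccessibilityResult(a_raw=a_raw, a_norm=a_norm, d0=float(d0))


def accessibility_suite(
    populations: Sequence[float],
    providers_by_type: Mapping[str, pd.DataFrame],
    travel_by_type: Mapping[str, np.ndarray | pd.DataFrame],
    d0: float = 60.0,
    index: pd.Index | None = None,
) -> pd.DataFrame:
    """One normalized accessibility column (``access_<type>``) per provider
    type, suitable for joining onto the covariate table."""
    if len(providers_by_type) == 0:
        raise ValueError("need at least one provider type")
    cols = {}
    for ptype, prov in providers_by_type.items():
        if ptype not in travel_by_type:
            raise KeyError(f"no travel-time matrix for provider type {ptype!r}")
        tt = travel_by_type[ptype]
        tt = tt.to_numpy() if isinstance(tt, pd.DataFrame) else np.asarray(tt)
        if len(prov) == 0:
            warnings.warn(f"provider type {ptype!r} has no sites; column all 0")
            cols[f"access_{ptype}"] = np.zeros(len(np.asarray(populations)))
            continue
        res = two_step_fca(
            populations, prov["capacity"].to_numpy(dtype=float), tt, d0=d0
        )
        cols[f"access_{ptype}"] = res.a_norm
    return pd.DataFrame(cols, index=index)
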