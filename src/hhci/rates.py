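"""Mortality rates per 100,000: crude, directly age-standardized, multi-year
averaged, and Empirical-Bayes smoothed.

The EB smoother is the Marshall (1991) *global* empirical Bayes estimator —
shrinkage of each small-area rate toward the global rate with a weight that
grows as the area's population shrinks.  Smoothed rates are always convex
combinations of the raw rate and the global rate.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import AGE_STRATA

__all__ = [
    "PER_100K",
    "crude_rate",
    "age_adjusted_rate",
    "period_mean_rate",
    "eb_smooth",
    "eb_smooth_rates",
    "outcome_series",
    "build_rate_table",
]

PER_100K = 100_000.0


def crude_rate(deaths: float, population: float) -> float:
    """Deaths per 100,000 person-years."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    if deaths < 0:
        raise ValueError(f"deaths must be non-negative, got {deaths}")
    return deaths / population * PER_100K


def age_adjusted_rate(
    stratum_deaths: Sequence[float],
    stratum_pops: Sequence[float],
    reference_weights: Sequence[float],
) -> float:
    """Directly standardized rate: sum_k w_k * (d_k / p_k) * 100000.

    A stratum with zero population and zero deaths contributes nothing (with a
    warning); zero population with positive deaths is an error.
    """
    d = np.asarray(stratum_deaths, dtype=float)
    p = np.asarray(stratum_pops, dtype=float)
    w = np.asarray(reference_weights, dtype=float)
    if not (d.shape == p.shape == w.shape):
        raise ValueError("strata of deaths, populations and weights must align")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError(f"reference weights must sum to 1, got {w.sum()}")
    empty = p == 0
    if np.any(empty & (d > 0)):
        raise ValueError("stratum with zero population but positive deaths")
    if np.any(empty):
        warnings.warn(
            "empty stratum (population 0, deaths 0) contributes 0 to the "
            "standardized rate"
        )
    rates = np.zeros_like(d)
    np.divide(d, p, out=rates, where=~empty)
    return float((w * rates).sum() * PER_100K)


def period_mean_rate(rates_by_year: Mapping[int, float], years: Iterable[int]) -> float:
    """Arithmetic mean of annual rates over an inclusive set of years."""
    years = list(years)
    missing = [y for y in years if y not in rates_by_year]
    if missing:
        raise KeyError(f"rates missing for year(s): {missing}")
    return float(np.mean([rates_by_year[y] for y in years]))


def eb_smooth(
    deaths: Sequence[float], populations: Sequence[float]
) -> np.ndarray:
    """Marshall global empirical Bayes smoothing of small-area rates.

    With raw rates r_i = d_i/p_i and global rate b = sum(d)/sum(p):

        s2  = sum_i p_i (r_i - b)^2 / sum_i p_i
        a   = max(0, s2 - b / mean(p))
        w_i = a / (a + b / p_i)
        theta_i = w_i r_i + (1 - w_i) b

    Returned on the per-100,000 scale.  w_i is non-decreasing in p_i, so small
    populations are shrunk hardest toward the global rate.
    """
    d = np.asarray(deaths, dtype=float)
    p = np.asarray(populations, dtype=float)
    if d.shape != p.shape:
        raise ValueError("deaths and populations must align")
    if np.any(p <= 0):
        raise ValueError("all populations must be positive")
    r = d / p
    b = d.sum() / p.sum()
    s2 = float((p * (r - b) ** 2).sum() / p.sum())
    a = max(0.0, s2 - b / p.mean())
    if a == 0.0:
        theta = np.full_like(r, b)
    else:
        w = a / (a + b / p)
        theta = w * r + (1.0 - w) * b
    return theta * PER_100K


def eb_smooth_rates(
    rates_per_100k: Sequence[float], populations: Sequence[float]
) -> np.ndarray:
    """EB-smooth rates that are not raw count ratios (e.g. age-adjusted or
    period-mean rates) by forming the implied pseudo-counts d_i = r_i * p_i."""
    r = np.asarray(rates_per_100k, dtype=float) / PER_100K
    p = np.asarray(populations, dtype=float)
    return eb_smooth(r * p, p)


# ---------------------------------------------------------------------------
# panel-level assembly


def _reference_weights(population: pd.DataFrame) -> np.ndarray:
    """Panel-wide age distribution used as the standardization reference."""
    totals = population[list(AGE_STRATA)].sum(axis=0).to_numpy(dtype=float)
    return totals / totals.sum()


def _annual_adjusted_rates(
    deaths: pd.DataFrame,
    population: pd.DataFrame,
    reference_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Age-adjusted rate per municipality (rows) and year (columns)."""
    if reference_weights is None:
        reference_weights = _reference_weights(population)
    wide = deaths.pivot_table(
        index="id", columns=["year", "age_stratum"], values="deaths", aggfunc="sum"
    ).reindex(population.index)
    years = sorted(deaths["year"].unique())
    pops = population[list(AGE_STRATA)].to_numpy(dtype=float)
    out = {}
    for year in years:
        counts = wide[year].reindex(columns=list(AGE_STRATA)).to_numpy(dtype=float)
        stratum_rates = np.zeros_like(counts)
        np.divide(counts, pops, out=stratum_rates, where=pops > 0)
        out[year] = stratum_rates @ reference_weights * PER_100K
    return pd.DataFrame(out, index=population.index)


def outcome_series(
    deaths: pd.DataFrame,
    population: pd.DataFrame,
    train_years: Sequence[int],
    year_2014: int,
    year_2015: int,
    reference_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """The three smoothed outcome series of the modelling design.

    ``train``: EB-smoothed mean age-adjusted rate over the training period
    (the learning outcome); ``y2014`` / ``y2015``: EB-smoothed single-year
    rates for the penultimate-year and final-year external validation analogs.
    """
    annual = _annual_adjusted_rates(deaths, population, reference_weights)
    for y in [*train_years, year_2014, year_2015]:
        if y not in annual.columns:
            raise KeyError(f"rates missing for year(s): [{y}]")
    adult_pop = population[list(AGE_STRATA)].sum(axis=1).to_numpy(dtype=float)
    train_mean = annual[list(train_years)].mean(axis=1).to_numpy()
    return pd.DataFrame(
        {
            "train": eb_smooth_rates(train_mean, adult_pop),
            "y2014": eb_smooth_rates(annual[year_2014].to_numpy(), adult_pop),
            "y2015": eb_smooth_rates(annual[year_2015].to_numpy(), adult_pop),
        },
        index=population.index,
    )


def build_rate_table(
    deaths: pd.DataFrame,
    population: pd.DataFrame,
    years: tuple[int, int],
) -> pd.DataFrame:
    """Per-municipality crude, adjusted and smoothed rates for the training
    period plus the two external-validation years (long format).

    ``deaths`` is the long (id, year, age_stratum, deaths) table;
    ``population`` is indexed by id with one column per age stratum; ``years``
    is the inclusive year range whose final year is the hold-out analog.
    """
    y0, y1 = years
    train_years = list(range(y0, y1))  # all but the final year
    annual = _annual_adjusted_rates(deaths, population)
    adult_pop = population[list(AGE_STRATA)].sum(axis=1)
    total_deaths = deaths.pivot_table(
        index="id", columns="year", values="deaths", aggfunc="sum"
    ).reindex(population.index)

    periods = {
        "train": train_years,
        "y2014": [y1 - 1],
        "y2015": [y1],
    }
    rows = []
    for label, years in periods.items():
        crude = (
            total_deaths[years].mean(axis=1) / adult_pop * PER_100K
        ).to_numpy()
        adjusted = annual[years].mean(axis=1).to_numpy()
        smoothed = eb_smooth_rates(adjusted, adult_pop.to_numpy(dtype=float))
        rows.append(
            pd.DataFrame(
                {
                    "id": population.index,
                    "period": label,
                    "crude": crude,
                    "adjusted": adjusted,
                    "smoothed": smoothed,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
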