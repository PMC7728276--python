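"""Covariate pre-processing: identifier removal, near-zero-variance screening,
Pearson-correlation pruning and center/scale standardization.

The pipeline order is fixed: drop identifiers -> near-zero-variance screen ->
correlation prune (|r| >= 0.7) -> center/scale.  Correlation pruning follows
the findCorrelation-style rule: for the worst offending pair, drop the member
with the larger mean absolute correlation against everything else, recompute,
and repeat until no pair remains at or above the threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationReport",
    "Scaler",
    "drop_identifiers",
    "center_scale",
    "near_zero_variance",
    "correlation_prune",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass
class CorrelationReport:
    threshold: float
    pairs: list[tuple[str, str, float]]          # offending pairs at entry
    removed: list[tuple[str, float]]             # dropped name, mean |r| at drop
    retained: list[str]

    @property
    def removed_names(self) -> list[str]:
        return [name for name, _ in self.removed]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["var_a", "var_b", "r"])


@dataclass
class Scaler:
    """Column means/sds fitted once and applied unchanged to later data."""

    mean: pd.Series
    sd: pd.Series
    columns: list[str] = field(default_factory=list)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise KeyError(f"columns missing at transform time: {missing}")
        return (X[self.columns] - self.mean) / self.sd


def drop_identifiers(
    table: pd.DataFrame, id_columns: tuple[str, ...] = ("id", "name")
) -> pd.DataFrame:
    """Remove flagged identifier columns, leaving the covariate matrix."""
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate column names: {dupes}")
    missing = [c for c in id_columns if c not in table.columns]
    if missing and id_columns != ():
        raise KeyError(f"flagged identifier column(s) absent: {missing}")
    return table.drop(columns=list(id_columns))


def center_scale(X: pd.DataFrame) -> tuple[pd.DataFrame, Scaler]:
    """Standardize columns to mean 0, sample sd 1 (ddof=1)."""
    mean = X.mean()
    sd = X.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(
            f"zero-variance column(s) must be filtered before scaling: {zero}"
        )
    scaler = Scaler(mean=mean, sd=sd, columns=list(X.columns))
    return scaler.transform(X), scaler


def near_zero_variance(
    X: pd.DataFrame, freq_ratio_cut: float = 95 / 5, unique_frac_cut: float = 0.1
) -> list[str]:
    """Columns that are both dominated by one value (frequency ratio of the
    two most common values above ``freq_ratio_cut``) and nearly discrete
    (distinct-value fraction below ``unique_frac_cut``)."""
    if freq_ratio_cut <= 0 or unique_frac_cut <= 0:
        raise ValueError("thresholds must be positive")
    flagged = []
    n = len(X)
    for col in X.columns:
        counts = X[col].value_counts().to_numpy()
        ratio = np.inf if len(counts) < 2 else counts[0] / counts[1]
        unique_frac = len(counts) / n
        if ratio > freq_ratio_cut and unique_frac < unique_frac_cut:
            flagged.append(col)
    return flagged


def _mean_abs_corr(corr: pd.DataFrame) -> pd.Series:
    a = corr.abs()
    np.fill_diagonal(a.values, np.nan)
    return a.mean(axis=1)


def correlation_prune(
    X: pd.DataFrame, threshold: float = 0.7
) -> tuple[pd.DataFrame, CorrelationReport]:
    """Iteratively drop one member of each |r| >= threshold pair.

    At each step the worst (largest |r|) remaining pair is examined and the
    member with the larger mean absolute correlation against all other
    variables is dropped; ties go to the earlier column.  Deterministic given
    column order.
    """
    corr0 = X.corr()
    a0 = corr0.abs().to_numpy()
    iu = np.triu_indices_from(a0, k=1)
    cols = list(X.columns)
    pairs = [
        (cols[i], cols[j], float(corr0.iloc[i, j]))
        for i, j in zip(*iu)
        if a0[i, j] >= threshold
    ]

    kept = X.copy()
    removed: list[tuple[str, float]] = []
    while kept.shape[1] >= 2:
        corr = kept.corr()
        a = corr.abs().to_numpy()
        np.fill_diagonal(a, 0.0)
        if a.max() < threshold:
            break
        i, j = np.unravel_index(np.argmax(a), a.shape)
        i, j = min(i, j), max(i, j)
        mac = _mean_abs_corr(corr)
        ci, cj = kept.columns[i], kept.columns[j]
        # drop the larger mean-|r| member; tie -> the earlier column
        drop = cj if mac[cj] > mac[ci] else ci
        removed.append((drop, float(mac[drop])))
        log.info("correlation prune: dropping %s (mean |r| = %.3f)", drop, mac[drop])
        kept = kept.drop(columns=drop)
    report = CorrelationReport(
        threshold=threshold,
        pairs=pairs,
        removed=removed,
        retained=list(kept.columns),
    )
    return kept, report


def preprocess(
    table: pd.DataFrame,
    id_columns: tuple[str, ...] = ("id", "name"),
    corr_threshold: float = 0.7,
    freq_ratio_cut: float = 95 / 5,
    unique_frac_cut: float = 0.1,
) -> tuple[pd.DataFrame, CorrelationReport, Scaler, list[str]]:
    """Full pre-processing pipeline; returns the standardized feature matrix,
    the correlation report, the fitted scaler and the NZV-flagged columns."""
    X = drop_identifiers(table, id_columns)
    log.info("dropped identifiers: %d -> %d columns", table.shape[1], X.shape[1])
    nzv = near_zero_variance(X, freq_ratio_cut, unique_frac_cut)
    if nzv:
        warnings.warn(f"near-zero-variance column(s) removed: {nzv}")
        X = X.drop(columns=nzv)
    X, report = correlation_prune(X, corr_threshold)
    log.info(
        "correlation prune: removed %d, retained %d",
        len(report.removed),
        len(report.retained),
    )
    Xs, scaler = center_scale(X)
    return Xs, report, scaler, nzv
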