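"""Spatial weights, global Moran's I with permutation inference, LISA cluster
labelling, and quantile map classing.

Conventions follow the standard ESDA workflow: queen contiguity,
row-standardized weights, 999 permutations, pseudo p-values with the +1
correction (floor 1/(M+1) = 0.001 at the default M = 999).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse
from shapely import STRtree
from shapely.geometry.base import BaseGeometry

__all__ = [
    "SpatialWeights",
    "LisaResult",
    "queen_weights",
    "contiguity_pairs",
    "morans_i",
    "permutation_test",
    "local_moran",
    "quantile_classes",
]


@dataclass
class SpatialWeights:
    """Row-standardized contiguity weights over n spatial units."""

    n: int
    neighbors: list[np.ndarray]     # neighbor indices per unit
    weights: list[np.ndarray]       # row-standardized weights per unit

    @classmethod
    def from_pairs(cls, n: int, pairs: Sequence[tuple[int, int]]) -> "SpatialWeights":
        adj: list[list[int]] = [[] for _ in range(n)]
        for i, j in pairs:
            if i == j:
                raise ValueError("self-neighbor pair")
            adj[i].append(j)
            adj[j].append(i)
        neighbors = [np.array(sorted(a), dtype=int) for a in adj]
        isolated = [i for i, a in enumerate(neighbors) if len(a) == 0]
        if isolated:
            warnings.warn(
                f"{len(isolated)} isolated unit(s) kept with zero weight rows: "
                f"{isolated[:10]}"
            )
        weights = [
            np.full(len(a), 1.0 / len(a)) if len(a) else np.array([])
            for a in neighbors
        ]
        return cls(n=n, neighbors=neighbors, weights=weights)

    @property
    def s0(self) -> float:
        """Sum of all weights (= number of non-isolated rows after
        row-standardization)."""
        return float(sum(w.sum() for w in self.weights))

    def to_sparse(self) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for i, (nbrs, w) in enumerate(zip(self.neighbors, self.weights)):
            rows.extend([i] * len(nbrs))
            cols.extend(nbrs.tolist())
            vals.extend(w.tolist())
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def lag(self, x: np.ndarray) -> np.ndarray:
        return self.to_sparse() @ x

    def to_gal(self) -> str:
        """Serialize as a GAL neighbor-list file (0-based ids)."""
        lines = [str(self.n)]
        for i, nbrs in enumerate(self.neighbors):
            lines.append(f"{i} {len(nbrs)}")
            lines.append(" ".join(str(j) for j in nbrs))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_gal(cls, text: str) -> "SpatialWeights":
        tokens = text.split()
        n = int(tokens[0])
        pos = 1
        pairs = []
        for _ in range(n):
            i = int(tokens[pos])
            k = int(tokens[pos + 1])
            pos += 2
            for _ in range(k):
                j = int(tokens[pos])
                pos += 1
                if i < j:
                    pairs.append((i, j))
        return cls.from_pairs(n, pairs)


@dataclass
class LisaResult:
    """Local Moran statistics with conditional-permutation pseudo p-values and
    cluster labels (HH, LL, HL, LH, or NS below significance)."""

    local_i: np.ndarray
    pseudo_p: np.ndarray
    labels: np.ndarray  # dtype=object of {"HH","LL","HL","LH","NS"}


def contiguity_pairs(
    polygons: Sequence[BaseGeometry], criterion: str = "queen"
) -> list[tuple[int, int]]:
    """Contiguity pairs from polygon geometry.

    queen: any shared boundary point; rook: shared edge (positive-length
    intersection).  Uses an STR-tree to prefilter candidate pairs.
    """
    if criterion not in {"queen", "rook"}:
        raise ValueError(f"criterion must be 'queen' or 'rook', got {criterion!r}")
    if len(polygons) == 0:
        raise ValueError("no polygons")
    tree = STRtree(list(polygons))
    pairs = set()
    for i, poly in enumerate(polygons):
        for j in tree.query(poly):
            j = int(j)
            if j <= i:
                continue
            inter = poly.intersection(polygons[j])
            if inter.is_empty:
                continue
            if criterion == "queen" or inter.length > 0:
                pairs.add((i, j))
    return sorted(pairs)


def queen_weights(
    polygons: Sequence[BaseGeometry], criterion: str = "queen"
) -> SpatialWeights:
    """Row-standardized contiguity weights from polygons (queen by default)."""
    pairs = contiguity_pairs(polygons, criterion)
    return SpatialWeights.from_pairs(len(polygons), pairs)


def _check_x(x: np.ndarray, w: SpatialWeights) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != w.n:
        raise ValueError(f"x must be a length-{w.n} vector")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I is undefined for a constant vector")
    return x


def morans_i(x: Sequence[float], w: SpatialWeights) -> float:
    """Global Moran's I = (n/S0) * (z'Wz)/(z'z) with z = x - mean(x)."""
    x = _check_x(np.asarray(x, dtype=float), w)
    z = x - x.mean()
    num = float(z @ w.lag(z))
    return w.n / w.s0 * num / float(z @ z)


def permutation_test(
    x: Sequence[float],
    w: SpatialWeights,
    permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float, np.ndarray]:
    """Pseudo p-value for global Moran's I under random relabelling.

    p = (#{permuted I as or more extreme} + 1) / (permutations + 1); the
    attainable floor is 1/(permutations+1).  One-sided 'greater' (clustering)
    by default; 'less' and 'two-sided' available.  Returns (I_obs, p, I_perm).
    """
    if permutations < 1:
        raise ValueError("need at least one permutation")
    if alternative not in {"greater", "less", "two-sided"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = _check_x(np.asarray(x, dtype=float), w)
    obs = morans_i(x, w)
    rng = np.random.default_rng(seed)
    z = x - x.mean()
    zz = float(z @ z)
    W = w.to_sparse()
    scale = w.n / w.s0 / zz
    perms = np.empty(permutations)
    Z = np.empty((w.n, permutations))
    for m in range(permutations):
        Z[:, m] = rng.permutation(z)
    perms = scale * np.einsum("im,im->m", Z, W @ Z)
    if alternative == "greater":
        extreme = int((perms >= obs).sum())
    elif alternative == "less":
        extreme = int((perms <= obs).sum())
    else:
        mean_p = perms.mean()
        extreme = int((np.abs(perms - mean_p) >= abs(obs - mean_p)).sum())
    p = (extreme + 1) / (permutations + 1)
    return obs, p, perms


def local_moran(
    x: Sequence[float],
    w: SpatialWeights,
    permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> LisaResult:
    """Local Moran's I with conditional permutation inference.

    I_i = z_i * sum_j w_ij z_j with z standardized (population sd).  For each
    unit the observed value is held fixed while neighbor values are drawn as
    random subsets of the remaining n-1 observations; the pseudo p-value is
    the smaller tail with the +1 correction.  Labels are quadrants of
    (z_i, lag_i) gated by pseudo_p <= alpha.
    """
    x = _check_x(np.asarray(x, dtype=float), w)
    z = (x - x.mean()) / x.std()  # ddof=0 so mean(local) == global I
    lag = w.lag(z)
    local = z * lag

    rng = np.random.default_rng(seed)
    pseudo_p = np.ones(w.n)
    for i in range(w.n):
        k = len(w.neighbors[i])
        if k == 0:
            continue
        others = np.delete(z, i)
        # uniform k-subsets of the n-1 other values, one per permutation
        r = rng.random((permutations, len(others)))
        idx = np.argpartition(r, k - 1, axis=1)[:, :k]
        sim = z[i] * others[idx].mean(axis=1)
        larger = int((sim >= local[i]).sum())
        smaller = int((sim <= local[i]).sum())
        pseudo_p[i] = (min(larger, smaller) + 1) / (permutations + 1)

    labels = np.empty(w.n, dtype=object)
    labels[:] = "NS"
    sig = pseudo_p <= alpha
    hh = sig & (z > 0) & (lag > 0)
    ll = sig & (z < 0) & (lag < 0)
    hl = sig & (z > 0) & (lag < 0)
    lh = sig & (z < 0) & (lag > 0)
    labels[hh], labels[ll], labels[hl], labels[lh] = "HH", "LL", "HL", "LH"
    return LisaResult(local_i=local, pseudo_p=pseudo_p, labels=labels)


def quantile_classes(values: Sequence[float], k: int = 5) -> np.ndarray:
    """Class index (0..k-1) per unit by empirical quantiles.

    Units are ranked with a stable sort (ties broken by original order) and
    split into k classes of near-equal size.  If fewer than k distinct values
    exist the classes collapse (with a warning); all-equal input yields a
    single class.
    """
    v = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(v)
    if n == 0:
        raise ValueError("empty input")
    distinct = len(np.unique(v))
    if distinct < k:
        warnings.warn(
            f"only {distinct} distinct value(s) for k={k} classes; collapsing"
        )
        uniq = np.unique(v)
        # class boundaries on the distinct values themselves
        edges = np.quantile(uniq, np.linspace(0, 1, min(k, distinct) + 1)[1:-1])
        return np.searchsorted(edges, v, side="left").astype(int)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * k // n).astype(int)
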