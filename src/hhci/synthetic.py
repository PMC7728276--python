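"""Synthetic municipality panels with the statistical structure of a state-level
ischemic-heart-disease mortality study.

The generator emulates a contiguous map of ~399 municipalities, 35 municipal
covariates (socioeconomic, demographic, health-management and health-coverage
strata, including engineered collinear pairs), heterogeneous populations,
seven annual death-count series driven by a spatially autocorrelated latent
risk field, and provider sites inducing a 0-1 accessibility gradient.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "SyntheticConfig",
    "SyntheticPanel",
    "AGE_STRATA",
    "COVARIATE_NAMES",
    "COLLINEAR_PAIRS",
    "DEFAULT_BETA",
    "generate_geography",
    "generate_covariates",
    "generate_population",
    "generate_mortality",
    "generate_providers",
    "generate_panel",
]

# Six age decades, 20-79, matching the study population.
AGE_STRATA = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79")

# Share of the adult (20-79) population in each decade, and the relative
# ischemic mortality risk of that decade.  Risk is normalized at build time so
# the population-weighted mean relative risk is 1 and the configured base rate
# is the crude adult rate.
_AGE_SHARES = np.array([0.24, 0.21, 0.19, 0.16, 0.12, 0.08])
_AGE_RELRISK_RAW = np.array([0.05, 0.15, 0.6, 1.8, 4.5, 10.0])
_AGE_RELRISK = _AGE_RELRISK_RAW / float(_AGE_SHARES @ _AGE_RELRISK_RAW)

_SOCIOECONOMIC = [
    "gdp",
    "mhdi",
    "child_study_expectancy",
    "illiteracy_rate",
    "elementary_school_pct",
    "gini",
    "income_per_capita",
    "employed_population",
    "informal_employment_rate",
    "unemployment_rate",
    "income_ratio",
    "low_income_pct",
    "aging_rate",
    "demographic_density",
    "urbanization_degree",
]
_MANAGEMENT = ["management_stratum"]  # ordinal, seven strata
_COVERAGE = [
    "family_health_coverage",
    "diabetic_consult_rate",
    "hypertensive_consult_rate",
    "cardiac_catheterization_rate",
    "myocardial_scintigraphy_rate",
    "echocardiography_rate",
    "ihd_morbidity_rate",
    "cardiologists_rate",
    "hemodynamic_labs_rate",
    "ambulances_basic",
    "ambulances_advanced",
]
_ACCESS = [
    "access_cardiologists",
    "access_hemodynamics",
    "access_ambulances_basic",
    "access_ambulances_advanced",
    "access_catheterization",
    "access_scintigraphy",
    "access_echocardiography",
    "access_emergency",
]

#: The 35 covariate columns of the canonical panel, in schema order.
COVARIATE_NAMES: tuple[str, ...] = tuple(
    _SOCIOECONOMIC + _MANAGEMENT + _COVERAGE + _ACCESS
)

#: Engineered near-duplicate covariate pairs (base, twin, sign).  The twin is
#: rebuilt as an affine copy of the base plus small noise so that |r| >= 0.7.
#: Pairs deliberately avoid every covariate carrying a planted effect, so that
#: correlation pruning cannot silently remove a signal column.
COLLINEAR_PAIRS: tuple[tuple[str, str, int], ...] = (
    ("income_per_capita", "mhdi", 1),
    ("elementary_school_pct", "child_study_expectancy", 1),
    ("demographic_density", "urbanization_degree", 1),
    ("low_income_pct", "income_ratio", 1),
    ("cardiologists_rate", "access_cardiologists", 1),
    ("employed_population", "unemployment_rate", -1),
    ("cardiac_catheterization_rate", "echocardiography_rate", 1),
)

#: Signed effects on the latent log mortality rate; signs follow the reported
#: top positive (aging rate, illiteracy, family-health coverage, diabetic
#: consultations, morbidity) and top negative (advanced/basic ambulances, GINI,
#: hemodynamics access, scintigraphy) covariates of the source study design.
DEFAULT_BETA: dict[str, float] = {
    "aging_rate": 0.27,
    "illiteracy_rate": 0.19,
    "family_health_coverage": 0.11,
    "diabetic_consult_rate": 0.11,
    "ihd_morbidity_rate": 0.08,
    "ambulances_advanced": -0.21,
    "gini": -0.16,
    "access_hemodynamics": -0.16,
    "myocardial_scintigraphy_rate": -0.11,
    "ambulances_basic": -0.11,
}

#: Provider categories generated for the accessibility covariates.  These map
#: onto ``access_<type>`` columns that are NOT engineered collinear twins, so
#: replacing them with computed 2SFCA scores leaves the planted correlation
#: structure intact.
PROVIDER_TYPES: tuple[str, ...] = ("hemodynamics", "ambulances_basic", "emergency")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study region.

    Defaults reproduce the canonical panel: a 20x20 lattice with one cell
    removed (399 municipalities), moderate spatial autocorrelation in the
    latent risk field, seven engineered collinear covariate pairs, and the
    2009-2015 annual death series.
    """

    n_rows: int = 20
    n_cols: int = 20
    n_drop: int = 1
    rho: float = 0.6
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    n_duplicate_pairs: int = 7
    n_providers: int = 10
    speed_kmh: float = 40.0
    cell_km: float = 15.0
    years: tuple[int, int] = (2009, 2015)
    seed: int = 0
    # Noise / scale conventions (see docs/methods.md)
    base_rate_per_100k: float = 130.0
    sigma_spatial: float = 0.25
    year_noise_sd: float = 0.08
    pop_median: float = 6000.0
    pop_sigma: float = 1.1
    travel_noise_sd: float = 3.0
    drop_cells: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        n_cells = self.n_rows * self.n_cols
        if n_cells - self.n_drop < 2:
            raise ValueError(
                f"lattice too small: {n_cells} cells minus {self.n_drop} drops < 2"
            )
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        y0, y1 = self.years
        if y1 - y0 + 1 < 3:
            raise ValueError(
                "year range must span >= 3 years (training / penultimate-year / "
                f"final-year splits), got {self.years}"
            )
        if self.n_duplicate_pairs < 0 or self.n_duplicate_pairs > len(COLLINEAR_PAIRS):
            raise ValueError(
                f"n_duplicate_pairs must be in [0, {len(COLLINEAR_PAIRS)}]"
            )
        unknown = set(self.beta) - set(COVARIATE_NAMES)
        if unknown:
            raise ValueError(f"beta refers to unknown covariates: {sorted(unknown)}")

    @property
    def n_municipalities(self) -> int:
        return self.n_rows * self.n_cols - self.n_drop

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class SyntheticPanel:
    """A fully generated study region (the in-memory analogue of the CSV set)."""

    config: SyntheticConfig
    ids: list[str]
    names: list[str]
    polygons: list[Polygon]
    contiguity: list[tuple[int, int]]
    covariates: pd.DataFrame          # index = ids, 35 columns
    population: pd.DataFrame          # index = ids, one column per age stratum
    deaths: pd.DataFrame              # long: id, year, age_stratum, deaths
    true_log_rate: pd.Series          # latent log adult rate, index = ids
    providers: dict[str, pd.DataFrame]     # type -> (id, x, y, capacity)
    travel_times: dict[str, pd.DataFrame]  # type -> municipality x provider matrix

    @property
    def table(self) -> pd.DataFrame:
        """Canonical 37-column table: two identifier columns + 35 covariates."""
        out = pd.DataFrame({"id": self.ids, "name": self.names})
        out = pd.concat([out, self.covariates.reset_index(drop=True)], axis=1)
        return out


# ---------------------------------------------------------------------------
# geography


def _queen_pairs(cells: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    index = {cell: i for i, cell in enumerate(cells)}
    pairs = []
    for (r, c), i in index.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and i < j:
                    pairs.append((i, j))
    return pairs


def _connected_components(n: int, pairs: Sequence[tuple[int, int]]) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        adj[i].append(j)
        adj[j].append(i)
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(comp)
    return comps


def generate_geography(
    cfg: SyntheticConfig,
) -> tuple[list[Polygon], list[tuple[int, int]]]:
    """Unit-square lattice polygons plus queen-contiguity pairs.

    Cells are laid out row-major on an ``n_rows x n_cols`` grid; ``n_drop``
    cells are removed (by default the trailing row-major cells, which keeps the
    lattice connected; an explicit ``drop_cells`` list may be supplied).
    Raises ``ValueError`` with component sizes if the retained lattice is
    disconnected.
    """
    all_cells = [(r, c) for r in range(cfg.n_rows) for c in range(cfg.n_cols)]
    if cfg.drop_cells is not None:
        dropped = set(cfg.drop_cells)
        if len(dropped) != cfg.n_drop:
            raise ValueError(
                f"drop_cells lists {len(dropped)} cells but n_drop={cfg.n_drop}"
            )
    else:
        dropped = set(range(len(all_cells) - cfg.n_drop, len(all_cells)))
    cells = [cell for k, cell in enumerate(all_cells) if k not in dropped]
    pairs = _queen_pairs(cells)
    comps = _connected_components(len(cells), pairs)
    if len(comps) > 1:
        sizes = sorted((len(c) for c in comps), reverse=True)
        raise ValueError(
            f"lattice is disconnected after drops: component sizes {sizes}"
        )
    polygons = [
        Polygon([(c, r), (c + 1, r), (c + 1, r + 1), (c, r + 1)]) for r, c in cells
    ]
    return polygons, pairs


# ---------------------------------------------------------------------------
# covariates

# marginal sampler family per column: (kind, params)
_MARGINALS: dict[str, tuple[str, tuple[float, ...]]] = {
    "gdp": ("lognormal", (10.0, 1.0)),
    "mhdi": ("normal", (0.70, 0.05)),
    "child_study_expectancy": ("normal", (10.0, 1.2)),
    "illiteracy_rate": ("gamma", (4.0, 2.0)),
    "elementary_school_pct": ("normal", (45.0, 10.0)),
    "gini": ("normal", (0.48, 0.05)),
    "income_per_capita": ("lognormal", (6.4, 0.35)),
    "employed_population": ("lognormal", (8.0, 1.0)),
    "informal_employment_rate": ("normal", (30.0, 8.0)),
    "unemployment_rate": ("gamma", (6.0, 1.0)),
    "income_ratio": ("gamma", (5.0, 2.0)),
    "low_income_pct": ("normal", (20.0, 7.0)),
    "aging_rate": ("normal", (8.0, 2.5)),
    "demographic_density": ("lognormal", (3.3, 1.2)),
    "urbanization_degree": ("normal", (75.0, 15.0)),
    "family_health_coverage": ("normal", (80.0, 18.0)),
    "diabetic_consult_rate": ("gamma", (5.0, 30.0)),
    "hypertensive_consult_rate": ("gamma", (5.0, 60.0)),
    "cardiac_catheterization_rate": ("gamma", (2.0, 5.0)),
    "myocardial_scintigraphy_rate": ("gamma", (2.0, 3.0)),
    "echocardiography_rate": ("gamma", (3.0, 8.0)),
    "ihd_morbidity_rate": ("gamma", (6.0, 40.0)),
    "cardiologists_rate": ("gamma", (1.5, 2.0)),
    "hemodynamic_labs_rate": ("gamma", (1.2, 0.5)),
    "ambulances_basic": ("gamma", (3.0, 1.0)),
    "ambulances_advanced": ("gamma", (1.5, 0.8)),
}


def _draw_column(name: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if name == "management_stratum":
        return rng.integers(1, 8, size=n).astype(float)
    if name in _ACCESS:
        return rng.beta(2.0, 2.0, size=n)
    kind, params = _MARGINALS[name]
    if kind == "normal":
        mu, sd = params
        return rng.normal(mu, sd, size=n)
    if kind == "lognormal":
        mu, sd = params
        return rng.lognormal(mu, sd, size=n)
    if kind == "gamma":
        shape, scale = params
        return rng.gamma(shape, scale, size=n)
    raise AssertionError(name)


def generate_covariates(
    cfg: SyntheticConfig, n: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """35 named covariate columns spanning the socioeconomic, demographic,
    management and coverage strata.

    The first ``cfg.n_duplicate_pairs`` of :data:`COLLINEAR_PAIRS` are rebuilt
    as affine copies of their base column plus small noise (|r| >= 0.7); the
    remaining columns are independent draws from plausible marginals.  The
    ``management_stratum`` column is ordinal with seven levels.
    """
    if n < 2:
        raise ValueError(f"need at least 2 municipalities, got {n}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    data = {name: _draw_column(name, n, rng) for name in COVARIATE_NAMES}
    for base, twin, sign in COLLINEAR_PAIRS[: cfg.n_duplicate_pairs]:
        b = data[base]
        t = data[twin]
        b_std = (b - b.mean()) / b.std()
        # preserve the twin's natural scale; 0.3 noise-to-signal ratio gives
        # |r| ~ 0.96, comfortably above the 0.7 screening threshold
        data[twin] = t.mean() + t.std() * (
            sign * b_std + rng.normal(0.0, 0.3, size=n)
        ) / math.sqrt(1.09)
    return pd.DataFrame(data, columns=list(COVARIATE_NAMES))


# ---------------------------------------------------------------------------
# population and mortality


def generate_population(
    cfg: SyntheticConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Adult (20-79) population by age decade; totals are log-normal so EB
    shrinkage is visibly population-dependent across ~3 orders of magnitude."""
    totals = rng.lognormal(math.log(cfg.pop_median), cfg.pop_sigma, size=n)
    shares = _AGE_SHARES * rng.lognormal(0.0, 0.1, size=(n, len(AGE_STRATA)))
    shares /= shares.sum(axis=1, keepdims=True)
    pops = np.maximum(1, np.rint(totals[:, None] * shares)).astype(int)
    return pd.DataFrame(pops, columns=list(AGE_STRATA))


def sar_field(
    pairs: Sequence[tuple[int, int]],
    n: int,
    rho: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simultaneous-autoregressive latent field: solves s = rho*W*s + e with W
    the row-standardized contiguity matrix and e ~ N(0, sigma^2) iid."""
    W = np.zeros((n, n))
    for i, j in pairs:
        W[i, j] = 1.0
        W[j, i] = 1.0
    rowsum = W.sum(axis=1, keepdims=True)
    np.divide(W, rowsum, out=W, where=rowsum > 0)
    e = rng.normal(0.0, sigma, size=n)
    A = np.eye(n) - rho * W
    try:
        return np.linalg.solve(A, e)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rho<1 guards this
        raise ValueError(f"(I - rho W) is singular for rho={rho}") from exc


def generate_mortality(
    cfg: SyntheticConfig,
    covariates: pd.DataFrame,
    contiguity: Sequence[tuple[int, int]],
    population: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Annual death counts by municipality, year and age stratum.

    The latent adult log-rate is ``log(base_rate) + beta . x_std + s`` where
    ``s`` is a SAR field with coefficient ``rho``.  Stratum-year counts are
    Poisson with expectation population x rate x age-relative-risk x
    log-normal year noise, truncated at the stratum population.  Returns the
    long deaths table and the latent log-rate vector (the planted truth used
    by parameter-recovery tests).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(covariates)
    s = sar_field(contiguity, n, cfg.rho, cfg.sigma_spatial, rng)
    lin = np.zeros(n)
    for name, b in cfg.beta.items():
        x = covariates[name].to_numpy(dtype=float)
        lin += b * (x - x.mean()) / x.std()
    log_rate = math.log(cfg.base_rate_per_100k / 1e5) + lin + s
    rate = np.exp(log_rate)

    years = cfg.year_list
    pops = population[list(AGE_STRATA)].to_numpy()
    records = []
    for year in years:
        year_noise = rng.lognormal(0.0, cfg.year_noise_sd, size=n)
        lam = pops * (rate * year_noise)[:, None] * _AGE_RELRISK[None, :]
        counts = np.minimum(rng.poisson(lam), pops)
        for k, stratum in enumerate(AGE_STRATA):
            records.append(
                pd.DataFrame(
                    {
                        "row": np.arange(n),
                        "year": year,
                        "age_stratum": stratum,
                        "deaths": counts[:, k],
                    }
                )
            )
    deaths = pd.concat(records, ignore_index=True)
    return deaths, log_rate


# ---------------------------------------------------------------------------
# providers and travel times


def generate_providers(
    cfg: SyntheticConfig,
    polygons: Sequence[Polygon],
    rng: np.random.Generator | None = None,
    n_providers: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Provider sites at random cell centroids plus a municipality x provider
    travel-time matrix (minutes).

    Times are Euclidean centroid distance (lattice units scaled by
    ``cell_km``) over ``speed_kmh`` plus non-negative noise.  With the default
    sparse provider layout some municipalities fall beyond 60 minutes of every
    site, exercising the zero-accessibility branch downstream.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    m = n_providers if n_providers is not None else cfg.n_providers
    if m < 1:
        raise ValueError("need at least one provider")
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polygons])
    sites = rng.choice(len(polygons), size=min(m, len(polygons)), replace=False)
    capacity = rng.poisson(20, size=len(sites)) + 1
    providers = pd.DataFrame(
        {
            "id": [f"P{k:02d}" for k in range(len(sites))],
            "x": centroids[sites, 0],
            "y": centroids[sites, 1],
            "capacity": capacity,
        }
    )
    d = np.hypot(
        centroids[:, [0]] - centroids[sites, 0][None, :],
        centroids[:, [1]] - centroids[sites, 1][None, :],
    )
    minutes = d * cfg.cell_km / cfg.speed_kmh * 60.0
    minutes = minutes + np.abs(rng.normal(0.0, cfg.travel_noise_sd, size=minutes.shape))
    tt = pd.DataFrame(minutes, columns=providers["id"].tolist())
    return providers, tt


# ---------------------------------------------------------------------------
# full panel


def generate_panel(cfg: SyntheticConfig | None = None) -> SyntheticPanel:
    """Generate the complete synthetic study region from one seed.

    Order of construction is fixed (geography, covariates, providers and
    2SFCA-derived accessibility covariates, population, mortality) so that a
    given seed yields a byte-identical panel.
    """
    from .accessibility import two_step_fca  # local import: avoid cycle

    if cfg is None:
        cfg = SyntheticConfig()
    if cfg.n_municipalities < 10:
        raise ValueError(
            f"a full panel needs >= 10 municipalities, got {cfg.n_municipalities}"
        )
    rng = np.random.default_rng(cfg.seed)
    polygons, pairs = generate_geography(cfg)
    n = len(polygons)
    ids = [f"M{k:03d}" for k in range(n)]
    names = [f"Municipality {k:03d}" for k in range(n)]

    covariates = generate_covariates(cfg, n, rng)
    population = generate_population(cfg, n, rng)

    providers: dict[str, pd.DataFrame] = {}
    travel: dict[str, pd.DataFrame] = {}
    adult_pop = population.sum(axis=1).to_numpy(dtype=float)
    for ptype in PROVIDER_TYPES:
        prov, tt = generate_providers(cfg, polygons, rng)
        providers[ptype] = prov
        travel[ptype] = tt
        colname = f"access_{ptype}"
        if colname in covariates.columns:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = two_step_fca(
                    adult_pop,
                    prov["capacity"].to_numpy(dtype=float),
                    tt.to_numpy(),
                    d0=60.0,
                )
            covariates[colname] = res.a_norm

    deaths, log_rate = generate_mortality(cfg, covariates, pairs, population, rng)
    deaths = deaths.assign(id=[ids[r] for r in deaths["row"]]).drop(columns="row")
    deaths = deaths[["id", "year", "age_stratum", "deaths"]]

    covariates.index = pd.Index(ids, name="id")
    population.index = pd.Index(ids, name="id")
    for ptype in PROVIDER_TYPES:
        travel[ptype].index = pd.Index(ids, name="id")

    return SyntheticPanel(
        config=cfg,
        ids=ids,
        names=names,
        polygons=polygons,
        contiguity=pairs,
        covariates=covariates,
        population=population,
        deaths=deaths,
        true_log_rate=pd.Series(log_rate, index=ids, name="true_log_rate"),
        providers=providers,
        travel_times=travel,
    )
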