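"""Community indicators: thermal affinity, life-history composition,
functional-group biomass, the regional hydroclimatic composite, and
autocorrelation-aware trend tests.

Weights follow two distinct conventions, both tied to how each indicator
is defined:

- community-weighted means (CWMT, life-history contributions) weight each
  species by its raw log(biomass + 1) in that year, W_{s,i};
- group biomass series z-score each member's log(biomass + 1) series over
  years before averaging, so every species counts equally regardless of
  its mean biomass.

Trends are tested by generalized least squares with AR(1)-correlated
errors (corAR1): rho is profiled out by maximum likelihood and the slope
gets a two-sided t-test on n - 2 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ordination import BiomassMatrix, log_transform

__all__ = [
    "TraitTable",
    "IndicatorSeries",
    "cwmt",
    "life_history_means",
    "group_mean_standardized",
    "compute_rhi",
    "gls_trend",
    "TrendFit",
]

STRATEGIES = ("opportunistic", "periodic", "equilibrium")
RHI_VARIABLES = ("air_temperature", "sst", "sea_level_pressure",
                 "geopotential_500", "precipitation")

TRAIT_COLUMNS = [
    "species", "opportunistic", "periodic", "equilibrium",
    "tpref", "taxon", "habitat", "commercial",
]


@dataclass(frozen=True)
class TraitTable:
    """Per-species traits: life-history proportions (summing to 1 for
    fish), preferred temperature (deg C), taxon, habitat, commercial flag."""

    data: pd.DataFrame  # indexed by species

    def __post_init__(self):
        missing = [c for c in TRAIT_COLUMNS[1:] if c not in self.data.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        fish = self.data[self.data["taxon"] == "fish"]
        if len(fish):
            sums = fish[list(STRATEGIES)].sum(axis=1)
            bad = fish.index[np.abs(sums - 1.0) > 1e-9].tolist()
            if bad:
                raise ValueError(f"life-history proportions do not sum to 1: {bad}")
        if not np.isfinite(self.data["tpref"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite preferred temperatures")

    @property
    def species(self) -> list:
        return list(self.data.index)

    def subset(self, taxon=None, habitat=None, commercial=None) -> list:
        """Species names matching the given predicates."""
        m = pd.Series(True, index=self.data.index)
        if taxon is not None:
            m &= self.data["taxon"] == taxon
        if habitat is not None:
            m &= self.data["habitat"] == habitat
        if commercial is not None:
            m &= self.data["commercial"] == bool(commercial)
        return list(self.data.index[m])


@dataclass
class IndicatorSeries:
    """A yearly indicator with an optional AR(1)-GLS trend fit attached."""

    name: str
    values: pd.Series
    trend: "TrendFit | None" = None
    flags: list | None = None

    def with_trend(self) -> "IndicatorSeries":
        self.trend = gls_trend(self.values.dropna())
        return self

    @property
    def significant(self) -> bool:
        return self.trend is not None and self.trend.p_value < 0.05


def _weights(matrix: BiomassMatrix, species: list) -> pd.DataFrame:
    missing = [s for s in species if s not in matrix.data.columns]
    if missing:
        raise KeyError(f"species not in biomass matrix: {missing}")
    return pd.DataFrame(
        log_transform(matrix.data.loc[:, species].to_numpy(dtype=float)),
        index=matrix.data.index, columns=species,
    )


def cwmt(matrix: BiomassMatrix, traits: TraitTable, subset: list | None = None,
         name: str = "cwmt") -> IndicatorSeries:
    """Community-weighted mean temperature:
    CWMT_i = sum_s Tpref_s * W_{s,i} / sum_s W_{s,i}, W = log(biomass + 1).

    Years where every weight is zero get a missing value and a flag.
    """
    species = subset if subset is not None else [
        s for s in traits.species if s in matrix.data.columns
    ]
    if not species:
        raise ValueError("empty species subset")
    W = _weights(matrix, species)
    tpref = traits.data.loc[species, "tpref"].to_numpy(dtype=float)
    num = W.to_numpy() @ tpref
    den = W.to_numpy().sum(axis=1)
    vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    flags = [f"all-zero weights in year {y}"
             for y, d in zip(W.index, den) if d == 0]
    return IndicatorSeries(name, pd.Series(vals, index=W.index, name=name), flags=flags or None)


def life_history_means(matrix: BiomassMatrix, traits: TraitTable,
                       fish_only: bool = True) -> dict[str, IndicatorSeries]:
    """Log-biomass-weighted mean of each life-history strategy proportion.

    Because each species' three proportions sum to 1, the three yearly
    outputs sum to 1 wherever any weight is positive.
    """
    species = traits.subset(taxon="fish") if fish_only else traits.species
    species = [s for s in species if s in matrix.data.columns]
    if not species:
        raise ValueError("empty fish subset")
    W = _weights(matrix, species)
    den = W.to_numpy().sum(axis=1)
    out = {}
    for strat in STRATEGIES:
        p = traits.data.loc[species, strat].to_numpy(dtype=float)
        num = W.to_numpy() @ p
        vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        out[strat] = IndicatorSeries(strat, pd.Series(vals, index=W.index, name=strat))
    return out


def group_mean_standardized(matrix: BiomassMatrix, members: list,
                            name: str = "group") -> IndicatorSeries:
    """Average of per-species z-scored log(biomass + 1) series.

    Species whose log series is constant carry no information about change
    and are excluded with a warning.
    """
    if not members:
        raise ValueError("empty group")
    W = _weights(matrix, members)
    sd = W.std(axis=0, ddof=1)
    flat = sd.index[sd < 1e-12].tolist()  # exact-0 variance rounds to ~1e-16
    if flat:
        warnings.warn(f"constant member series excluded from {name!r}: {flat}")
        W = W.drop(columns=flat)
        if W.shape[1] == 0:
            raise ValueError(f"all members of {name!r} are constant")
        sd = sd.drop(flat)
    Z = (W - W.mean(axis=0)) / sd
    vals = Z.mean(axis=1)
    return IndicatorSeries(name, pd.Series(vals, index=W.index, name=name),
                           flags=[f"excluded constant member {s}" for s in flat] or None)


def compute_rhi(anomalies: pd.DataFrame, name: str = "rhi") -> IndicatorSeries:
    """Regional Hydroclimatic Index: PC1 of five standardized anomaly series
    (air temperature, SST, sea-level pressure, 500 hPa geopotential height,
    precipitation rate) on a common time axis.

    The component sign is anchored so the sea-level-pressure loading is
    positive: high RHI goes with high atmospheric pressure.
    """
    missing = [v for v in RHI_VARIABLES if v not in anomalies.columns]
    if missing:
        raise ValueError(f"missing RHI input variables: {missing}")
    X = anomalies[list(RHI_VARIABLES)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in RHI inputs")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant RHI input series")
    Z = (X - mu) / sd
    n = Z.shape[0]
    corr = Z.T @ Z / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    v1 = eigvecs[:, -1]
    slp = list(RHI_VARIABLES).index("sea_level_pressure")
    if v1[slp] < 0:
        v1 = -v1
    scores = Z @ v1
    series = pd.Series(scores, index=anomalies.index, name=name)
    out = IndicatorSeries(name, series)
    out.explained_fraction = float(eigvals[-1] / eigvals.sum())
    out.loadings = pd.Series(v1, index=list(RHI_VARIABLES))
    return out


# ---------------------------------------------------------------------------
# AR(1)-GLS trend test


@dataclass
class TrendFit:
    slope: float
    intercept: float
    p_value: float
    rho: float
    stderr: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def summary(self) -> str:
        star = "*" if self.significant else ""
        return (f"slope={self.slope:.4g}/yr (SE {self.stderr:.3g}), "
                f"p={self.p_value:.3g}{star}, AR(1) rho={self.rho:.2f}, n={self.n}")


def _gls_profile(y: np.ndarray, X: np.ndarray, rho: float):
    """Prais–Winsten transform GLS for fixed rho; returns (beta, rss, XtX_inv)."""
    n = y.size
    c = np.sqrt(1.0 - rho**2)
    ys = np.empty(n)
    Xs = np.empty_like(X)
    ys[0] = c * y[0]
    Xs[0] = c * X[0]
    ys[1:] = y[1:] - rho * y[:-1]
    Xs[1:] = X[1:] - rho * X[:-1]
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    rss = float(resid @ resid)
    XtX_inv = np.linalg.inv(Xs.T @ Xs)
    return beta, rss, XtX_inv


def gls_trend(series: pd.Series, rho: float | None = None,
              method: str = "reml") -> TrendFit:
    """Linear trend (value ~ year) with AR(1)-correlated errors.

    rho is profiled out over (-0.95, 0.95) by restricted maximum
    likelihood (default, the convention of standard GLS trend software) or
    plain maximum likelihood (``method="ml"``), unless fixed explicitly
    (``rho=0`` reduces to OLS). The slope is tested two-sided against
    t(n - 2). Constant series return slope 0, p = 1. The test retains some
    small-sample anti-conservatism from estimating rho (see the methods
    note); REML keeps it materially smaller than ML at n ~ 26.
    """
    s = series.dropna()
    n = len(s)
    if n < 8:
        raise ValueError(f"need at least 8 values for a trend test, got {n}")
    years = np.asarray(s.index, dtype=float)
    y = s.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return TrendFit(0.0, float(y[0]), 1.0, 0.0, 0.0, n)
    X = np.column_stack([np.ones(n), years])
    p = X.shape[1]

    def negloglik(r: float) -> float:
        _, rss, _ = _gls_profile(y, X, r)
        if rss <= 0:
            return np.inf
        # -2 log (restricted) profile likelihood up to constants
        if method == "ml":
            return n * np.log(rss / n) - np.log(1.0 - r**2)
        _, _, XtX_inv = _gls_profile(y, X, r)
        sign, logdet = np.linalg.slogdet(np.linalg.inv(XtX_inv))
        return (n - p) * np.log(rss / (n - p)) - np.log(1.0 - r**2) + logdet

    if method not in ("ml", "reml"):
        raise ValueError(f"unknown method {method!r}")
    if rho is None:
        opt = optimize.minimize_scalar(negloglik, bounds=(-0.95, 0.95), method="bounded")
        rho = float(opt.x)
    beta, rss, XtX_inv = _gls_profile(y, X, float(rho))
    sigma2 = rss / (n - 2)
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    if se == 0:
        return TrendFit(float(beta[1]), float(beta[0]), 1.0, float(rho), 0.0, n)
    t = beta[1] / se
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return TrendFit(float(beta[1]), float(beta[0]), p, float(rho), se, n)
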