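"""Synthetic fold-bifurcation community generator.

Every pipeline stage needs data with known ground truth: a stressor series,
a latent community state that responds to the (lagged, standardized)
stressor through two linear attractor branches separated at a threshold
year (with hysteresis: once shifted, the regime is fixed by year, not by
the stressor returning to old values), a species biomass matrix whose
log-biomasses load linearly on that latent state, and a trait table with
life-history proportions on the simplex.

Default parameters mirror the study conditions the pipeline is built for:
26 survey years (1994–2019), a community of 100 well-sampled species with
sporadic catches (per-species yearly presence probability ~ Beta(8, 2)),
winter/spring chlorophyll, SST and hydroclimatic stressors as stationary
AR(1) series, a regime shift at the 16th year (2009) with a branch offset
of 2.0 state units against residual noise SD 0.35, and a 1-year stressor
lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .indicators import STRATEGIES, TraitTable
from .ordination import BiomassMatrix

__all__ = [
    "SyntheticTruth",
    "FoldSystem",
    "simulate_stressor",
    "simulate_fold_system",
    "simulate_community",
    "simulate_traits",
    "default_truth",
    "default_stressors",
    "simulate_dataset",
]

DEFAULT_YEARS = np.arange(1994, 2020)  # 26 survey years

#: default stressor climatologies: (mean, sd, AR(1) coefficient)
STRESSOR_CLIMATOLOGY = {
    ("chl", "winter"): (0.30, 0.06, 0.4),
    ("chl", "spring"): (0.45, 0.08, 0.4),
    ("sst", "winter"): (14.5, 0.45, 0.3),
    ("sst", "spring"): (17.0, 0.50, 0.3),
    ("rhi", "winter"): (0.0, 1.0, 0.3),
    ("rhi", "spring"): (0.0, 1.0, 0.3),
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of the latent fold-bifurcation system."""

    threshold_year: int = 2009
    regime1_attractor: tuple = (1.0, 0.8)  # (intercept, slope), standardized axes
    regime2_attractor: tuple = (-1.0, 0.8)
    lag: int = 1
    noise_sd: float = 0.35
    hysteresis: bool = True
    seed: int = 0
    years: tuple = tuple(int(y) for y in DEFAULT_YEARS)

    def __post_init__(self):
        ys = np.asarray(self.years)
        if not (ys[0] + 5 <= self.threshold_year <= ys[-1] - 4):
            raise ValueError("threshold_year must leave >= 5 years on each side")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.lag <= 2:
            raise ValueError("lag must be in {0, 1, 2}")

    @property
    def branch_offset(self) -> float:
        return abs(self.regime1_attractor[0] - self.regime2_attractor[0])


def simulate_stressor(
    n_years: int,
    mean: float,
    sd: float,
    ar1: float,
    seed: int,
    start_year: int = int(DEFAULT_YEARS[0]),
    name: str = "stressor",
) -> pd.Series:
    """Stationary AR(1) stressor series with given marginal mean/SD.

    x_t = mean + ar1 * (x_{t-1} - mean) + eps_t with
    eps ~ N(0, sd^2 * (1 - ar1^2)) and x_0 drawn from the stationary
    distribution, so the marginal SD is ``sd`` and the lag-1
    autocorrelation is ``ar1`` at every t.
    """
    if n_years < 10:
        raise ValueError("need n_years >= 10")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not abs(ar1) < 1:
        raise ValueError("|ar1| must be < 1 for stationarity")
    rng = np.random.default_rng(seed)
    innov_sd = sd * np.sqrt(1.0 - ar1**2)
    x = np.empty(n_years)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n_years - 1)
    for t in range(1, n_years):
        x[t] = ar1 * x[t - 1] + eps[t - 1]
    years = np.arange(start_year, start_year + n_years)
    return pd.Series(mean + x, index=pd.Index(years, name="year"), name=name)


@dataclass
class FoldSystem:
    """A simulated latent state trajectory plus its building blocks."""

    state: pd.Series  # yearly latent community state
    regimes: pd.Series  # 0 before threshold_year, 1 from it onward
    stressor_lagged: pd.Series  # standardized stressor at y - lag, indexed by y
    noise: pd.Series  # the exact Gaussian draws added per year
    truth: SyntheticTruth


def simulate_fold_system(stressor: pd.Series, truth: SyntheticTruth) -> FoldSystem:
    """Latent state on two linear attractor branches split at a year.

    Before the threshold year the state lies on the regime-1 line evaluated
    at the lagged standardized stressor (plus Gaussian noise); from the
    threshold year onward on the regime-2 line. With hysteresis the regime
    assignment depends only on the year — the state stays on branch 2 even
    when the stressor returns to pre-shift values. Without hysteresis the
    regime reverts to 1 whenever the lagged stressor exceeds its pre-shift
    mean.
    """
    years = np.asarray(truth.years)
    lagged_years = years - truth.lag
    missing = [int(y) for y in lagged_years if y not in stressor.index]
    if missing:
        raise ValueError(f"lagged stressor unavailable for years {missing}")
    raw = stressor.loc[lagged_years].to_numpy(dtype=float)
    xs = (raw - raw.mean()) / raw.std(ddof=1)

    rng = np.random.default_rng(truth.seed)
    noise = rng.normal(0.0, truth.noise_sd, size=years.size) if truth.noise_sd > 0 \
        else np.zeros(years.size)

    regime = (years >= truth.threshold_year).astype(int)
    if not truth.hysteresis:
        # state-dependent reversal: high driver pushes back to branch 1
        pre_mean = xs[years < truth.threshold_year].mean()
        regime = np.where((years >= truth.threshold_year) & (xs <= pre_mean), 1, 0)

    b1, b2 = truth.regime1_attractor, truth.regime2_attractor
    state = np.where(regime == 0, b1[0] + b1[1] * xs, b2[0] + b2[1] * xs) + noise

    idx = pd.Index(years, name="year")
    return FoldSystem(
        state=pd.Series(state, index=idx, name="state"),
        regimes=pd.Series(regime, index=idx, name="regime"),
        stressor_lagged=pd.Series(xs, index=idx, name="stressor_lagged"),
        noise=pd.Series(noise, index=idx, name="noise"),
        truth=truth,
    )


def simulate_community(
    latent_state: pd.Series,
    n_species: int = 100,
    loading_sd: float = 0.5,
    presence_profile=None,
    lognorm_sd: float = 0.2,
    seed: int = 0,
    area: str = "synthetic",
) -> tuple[BiomassMatrix, pd.DataFrame]:
    """Species biomass matrix loading on a latent state.

    Species i in year y has biomass exp(a_i + b_i * state_y + eps_iy) with
    eps ~ N(0, lognorm_sd^2), then zeroed with probability 1 - presence_i
    independently per year ("sporadically caught" species). Baselines
    a_i ~ N(2, 1), loadings b_i ~ N(0, loading_sd^2). Returns the matrix
    plus a species table with the true a_i, b_i and presence_i.
    """
    if n_species < 5:
        raise ValueError("need n_species >= 5")
    rng = np.random.default_rng(seed)
    if presence_profile is None:
        presence = rng.beta(8.0, 2.0, size=n_species)
    else:
        presence = np.asarray(presence_profile, dtype=float)
        if presence.shape != (n_species,):
            raise ValueError("presence_profile must have one value per species")
        if np.any((presence <= 0) | (presence > 1)):
            raise ValueError("presence probabilities must lie in (0, 1]")
    a = rng.normal(2.0, 1.0, size=n_species)
    b = rng.normal(0.0, loading_sd, size=n_species)
    state = latent_state.to_numpy(dtype=float)
    n_years = state.size
    eps = rng.normal(0.0, lognorm_sd, size=(n_years, n_species))
    biomass = np.exp(a[None, :] + np.outer(state, b) + eps)
    present = rng.random((n_years, n_species)) < presence[None, :]
    biomass = np.where(present, biomass, 0.0)

    names = [f"sp{i:03d}" for i in range(n_species)]
    matrix = BiomassMatrix(
        pd.DataFrame(biomass, index=latent_state.index.copy(), columns=names),
        area=area,
    )
    truth = pd.DataFrame(
        {"baseline": a, "loading": b, "presence": presence},
        index=pd.Index(names, name="species"),
    )
    return matrix, truth


def simulate_traits(
    species: list,
    seed: int = 0,
    tpref_range: tuple = (12.0, 26.0),
    taxon_probs: tuple = (0.6, 0.25, 0.15),  # fish, crustacean, cephalopod
    p_benthic: float = 0.6,
    p_commercial: float = 0.4,
) -> TraitTable:
    """Trait table with life-history proportions on the simplex.

    Proportions are Dirichlet(2, 2, 2) renormalized to sum exactly 1;
    preferred temperature is uniform on ``tpref_range`` (deg C); taxon,
    habitat and commercial flags are drawn with the stated probabilities.
    """
    if not species:
        raise ValueError("empty species list")
    rng = np.random.default_rng(seed)
    n = len(species)
    props = rng.dirichlet(np.full(3, 2.0), size=n)
    props = props / props.sum(axis=1, keepdims=True)
    tpref = rng.uniform(*tpref_range, size=n)
    taxon = rng.choice(["fish", "crustacean", "cephalopod"], size=n, p=taxon_probs)
    habitat = rng.choice(["benthic", "pelagic"], size=n, p=(p_benthic, 1 - p_benthic))
    commercial = rng.random(n) < p_commercial
    df = pd.DataFrame(
        {
            "opportunistic": props[:, 0], "periodic": props[:, 1],
            "equilibrium": props[:, 2], "tpref": tpref, "taxon": taxon,
            "habitat": habitat, "commercial": commercial,
        },
        index=pd.Index(species, name="species"),
    )
    return TraitTable(df)


def default_truth(seed: int = 0, **overrides) -> SyntheticTruth:
    return SyntheticTruth(seed=seed, **overrides)


def default_stressors(seed: int = 0, n_years: int | None = None,
                      start_year: int | None = None) -> dict[tuple, pd.Series]:
    """The 3-variable x 2-season stressor set as stationary AR(1) series.

    Series start two years before the first survey year so that 2-year
    lagged pairings keep all survey years.
    """
    if n_years is None:
        n_years = DEFAULT_YEARS.size + 2
    if start_year is None:
        start_year = int(DEFAULT_YEARS[0]) - 2
    rng = np.random.default_rng(seed)
    out = {}
    for (var, season), (mean, sd, ar1) in STRESSOR_CLIMATOLOGY.items():
        sub = int(rng.integers(0, 2**31 - 1))
        out[(var, season)] = simulate_stressor(
            n_years, mean, sd, ar1, seed=sub, start_year=start_year,
            name=f"{var}_{season}",
        )
    return out


@dataclass
class SyntheticDataset:
    """One full synthetic study: inputs plus every piece of ground truth."""

    biomass: BiomassMatrix
    traits: TraitTable
    stressors: dict
    system: FoldSystem
    species_truth: pd.DataFrame
    truth: SyntheticTruth
    driver: tuple = ("chl", "winter")

    def truth_dict(self) -> dict:
        d = asdict(self.truth)
        d["driver"] = "_".join(self.driver)
        return d


def simulate_dataset(seed: int = 0, n_species: int = 100,
                     truth: SyntheticTruth | None = None,
                     driver: tuple = ("chl", "winter"),
                     **community_kwargs) -> SyntheticDataset:
    """Generate the default end-to-end fixture with known ground truth.

    The latent state responds to the winter chlorophyll series at the
    truth's lag; all six stressor series are generated so the model grid
    has genuine negative controls.
    """
    rng = np.random.default_rng(seed)
    s_stress, s_truth, s_comm, s_traits = (int(x) for x in rng.integers(0, 2**31 - 1, 4))
    stressors = default_stressors(seed=s_stress)
    truth = truth if truth is not None else SyntheticTruth(seed=s_truth)
    system = simulate_fold_system(stressors[driver], truth)
    biomass, species_truth = simulate_community(
        system.state, n_species=n_species, seed=s_comm, **community_kwargs
    )
    traits = simulate_traits(biomass.species, seed=s_traits)
    return SyntheticDataset(biomass, traits, stressors, system, species_truth,
                            truth, driver)
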