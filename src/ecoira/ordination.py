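"""Community ordination: presence filtering, correlation-matrix PCA,
parsimony-based optimal-PCA selection and traffic-light ordering.

The community observable is a years x species biomass matrix (kg/km^2 per
species and survey year). Because many species are caught only sporadically,
the PCA is run on a family of matrices — species present in at least
``min_presence`` of the surveyed years — and the most parsimonious PCA whose
leading score series still track the most inclusive one is retained.

PCAs are computed on the correlation matrix of log-transformed biomasses:
each species series is log(x+1)-transformed and standardized to mean 0 /
SD 1, and the standardized matrix is eigen-decomposed (via SVD). Component
signs follow a fixed convention: the loading of largest magnitude on each
component is made positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BiomassMatrix",
    "PCAResult",
    "filter_species",
    "run_pca",
    "select_optimal_pca",
    "traffic_light",
    "log_transform",
]


class NoSpeciesRetained(ValueError):
    """Raised when a presence filter removes every species."""


@dataclass(frozen=True)
class BiomassMatrix:
    """Years x species biomass (kg/km^2) for one survey area.

    ``data`` has the calendar years as a strictly increasing integer index
    and one column per species; values are nonnegative yearly mean biomass
    per swept area.
    """

    data: pd.DataFrame
    area: str = "area"

    def __post_init__(self):
        df = self.data
        years = np.asarray(df.index)
        if len(years) > 1 and not np.all(np.diff(years) > 0):
            raise ValueError("years must be strictly increasing")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate species columns: {dup}")
        if (df.to_numpy() < 0).any():
            raise ValueError("biomass values must be nonnegative")

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.data.index)

    @property
    def species(self) -> list:
        return list(self.data.columns)

    def presence_counts(self) -> pd.Series:
        """Number of years each species was caught (biomass > 0)."""
        return (self.data > 0).sum(axis=0)


@dataclass
class PCAResult:
    """Correlation-matrix PCA of a (filtered) biomass matrix.

    ``scores`` are the projections of the standardized log-biomass rows on
    the eigenvectors (years x components); ``loadings`` are the
    eigenvectors (species x components); ``explained_fraction[i]`` is
    eigenvalue_i / n_species, i.e. the fraction of total correlation-matrix
    variance carried by component i.
    """

    inclusion_threshold: int
    species_used: list
    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_fraction: np.ndarray
    area: str = "area"
    selection_warning: str | None = None

    @property
    def n_species(self) -> int:
        return len(self.species_used)

    def score(self, component: int = 1) -> pd.Series:
        """Yearly score series of a component (1-based)."""
        return self.scores[f"PC{component}"]


def log_transform(values: np.ndarray) -> np.ndarray:
    """ln(x + 1) on kg/km^2; keeps absence years at exactly zero."""
    return np.log1p(values)


def filter_species(matrix: BiomassMatrix, min_presence: int) -> BiomassMatrix:
    """Keep species caught (biomass > 0) in at least ``min_presence`` years."""
    n_years = len(matrix.years)
    if not 0 <= min_presence <= n_years:
        raise ValueError(f"min_presence must be in [0, {n_years}]")
    keep = matrix.presence_counts() >= min_presence
    if not keep.any():
        raise NoSpeciesRetained(
            f"no species retained at min_presence={min_presence} "
            f"({matrix.area}, {n_years} years)"
        )
    return BiomassMatrix(matrix.data.loc[:, keep[keep].index], matrix.area)


def _standardize_log(matrix: BiomassMatrix) -> pd.DataFrame:
    """log(x+1) then per-species z-score (ddof=1); errors on flat species."""
    logged = log_transform(matrix.data.to_numpy(dtype=float))
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd < 1e-12)  # constant series round to ~1e-16
    if flat.size:
        names = [matrix.species[i] for i in flat]
        raise ValueError(f"zero-variance species after log transform: {names}")
    z = (logged - mean) / sd
    return pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns)


def run_pca(matrix: BiomassMatrix, inclusion_threshold: int | None = None) -> PCAResult:
    """Correlation-matrix PCA of log-transformed biomasses.

    Equivalent to eigen-decomposing the species correlation matrix of the
    log(x+1) series; computed via SVD of the standardized matrix for
    numerical stability. Explained fractions are eigenvalues over their
    total (= the number of species, the trace of the correlation matrix).
    """
    if len(matrix.years) < 3:
        raise ValueError("need at least 3 years for a PCA")
    if len(matrix.species) < 2:
        raise ValueError("need at least 2 species for a PCA")
    Z = _standardize_log(matrix)
    z = Z.to_numpy()
    n_years, n_species = z.shape
    n_comp = min(n_years - 1, n_species)

    U, sv, Vt = np.linalg.svd(z, full_matrices=False)
    eigvals = sv**2 / (n_years - 1)  # eigenvalues of the correlation matrix
    loadings = Vt.T[:, :n_comp]
    scores = z @ loadings

    # sign convention: largest-|loading| species positive on each component
    for j in range(n_comp):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]

    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        inclusion_threshold=(
            inclusion_threshold
            if inclusion_threshold is not None
            else int(matrix.presence_counts().min())
        ),
        species_used=matrix.species,
        loadings=pd.DataFrame(loadings, index=matrix.data.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=matrix.data.index, columns=comp_names),
        explained_fraction=eigvals[:n_comp] / n_species,
        area=matrix.area,
    )


def select_optimal_pca(candidates: list[PCAResult], similarity_min: float = 0.95) -> PCAResult:
    """Most parsimonious PCA still capturing the full-community dynamics.

    The reference is the candidate with the most species. A candidate
    qualifies when both its PC1 and PC2 score series correlate with the
    reference's at |Pearson r| >= ``similarity_min`` (sign-agnostic);
    among qualifiers, the one with the fewest species wins. If none
    qualifies, the reference itself is returned with a warning record.
    """
    if not candidates:
        raise ValueError("no PCA candidates")
    if len(candidates) == 1:
        return candidates[0]
    ref = max(candidates, key=lambda c: c.n_species)
    years = ref.scores.index
    if any(not c.scores.index.equals(years) for c in candidates):
        raise ValueError("candidates must share the year axis")

    def similar(c: PCAResult) -> bool:
        for pc in ("PC1", "PC2"):
            if pc not in c.scores.columns or pc not in ref.scores.columns:
                return False
            r = np.corrcoef(c.scores[pc], ref.scores[pc])[0, 1]
            if abs(r) < similarity_min:
                return False
        return True

    qualifiers = [c for c in candidates if c is not ref and similar(c)]
    if not qualifiers:
        msg = (
            f"no candidate reaches |r| >= {similarity_min} with the most "
            f"inclusive PCA; returning the most inclusive one"
        )
        warnings.warn(msg)
        ref.selection_warning = msg
        return ref
    return min(qualifiers, key=lambda c: c.n_species)


def traffic_light(matrix: BiomassMatrix, pca: PCAResult, component: int = 1) -> pd.DataFrame:
    """Species x years matrix for a traffic-light plot.

    Rows are the PCA's species sorted by descending loading on the chosen
    component (1-based); each row is the species' log(x+1) biomass series
    standardized to mean 0 / SD 1 across years.
    """
    name = f"PC{component}"
    if name not in pca.loadings.columns:
        raise ValueError(f"component {component} not present in PCA")
    sub = BiomassMatrix(matrix.data.loc[:, pca.species_used], matrix.area)
    Z = _standardize_log(sub)
    order = pca.loadings[name].sort_values(ascending=False, kind="stable").index
    return Z.T.loc[order]
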