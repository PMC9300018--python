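"""CSV dialects for the pipeline's tabular inputs and outputs.

Biomass matrices are accepted wide (rows = years, columns = species) or
long (``year,species,biomass_kg_km2``), auto-detected from the header;
both round-trip losslessly. Stressor series are ``year,value`` CSVs named
``<variable>_<season>``; trait tables use the declared column names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .indicators import TRAIT_COLUMNS, TraitTable
from .ordination import BiomassMatrix, PCAResult

__all__ = [
    "read_biomass", "write_biomass_wide", "write_biomass_long",
    "read_traits", "write_traits", "read_stressor", "write_stressor",
    "write_pca",
]

LONG_COLUMNS = ["year", "species", "biomass_kg_km2"]

# fixed float formatting keeps repeated runs byte-identical
FLOAT_FMT = "%.10g"


def read_biomass(path, area: str | None = None) -> BiomassMatrix:
    """Read a biomass CSV, auto-detecting the wide or long dialect."""
    path = Path(path)
    header = pd.read_csv(path, nrows=0).columns.tolist()
    if [c.strip() for c in header[:3]] == LONG_COLUMNS:
        df = pd.read_csv(path)
        dup = df.duplicated(subset=["year", "species"])
        if dup.any():
            keys = df.loc[dup, ["year", "species"]].to_records(index=False).tolist()
            raise ValueError(f"duplicate (year, species) rows: {keys}")
        if not np.issubdtype(df["biomass_kg_km2"].dtype, np.number):
            bad = df.loc[pd.to_numeric(df["biomass_kg_km2"], errors="coerce").isna()]
            raise ValueError(f"non-numeric biomass values: {bad.head().to_dict('records')}")
        wide = df.pivot(index="year", columns="species", values="biomass_kg_km2")
        wide = wide.fillna(0.0).sort_index()
        wide.columns.name = None
        return BiomassMatrix(wide, area or path.stem)
    # wide dialect: first column is the year
    df = pd.read_csv(path, index_col=0)
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate species columns: "
                         f"{df.columns[df.columns.duplicated()].tolist()}")
    if not all(np.issubdtype(d, np.number) for d in df.dtypes):
        bad = [c for c, d in df.dtypes.items() if not np.issubdtype(d, np.number)]
        raise ValueError(f"non-numeric biomass columns: {bad}")
    df.index = df.index.astype(int)
    df.index.name = "year"
    return BiomassMatrix(df.sort_index(), area or path.stem)


def write_biomass_wide(matrix: BiomassMatrix, path) -> None:
    matrix.data.to_csv(path, index_label="year", float_format=FLOAT_FMT)


def write_biomass_long(matrix: BiomassMatrix, path) -> None:
    long = (
        matrix.data.rename_axis(index="year", columns="species")
        .stack()
        .rename("biomass_kg_km2")
        .reset_index()
    )
    long.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait CSV missing columns: {missing}")
    if df["species"].duplicated().any():
        raise ValueError(f"duplicate species in trait table: "
                         f"{df.loc[df['species'].duplicated(), 'species'].tolist()}")
    df = df.set_index("species")
    df["commercial"] = df["commercial"].astype(bool)
    return TraitTable(df)


def write_traits(traits: TraitTable, path) -> None:
    traits.data.to_csv(path, index_label="species", float_format=FLOAT_FMT)


def read_stressor(path, name: str | None = None) -> pd.Series:
    df = pd.read_csv(path)
    if "year" not in df.columns or "value" not in df.columns:
        raise ValueError(f"stressor CSV needs columns year,value; got {df.columns.tolist()}")
    if df["year"].duplicated().any():
        raise ValueError("duplicate years in stressor series")
    s = df.set_index("year")["value"].sort_index()
    s.index = s.index.astype(int)
    s.name = name or Path(path).stem
    return s


def write_stressor(series: pd.Series, path) -> None:
    df = pd.DataFrame({"year": series.index.astype(int), "value": series.to_numpy()})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_pca(pca: PCAResult, prefix: Path) -> None:
    """PCAResult as loadings CSV + scores CSV + JSON metadata."""
    prefix = Path(prefix)
    pca.loadings.to_csv(f"{prefix}_loadings.csv", index_label="species",
                        float_format=FLOAT_FMT)
    pca.scores.to_csv(f"{prefix}_scores.csv", index_label="year",
                      float_format=FLOAT_FMT)
    meta = {
        "area": pca.area,
        "inclusion_threshold": int(pca.inclusion_threshold),
        "n_species": pca.n_species,
        "explained_fraction": [float(f) for f in pca.explained_fraction],
        "selection_warning": pca.selection_warning,
    }
    Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
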