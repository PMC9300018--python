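"""Configuration-driven orchestration of the full Integrated Resilience
Assessment: ordination -> regime-shift detection -> GAM/TGAM model grid ->
resilience landscape -> community indicators, with reproducible seeding
and tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .indicators import (IndicatorSeries, TraitTable, cwmt, group_mean_standardized,
                         life_history_means)
from .ordination import (BiomassMatrix, NoSpeciesRetained, PCAResult, filter_species,
                         run_pca, select_optimal_pca)
from .resilience import ResilienceAssessment, ResilienceResult
from .stars import ShiftDetection, detect_shifts
from .threshold_models import ModelSelection, select_best_model

logger = logging.getLogger("ecoira")

__all__ = ["RunConfig", "OutputBundle", "run_ira", "read_inputs", "write_bundle"]


@dataclass
class RunConfig:
    """Everything a reproducible IRA run needs.

    Paths may be None when the corresponding objects are passed to
    :func:`run_ira` directly (e.g. straight from the synthetic generator).
    """

    biomass_path: str | None = None
    traits_path: str | None = None
    stressor_paths: dict = field(default_factory=dict)  # (var, season) -> path
    area: str = "area"
    inclusion_grid: tuple = (26, 25, 24, 23, 22, 21)
    similarity_min: float = 0.95
    stars_cutoff: int = 3
    stars_alpha: float = 0.05
    stars_prewhiten: bool = True
    model_lags: tuple = (0, 1, 2)
    model_k: int = 4
    min_branch_years: int = 5
    response_pcs: tuple = ("PC1", "PC2", "PC3")
    excluded_years: tuple = ()
    tipping_sides: dict | None = None
    seed: int = 0
    out_dir: str = "ira_out"

    def config_hash(self) -> str:
        d = asdict(self)
        d["stressor_paths"] = {
            ("_".join(k) if isinstance(k, tuple) else str(k)): v
            for k, v in (self.stressor_paths or {}).items()
        }
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def validate_paths(self) -> None:
        for label, p in [("biomass", self.biomass_path), ("traits", self.traits_path),
                         *[(f"stressor {k}", v) for k, v in self.stressor_paths.items()]]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")


@dataclass
class OutputBundle:
    config: RunConfig
    pca_candidates: list
    optimal_pca: PCAResult
    shift_detections: dict  # pc name -> ShiftDetection
    model_selection: ModelSelection
    retained_pc: str
    resilience: ResilienceResult | None
    indicators: dict  # name -> IndicatorSeries
    log: list = field(default_factory=list)

    def metadata(self) -> dict:
        return {"config_hash": self.config.config_hash(), "seed": self.config.seed}


def read_inputs(config: RunConfig):
    """Load biomass matrix, trait table and stressor series from config paths."""
    config.validate_paths()
    if config.biomass_path is None:
        raise FileNotFoundError("no biomass path configured")
    biomass = eio.read_biomass(config.biomass_path, area=config.area)
    traits = eio.read_traits(config.traits_path) if config.traits_path else None
    stressors = {}
    for key, path in config.stressor_paths.items():
        var, season = key if isinstance(key, tuple) else tuple(key.split("_", 1))
        stressors[(var, season)] = eio.read_stressor(path, name=f"{var}_{season}")
    return biomass, traits, stressors


def _stage(bundle_log: list, name: str):
    logger.info("stage: %s", name)
    bundle_log.append(name)


def run_ira(
    config: RunConfig,
    biomass: BiomassMatrix | None = None,
    traits: TraitTable | None = None,
    stressors: dict | None = None,
) -> OutputBundle:
    """Execute the full IRA and return every stage's artifact.

    Stages: presence filtering + PCA over the inclusion grid -> optimal
    PCA -> STARS on PC1/PC2 -> GAM/TGAM grid on the response PCs ->
    retained system PC -> resilience + stability landscape (when the
    retained model is a TGAM) -> indicator series with AR(1)-GLS trends.
    Identical config + seed give identical outputs.
    """
    log: list = []
    if biomass is None or (traits is None and config.traits_path):
        _stage(log, "read_inputs")
        b2, t2, s2 = read_inputs(config)
        biomass = biomass if biomass is not None else b2
        traits = traits if traits is not None else t2
        stressors = stressors if stressors is not None else s2
    if stressors is None:
        raise ValueError("no stressor series provided or configured")

    n_years = len(biomass.years)
    _stage(log, "ordination")
    candidates = []
    for k in config.inclusion_grid:
        if k > n_years:
            continue
        try:
            filt = filter_species(biomass, k)
            candidates.append(run_pca(filt, inclusion_threshold=k))
        except (NoSpeciesRetained, ValueError) as exc:
            log.append(f"ordination: inclusion {k} skipped ({exc})")
    if not candidates:
        raise RuntimeError("ordination stage failed: no PCA candidate could be fitted")
    optimal = select_optimal_pca(candidates, similarity_min=config.similarity_min)

    _stage(log, "stars")
    detections: dict[str, ShiftDetection] = {}
    for pc in ("PC1", "PC2"):
        if pc in optimal.scores.columns:
            detections[pc] = detect_shifts(
                optimal.scores[pc].to_numpy(), years=optimal.scores.index.to_numpy(),
                cutoff_l=config.stars_cutoff, alpha=config.stars_alpha,
                prewhiten_flag=config.stars_prewhiten,
            )

    _stage(log, "model_selection")
    responses = {pc: optimal.scores[pc] for pc in config.response_pcs
                 if pc in optimal.scores.columns}
    selection = select_best_model(
        responses, stressors, k=config.model_k,
        min_branch_years=config.min_branch_years, lags=config.model_lags,
    )
    retained = selection.retained_pc

    resilience = None
    best = selection.best_fit(retained)
    if getattr(best, "model_type", "GAM") == "TGAM":
        _stage(log, "resilience")
        resilience = ResilienceAssessment(
            best,
            tipping_sides=config.tipping_sides,
            excluded_years=list(config.excluded_years),
        ).fit()
    else:
        log.append("resilience: skipped (retained model is continuous)")

    indicators: dict[str, IndicatorSeries] = {}
    if traits is not None:
        _stage(log, "indicators")
        common = [s for s in optimal.species_used if s in traits.data.index]
        sub = BiomassMatrix(biomass.data.loc[:, common], biomass.area)
        tsub = TraitTable(traits.data.loc[common])
        for label, kw in [("all", {}), ("commercial", {"commercial": True}),
                          ("noncommercial", {"commercial": False}),
                          ("fish", {"taxon": "fish"}),
                          ("crustacean", {"taxon": "crustacean"}),
                          ("cephalopod", {"taxon": "cephalopod"})]:
            members = tsub.subset(**kw) if kw else common
            if members:
                indicators[f"cwmt_{label}"] = cwmt(sub, tsub, members,
                                                   name=f"cwmt_{label}").with_trend()
        if tsub.subset(taxon="fish"):
            for strat, series in life_history_means(sub, tsub).items():
                indicators[f"lh_{strat}"] = series.with_trend()
        for taxon in ("crustacean", "cephalopod"):
            for habitat in ("benthic", "pelagic"):
                members = tsub.subset(taxon=taxon, habitat=habitat)
                if members:
                    name = f"{taxon}_{habitat}"
                    indicators[name] = group_mean_standardized(sub, members,
                                                               name=name).with_trend()
        for label, flag in [("commercial", True), ("noncommercial", False)]:
            members = tsub.subset(taxon="fish", commercial=flag)
            if members:
                name = f"fish_{label}"
                indicators[name] = group_mean_standardized(sub, members,
                                                           name=name).with_trend()
    else:
        log.append("indicators: skipped (no trait table)")

    return OutputBundle(
        config=config, pca_candidates=candidates, optimal_pca=optimal,
        shift_detections=detections, model_selection=selection,
        retained_pc=retained, resilience=resilience, indicators=indicators, log=log,
    )


def write_bundle(bundle: OutputBundle, out_dir) -> list[Path]:
    """Write every artifact as CSV/JSON under ``out_dir``; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = bundle.metadata()
    written: list[Path] = []

    def _register(p):
        written.append(Path(p))

    eio.write_pca(bundle.optimal_pca, out / "optimal_pca")
    _register(out / "optimal_pca_scores.csv")

    for pc, det in bundle.shift_detections.items():
        df = pd.DataFrame({"year": det.years, "value": det.series,
                           "rsi": det.rsi, "regime_mean": det.regime_means})
        p = out / f"stars_{pc}.csv"
        df.to_csv(p, index=False, float_format=eio.FLOAT_FMT)
        _register(p)

    tab = bundle.model_selection.table.copy()
    p = out / "model_selection.csv"
    tab.to_csv(p, index=False, float_format=eio.FLOAT_FMT)
    _register(p)

    if bundle.resilience is not None:
        r = bundle.resilience
        p = out / "resilience_per_year.csv"
        r.per_year.to_csv(p, index_label="year", float_format=eio.FLOAT_FMT)
        _register(p)
        if r.landscape is not None:
            p = out / "stability_landscape.csv"
            np.savetxt(p, r.landscape, delimiter=",", fmt=eio.FLOAT_FMT)
            _register(p)
            (out / "stability_landscape_axes.json").write_text(json.dumps({
                "x_grid": r.landscape_x.tolist(), "z_grid": r.landscape_z.tolist(),
                "tipping_points": {str(k): v for k, v in r.tipping_points.items()},
                "tipping_sides": {str(k): v for k, v in r.tipping_sides.items()},
                "excluded_years": [int(y) for y in r.excluded_years],
                **meta,
            }, indent=2, sort_keys=True))

    if bundle.indicators:
        tidy = []
        trends = []
        for name, ind in sorted(bundle.indicators.items()):
            for year, value in ind.values.items():
                tidy.append({"indicator": name, "year": int(year), "value": value})
            if ind.trend is not None:
                trends.append({"indicator": name, "slope": ind.trend.slope,
                               "p": ind.trend.p_value, "rho": ind.trend.rho,
                               "significant": ind.trend.significant})
        p = out / "indicators.csv"
        pd.DataFrame(tidy).to_csv(p, index=False, float_format=eio.FLOAT_FMT)
        _register(p)
        p = out / "indicator_trends.csv"
        pd.DataFrame(trends).to_csv(p, index=False, float_format=eio.FLOAT_FMT)
        _register(p)

    (out / "run_meta.json").write_text(json.dumps({
        **meta, "retained_pc": bundle.retained_pc, "log": bundle.log,
        "shift_years": {pc: [[int(y), int(s)] for y, s in det.shift_years]
                        for pc, det in bundle.shift_detections.items()},
    }, indent=2, sort_keys=True))
    _register(out / "run_meta.json")
    return written
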