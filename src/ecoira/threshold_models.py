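"""Continuous (GAM) versus discontinuous (threshold GAM) driver–response
models with genuine cross-validation.

A GAM regresses the standardized community score on a lagged seasonal
stressor through a single penalized spline — a system that tracks its
driver continuously. A threshold GAM (TGAM) splits the years at a
candidate threshold year and fits a separate spline (its own smoothing
parameter) to each side — a response curve that can jump between two
branches, the signature of a discontinuous (fold-type) shift. The two are
made comparable by the genuine cross-validation error (gCV): for each
held-out year the entire estimation — threshold-year search and smoothing
parameter selection included — is re-run on the remaining years, and the
squared prediction errors are averaged. Because responses are standardized
to unit variance, gCV ~ n/(n-1) marks the skill of an intercept-only model.

Model objects follow the fit()-returns-results convention: build a
:class:`GAM` or :class:`ThresholdGAM` from a lagged response/stressor
frame, call ``fit()``, and read gCV, variance explained, threshold year and
branch predictions off the results object.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .smoothing import SplineFit, fit_penalized_spline

__all__ = [
    "LaggedFrame",
    "build_lagged_frame",
    "GAM",
    "GAMResults",
    "ThresholdGAM",
    "TGAMResults",
    "genuine_cv",
    "enumerate_model_grid",
    "select_best_model",
]

STRESSOR_VARS = ("chl", "sst", "rhi")
SEASONS = ("winter", "spring")
LAGS = (0, 1, 2)


@dataclass(frozen=True)
class LaggedFrame:
    """Paired response/stressor values at a fixed lag.

    ``response[i]`` is the standardized community score of ``years[i]``;
    ``stressor[i]`` is the driver value of season ending in
    ``years[i] - lag``.
    """

    years: np.ndarray
    response: np.ndarray
    stressor: np.ndarray
    lag: int
    stressor_name: str = "stressor"

    @property
    def n(self) -> int:
        return self.years.size

    def drop(self, idx: int) -> "LaggedFrame":
        keep = np.arange(self.n) != idx
        return LaggedFrame(
            self.years[keep], self.response[keep], self.stressor[keep],
            self.lag, self.stressor_name,
        )


def build_lagged_frame(
    pc_scores: pd.Series,
    stressor: pd.Series,
    lag: int,
    stressor_name: str = "stressor",
    standardize_response: bool = True,
) -> LaggedFrame:
    """Pair response year y with stressor year y - lag.

    The response is standardized to mean 0 / SD 1 over the retained years
    (unit-variance responses make gCV values comparable across components).
    Years whose lagged stressor is missing are dropped; the remaining
    pairing must be complete.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    years = np.asarray(pc_scores.index)
    avail = np.array([(y - lag) in stressor.index for y in years])
    if not avail.any():
        raise ValueError(f"stressor does not cover any response year at lag {lag}")
    years = years[avail]
    resp = pc_scores.loc[years].to_numpy(dtype=float)
    stress = stressor.loc[[y - lag for y in years]].to_numpy(dtype=float)
    if np.isnan(resp).any() or np.isnan(stress).any():
        raise ValueError("missing values in lagged pairing")
    if standardize_response:
        sd = resp.std(ddof=1)
        if sd == 0:
            raise ValueError("constant response series")
        resp = (resp - resp.mean()) / sd
    return LaggedFrame(years, resp, stress, lag, stressor_name)


# ---------------------------------------------------------------------------
# GAM


class GAM:
    """Penalized-spline regression of response on a lagged stressor."""

    def __init__(self, frame: LaggedFrame, k: int = 4):
        if frame.n < 8:
            raise ValueError(f"need at least 8 pairs, got {frame.n}")
        if np.ptp(frame.stressor) == 0:
            raise ValueError("constant stressor: rank-deficient design")
        self.frame = frame
        self.k = k

    def fit(self, lam: float | None = None) -> "GAMResults":
        sf = fit_penalized_spline(self.frame.stressor, self.frame.response, k=self.k, lam=lam)
        return GAMResults(self.frame, self.k, sf)


@dataclass
class GAMResults:
    frame: LaggedFrame
    k: int
    smooth: SplineFit
    model_type: str = "GAM"
    threshold_year: int | None = None

    def predict(self, stressor_values, year=None) -> np.ndarray:
        return self.smooth.predict(stressor_values)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.smooth.fitted

    @property
    def edf(self) -> float:
        return self.smooth.edf

    @property
    def variance_explained(self) -> float:
        y = self.frame.response
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0:
            return 0.0
        return 1.0 - self.smooth.rss / tss

    def summary(self) -> str:
        return (
            f"{self.model_type}(response ~ s({self.frame.stressor_name}, k={self.k}), "
            f"lag={self.frame.lag}, n={self.frame.n})\n"
            f"  edf={self.edf:.2f}  var.expl={100 * self.variance_explained:.1f}%"
        )


# ---------------------------------------------------------------------------
# Threshold GAM


def threshold_candidates(years: np.ndarray, min_branch_years: int) -> list:
    """Threshold years leaving >= min_branch_years on each side.

    The threshold year is the first year of the second regime.
    """
    years = np.sort(np.asarray(years))
    n = years.size
    return [int(years[i]) for i in range(min_branch_years, n - min_branch_years + 1)]


class ThresholdGAM:
    """Two-regime GAM: separate smooths before/after a threshold year.

    The threshold year is searched over ``candidates`` (by default every
    year leaving at least ``min_branch_years`` years per branch) by
    minimizing the combined GCV score of the two-branch fit; each branch
    has its own GCV-selected smoothing parameter.
    """

    def __init__(
        self,
        frame: LaggedFrame,
        k: int = 4,
        min_branch_years: int = 5,
        candidates: list | None = None,
    ):
        if frame.n < 2 * min_branch_years:
            raise ValueError("too few pairs for two branches")
        self.frame = frame
        self.k = k
        self.min_branch_years = min_branch_years
        full = threshold_candidates(frame.years, min_branch_years)
        if candidates is None:
            self.candidates = full
            self.candidates_restricted = False
        else:
            self.candidates = [c for c in candidates if c in full]
            self.candidates_restricted = len(self.candidates) < len(candidates)
        if not self.candidates:
            raise ValueError("no feasible threshold candidates after branch-size constraint")

    def fit(self) -> "TGAMResults":
        f = self.frame
        n = f.n
        best = None
        for thr in self.candidates:
            pre = f.years < thr
            post = ~pre
            s1 = fit_penalized_spline(f.stressor[pre], f.response[pre], k=self.k)
            s2 = fit_penalized_spline(f.stressor[post], f.response[post], k=self.k)
            rss = s1.rss + s2.rss
            edf = s1.edf + s2.edf
            denom = n - edf
            score = n * rss / denom**2 if denom > 1e-8 else np.inf
            if best is None or score < best[0] - 1e-15:
                best = (score, thr, s1, s2)
        score, thr, s1, s2 = best
        return TGAMResults(
            frame=f, k=self.k, min_branch_years=self.min_branch_years,
            threshold_year=int(thr), branches=(s1, s2), gcv_internal=score,
            candidates_restricted=self.candidates_restricted,
        )


@dataclass
class TGAMResults:
    frame: LaggedFrame
    k: int
    min_branch_years: int
    threshold_year: int
    branches: tuple  # (pre, post) SplineFit
    gcv_internal: float
    candidates_restricted: bool = False
    model_type: str = "TGAM"

    def regime_of(self, year) -> np.ndarray:
        """0 for pre-threshold years, 1 from the threshold year onward."""
        return (np.atleast_1d(np.asarray(year)) >= self.threshold_year).astype(int)

    def predict(self, stressor_values, year) -> np.ndarray:
        x = np.atleast_1d(np.asarray(stressor_values, dtype=float))
        reg = self.regime_of(year)
        out = np.empty(x.shape)
        for r in (0, 1):
            m = reg == r
            if m.any():
                out[m] = self.branches[r].predict(x[m])
        return out

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.frame.stressor, self.frame.years)

    @property
    def edf(self) -> float:
        return self.branches[0].edf + self.branches[1].edf

    @property
    def rss(self) -> float:
        return self.branches[0].rss + self.branches[1].rss

    @property
    def variance_explained(self) -> float:
        y = self.frame.response
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0:
            return 0.0
        return 1.0 - self.rss / tss

    def summary(self) -> str:
        return (
            f"TGAM(response ~ s({self.frame.stressor_name}, k={self.k}) | "
            f"year < {self.threshold_year} vs >= {self.threshold_year}, "
            f"lag={self.frame.lag}, n={self.frame.n})\n"
            f"  edf={self.edf:.2f}  var.expl={100 * self.variance_explained:.1f}%"
        )


# ---------------------------------------------------------------------------
# genuine cross-validation


def _fit_for_spec(frame: LaggedFrame, model_type: str, k: int, min_branch_years: int,
                  candidates: list | None = None):
    if model_type == "GAM":
        return GAM(frame, k=k).fit()
    elif model_type == "TGAM":
        return ThresholdGAM(frame, k=k, min_branch_years=min_branch_years,
                            candidates=candidates).fit()
    raise ValueError(f"unknown model type {model_type!r}")


def genuine_cv(
    frame: LaggedFrame,
    model_type: str,
    k: int = 4,
    min_branch_years: int = 5,
) -> float:
    """Leave-one-year-out squared prediction error, re-estimating everything.

    For every held-out year the full estimation — threshold-year search for
    TGAMs and smoothing-parameter selection for every smooth — is re-run on
    the remaining years, and the model predicts the held-out response (a
    held-out year beyond a branch's stressor range is predicted by the
    branch's linear extension). A fold whose reduced frame cannot sustain
    the branch-size constraint falls back to the nearest fittable model (a
    single smooth); this is recorded implicitly via the GAM fallback.
    """
    if model_type == "TGAM":
        return _tgam_loo(frame, k, min_branch_years)
    n = frame.n
    errors = np.empty(n)
    for i in range(n):
        sub = frame.drop(i)
        try:
            res = _fit_for_spec(sub, model_type, k, min_branch_years)
        except ValueError:
            res = GAM(sub, k=k).fit()
        pred = res.predict(frame.stressor[i : i + 1], frame.years[i : i + 1])
        errors[i] = (frame.response[i] - pred[0]) ** 2
    return float(np.mean(errors))


def _tgam_loo(frame: LaggedFrame, k: int, min_branch_years: int) -> float:
    """LOO TGAM error with branch-fit caching.

    Identical to dropping each year and re-running the full TGAM fit: for a
    candidate threshold, the branch not containing the held-out year equals
    the full-data branch fit, so those fits are shared across folds.
    """
    from .smoothing import fit_penalized_spline

    n = frame.n
    cache: dict = {}

    def branch(x, y, key):
        hit = cache.get(key)
        if hit is None:
            hit = cache[key] = fit_penalized_spline(x, y, k=k)
        return hit

    errors = np.empty(n)
    for i in range(n):
        sub = frame.drop(i)
        yi = frame.years[i]
        cands = (threshold_candidates(sub.years, min_branch_years)
                 if sub.n >= 2 * min_branch_years else [])
        if not cands:
            res = GAM(sub, k=k).fit()
            pred = res.predict(frame.stressor[i : i + 1], frame.years[i : i + 1])
            errors[i] = (frame.response[i] - pred[0]) ** 2
            continue
        best = None
        for thr in cands:
            pre = sub.years < thr
            excl_pre = yi if yi < thr else None
            excl_post = None if yi < thr else yi
            s1 = branch(sub.stressor[pre], sub.response[pre], (0, thr, excl_pre))
            s2 = branch(sub.stressor[~pre], sub.response[~pre], (1, thr, excl_post))
            rss = s1.rss + s2.rss
            edf = s1.edf + s2.edf
            denom = sub.n - edf
            score = sub.n * rss / denom**2 if denom > 1e-8 else np.inf
            if best is None or score < best[0] - 1e-15:
                best = (score, thr, s1, s2)
        _, thr, s1, s2 = best
        fit = s2 if yi >= thr else s1
        pred = fit.predict(frame.stressor[i : i + 1])
        errors[i] = (frame.response[i] - pred[0]) ** 2
    return float(np.mean(errors))


# ---------------------------------------------------------------------------
# model-grid enumeration and selection


def enumerate_model_grid(
    stressor_vars=STRESSOR_VARS,
    seasons=SEASONS,
    lags=LAGS,
    model_types=("GAM", "TGAM"),
) -> list[dict]:
    """The full candidate grid: stressors x seasons x lags x model types."""
    return [
        {"stressor": v, "season": s, "lag": lag, "model_type": mt}
        for mt in model_types
        for v, s, lag in itertools.product(stressor_vars, seasons, lags)
    ]


def _spec_sort_key(row) -> tuple:
    """Deterministic tie-break among equal-gCV models: GAM before TGAM,
    then smaller lag, then stressor/season order."""
    return (
        0 if row["model_type"] == "GAM" else 1,
        row["lag"],
        STRESSOR_VARS.index(row["stressor"]) if row["stressor"] in STRESSOR_VARS else 99,
        SEASONS.index(row["season"]) if row["season"] in SEASONS else 99,
    )


def select_best_model(
    pc_scores: dict[str, pd.Series],
    stressors: dict[tuple, pd.Series],
    k: int = 4,
    min_branch_years: int = 5,
    lags=LAGS,
    gcv_tie_tol: float = 1e-12,
) -> "ModelSelection":
    """Fit the full GAM/TGAM grid for each response PC and rank by gCV.

    ``stressors`` maps (variable, season) -> yearly series. Missing
    combinations are marked absent and skipped. Returns a
    :class:`ModelSelection` holding the per-model table, the per-PC best
    models and the overall retained system PC (lowest gCV across PCs).
    """
    rows = []
    fits = {}
    for pc_name, series in pc_scores.items():
        for cell in enumerate_model_grid(lags=lags):
            key = (cell["stressor"], cell["season"])
            if key not in stressors:
                rows.append({"response": pc_name, **cell, "gcv": np.nan,
                             "variance_explained": np.nan, "threshold_year": None,
                             "status": "absent"})
                continue
            try:
                frame = build_lagged_frame(series, stressors[key], cell["lag"],
                                           stressor_name=f"{key[0]}_{key[1]}")
                res = _fit_for_spec(frame, cell["model_type"], k, min_branch_years)
                gcv = genuine_cv(frame, cell["model_type"], k=k,
                                 min_branch_years=min_branch_years)
            except ValueError as exc:
                rows.append({"response": pc_name, **cell, "gcv": np.nan,
                             "variance_explained": np.nan, "threshold_year": None,
                             "status": f"failed: {exc}"})
                continue
            rows.append({
                "response": pc_name, **cell, "gcv": gcv,
                "variance_explained": res.variance_explained,
                "threshold_year": getattr(res, "threshold_year", None),
                "status": "ok",
            })
            fits[(pc_name, cell["stressor"], cell["season"], cell["lag"],
                  cell["model_type"])] = res
    table = pd.DataFrame(rows)
    return ModelSelection(table=table, fits=fits, gcv_tie_tol=gcv_tie_tol)


@dataclass
class ModelSelection:
    """Ranked GAM/TGAM grid; mirrors the optimal-model table structure."""

    table: pd.DataFrame
    fits: dict = field(repr=False, default_factory=dict)
    gcv_tie_tol: float = 1e-12

    def best_row(self, response: str | None = None) -> pd.Series:
        t = self.table[self.table["status"] == "ok"]
        if response is not None:
            t = t[t["response"] == response]
        if t.empty:
            raise ValueError("no successfully fitted model")
        rows = t.to_dict("records")
        gmin = min(r["gcv"] for r in rows)
        contenders = [r for r in rows if r["gcv"] <= gmin + self.gcv_tie_tol]
        best = min(contenders, key=_spec_sort_key)
        return pd.Series(best)

    def best_fit(self, response: str | None = None):
        r = self.best_row(response)
        return self.fits[(r["response"], r["stressor"], r["season"], r["lag"],
                          r["model_type"])]

    @property
    def retained_pc(self) -> str:
        """The system PC: response whose optimal model has the lowest gCV."""
        return str(self.best_row()["response"])

    def summary(self) -> str:
        lines = ["optimal model per response (by genuine CV):"]
        for pc in self.table["response"].unique():
            r = self.best_row(pc)
            thr = f", threshold={r['threshold_year']}" if r["threshold_year"] else ""
            lines.append(
                f"  {pc}: {r['model_type']} {r['stressor']}_{r['season']} "
                f"lag={r['lag']}  gCV={r['gcv']:.3f}  "
                f"var.expl={100 * r['variance_explained']:.1f}%{thr}"
            )
        lines.append(f"retained system PC: {self.retained_pc}")
        return "\n".join(lines)
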