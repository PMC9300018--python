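"""Resilience quantification on a folded stability landscape.

Once the optimal threshold GAM is identified, its two fitted branches are
taken as the attractors of a fold bifurcation on standardized axes
(driver x, community state z, both mean 0 / SD 1). For every year y,

    v_y = |z_y - attractor_r(x_y)|      vertical distance to its attractor
    h_y = |x_y - x_F(r)|                horizontal distance to the tipping
                                        point of its regime r
    Res_y = h_y - v_y                   annual ecological resilience
    rRes_y = Res_y / max_y Res_y        relative resilience in [0, 1]

The tipping-point x-coordinate x_F of each regime is calibrated so the
lowest Res_y inside the regime equals exactly zero, with x_F placed on the
declared side of the regime's driver range (the end of the attractor that
points toward the other regime's basin). Attractors evaluate the fitted
branch inside its observed stressor range and extend linearly beyond it
with the boundary slope. The stability landscape is the triangulation-based
linear interpolation of all rRes_y values onto a 100 x 100 grid over the
observed (x, z) plane; cells outside the convex hull are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from scipy.spatial import QhullError

from .threshold_models import TGAMResults

__all__ = [
    "standardize_axes",
    "Attractor",
    "build_attractors",
    "compute_resilience",
    "stability_landscape",
    "ResilienceAssessment",
    "ResilienceResult",
]

GRID_SIZE = 100


def standardize_axes(z: pd.Series, x: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Center and scale both series to mean 0 / SD 1 over shared years."""
    if not z.index.equals(x.index):
        raise ValueError("state and stressor series must share the same years")
    out = []
    for s in (z, x):
        sd = s.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"constant series cannot be standardized: {s.name}")
        out.append((s - s.mean()) / sd)
    return out[0], out[1]


@dataclass(frozen=True)
class Attractor:
    """A fitted TGAM branch with linear extension beyond its x-range."""

    branch: object  # SplineFit
    x_min: float
    x_max: float
    regime: int

    def __call__(self, x) -> np.ndarray:
        # the natural cubic spline is already linear beyond its boundary
        # knots, so evaluation handles the extension with the end slope
        return self.branch.predict(x)

    def end_slope(self, side: str, eps: float = 1e-6) -> float:
        x0 = self.x_min if side == "low" else self.x_max
        return float(self.branch.derivative(np.array([x0 + (eps if side == "low" else -eps)]))[0])


def build_attractors(fit: TGAMResults) -> dict[int, Attractor]:
    """Per-regime attractor functions from an optimal TGAM.

    Requires a TGAM fitted on standardized axes (the branches *are* the
    attractors; a continuous GAM has no fold to quantify resilience on).
    """
    if getattr(fit, "model_type", None) != "TGAM":
        raise TypeError("attractors are defined by a TGAM fit, got "
                        f"{getattr(fit, 'model_type', type(fit).__name__)}")
    out = {}
    for r in (0, 1):
        mask = fit.regime_of(fit.frame.years) == r
        xs = fit.frame.stressor[mask]
        out[r] = Attractor(fit.branches[r], float(xs.min()), float(xs.max()), r)
    return out


def _calibrate_tipping(x: np.ndarray, v: np.ndarray, side: str) -> float:
    """x_F such that min_y (|x_y - x_F| - v_y) = 0 on the declared side.

    side='low_x' places the tipping point at/below the regime's states:
    x_F = min(x_y - v_y); side='high_x' symmetrically x_F = max(x_y + v_y).
    Every year then has Res_y >= 0 with the minimum exactly zero.
    """
    if side == "low_x":
        return float(np.min(x - v))
    elif side == "high_x":
        return float(np.max(x + v))
    raise ValueError(f"tipping side must be 'low_x' or 'high_x', got {side!r}")


def infer_tipping_sides(x: np.ndarray, z: np.ndarray, regimes: np.ndarray) -> dict[int, str]:
    """Default tipping-side rule from the state offset between regimes.

    In a fold, the branch at higher state loses stability at the low-driver
    end and the lower branch at the high-driver end (the regime-shift
    pathway of the classic backward-folded response curve).
    """
    z0 = z[regimes == 0].mean()
    z1 = z[regimes == 1].mean()
    if z0 >= z1:
        return {0: "low_x", 1: "high_x"}
    return {0: "high_x", 1: "low_x"}


@dataclass
class ResilienceResult:
    """Per-year resilience table, per-regime tipping points and landscape."""

    per_year: pd.DataFrame  # year-indexed: regime, x, z, v, h, res, rres
    tipping_points: dict[int, float]
    tipping_sides: dict[int, str]
    attractors: dict[int, Attractor]
    excluded_years: list
    exclusion_reasons: dict = field(default_factory=dict)
    landscape: np.ndarray | None = None  # (100, 100), NaN outside hull
    landscape_x: np.ndarray | None = None
    landscape_z: np.ndarray | None = None

    @property
    def res(self) -> pd.Series:
        return self.per_year["res"]

    @property
    def rres(self) -> pd.Series:
        return self.per_year["rres"]

    def summary(self) -> str:
        lines = ["resilience assessment (standardized axes):"]
        for r, xf in sorted(self.tipping_points.items()):
            lines.append(f"  regime {r}: tipping x_F = {xf:+.3f} ({self.tipping_sides[r]})")
        lines.append(f"  max Res_y = {self.per_year['res'].max():.3f} "
                     f"(rRes max = {self.per_year['rres'].max():.3f})")
        if self.excluded_years:
            lines.append(f"  excluded years: {self.excluded_years}")
        return "\n".join(lines)


def compute_resilience(
    x: pd.Series,
    z: pd.Series,
    regimes: pd.Series,
    attractors: dict[int, Attractor],
    tipping_sides: dict[int, str] | None = None,
    excluded_years: list | None = None,
    exclusion_reasons: dict | None = None,
) -> ResilienceResult:
    """Annual resilience from standardized states, attractors and tipping.

    Excluded years (expert judgement, e.g. the tail of an older state)
    carry no resilience value and enter neither the tipping calibration nor
    the rRes maximum.
    """
    excluded_years = list(excluded_years or [])
    years = np.asarray(x.index)
    xv = x.to_numpy(dtype=float)
    zv = z.to_numpy(dtype=float)
    reg = regimes.to_numpy()
    included = ~np.isin(years, excluded_years)

    uniq = np.unique(reg[included])
    if uniq.size < 2:
        raise ValueError("need at least 2 regimes with non-excluded years")
    for r in uniq:
        if np.sum(included & (reg == r)) < 2:
            raise ValueError(f"regime {r} has fewer than 2 non-excluded years")

    if tipping_sides is None:
        tipping_sides = infer_tipping_sides(xv[included], zv[included], reg[included])

    v = np.abs(zv - np.concatenate([
        np.atleast_1d(attractors[int(r)](np.array([xx]))) for r, xx in zip(reg, xv)
    ]))

    tipping = {}
    for r in uniq:
        m = included & (reg == r)
        xf = _calibrate_tipping(xv[m], v[m], tipping_sides[int(r)])
        tipping[int(r)] = xf

    h = np.array([abs(xx - tipping[int(r)]) for r, xx in zip(reg, xv)])
    res = h - v
    res[~included] = np.nan
    h_out = h.copy()
    h_out[~included] = np.nan
    res_max = np.nanmax(res)
    if res_max <= 0:
        raise ValueError("maximum resilience is not positive; tipping calibration infeasible")
    rres = res / res_max

    per_year = pd.DataFrame(
        {"regime": reg, "x": xv, "z": zv, "v": np.where(included, v, np.nan),
         "h": h_out, "res": res, "rres": rres},
        index=pd.Index(years, name="year"),
    )
    return ResilienceResult(
        per_year=per_year, tipping_points=tipping, tipping_sides=dict(tipping_sides),
        attractors=attractors, excluded_years=excluded_years,
        exclusion_reasons=dict(exclusion_reasons or {}),
    )


def stability_landscape(result: ResilienceResult, grid_size: int = GRID_SIZE):
    """Linear interpolation of rRes_y onto a grid over the (x, z) plane.

    Triangulation-based (barycentric) interpolation; grid cells outside the
    convex hull of the observed annual states are NaN. Returns (grid,
    x_axis, z_axis) and stores them on the result.
    """
    py = result.per_year.dropna(subset=["rres"])
    pts = py[["x", "z"]].to_numpy()
    vals = py["rres"].to_numpy()
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 annual states to interpolate")
    gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_size)
    gz = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_size)
    XX, ZZ = np.meshgrid(gx, gz)
    try:
        grid = griddata(pts, vals, (XX, ZZ), method="linear")
    except QhullError as exc:
        raise ValueError(f"degenerate (collinear) annual states: {exc}") from exc
    if np.isnan(grid).all():
        raise ValueError("degenerate (collinear) annual states: empty triangulation")
    result.landscape = grid
    result.landscape_x = gx
    result.landscape_z = gz
    return grid, gx, gz


class ResilienceAssessment:
    """Model-style wrapper: from an optimal TGAM to a ResilienceResult.

    Standardizes the state and (lagged) stressor axes, refits the TGAM on
    those axes, builds attractors, calibrates tipping points and
    interpolates the landscape. ``fit()`` returns the results object.
    """

    def __init__(
        self,
        tgam: TGAMResults,
        tipping_sides: dict[int, str] | None = None,
        excluded_years: list | None = None,
        exclusion_reasons: dict | None = None,
        grid_size: int = GRID_SIZE,
    ):
        self.tgam = tgam
        self.tipping_sides = tipping_sides
        self.excluded_years = excluded_years or []
        self.exclusion_reasons = exclusion_reasons or {}
        self.grid_size = grid_size

    def fit(self) -> ResilienceResult:
        f = self.tgam.frame
        years = pd.Index(f.years, name="year")
        z = pd.Series(f.response, index=years, name="state")
        x = pd.Series(f.stressor, index=years, name="stressor")
        zs, xs = standardize_axes(z, x)

        # refit the branches on standardized axes so branch values and
        # distances live on the same scale
        from .threshold_models import LaggedFrame, ThresholdGAM

        frame = LaggedFrame(f.years, zs.to_numpy(), xs.to_numpy(), f.lag, f.stressor_name)
        tg = ThresholdGAM(frame, k=self.tgam.k, min_branch_years=self.tgam.min_branch_years,
                          candidates=[self.tgam.threshold_year]).fit()
        attractors = build_attractors(tg)
        regimes = pd.Series(tg.regime_of(f.years), index=years)
        result = compute_resilience(
            xs, zs, regimes, attractors,
            tipping_sides=self.tipping_sides,
            excluded_years=self.excluded_years,
            exclusion_reasons=self.exclusion_reasons,
        )
        stability_landscape(result, self.grid_size)
        return result
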