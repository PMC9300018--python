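"""Sequential t-test analysis of regime shifts (STARS) with a Regime Shift
Index and red-noise (AR(1)) prewhitening.

The detector walks along a yearly series maintaining a current-regime mean.
A new value departing from that mean by more than

    diff = t_crit(alpha, 2l - 2) * sqrt(2 * sigma_l^2 / l)

(with ``sigma_l^2`` the average variance of all l-year windows of the
series) flags a candidate shift year. The Regime Shift Index (RSI) then
accumulates the anomalies of the next ``l`` values beyond the critical
level, normalized by ``sigma_l * sqrt(l)``: if the cumulative sum stays
positive through the cut-off window the shift is confirmed (RSI > 0 stored
at the shift year), if it dips below zero the candidate is rejected and the
value is absorbed into the current regime.

Autocorrelated (red) series inflate the false-alarm rate, so the series can
first be prewhitened with a subsampling-based bias-corrected AR(1)
estimate: w_t = (x_t - rho * x_{t-1}) / (1 - rho), which preserves regime
means and hence step locations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["ShiftDetection", "estimate_ar1", "detect_shifts", "prewhiten"]


@dataclass
class ShiftDetection:
    years: np.ndarray
    series: np.ndarray
    cutoff_l: int
    alpha: float
    prewhiten: bool
    ar1_estimate: float
    ar1_method: str
    rsi: np.ndarray  # signed RSI, nonzero only at confirmed shift years
    shift_years: list  # [(year, sign)], strictly increasing years
    regime_means: np.ndarray  # current-regime mean assigned to each year
    diff: float
    warnings: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"STARS: l={self.cutoff_l}, alpha={self.alpha}, "
            f"prewhiten={self.prewhiten} (rho={self.ar1_estimate:.3f}, "
            f"{self.ar1_method})",
            f"critical departure diff={self.diff:.4f}",
        ]
        if self.shift_years:
            for y, s in self.shift_years:
                arrow = "up" if s > 0 else "down"
                lines.append(f"  shift at {y} ({arrow}), RSI={self.rsi[self.years == y][0]:+.3f}")
        else:
            lines.append("  no shifts detected")
        return "\n".join(lines)


def _ar1_ols(x: np.ndarray) -> float:
    """Lag-1 autocorrelation by least squares within one subsample."""
    x0, x1 = x[:-1], x[1:]
    xm = x.mean()
    denom = np.sum((x - xm) ** 2)
    if denom <= 0:
        return 0.0
    return float(np.sum((x0 - xm) * (x1 - xm)) / denom)


def estimate_ar1(
    series: np.ndarray,
    method: str = "ip4",
    subsample_m: int | None = None,
) -> float:
    """Bias-corrected lag-1 autocorrelation from overlapping subsamples.

    Each length-``m`` window of the series yields a least-squares lag-1
    estimate; the median over windows is bias-corrected (Marriott–Pope /
    Kendall expansion) and clipped to [0, 0.99]:

    - ``ols``: median, no correction;
    - ``mpk``: one correction step r + (1 + 3r)/m;
    - ``ip4``: the correction iterated four times (close to the solved
      inversion (m*r + 1)/(m - 3) for m > 3).

    Subsampling keeps step-like regime shifts from inflating the estimate.
    Constant series return 0 with a warning.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if subsample_m is None:
        subsample_m = min(n, max(6, math.ceil((n + 1) / 3)))
    m = int(subsample_m)
    if not 3 <= m <= n:
        raise ValueError(f"need series length >= subsample_m >= 3 (n={n}, m={m})")
    if np.ptp(x) == 0:
        warnings.warn("constant series: AR(1) estimate set to 0")
        return 0.0
    ests = [_ar1_ols(x[i : i + m]) for i in range(n - m + 1)]
    r = float(np.median(ests))
    if method == "ols":
        rc = r
    elif method == "mpk":
        rc = r + (1.0 + 3.0 * r) / m
    elif method == "ip4":
        rc = r
        for _ in range(4):
            rc = r + (1.0 + 3.0 * rc) / m
    else:
        raise ValueError(f"unknown AR(1) method: {method!r}")
    return float(np.clip(rc, 0.0, 0.99))


def prewhiten(series: np.ndarray, rho: float) -> np.ndarray:
    """Remove an AR(1) component while preserving regime means."""
    x = np.asarray(series, dtype=float).ravel()
    if rho == 0.0:
        return x.copy()
    w = x.copy()
    w[1:] = (x[1:] - rho * x[:-1]) / (1.0 - rho)
    return w


def detect_shifts(
    series,
    years=None,
    cutoff_l: int = 3,
    alpha: float = 0.05,
    prewhiten_flag: bool = True,
    ar1_method: str = "ip4",
    ar1_subsample_m: int | None = None,
    huber: float | None = None,
) -> ShiftDetection:
    """Run the sequential mean-shift test on a yearly series.

    ``huber`` is accepted for interface completeness (outlier
    down-weighting tuning constant); the default ``None`` applies weight 1
    to every value.
    """
    x_raw = np.asarray(series, dtype=float).ravel()
    n = x_raw.size
    if years is None:
        years = np.arange(n)
    years = np.asarray(years)
    l = int(cutoff_l)
    if n < 2 * l:
        raise ValueError(f"series length {n} < 2 * cutoff_l = {2 * l}")
    if huber is not None:
        raise NotImplementedError("Huber weighting is not implemented; use huber=None")

    warns: list[str] = []
    rho = 0.0
    if prewhiten_flag:
        if ar1_subsample_m is None:
            ar1_subsample_m = min(n, max(6, math.ceil((l + 1) / 3)))
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            rho = estimate_ar1(x_raw, method=ar1_method, subsample_m=ar1_subsample_m)
            warns.extend(str(w.message) for w in wrec)
        x = prewhiten(x_raw, rho)
    else:
        x = x_raw.copy()

    if np.ptp(x) == 0:
        return ShiftDetection(
            years, x_raw, l, alpha, prewhiten_flag, rho, ar1_method,
            np.zeros(n), [], np.full(n, x.mean()), 0.0, warns + ["constant series"],
        )

    # average variance of all l-year windows
    wins = np.lib.stride_tricks.sliding_window_view(x, l)
    sigma2_l = float(np.mean(np.var(wins, axis=1, ddof=1)))
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df=2 * l - 2))
    diff = t_crit * math.sqrt(2.0 * sigma2_l / l)
    norm = math.sqrt(sigma2_l) * math.sqrt(l)

    rsi = np.zeros(n)
    regime_means = np.zeros(n)
    shifts: list[tuple] = []

    cur_vals = list(x[:l])
    cur_mean = float(np.mean(cur_vals))
    regime_means[:l] = cur_mean

    i = l
    while i < n:
        xi = x[i]
        sign = 0
        if xi > cur_mean + diff:
            sign = +1
        elif xi < cur_mean - diff:
            sign = -1
        if sign == 0:
            cur_vals.append(xi)
            cur_mean = float(np.mean(cur_vals))
            regime_means[i] = cur_mean
            i += 1
            continue
        # candidate shift at year i: accumulate anomalies beyond the
        # critical level over the next l years (truncated at the end)
        level = cur_mean + sign * diff
        csum = 0.0
        confirmed = True
        for j in range(i, min(i + l, n)):
            csum += sign * (x[j] - level) / norm
            if csum < 0.0:
                confirmed = False
                break
        if confirmed:
            rsi[i] = sign * csum
            shifts.append((years[i], sign))
            cur_vals = [xi]  # new regime grows value by value from here
            cur_mean = xi
            regime_means[i] = cur_mean
            i += 1
        else:
            cur_vals.append(xi)
            cur_mean = float(np.mean(cur_vals))
            regime_means[i] = cur_mean
            i += 1

    return ShiftDetection(
        years, x_raw, l, alpha, prewhiten_flag, rho, ar1_method,
        rsi, shifts, regime_means, diff, warns,
    )
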