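"""Penalized natural cubic regression splines.

This is the smoother underneath the GAM/TGAM driver–response models: a
natural cubic spline parameterized by its values at a small set of knots
(Green & Silverman parameterisation), fitted by penalized least squares

    min_g ||y - A g||^2 + lam * g' K g

where ``A`` evaluates the natural interpolating spline at the data points
and ``K = Q R^{-1} Q'`` is the integrated squared second derivative. The
null space of ``K`` is the space of straight lines, so ``lam -> inf``
recovers the ordinary least-squares line, and the natural spline is exactly
linear beyond the boundary knots — which is what lets a fitted branch be
extended linearly along its end slope.

The smoothing parameter is chosen by minimizing the GCV score
``n * RSS / (n - edf)^2`` over a fixed logarithmic grid, with
``edf = tr(H)`` the effective degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasis", "SplineFit", "fit_penalized_spline"]

# log10(lambda) grid for GCV search; wide enough to reach both the
# interpolating and the straight-line limits at n ~ 26, k = 4
_LOG_LAM_GRID = np.linspace(-7.0, 9.0, 33)


def _knots_from_data(x: np.ndarray, k: int) -> np.ndarray:
    """Place ``k`` knots at quantiles of the unique covariate values."""
    ux = np.unique(x)
    k = min(k, ux.size)
    if k < 2:
        raise ValueError("need at least 2 distinct covariate values for a spline")
    # type-7 quantiles of the unique values, via direct interpolation
    pos = np.linspace(0.0, ux.size - 1.0, k)
    knots = np.interp(pos, np.arange(ux.size), ux)
    # quantiles of few unique values can coincide; fall back to unique values
    knots = np.unique(knots)
    if knots.size < 2:
        raise ValueError("degenerate knot sequence")
    return knots


@dataclass(frozen=True)
class SplineBasis:
    """Natural cubic spline basis on fixed knots, in value space.

    A coefficient vector ``g`` holds the spline's values at the knots; the
    interior second derivatives are the linear map ``gamma = R^{-1} Q' g``.
    """

    knots: np.ndarray
    _RinvQt: np.ndarray = field(repr=False)  # (k-2, k) map g -> gamma interior
    penalty: np.ndarray = field(repr=False)  # (k, k) K = Q R^{-1} Q'

    @classmethod
    def from_knots(cls, knots: np.ndarray) -> "SplineBasis":
        t = np.asarray(knots, dtype=float)
        k = t.size
        if k == 2:
            return cls(t, np.zeros((0, 2)), np.zeros((2, 2)))
        h = np.diff(t)
        Q = np.zeros((k, k - 2))
        R = np.zeros((k - 2, k - 2))
        for j in range(1, k - 1):
            c = j - 1
            Q[j - 1, c] = 1.0 / h[j - 1]
            Q[j, c] = -1.0 / h[j - 1] - 1.0 / h[j]
            Q[j + 1, c] = 1.0 / h[j]
            R[c, c] = (h[j - 1] + h[j]) / 3.0
            if j < k - 2:
                R[c, c + 1] = R[c + 1, c] = h[j] / 6.0
        RinvQt = np.linalg.solve(R, Q.T)
        K = Q @ RinvQt
        # enforce exact symmetry against round-off
        K = 0.5 * (K + K.T)
        return cls(t, RinvQt, K)

    @property
    def n_params(self) -> int:
        return self.knots.size

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        """Rows evaluate the natural spline (values ``g``) at each ``x``.

        Points beyond the boundary knots are extended linearly with the
        boundary slope, as the natural spline itself does.
        """
        x = np.asarray(x, dtype=float)
        t = self.knots
        k = t.size
        n = x.size
        Wg = np.zeros((n, k))  # weights on knot values
        Wgam = np.zeros((n, k - 2))  # weights on interior second derivatives
        h = np.diff(t)

        xc = np.clip(x, t[0], t[-1])
        j = np.clip(np.searchsorted(t, xc, side="right") - 1, 0, k - 2)
        d = xc - t[j]  # distance from left knot
        u = t[j + 1] - xc  # distance to right knot
        hj = h[j]
        rows = np.arange(n)
        Wg[rows, j] += u / hj
        Wg[rows, j + 1] += d / hj
        if k > 2:
            cub = d * u / 6.0
            wl = -cub * (1.0 + u / hj)  # weight on gamma_j
            wr = -cub * (1.0 + d / hj)  # weight on gamma_{j+1}
            # gamma_0 and gamma_{k-1} are zero (natural); interior index j-1
            inner_l = (j >= 1) & (j <= k - 2)
            Wgam[rows[inner_l], j[inner_l] - 1] += wl[inner_l]
            inner_r = j + 1 <= k - 2
            Wgam[rows[inner_r], j[inner_r]] += wr[inner_r]

        # linear extension beyond the boundary knots
        lo = x < t[0]
        if np.any(lo):
            dx = x[lo] - t[0]
            Wg[lo, 0] += -dx / h[0]
            Wg[lo, 1] += dx / h[0]
            if k > 2:
                Wgam[lo, 0] += -dx * h[0] / 6.0
        hi = x > t[-1]
        if np.any(hi):
            dx = x[hi] - t[-1]
            Wg[hi, k - 2] += -dx / h[-1]
            Wg[hi, k - 1] += dx / h[-1]
            if k > 2:
                Wgam[hi, k - 3] += dx * h[-1] / 6.0

        if k == 2:
            return Wg
        return Wg + Wgam @ self._RinvQt


@dataclass
class SplineFit:
    """A fitted penalized spline: callable prediction plus fit diagnostics."""

    basis: SplineBasis | None
    coef: np.ndarray  # values at knots (or [mean] for the constant fallback)
    lam: float
    edf: float
    rss: float
    gcv_score: float
    fitted: np.ndarray
    n_obs: int

    def predict(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.basis is None:
            return np.full(x.shape, self.coef[0])
        return self.basis.design_matrix(x) @ self.coef

    def derivative(self, x, eps: float = 1e-6) -> np.ndarray:
        """Central-difference first derivative of the fitted curve."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return (self.predict(x + eps) - self.predict(x - eps)) / (2.0 * eps)


def _constant_fit(y: np.ndarray) -> SplineFit:
    mu = float(np.mean(y))
    fitted = np.full(y.shape, mu)
    rss = float(np.sum((y - fitted) ** 2))
    n = y.size
    denom = max(n - 1.0, 1e-12)
    return SplineFit(None, np.array([mu]), np.inf, 1.0, rss, n * rss / denom**2, fitted, n)


def fit_penalized_spline(
    x: np.ndarray,
    y: np.ndarray,
    k: int = 4,
    lam: float | None = None,
) -> SplineFit:
    """Fit a penalized natural cubic spline of ``y`` on ``x``.

    Parameters
    ----------
    k
        Basis dimension (number of knots), default 4 — deliberately small
        because the regime-shift models are fitted to ~26 yearly values
        (or 5–21 per TGAM branch).
    lam
        Fixed smoothing parameter. ``None`` selects it by GCV;
        ``numpy.inf`` gives the ordinary least-squares straight line.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 2 or np.unique(x).size < 2:
        return _constant_fit(y)

    if lam is not None and np.isinf(lam):
        # straight-line limit, computed exactly
        X = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        rss = float(np.sum((y - fitted) ** 2))
        basis = SplineBasis.from_knots(np.array([x.min(), x.max()], dtype=float))
        g = beta[0] + beta[1] * basis.knots
        edf = 2.0
        gcv = n * rss / max(n - edf, 1e-12) ** 2
        return SplineFit(basis, g, np.inf, edf, rss, gcv, fitted, n)

    knots = _knots_from_data(x, k)
    basis = SplineBasis.from_knots(knots)
    A = basis.design_matrix(x)
    K = basis.penalty

    AtA = A.T @ A
    Aty = A.T @ y
    yty = float(y @ y)
    p = AtA.shape[0]
    # simultaneous diagonalisation of (AtA, K): lets the lambda sweep run in
    # O(p) per value.  Tiny ridge keeps the Cholesky well posed when A is
    # column-rank deficient (few distinct x per branch).
    ridge = 1e-9 * max(np.trace(AtA) / p, 1.0)
    L = np.linalg.cholesky(AtA + ridge * np.eye(p))
    Linv = np.linalg.inv(L)
    C = Linv @ K @ Linv.T
    s, V = np.linalg.eigh(0.5 * (C + C.T))
    s = np.clip(s, 0.0, None)
    c = V.T @ (Linv @ Aty)

    c2 = c * c

    def solve_for(lmb: float):
        w = 1.0 / (1.0 + lmb * s)
        rss = yty - 2.0 * float(w @ c2) + float((w * w) @ c2)
        edf = float(w.sum())
        g = Linv.T @ (V @ (w * c))
        return max(rss, 0.0), edf, g

    if lam is None:
        # vectorized GCV sweep over the whole lambda grid
        W = 1.0 / (1.0 + np.outer(10.0**_LOG_LAM_GRID, s))
        rss_v = yty - 2.0 * (W @ c2) + (W * W) @ c2
        edf_v = W.sum(axis=1)
        denom = n - edf_v
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(denom > 1e-8, n * np.maximum(rss_v, 0.0) / denom**2, np.inf)
        lam = float(10.0 ** _LOG_LAM_GRID[int(np.argmin(scores))])

    rss, edf, g = solve_for(lam)
    denom = max(n - edf, 1e-12)
    gcv = n * rss / denom**2
    fitted = A @ g
    return SplineFit(basis, g, float(lam), edf, rss, gcv, fitted, n)
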