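"""Penalized thin-plate regression spline smooths with GCV selection.

Smooth environmental response curves — alr-transformed cover against water
depth, substrate slope, or light — are fitted as one-dimensional thin-plate
regression splines with a normal error structure and identity link.  The
smoothing penalty is chosen by generalized cross-validation,

    GCV(lambda) = n * RSS(lambda) / (n - tr H(lambda))^2,

minimized over a 61-point log-spaced grid on [1e-6, 1e6] followed by
golden-section refinement.  Fitted alr curves are back-transformed to
percent cover by inverse alr, normalization to 100%, and the 0.25% floor
(values below half the recording resolution are reported as 0).

The basis dimension ``k`` counts the intercept, the linear term, and k - 2
radial knots placed at quantiles of the distinct covariate values, so the
reported effective degrees of freedom (which exclude the intercept) range
from 1 (a straight line) to k - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .composition import FLOOR_PERCENT, AlrVector, inverse_alr

logger = logging.getLogger(__name__)

__all__ = ["SmoothFit", "fit_smooth", "predict_curve", "back_transform_curves"]


@dataclass
class SmoothFit:
    """A fitted 1-D thin-plate regression spline."""

    k: int
    lambda_: float
    edf: float                 # excludes the intercept
    gcv: float
    coefficients: np.ndarray   # [intercept, linear, spline...] on scaled x
    covariance: np.ndarray     # Bayesian covariance of the coefficients
    sigma2: float
    knots: np.ndarray          # on the scaled [0, 1] axis
    null_basis: np.ndarray     # maps spline coefficients to kernel weights
    x_min: float
    x_range: float

    def _design(self, x: np.ndarray) -> np.ndarray:
        t = (np.asarray(x, dtype=float) - self.x_min) / self.x_range
        e = np.abs(t[:, None] - self.knots[None, :]) ** 3
        return np.column_stack([np.ones_like(t), t, e @ self.null_basis])

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._design(x) @ self.coefficients

    def standard_error(self, x: np.ndarray) -> np.ndarray:
        c = self._design(x)
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", c, self.covariance, c), 0.0))


def _tprs_design(x01: np.ndarray, knots: np.ndarray):
    """Constrained thin-plate basis: [1, x, E @ Z] with penalty Z' E_k Z."""
    t_k = np.column_stack([np.ones_like(knots), knots])
    q, _ = np.linalg.qr(t_k, mode="complete")
    z = q[:, 2:]                                   # null space of the linear part
    e_k = np.abs(knots[:, None] - knots[None, :]) ** 3
    penalty = z.T @ e_k @ z
    penalty = 0.5 * (penalty + penalty.T)
    e_x = np.abs(x01[:, None] - knots[None, :]) ** 3
    design = np.column_stack([np.ones_like(x01), x01, e_x @ z])
    return design, penalty, z


def fit_smooth(
    x: np.ndarray, y: np.ndarray, k: int = 10, *, lam: float | None = None
) -> SmoothFit:
    """Fit a penalized thin-plate spline of ``y`` on ``x`` with GCV-chosen lambda.

    ``k`` is the basis dimension; it is reduced (with a warning) when the
    covariate has fewer than ``k`` distinct values, and at least 3 distinct
    values are required.  Passing ``lam`` skips GCV selection and fits at
    that fixed penalty (``lam=0`` is the unpenalized regression-spline fit;
    a very large ``lam`` approaches the least-squares straight line).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    distinct = np.unique(x)
    if distinct.size < 3:
        raise ValueError("need at least 3 distinct covariate values")
    if distinct.size < k:
        logger.warning(
            "basis dimension reduced from %d to %d (distinct covariate values)",
            k, distinct.size,
        )
        k = int(distinct.size)
    n = x.size
    if n <= k:
        raise ValueError(f"need n > k ({n} <= {k})")

    x_min = float(distinct[0])
    x_range = float(distinct[-1] - distinct[0])
    x01 = (x - x_min) / x_range
    d01 = (distinct - x_min) / x_range
    knots = np.unique(np.quantile(d01, np.linspace(0.0, 1.0, k - 2)))
    design, penalty, z = _tprs_design(x01, knots)
    p = design.shape[1]
    s_full = np.zeros((p, p))
    s_full[2:, 2:] = penalty
    ctc = design.T @ design
    cty = design.T @ y

    def solve(lam: float):
        a = ctc + lam * s_full
        try:
            ainv = np.linalg.inv(a)
        except np.linalg.LinAlgError:
            ainv = np.linalg.pinv(a)
        beta = ainv @ cty
        fitted = design @ beta
        rss = float(np.sum((y - fitted) ** 2))
        tr_h = float(np.trace(ctc @ ainv))
        return beta, ainv, rss, tr_h

    def gcv_of(log_lam: float) -> float:
        _, _, rss, tr_h = solve(10.0**log_lam)
        denom = n - tr_h
        return np.inf if denom <= 0 else n * rss / denom**2

    if lam is None:
        grid = np.linspace(-6.0, 6.0, 61)
        scores = np.array([gcv_of(g) for g in grid])
        i = int(np.argmin(scores))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        refine = minimize_scalar(gcv_of, bounds=(lo, hi), method="bounded")
        log_lam = float(refine.x) if refine.fun <= scores[i] else float(grid[i])
        lam = 10.0**log_lam

    beta, ainv, rss, tr_h = solve(lam)
    sigma2 = rss / max(n - tr_h, 1.0)
    return SmoothFit(
        k=k,
        lambda_=lam,
        edf=tr_h - 1.0,
        gcv=n * rss / (n - tr_h) ** 2,
        coefficients=beta,
        covariance=ainv * sigma2,
        sigma2=sigma2,
        knots=knots,
        null_basis=z,
        x_min=x_min,
        x_range=x_range,
    )


def predict_curve(fit: SmoothFit, grid: np.ndarray) -> pd.DataFrame:
    """Evaluate a smooth on a grid with pointwise 95% confidence bands.

    Grid points outside the observed covariate range are flagged as
    extrapolation (the band formula is still evaluated there).
    """
    grid = np.asarray(grid, dtype=float)
    fitted = fit.predict(grid)
    se = fit.standard_error(grid)
    t01 = (grid - fit.x_min) / fit.x_range
    extrapolated = (t01 < 0.0) | (t01 > 1.0)
    if extrapolated.any():
        logger.warning("%d grid points are outside the observed range", extrapolated.sum())
    return pd.DataFrame(
        {
            "x": grid,
            "fit": fitted,
            "se": se,
            "ci_low": fitted - 1.96 * se,
            "ci_high": fitted + 1.96 * se,
            "extrapolated": extrapolated,
        }
    )


def back_transform_curves(
    taxon_fits: dict[str, SmoothFit],
    grid: np.ndarray,
    total_fit: SmoothFit | None = None,
    *,
    floor_percent: float = FLOOR_PERCENT,
) -> pd.DataFrame:
    """Back-transform fitted alr curves to percent cover on a shared grid.

    Per grid point the taxon alr values (plus the other-benthic part at
    exp(0)) are inverse-alr transformed and normalized to 100%, then covers
    below ``floor_percent`` are set to 0 without re-normalization.  A
    ``total_fit`` is handled as the two-part total-vs-other case and reported
    in columns ``total``/``total_other``.
    """
    if not taxon_fits and total_fit is None:
        raise ValueError("no fits supplied")
    grid = np.asarray(grid, dtype=float)
    out: dict[str, np.ndarray] = {"x": grid}
    if taxon_fits:
        preds = {t: f.predict(grid) for t, f in taxon_fits.items()}
        names = list(taxon_fits) + ["other_benthic"]
        cols = {name: np.empty(grid.size) for name in names}
        for i in range(grid.size):
            vec = AlrVector(coords={t: float(preds[t][i]) for t in taxon_fits})
            percent = inverse_alr(vec, floor_percent=floor_percent)
            for name in names:
                cols[name][i] = percent[name]
        out.update(cols)
    if total_fit is not None:
        pred = total_fit.predict(grid)
        total = np.empty(grid.size)
        other = np.empty(grid.size)
        for i in range(grid.size):
            vec = AlrVector(coords={"total": float(pred[i])}, scope="total_only")
            percent = inverse_alr(vec, floor_percent=floor_percent)
            total[i], other[i] = percent["total"], percent["other_benthic"]
        out["total"] = total
        out["total_other"] = other
    return pd.DataFrame(out)
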