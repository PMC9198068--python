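"""Smooth pixel-level index surfaces via penalized tensor-product B-splines.

Cluster-level mean scores y at coordinates (lon, lat) are smoothed with a
2-D P-spline: cubic B-splines on equidistant knots in each coordinate,
tensor-product design B, and a second-order difference penalty applied as a
Kronecker sum.  Coefficients solve

    (B' W B + lambda * P) beta = B' W y,      W = diag(n_households),

which is also the posterior mean under a Gaussian partially improper prior
beta ~ N(0, sigma^2 / lambda * P^-), so a closed-form posterior covariance
gives pixel-wise prediction standard deviations.  The smoothing parameter
can be fixed or selected by generalized cross-validation on a log-spaced
grid.

With uniform knots the order-2 penalty has a four-dimensional null space
spanned by {1, lon, lat, lon*lat}: as lambda grows the surface shrinks to
the weighted least-squares fit in that bilinear family, and a constant fit
is never penalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.interpolate import BSpline

from .errors import DomainError, SchemaError, SingularSystemError
from .raster import DensityRaster

DEFAULT_N_KNOTS = 12  # interior knots per coordinate
DEFAULT_DEGREE = 3
DEFAULT_PENALTY_ORDER = 2


def _uniform_knots(lo: float, hi: float, n_interior: int, degree: int) -> np.ndarray:
    """Equidistant knot vector extended beyond [lo, hi] by `degree` knots each side.

    Uniform (unclamped) extension keeps Greville sites equidistant, so the
    difference penalty's null space is exactly the polynomial family it is
    meant to leave free.
    """
    h = (hi - lo) / (n_interior + 1)
    return lo + h * np.arange(-degree, n_interior + 2 + degree)


def _basis(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    lo, hi = knots[degree], knots[-degree - 1]
    x = np.asarray(x, dtype=float)
    if (x < lo).any() or (x > hi).any():
        raise DomainError(
            f"coordinates outside the spline domain [{lo:.6g}, {hi:.6g}]"
        )
    B = BSpline.design_matrix(x, knots, degree, extrapolate=False)
    return np.asarray(B.todense())


def _difference_penalty(n_basis: int, order: int) -> np.ndarray:
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


@dataclass
class PdiSurface:
    """Fitted tensor-product P-spline surface."""

    knots_lon: np.ndarray
    knots_lat: np.ndarray
    degree: int
    penalty_order: int
    lam: float
    coefficients: np.ndarray      # flat, C-order over (lon basis, lat basis)
    coef_cov: np.ndarray          # posterior covariance of the coefficients
    noise_variance: float
    edf: float                    # effective degrees of freedom of the fit
    gcv_score: float | None = None

    @property
    def n_basis(self) -> tuple[int, int]:
        return (
            len(self.knots_lon) - self.degree - 1,
            len(self.knots_lat) - self.degree - 1,
        )

    @property
    def domain(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) where the basis is complete."""
        d = self.degree
        return (
            float(self.knots_lon[d]), float(self.knots_lat[d]),
            float(self.knots_lon[-d - 1]), float(self.knots_lat[-d - 1]),
        )

    def design(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        Bx = _basis(np.asarray(lon, float), self.knots_lon, self.degree)
        By = _basis(np.asarray(lat, float), self.knots_lat, self.degree)
        return (Bx[:, :, None] * By[:, None, :]).reshape(len(Bx), -1)


def fit_surface(
    cluster_points: pd.DataFrame,
    n_knots: int = DEFAULT_N_KNOTS,
    degree: int = DEFAULT_DEGREE,
    penalty_order: int = DEFAULT_PENALTY_ORDER,
    lam: float | str = "auto",
    domain: tuple[float, float, float, float] | None = None,
    lambda_grid: np.ndarray | None = None,
) -> PdiSurface:
    """Fit the penalized surface to cluster mean scores.

    ``cluster_points`` needs columns lon, lat, mean_score and (optionally)
    n_households, which enters as the observation weight.  ``lam`` is a
    positive number or "auto" for GCV selection.  ``domain`` optionally
    fixes the spline domain (lon_min, lat_min, lon_max, lat_max); by
    default the data extent is used.
    """
    for col in ("lon", "lat", "mean_score"):
        if col not in cluster_points.columns:
            raise SchemaError(f"cluster_points lacks required column {col!r}")
    pts = cluster_points
    if len(pts) < 10:
        raise SchemaError(f"need at least 10 clusters to fit a surface, got {len(pts)}")
    lon = pts["lon"].to_numpy(float)
    lat = pts["lat"].to_numpy(float)
    if np.ptp(lon) == 0 or np.ptp(lat) == 0:
        raise SchemaError("clusters are collinear in one coordinate; "
                          "a 2-D surface cannot be identified")
    y = pts["mean_score"].to_numpy(float)
    w = (pts["n_households"].to_numpy(float)
         if "n_households" in pts.columns else np.ones(len(pts)))
    if (w <= 0).any():
        raise SchemaError("observation weights must be positive")

    if domain is None:
        domain = (lon.min(), lat.min(), lon.max(), lat.max())
    lon_min, lat_min, lon_max, lat_max = domain
    knots_lon = _uniform_knots(lon_min, lon_max, n_knots, degree)
    knots_lat = _uniform_knots(lat_min, lat_max, n_knots, degree)

    Bx = _basis(lon, knots_lon, degree)
    By = _basis(lat, knots_lat, degree)
    B = (Bx[:, :, None] * By[:, None, :]).reshape(len(lon), -1)
    nx, ny = Bx.shape[1], By.shape[1]
    P = (np.kron(_difference_penalty(nx, penalty_order), np.eye(ny))
         + np.kron(np.eye(nx), _difference_penalty(ny, penalty_order)))

    BtWB = (B * w[:, None]).T @ B
    BtWy = B.T @ (w * y)
    n = len(y)

    def solve(lam_val: float):
        A = BtWB + lam_val * P
        try:
            c, low = linalg.cho_factor(A)
        except linalg.LinAlgError as exc:
            raise SingularSystemError(
                f"penalized system singular at lambda={lam_val:g}; "
                "increase lambda or reduce the number of knots"
            ) from exc
        beta = linalg.cho_solve((c, low), BtWy)
        Ainv = linalg.cho_solve((c, low), np.eye(A.shape[0]))
        edf = float(np.trace(Ainv @ BtWB))
        resid = y - B @ beta
        rss = float(w @ resid ** 2)
        return beta, Ainv, edf, rss

    gcv_score = None
    if lam == "auto":
        grid = (np.logspace(-4, 8, 25) if lambda_grid is None
                else np.asarray(lambda_grid, float))
        best = None
        for lv in grid:
            beta, Ainv, edf, rss = solve(lv)
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lv, beta, Ainv, edf, rss)
        gcv_score, lam_sel, beta, Ainv, edf, rss = best
        lam = lam_sel
    else:
        lam = float(lam)
        if lam <= 0:
            raise SchemaError("lambda must be positive")
        beta, Ainv, edf, rss = solve(lam)

    dof = max(n - edf, 1.0)
    noise_variance = max(rss / dof, 1e-12)
    return PdiSurface(
        knots_lon=knots_lon, knots_lat=knots_lat, degree=degree,
        penalty_order=penalty_order, lam=float(lam),
        coefficients=beta, coef_cov=noise_variance * Ainv,
        noise_variance=noise_variance, edf=edf, gcv_score=gcv_score,
    )


def predict_points(surface: PdiSurface, lon, lat,
                   return_sd: bool = False):
    """Posterior mean (and optionally sd) of the surface at arbitrary points."""
    Bg = surface.design(np.atleast_1d(lon), np.atleast_1d(lat))
    mean = Bg @ surface.coefficients
    if not return_sd:
        return mean
    var = np.einsum("ij,jk,ik->i", Bg, surface.coef_cov, Bg)
    return mean, np.sqrt(np.maximum(var, 0.0))


def predict_grid(
    surface: PdiSurface,
    origin_lon: float,
    origin_lat: float,
    cell_size: float,
    n_rows: int,
    n_cols: int,
) -> tuple[DensityRaster, DensityRaster]:
    """Evaluate the surface on a regular grid of cell centers.

    The grid follows the package raster convention (row 0 = northernmost;
    origin at the upper-left corner).  Returns (mean, sd) grids as raster
    objects; any cell center outside the spline domain raises.
    """
    lons = origin_lon + (np.arange(n_cols) + 0.5) * cell_size
    lats = origin_lat - (np.arange(n_rows) + 0.5) * cell_size
    glon, glat = np.meshgrid(lons, lats)
    mean, sd = predict_points(surface, glon.ravel(), glat.ravel(), return_sd=True)
    mk = dict(origin_lon=origin_lon, origin_lat=origin_lat, cell_size=cell_size)
    return (
        DensityRaster(values=mean.reshape(n_rows, n_cols), **mk),
        DensityRaster(values=sd.reshape(n_rows, n_cols), **mk),
    )


def normalize_surface(grid: DensityRaster,
                      domain: tuple[float, float] | None = None) -> DensityRaster:
    """Min-max normalize a mean grid to [0, 1] (constant grids are an error)."""
    from .aggregation import normalize

    return DensityRaster(
        origin_lon=grid.origin_lon, origin_lat=grid.origin_lat,
        cell_size=grid.cell_size,
        values=normalize(grid.values.ravel(), domain).reshape(grid.values.shape),
        nodata=grid.nodata,
    )
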