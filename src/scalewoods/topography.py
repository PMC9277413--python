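"""Kriged elevation trend surface and per-quadrat terrain covariates.

Elevation measured at grid corners is interpolated by ordinary kriging with
an exponential semivariogram and zero nugget, which makes the surface an
exact interpolator at the corners.  Per-quadrat terrain is derived from the
kriged elevations of the quadrat centre and its four corners:

* ``E``   -- mean of the five elevations (m),
* ``SLO`` -- for each of the four corner triples, the unique plane through
  them is tilted at some angle to the horizontal; SLO is the mean of the
  four angles (degrees),
* ``ASP`` -- azimuth, clockwise from north, of the steepest-descent
  direction of each triple's plane, averaged circularly (degrees); 0 by
  convention on flat terrain,
* ``CE = cos(ASP) * ln(E)`` and ``SLC = tan(SLO) * cos(ASP)``, the two
  composite covariates entering the productivity model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import curve_fit

from .sampling import Quadrat
from .synthetic import ElevationGrid


def _exponential_variogram(h: np.ndarray, sill: float, rng_param: float) -> np.ndarray:
    return sill * (1.0 - np.exp(-np.asarray(h, float) / rng_param))


@dataclass
class TrendSurface:
    """Fitted ordinary-kriging interpolator over the corner elevations."""

    points: np.ndarray          # (n, 2) corner coordinates
    values: np.ndarray          # (n,) corner elevations
    sill: float
    range_: float
    nugget: float = 0.0
    _lu: tuple = None

    def __post_init__(self) -> None:
        n = len(self.points)
        if self.sill <= 0:
            return  # constant field; predict() short-circuits
        d = np.linalg.norm(self.points[:, None, :] - self.points[None, :, :], axis=-1)
        gamma = _exponential_variogram(d, self.sill, self.range_)
        gamma[np.diag_indices_from(gamma)] += self.nugget
        a = np.empty((n + 1, n + 1))
        a[:n, :n] = gamma
        a[n, :] = 1.0
        a[:, n] = 1.0
        a[n, n] = 0.0
        self._lu = lu_factor(a)

    def predict(self, xy: np.ndarray) -> np.ndarray:
        """Kriged elevation at the given (x, y) points (any shape (m, 2))."""
        xy = np.atleast_2d(np.asarray(xy, float))
        n = len(self.points)
        if self.sill <= 0:
            return np.full(len(xy), float(self.values.mean()))
        d = np.linalg.norm(xy[:, None, :] - self.points[None, :, :], axis=-1)
        b = np.empty((n + 1, len(xy)))
        b[:n] = _exponential_variogram(d, self.sill, self.range_).T
        b[n] = 1.0
        lam = lu_solve(self._lu, b)
        return lam[:n].T @ self.values


def empirical_variogram(points: np.ndarray, values: np.ndarray,
                        n_lags: int = 15) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned semivariances up to half the maximum pair distance."""
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    iu = np.triu_indices_from(d, k=1)
    dist = d[iu]
    gam = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    hmax = dist.max() / 2.0
    edges = np.linspace(0, hmax, n_lags + 1)
    idx = np.digitize(dist, edges) - 1
    keep = (idx >= 0) & (idx < n_lags)
    counts = np.bincount(idx[keep], minlength=n_lags)
    lag_gamma = np.bincount(idx[keep], weights=gam[keep], minlength=n_lags)
    lag_dist = np.bincount(idx[keep], weights=dist[keep], minlength=n_lags)
    ok = counts > 0
    return lag_dist[ok] / counts[ok], lag_gamma[ok] / counts[ok], counts[ok]


def fit_kriging_surface(grid: ElevationGrid) -> TrendSurface:
    """Fit zero-nugget exponential-variogram ordinary kriging to grid corners.

    The variogram is fitted by count-weighted least squares to the binned
    empirical semivariogram.  A constant field yields a degenerate (constant)
    surface rather than a fit error.
    """
    tbl = grid.corner_table()
    points = tbl[["x_m", "y_m"]].to_numpy(float)
    values = tbl["z_m"].to_numpy(float)
    if len(points) < 10:
        raise ValueError("need at least 10 corners to fit a trend surface")
    if np.allclose(points, points[0]):
        raise ValueError("degenerate corner coordinates")
    var = values.var()
    if var < 1e-12:
        return TrendSurface(points, values, sill=0.0, range_=1.0)

    h, gam, counts = empirical_variogram(points, values)
    hmax = h.max()
    p0 = (max(gam.max(), 1e-9), max(hmax / 3.0, grid.spacing))
    try:
        popt, _ = curve_fit(
            _exponential_variogram, h, gam, p0=p0,
            sigma=1.0 / np.sqrt(counts), absolute_sigma=False,
            bounds=([1e-12, grid.spacing / 10.0], [np.inf, np.inf]),
            maxfev=10000,
        )
        sill, rng_param = popt
    except RuntimeError:
        sill, rng_param = p0
    return TrendSurface(points, values, sill=float(sill), range_=float(rng_param))


def _triple_planes(corners_xy: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Gradients (dz/dx, dz/dy) of the planes through each corner triple.

    ``corners_xy`` is the 4 x 2 corner array, ``z`` the matching elevations.
    Returns a 4 x 2 array, one gradient per omitted corner.
    """
    grads = np.empty((4, 2))
    for k in range(4):
        idx = [i for i in range(4) if i != k]
        p = corners_xy[idx]
        a = np.column_stack([np.ones(3), p])
        coef = np.linalg.solve(a, z[idx])  # z = c + bx*x + by*y
        grads[k] = coef[1:]
    return grads


def _slope_deg(grad: np.ndarray) -> np.ndarray:
    return np.degrees(np.arctan(np.hypot(grad[..., 0], grad[..., 1])))


def _aspect_deg(grad: np.ndarray) -> np.ndarray:
    """Azimuth of steepest descent, clockwise from north (+y)."""
    return np.degrees(np.arctan2(-grad[..., 0], -grad[..., 1])) % 360.0


def circular_mean_deg(angles: np.ndarray) -> float:
    """Circular mean of azimuths in degrees, result in [0, 360)."""
    rad = np.radians(np.asarray(angles, float))
    return float(np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))) % 360.0)


FLAT_SLOPE_DEG = 1e-6


def quadrat_elevation(surface: TrendSurface, quadrat: Quadrat) -> float:
    """Mean kriged elevation of the quadrat centre and four corners (m)."""
    pts = np.vstack([[quadrat.cx, quadrat.cy], quadrat.corners()])
    return float(surface.predict(pts).mean())


def quadrat_slope(surface: TrendSurface, quadrat: Quadrat) -> float:
    """Mean inclination (degrees) of the four corner-triple planes."""
    z = surface.predict(quadrat.corners())
    grads = _triple_planes(quadrat.corners(), z)
    return float(_slope_deg(grads).mean())


def quadrat_aspect(surface: TrendSurface, quadrat: Quadrat) -> float:
    """Circular-mean steepest-descent azimuth (degrees from north).

    Returns 0 by convention when the quadrat is essentially flat.
    """
    z = surface.predict(quadrat.corners())
    grads = _triple_planes(quadrat.corners(), z)
    slopes = _slope_deg(grads)
    if slopes.mean() < FLAT_SLOPE_DEG:
        return 0.0
    return circular_mean_deg(_aspect_deg(grads))


def ce(asp_deg: float, elevation_m: float) -> float:
    """Composite aspect-elevation covariate cos(ASP) * ln(E)."""
    if elevation_m <= 0:
        raise ValueError("elevation must be positive for ln(E)")
    return float(np.cos(np.radians(asp_deg)) * np.log(elevation_m))


def slc(slo_deg: float, asp_deg: float) -> float:
    """Composite slope-aspect covariate tan(SLO) * cos(ASP)."""
    if not 0.0 <= slo_deg < 90.0:
        raise ValueError("slope must lie in [0, 90) degrees")
    return float(np.tan(np.radians(slo_deg)) * np.cos(np.radians(asp_deg)))


def quadrat_topography(surface: TrendSurface, quadrat: Quadrat) -> dict[str, float]:
    """E, SLO, ASP, CE and SLC for one quadrat."""
    pts = np.vstack([[quadrat.cx, quadrat.cy], quadrat.corners()])
    z = surface.predict(pts)
    return topo_from_z5(quadrat.corners(), z)


def topo_from_z5(corners_xy: np.ndarray, z5: np.ndarray) -> dict[str, float]:
    """Terrain covariates from precomputed centre+corner elevations.

    ``z5`` holds the centre elevation first, then the four corners in the
    order returned by :meth:`Quadrat.corners`.
    """
    e = float(np.mean(z5))
    grads = _triple_planes(corners_xy, z5[1:])
    slopes = _slope_deg(grads)
    slo = float(slopes.mean())
    asp = 0.0 if slo < FLAT_SLOPE_DEG else circular_mean_deg(_aspect_deg(grads))
    return {"E": e, "SLO": slo, "ASP": asp, "CE": ce(asp, e), "SLC": slc(slo, asp)}
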