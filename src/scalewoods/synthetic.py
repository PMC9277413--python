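"""Seeded synthetic stem-mapped forest plots with two censuses.

The generator produces the statistical structure the downstream analysis
assumes rather than any particular real forest:

* a spatially autocorrelated elevation surface sampled at 20-m grid corners,
* species abundances following a geometric series, stems clustered by a
  Thomas process (Poisson cluster centres, Gaussian dispersal),
* diameters from a Weibull distribution truncated at the 1-cm census limit,
* five-year diameter growth with size, crowding and elevation effects plus a
  spatially correlated lognormal noise field whose short correlation range
  makes quadrat productivity noisy at fine grains and stable at coarse ones,
* density-dependent mortality and uniform recruitment.

Identical configurations (including the seed) give byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .config import SyntheticConfig

logger = logging.getLogger(__name__)

STEM_COLUMNS = ["tag", "species", "x_m", "y_m", "dbh1_cm", "h1_m", "dbh2_cm", "h2_m", "status"]

STATUS_ALIVE_BOTH = "alive-both"
STATUS_DIED = "died"
STATUS_RECRUITED = "recruited"


@dataclass
class ElevationGrid:
    """Corner elevations on a regular grid covering the plot.

    ``z`` has shape (ny, nx); ``z[j, i]`` is the elevation at
    x = i * spacing, y = j * spacing.
    """

    spacing: float
    nx: int
    ny: int
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (self.ny, self.nx):
            raise ValueError(f"z shape {self.z.shape} != (ny={self.ny}, nx={self.nx})")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("elevations must be finite")

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.nx) * self.spacing

    @property
    def y(self) -> np.ndarray:
        return np.arange(self.ny) * self.spacing

    @property
    def n_cells(self) -> int:
        return (self.nx - 1) * (self.ny - 1)

    def corner_table(self) -> pd.DataFrame:
        jj, ii = np.meshgrid(np.arange(self.ny), np.arange(self.nx), indexing="ij")
        return pd.DataFrame(
            {
                "i": ii.ravel(),
                "j": jj.ravel(),
                "x_m": ii.ravel() * self.spacing,
                "y_m": jj.ravel() * self.spacing,
                "z_m": self.z.ravel(),
            }
        )

    @classmethod
    def from_corner_table(cls, df: pd.DataFrame) -> "ElevationGrid":
        nx = int(df["i"].max()) + 1
        ny = int(df["j"].max()) + 1
        spacing = float(df.loc[df["i"] == 1, "x_m"].iloc[0]) if nx > 1 else float(
            df.loc[df["j"] == 1, "y_m"].iloc[0]
        )
        z = np.full((ny, nx), np.nan)
        z[df["j"].to_numpy(int), df["i"].to_numpy(int)] = df["z_m"].to_numpy(float)
        return cls(spacing=spacing, nx=nx, ny=ny, z=z)

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator((self.y, self.x), self.z, method="linear")


def generate_elevation_grid(config: SyntheticConfig) -> ElevationGrid:
    """Sample a smooth elevation surface at the grid corners.

    The surface is a base elevation plus a long-wavelength sinusoidal trend
    plus a Gaussian random field with exponential covariance of range
    ``elev_range``; trend and field amplitudes scale with ``elev_amplitude``
    so the realized relief is roughly twice that amplitude.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    nx = int(round(config.plot_x / config.grid_spacing)) + 1
    ny = int(round(config.plot_y / config.grid_spacing)) + 1
    x = np.arange(nx) * config.grid_spacing
    y = np.arange(ny) * config.grid_spacing
    xx, yy = np.meshgrid(x, y)

    amp = config.elev_amplitude
    trend = 0.6 * amp * np.sin(2 * np.pi * xx / config.plot_x) + 0.4 * amp * np.cos(
        np.pi * yy / config.plot_y
    )

    field = np.zeros_like(xx)
    sd = 0.25 * amp
    if sd > 0:
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        cov = sd**2 * np.exp(-d / config.elev_range)
        cov[np.diag_indices_from(cov)] += 1e-8
        chol = np.linalg.cholesky(cov)
        field = (chol @ rng.standard_normal(pts.shape[0])).reshape(xx.shape)

    return ElevationGrid(spacing=config.grid_spacing, nx=nx, ny=ny,
                         z=config.elev_base + trend + field)


def _truncated_weibull(rng: np.random.Generator, shape: float, scale: float,
                       lower: float, size: int) -> np.ndarray:
    # inverse-CDF sampling conditioned on X >= lower
    u = rng.random(size)
    s_lo = np.exp(-((lower / scale) ** shape))
    return scale * (-np.log(u * s_lo)) ** (1.0 / shape)


def stem_height(dbh: np.ndarray, params: tuple[float, float]) -> np.ndarray:
    """Height (m) from the standard power-law height-diameter model."""
    a, b = params
    return 1.3 + a * np.asarray(dbh, float) ** b


def geometric_abundances(n_species: int, k: float) -> np.ndarray:
    """Expected relative abundances of a geometric (niche-preemption) series."""
    if n_species == 1:
        return np.ones(1)
    p = k * (1 - k) ** np.arange(n_species)
    return p / p.sum()


def generate_stem_map(config: SyntheticConfig, grid: ElevationGrid) -> pd.DataFrame:
    """Generate the census-1 stem map.

    Species abundances follow a geometric series; within each species stems
    follow a Thomas cluster process (torus-wrapped so intensity stays uniform)
    thinned to the configured total density; DBH is Weibull truncated at 1 cm.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    area = config.plot_x * config.plot_y
    rel = geometric_abundances(config.n_species, config.abundance_k)

    xs, ys, sp = [], [], []
    for s in range(config.n_species):
        n_expect = config.stem_density * area * rel[s]
        n_parents = rng.poisson(max(n_expect / config.cluster_mean_offspring, 1e-12))
        if n_parents == 0:
            continue
        px = rng.uniform(0, config.plot_x, n_parents)
        py = rng.uniform(0, config.plot_y, n_parents)
        n_off = rng.poisson(config.cluster_mean_offspring, n_parents)
        total = int(n_off.sum())
        if total == 0:
            continue
        ox = np.repeat(px, n_off) + rng.normal(0, config.cluster_sd, total)
        oy = np.repeat(py, n_off) + rng.normal(0, config.cluster_sd, total)
        xs.append(np.mod(ox, config.plot_x))
        ys.append(np.mod(oy, config.plot_y))
        sp.append(np.full(total, s))

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        species = np.concatenate(sp)
    else:  # pragma: no cover - zero-density degenerate case
        x = np.empty(0)
        y = np.empty(0)
        species = np.empty(0, int)

    # stable spatial ordering so output does not depend on species loop order
    order = np.lexsort((x, y))
    x, y, species = x[order], y[order], species[order]

    n = x.size
    dbh = _truncated_weibull(rng, config.dbh_weibull_shape, config.dbh_weibull_scale, 1.0, n)
    h = stem_height(dbh, config.height_params)

    return pd.DataFrame(
        {
            "tag": np.arange(1, n + 1),
            "species": np.array([f"sp{int(s):02d}" for s in species]),
            "x_m": x,
            "y_m": y,
            "dbh1_cm": dbh,
            "h1_m": h,
            "dbh2_cm": np.nan,
            "h2_m": np.nan,
            "status": STATUS_ALIVE_BOTH,
        }
    )


def _growth_noise_field(config: SyntheticConfig, rng: np.random.Generator):
    """Smoothed white-noise field with correlation length ~ noise_range.

    Returns a callable mapping (x, y) stem coordinates to zero-mean Gaussian
    noise with standard deviation ``noise_sd``.
    """
    if config.noise_sd == 0:
        return lambda x, y: np.zeros_like(np.asarray(x, float))
    res = max(config.noise_range / 3.0, 1.0)
    nxg = int(np.ceil(config.plot_x / res)) + 1
    nyg = int(np.ceil(config.plot_y / res)) + 1
    white = rng.standard_normal((nyg, nxg))
    sigma_cells = (config.noise_range / 2.0) / res
    smooth = gaussian_filter(white, sigma_cells, mode="wrap")
    smooth *= config.noise_sd / smooth.std()
    interp = RegularGridInterpolator(
        (np.arange(nyg) * res, np.arange(nxg) * res), smooth,
        method="linear", bounds_error=False, fill_value=None,
    )
    return lambda x, y: interp(np.column_stack([np.asarray(y, float), np.asarray(x, float)]))


def local_basal_area(x: np.ndarray, y: np.ndarray, dbh: np.ndarray,
                     radius: float = 10.0) -> np.ndarray:
    """Basal area (m^2) of neighbours within ``radius`` m of each stem, self excluded."""
    ba = np.pi * (np.asarray(dbh, float) / 200.0) ** 2
    tree = cKDTree(np.column_stack([x, y]))
    pairs = tree.query_pairs(radius, output_type="ndarray")
    out = np.zeros(x.size)
    if pairs.size:
        np.add.at(out, pairs[:, 0], ba[pairs[:, 1]])
        np.add.at(out, pairs[:, 1], ba[pairs[:, 0]])
    return out


def advance_census(stems: pd.DataFrame, config: SyntheticConfig,
                   grid: ElevationGrid) -> pd.DataFrame:
    """Fill census 2 from a census-1 stem map.

    Survivor increment over the census interval is
    ``g0 * DBH^g1 * exp(-g2 * localBA) * f(elev) * exp(eps)`` with ``eps`` a
    zero-mean Gaussian field (range ``noise_range``, sd ``noise_sd``);
    mortality is Bernoulli with probability increasing in local crowding;
    recruits enter at 1-5 cm DBH.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    g0, g1, g2 = config.growth_params

    out = stems.copy(deep=True)
    x = out["x_m"].to_numpy(float)
    y = out["y_m"].to_numpy(float)
    dbh1 = out["dbh1_cm"].to_numpy(float)

    ba_local = local_basal_area(x, y, dbh1)
    elev = grid.interpolator()(np.column_stack([y, x]))
    f_elev = np.exp(config.elev_growth_coef * (config.elev_base - elev) / 100.0)

    eps = _growth_noise_field(config, rng)(x, y)
    increment = g0 * dbh1**g1 * np.exp(-g2 * ba_local) * f_elev * np.exp(eps)

    p_death = np.clip(config.mortality_base * (1.0 + ba_local), 0.0, 1.0)
    dies = rng.random(len(out)) < p_death

    dbh2 = dbh1 + increment
    out["dbh2_cm"] = np.where(dies, np.nan, dbh2)
    out["h2_m"] = np.where(dies, np.nan, stem_height(dbh2, config.height_params))
    out["status"] = np.where(dies, STATUS_DIED, STATUS_ALIVE_BOTH)

    n_recruit = rng.poisson(config.recruit_density * config.plot_x * config.plot_y)
    if n_recruit:
        rel = geometric_abundances(config.n_species, config.abundance_k)
        r_species = rng.choice(config.n_species, size=n_recruit, p=rel)
        r_dbh = rng.uniform(1.0, 5.0, n_recruit)
        recruits = pd.DataFrame(
            {
                "tag": np.arange(len(out) + 1, len(out) + 1 + n_recruit),
                "species": np.array([f"sp{int(s):02d}" for s in r_species]),
                "x_m": rng.uniform(0, config.plot_x, n_recruit),
                "y_m": rng.uniform(0, config.plot_y, n_recruit),
                "dbh1_cm": np.nan,
                "h1_m": np.nan,
                "dbh2_cm": r_dbh,
                "h2_m": stem_height(r_dbh, config.height_params),
                "status": STATUS_RECRUITED,
            }
        )
        out = pd.concat([out, recruits], ignore_index=True)
    return out


def species_allometry_table(config: SyntheticConfig):
    """Per-species allometric coefficients with seeded jitter around defaults.

    Each species' (a, b) pair is the configured default multiplied by a
    uniform factor within ±``allometry_species_jitter`` (b jittered at a
    quarter of that, keeping the exponent in a narrow realistic band).
    """
    from .biomass import DEFAULT_SPECIES, AllometryTable

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    a0, b0 = config.allometry_defaults
    j = config.allometry_species_jitter
    coeff = {DEFAULT_SPECIES: (a0, b0)}
    for s in range(config.n_species):
        coeff[f"sp{s:02d}"] = (
            float(a0 * (1 + rng.uniform(-j, j))),
            float(b0 * (1 + rng.uniform(-j / 4, j / 4))),
        )
    return AllometryTable(coeff)


def generate_forest(config: SyntheticConfig) -> tuple[pd.DataFrame, ElevationGrid]:
    """Convenience wrapper: elevation grid + two-census stem table."""
    grid = generate_elevation_grid(config)
    stems = generate_stem_map(config, grid)
    stems = advance_census(stems, config, grid)
    return stems, grid


def write_stems_csv(stems: pd.DataFrame, path: str | Path) -> None:
    """Write the stem table; missing DBH/height are empty fields, never 0."""
    stems.to_csv(path, index=False, float_format="%.6f", columns=STEM_COLUMNS)


def read_stems_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(STEM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stem table missing columns: {sorted(missing)}")
    return df


def write_elevation_csv(grid: ElevationGrid, path: str | Path) -> None:
    grid.corner_table().to_csv(path, index=False, float_format="%.6f")


def read_elevation_csv(path: str | Path) -> ElevationGrid:
    return ElevationGrid.from_corner_table(pd.read_csv(path))
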