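"""Quadrat-level diversity, structure and density indices, and the assembly
of the 22-predictor feature row.

Species diversity (7): richness, Hill numbers of order 1 and 2, the two
evenness measures E1 = ln(D1)/ln(S) (Pielou) and E2 = D2/S, and the ACE and
Chao1 richness estimators.

Stand structure (12): stem count Nall, large-stem count N60 (DBH >= 60 cm),
skewness of the fitted lognormal DBH distribution, Weibull shape of the DBH
distribution, Shannon and Gini-Simpson diversity of 2-cm DBH classes and of
1-m height classes, Gini coefficients of basal area and of height, and
coefficients of variation of DBH and height.

Density (1): Reineke's stand density index at the 20-cm reference diameter.

Degenerate quadrats (too few stems for an index) take documented fallback
values of 0 rather than raising, so a feature table is always complete.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import biomass
from .biomass import AllometryTable
from .sampling import Quadrat
from .topography import TrendSurface, quadrat_topography, topo_from_z5

logger = logging.getLogger(__name__)

PREDICTOR_NAMES = [
    "CE", "SLC",
    "Richness", "D1", "D2", "E1", "E2", "ACE", "Chao1",
    "Nall", "N60", "skewness", "shape",
    "DBHShannon", "DBHSimpson", "GiDBH", "CVDBH",
    "HShannon", "HSimpson", "GiH", "CVH",
    "SDI",
]

CATEGORY_MAP = {
    "CE": "Topography", "SLC": "Topography",
    "Richness": "Diversity", "D1": "Diversity", "D2": "Diversity",
    "E1": "Diversity", "E2": "Diversity", "ACE": "Diversity", "Chao1": "Diversity",
    "Nall": "Structure", "N60": "Structure", "skewness": "Structure",
    "shape": "Structure", "DBHShannon": "Structure", "DBHSimpson": "Structure",
    "GiDBH": "Structure", "CVDBH": "Structure", "HShannon": "Structure",
    "HSimpson": "Structure", "GiH": "Structure", "CVH": "Structure",
    "SDI": "Density",
}

CATEGORIES = ["Topography", "Diversity", "Structure", "Density"]

LARGE_TREE_DBH_CM = 60.0
ACE_RARE_THRESHOLD = 10
SDI_REFERENCE_DBH_CM = 20.0
SDI_BETA = 1.605
DBH_CLASS_WIDTH_CM = 2.0
HEIGHT_CLASS_WIDTH_M = 1.0


# ---------------------------------------------------------------------------
# species diversity

def _counts(ab) -> np.ndarray:
    c = np.asarray(ab, float)
    if np.any(c < 0):
        raise ValueError("abundances must be non-negative")
    return c[c > 0]


def richness(ab) -> int:
    """Number of species with at least one stem."""
    return int(len(_counts(ab)))


def hill_number(ab, q: float) -> float:
    """Effective species number of order q, (sum p^q)^(1/(1-q)).

    q = 1 is the exponential Shannon limit; an empty vector falls back to 0.
    """
    c = _counts(ab)
    if c.size == 0:
        logger.debug("hill_number on empty abundance vector; fallback 0")
        return 0.0
    p = c / c.sum()
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def evenness(ab, q: int) -> float:
    """Evenness of order q: E1 = ln(D1)/ln(S) (Pielou), E2 = D2/S.

    Quadrats with fewer than two species fall back to 0.
    """
    if q not in (1, 2):
        raise ValueError("evenness is defined here for q in {1, 2}")
    s = richness(ab)
    if s < 2:
        logger.debug("evenness with richness < 2; fallback 0")
        return 0.0
    d = hill_number(ab, q)
    return float(np.log(d) / np.log(s)) if q == 1 else float(d / s)


def _frequency_counts(ab, upto: int) -> np.ndarray:
    """F[i] = number of species with exactly i individuals, i = 1..upto."""
    c = _counts(ab)
    f = np.zeros(upto + 1)
    for k in c:
        k = int(round(k))
        if 1 <= k <= upto:
            f[k] += 1
    return f


def ace(ab, rare_threshold: int = ACE_RARE_THRESHOLD) -> float:
    """Abundance-based coverage estimator of species richness.

    Rare species are those with <= ``rare_threshold`` individuals.  When all
    rare species are singletons the sample coverage is zero and the estimate
    falls back to Chao1; with no rare species ACE equals the richness.
    """
    c = _counts(ab)
    if c.size == 0:
        return 0.0
    rare = c[c <= rare_threshold]
    s_abund = int(np.sum(c > rare_threshold))
    s_rare = int(rare.size)
    if s_rare == 0:
        return float(richness(ab))
    f = _frequency_counts(rare, rare_threshold)
    f1 = f[1]
    n_rare = float(np.sum(np.arange(rare_threshold + 1) * f))
    c_ace = 1.0 - f1 / n_rare
    if c_ace <= 0:
        logger.debug("ACE coverage zero (all rare species singletons); falling back to Chao1")
        return chao1(ab)
    i = np.arange(1, rare_threshold + 1)
    het = float(np.sum(i * (i - 1) * f[1:]))
    gamma2 = 0.0
    if n_rare > 1:
        gamma2 = max((s_rare / c_ace) * het / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def chao1(ab) -> float:
    """Bias-corrected Chao1 richness estimator S + F1(F1-1)/(2(F2+1))."""
    c = _counts(ab)
    if c.size == 0:
        return 0.0
    f1 = float(np.sum(c == 1))
    f2 = float(np.sum(c == 2))
    return float(c.size + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0)))


# ---------------------------------------------------------------------------
# stand structure

def class_diversity(values, class_width: float, kind: str) -> float:
    """Shannon or Gini-Simpson diversity of size classes [k*w, (k+1)*w)."""
    v = np.asarray(values, float)
    if v.size == 0:
        logger.debug("class_diversity on empty input; fallback 0")
        return 0.0
    classes = np.floor(v / class_width).astype(int)
    p = np.array(list(Counter(classes).values()), float)
    p /= p.sum()
    if kind == "shannon":
        return float(-np.sum(p * np.log(p)))
    if kind == "simpson":
        return float(1.0 - np.sum(p**2))
    raise ValueError(f"unknown diversity kind {kind!r}")


def gini(values) -> float:
    """Gini inequality with the (n-1) forestry normalization.

    ``G = sum_m (2m - n - 1) x_(m) / ((n - 1) sum x)`` over ascending-sorted
    values; fewer than two values fall back to 0.
    """
    x = np.sort(np.asarray(values, float))
    if np.any(x < 0):
        raise ValueError("gini requires non-negative values")
    n = x.size
    if n < 2:
        logger.debug("gini with n < 2; fallback 0")
        return 0.0
    total = x.sum()
    if total == 0:
        return 0.0
    m = np.arange(1, n + 1)
    return float(np.sum((2 * m - n - 1) * x) / ((n - 1) * total))


def cv(values) -> float:
    """Coefficient of variation in percent (population SD / mean * 100)."""
    x = np.asarray(values, float)
    if x.size == 0:
        logger.debug("cv on empty input; fallback 0")
        return 0.0
    mu = x.mean()
    if mu <= 0:
        raise ValueError("cv requires a positive mean")
    return float(100.0 * x.std() / mu)


def lognormal_skewness(dbh_values) -> float:
    """Skewness of the lognormal fitted by log-moments to the diameters.

    With sigma^2 the (1/N) variance of ln(DBH), the lognormal skewness is
    ``(exp(sigma^2) + 2) * sqrt(exp(sigma^2) - 1)``; n < 3 falls back to 0.
    """
    x = np.asarray(dbh_values, float)
    if x.size < 3:
        logger.debug("lognormal_skewness with n < 3; fallback 0")
        return 0.0
    if np.any(x <= 0):
        raise ValueError("lognormal fit requires positive diameters")
    s2 = np.log(x).var()
    w = np.exp(s2)
    return float((w + 2.0) * np.sqrt(w - 1.0))


def weibull_shape(dbh_values) -> float:
    """Maximum-likelihood shape of the 2-parameter Weibull DBH distribution.

    Solves the profile-likelihood equation for the shape k,
    ``sum x^k ln x / sum x^k - 1/k = mean(ln x)``, by bracketed root finding.
    Degenerate inputs (n < 3, all values equal, failed bracket) fall back
    to 0 and are logged.
    """
    x = np.asarray(dbh_values, float)
    if x.size < 3 or np.any(x <= 0):
        logger.debug("weibull_shape degenerate input; fallback 0")
        return 0.0
    if np.isclose(x.min(), x.max()):
        logger.debug("weibull_shape on constant values; fallback 0")
        return 0.0
    # work on scaled values for numerical stability; shape is scale-invariant
    xs = x / x.mean()
    lx = np.log(xs)
    mean_lx = lx.mean()

    def profile(k: float) -> float:
        xk = xs**k
        return float(np.sum(xk * lx) / np.sum(xk) - 1.0 / k - mean_lx)

    lo, hi = 1e-2, 1e2
    try:
        if profile(lo) > 0 or profile(hi) < 0:
            raise ValueError("no sign change")
        return float(brentq(profile, lo, hi, xtol=1e-10))
    except (ValueError, RuntimeError):
        logger.debug("weibull_shape fit failed; fallback 0")
        return 0.0


def stem_counts(dbh_values, min_dbh: float = biomass.MIN_DBH_CM,
                large_dbh: float = LARGE_TREE_DBH_CM) -> tuple[int, int]:
    """(Nall, N60): stems with DBH >= min_dbh and >= large_dbh."""
    x = np.asarray(dbh_values, float)
    x = x[np.isfinite(x)]
    return int(np.sum(x >= min_dbh)), int(np.sum(x >= large_dbh))


def sdi(n_stems: int, quadratic_mean_dbh: float, area_ha: float,
        beta: float = SDI_BETA, reference_dbh: float = SDI_REFERENCE_DBH_CM) -> float:
    """Reineke stand density index (stems-equivalent per hectare).

    ``SDI = (N / area_ha) * (Dg / 20)^beta``; an empty quadrat gives 0.
    """
    if n_stems == 0:
        return 0.0
    if quadratic_mean_dbh <= 0:
        raise ValueError("quadratic mean DBH must be positive")
    if area_ha <= 0:
        raise ValueError("area must be positive")
    return float(n_stems / area_ha * (quadratic_mean_dbh / reference_dbh) ** beta)


def quadratic_mean_dbh(dbh_values) -> float:
    x = np.asarray(dbh_values, float)
    if x.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(x**2)))


# ---------------------------------------------------------------------------
# feature assembly

def _census1_live(stems: pd.DataFrame, min_dbh: float) -> pd.DataFrame:
    dbh = stems["dbh1_cm"].to_numpy(float)
    return stems[np.isfinite(dbh) & (dbh >= min_dbh)]


def feature_vector(stems_in_quadrat: pd.DataFrame, quadrat: Quadrat,
                   surface: TrendSurface, allometry: AllometryTable,
                   interval_yr: float = 5.0,
                   min_dbh: float = biomass.MIN_DBH_CM) -> dict[str, float]:
    """The 22 named predictors plus the response P for one quadrat.

    Predictors are computed on census-1 live stems with DBH >= ``min_dbh``
    (the same population that defines the biomass totals); P uses both
    censuses.  Empty quadrats produce the documented zero fallbacks.
    """
    topo = quadrat_topography(surface, quadrat)
    row = _assemble(stems_in_quadrat, quadrat, topo, min_dbh)
    row["P"] = biomass.quadrat_productivity(stems_in_quadrat, quadrat.area_ha,
                                            allometry, interval_yr, min_dbh)
    return row


def _assemble(stems_q: pd.DataFrame, quadrat: Quadrat, topo: dict[str, float],
              min_dbh: float) -> dict[str, float]:
    live = _census1_live(stems_q, min_dbh)
    dbh = live["dbh1_cm"].to_numpy(float)
    height = live["h1_m"].to_numpy(float)
    ab = live["species"].value_counts().to_numpy()

    nall, n60 = stem_counts(dbh, min_dbh)
    ba = np.pi * (dbh / 2.0) ** 2  # cm^2; Gini is scale-invariant

    row = {
        "CE": topo["CE"],
        "SLC": topo["SLC"],
        "Richness": float(richness(ab)),
        "D1": hill_number(ab, 1) if ab.size else 0.0,
        "D2": hill_number(ab, 2) if ab.size else 0.0,
        "E1": evenness(ab, 1),
        "E2": evenness(ab, 2),
        "ACE": ace(ab),
        "Chao1": chao1(ab),
        "Nall": float(nall),
        "N60": float(n60),
        "skewness": lognormal_skewness(dbh),
        "shape": weibull_shape(dbh),
        "DBHShannon": class_diversity(dbh, DBH_CLASS_WIDTH_CM, "shannon"),
        "DBHSimpson": class_diversity(dbh, DBH_CLASS_WIDTH_CM, "simpson"),
        "GiDBH": gini(ba),
        "CVDBH": cv(dbh) if dbh.size else 0.0,
        "HShannon": class_diversity(height, HEIGHT_CLASS_WIDTH_M, "shannon"),
        "HSimpson": class_diversity(height, HEIGHT_CLASS_WIDTH_M, "simpson"),
        "GiH": gini(height),
        "CVH": cv(height) if height.size else 0.0,
        "SDI": sdi(nall, quadratic_mean_dbh(dbh), quadrat.area_ha) if nall else 0.0,
    }
    if nall == 0:
        logger.debug("empty quadrat at (%.1f, %.1f) side %.0f; zero fallbacks",
                     quadrat.cx, quadrat.cy, quadrat.side)
    return row


def build_feature_table(stems: pd.DataFrame, quadrats: list[Quadrat],
                        surface: TrendSurface, allometry: AllometryTable,
                        interval_yr: float = 5.0,
                        min_dbh: float = biomass.MIN_DBH_CM) -> pd.DataFrame:
    """Feature rows for a batch of quadrats.

    Kriging predictions for all centre/corner points are batched into a
    single solve; per-stem biomass is computed once for the whole stem table
    and summed per quadrat.
    """
    if not quadrats:
        return pd.DataFrame(columns=PREDICTOR_NAMES + ["P"])

    pts = np.vstack([
        np.vstack([[q.cx, q.cy], q.corners()]) for q in quadrats
    ])
    z_all = surface.predict(pts).reshape(len(quadrats), 5)

    x = stems["x_m"].to_numpy(float)
    y = stems["y_m"].to_numpy(float)
    dbh1 = stems["dbh1_cm"].to_numpy(float)
    dbh2 = stems["dbh2_cm"].to_numpy(float)
    species = stems["species"].to_numpy()
    agb1 = biomass.stems_agb(species, dbh1, allometry) / biomass.KG_PER_MG
    agb2 = biomass.stems_agb(species, dbh2, allometry) / biomass.KG_PER_MG
    live1 = np.isfinite(dbh1) & (dbh1 >= min_dbh)
    live2 = np.isfinite(dbh2) & (dbh2 >= min_dbh)

    rows = []
    for qi, q in enumerate(quadrats):
        x0, y0, x1, y1 = q.bounds
        inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        topo = topo_from_z5(q.corners(), z_all[qi])
        sub = stems.iloc[np.flatnonzero(inside)]
        row = _assemble(sub, q, topo, min_dbh)
        agb_1 = agb1[inside & live1].sum()
        agb_2 = agb2[inside & live2].sum()
        row["P"] = (agb_2 - agb_1) / (q.area_ha * interval_yr)
        rows.append(row)
    return pd.DataFrame(rows, columns=PREDICTOR_NAMES + ["P"])
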