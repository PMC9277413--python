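"""Tree above-ground biomass (AGB) allometry and quadrat productivity.

AGB of a stem is a species-specific power law of diameter,
``AGB_kg = a * DBH_cm^b``.  Quadrat productivity P is the periodic annual
increment of total AGB per unit area and time (Mg ha^-1 yr^-1), computed as
the NET change between censuses: recruitment into the >= 5 cm class adds,
mortality subtracts.  P may therefore be negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SPECIES = "_default_"
MIN_DBH_CM = 5.0
KG_PER_MG = 1000.0


@dataclass
class AllometryTable:
    """Per-species (a, b) coefficients with a required default pair.

    Unlisted species fall back to the default row (logged once per species).
    """

    coefficients: dict[str, tuple[float, float]]
    _warned: set = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        if DEFAULT_SPECIES not in self.coefficients:
            raise ValueError(f"allometry table requires a '{DEFAULT_SPECIES}' row")
        for sp, (a, b) in self.coefficients.items():
            if a <= 0:
                raise ValueError(f"coefficient a must be positive for {sp}")
            if not 1.0 < b < 4.0:
                raise ValueError(f"exponent b for {sp} must lie in (1, 4), got {b}")

    def lookup(self, species: str) -> tuple[float, float]:
        if species in self.coefficients:
            return self.coefficients[species]
        if species not in self._warned:
            logger.info("species %r not in allometry table; using default coefficients", species)
            self._warned.add(species)
        return self.coefficients[DEFAULT_SPECIES]

    def coef_arrays(self, species: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized coefficient lookup for a species array."""
        a = np.empty(len(species))
        b = np.empty(len(species))
        for i, sp in enumerate(species):
            a[i], b[i] = self.lookup(sp)
        return a, b

    @classmethod
    def default(cls, a: float = 0.1, b: float = 2.4) -> "AllometryTable":
        return cls({DEFAULT_SPECIES: (a, b)})

    @classmethod
    def from_csv(cls, path: str | Path) -> "AllometryTable":
        df = pd.read_csv(path)
        coeff = {str(r.species): (float(r.a), float(r.b)) for r in df.itertuples()}
        return cls(coeff)

    def to_csv(self, path: str | Path) -> None:
        rows = [{"species": sp, "a": a, "b": b} for sp, (a, b) in self.coefficients.items()]
        pd.DataFrame(rows).to_csv(path, index=False)


def tree_agb(species: str, dbh_cm: float, table: AllometryTable) -> float:
    """AGB (kg) of one stem from its species allometry."""
    if dbh_cm <= 0:
        raise ValueError(f"DBH must be positive, got {dbh_cm}")
    a, b = table.lookup(species)
    return a * dbh_cm**b


def stems_agb(species: np.ndarray, dbh_cm: np.ndarray, table: AllometryTable) -> np.ndarray:
    """Vectorized per-stem AGB (kg); NaN diameters give NaN mass."""
    a, b = table.coef_arrays(np.asarray(species))
    dbh = np.asarray(dbh_cm, float)
    with np.errstate(invalid="ignore"):
        return a * dbh**b


def quadrat_agb(stems: pd.DataFrame, census: int, table: AllometryTable,
                min_dbh: float = MIN_DBH_CM) -> float:
    """Total AGB (Mg) of stems alive at the given census with DBH >= min_dbh."""
    if census not in (1, 2):
        raise ValueError("census must be 1 or 2")
    col = "dbh1_cm" if census == 1 else "dbh2_cm"
    dbh = stems[col].to_numpy(float)
    sel = np.isfinite(dbh) & (dbh >= min_dbh)
    if not sel.any():
        return 0.0
    mass = stems_agb(stems["species"].to_numpy()[sel], dbh[sel], table)
    return float(mass.sum()) / KG_PER_MG


def quadrat_productivity(stems: pd.DataFrame, area_ha: float, table: AllometryTable,
                         interval_yr: float = 5.0, min_dbh: float = MIN_DBH_CM) -> float:
    """Periodic annual AGB increment P (Mg ha^-1 yr^-1) for one quadrat.

    Each census total uses that census's own >= min_dbh membership, so the
    result is a net change that may be negative under mortality.
    """
    if area_ha <= 0:
        raise ValueError("quadrat area must be positive")
    if interval_yr <= 0:
        raise ValueError("census interval must be positive")
    agb1 = quadrat_agb(stems, 1, table, min_dbh)
    agb2 = quadrat_agb(stems, 2, table, min_dbh)
    return (agb2 - agb1) / (area_ha * interval_yr)
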