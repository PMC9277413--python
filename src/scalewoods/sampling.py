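"""Random spatial sampling design: scale series and buffered square quadrats.

A quadrat of side ``s`` has half-open bounds
``[cx - s/2, cx + s/2) x [cy - s/2, cy + s/2)`` so that a disjoint tiling of
the plot partitions the stems exactly.  Quadrat centres are drawn uniformly,
with replacement, from the plot shrunk by a buffer of half the side length,
which guarantees full containment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, SamplingDesign


class InfeasibleScaleError(ValueError):
    """Quadrat side exceeds a plot dimension."""


@dataclass(frozen=True)
class Quadrat:
    cx: float
    cy: float
    side: float

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("quadrat side must be positive")

    @property
    def x0(self) -> float:
        return self.cx - self.side / 2.0

    @property
    def y0(self) -> float:
        return self.cy - self.side / 2.0

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1); membership is half-open on the upper edges."""
        return (self.x0, self.y0, self.x0 + self.side, self.y0 + self.side)

    @property
    def area_ha(self) -> float:
        return self.side * self.side / 1e4

    def corners(self) -> np.ndarray:
        """The four corners, counter-clockwise from the lower-left, as (x, y)."""
        x0, y0, x1, y1 = self.bounds
        return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])


def scale_series(design: SamplingDesign) -> list[float]:
    """Arithmetic sequence of quadrat side lengths, ends inclusive."""
    n = int(np.floor((design.side_max - design.side_min) / design.step + 1e-9)) + 1
    return [design.side_min + k * design.step for k in range(n)]


def sample_quadrats(plot_x: float, plot_y: float, side: float, n: int,
                    rng: np.random.Generator) -> list[Quadrat]:
    """Draw ``n`` quadrats with centres uniform on the buffered region.

    Sampling is independent with replacement; every quadrat lies entirely
    inside the plot by construction.
    """
    if side > min(plot_x, plot_y):
        raise InfeasibleScaleError(
            f"side {side} m does not fit in a {plot_x} x {plot_y} m plot"
        )
    half = side / 2.0
    cx = rng.uniform(half, plot_x - half, n)
    cy = rng.uniform(half, plot_y - half, n)
    return [Quadrat(float(a), float(b), float(side)) for a, b in zip(cx, cy)]


def stems_in_quadrat(stems: pd.DataFrame, quadrat: Quadrat) -> pd.DataFrame:
    """Stems with coordinates inside the quadrat's half-open bounds."""
    x0, y0, x1, y1 = quadrat.bounds
    x = stems["x_m"].to_numpy(float)
    y = stems["y_m"].to_numpy(float)
    return stems[(x >= x0) & (x < x1) & (y >= y0) & (y < y1)]


def quadrat_table(quadrats: list[Quadrat], scale_m: float, rep: int) -> pd.DataFrame:
    """Long-format table of sampled quadrats (one row per placement)."""
    return pd.DataFrame(
        {
            "scale_m": scale_m,
            "rep": rep,
            "quadrat_id": np.arange(len(quadrats)),
            "cx": [q.cx for q in quadrats],
            "cy": [q.cy for q in quadrats],
        }
    )
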