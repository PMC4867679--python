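"""Buoyant-density physical chemistry for CsCl gradients.

Converts refractometer readings to CsCl buoyant density (rho = a*eta - b,
with a = 10.9276 and b = 13.593 g/mL for CsCl at 20 degrees C), corrects for
the refractive index of gradient buffer, selects the heavy (high-density)
fraction window where 13C-labeled DNA concentrates, and provides the shared
density range / interpolation grid used by the density-profile statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DensityModel",
    "HeavyWindow",
    "correct_ri",
    "density_from_ri",
    "ri_from_density",
    "select_heavy",
    "common_density_range",
    "interpolation_grid",
    "interp_profile",
]

RI_RANGE = (1.3, 1.5)


@dataclass(frozen=True)
class DensityModel:
    """Linear RI -> density calibration for CsCl at 20 C."""

    a: float = 10.9276  # g/mL per RI unit
    b: float = 13.593  # g/mL
    ri_water: float = 1.3333

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("calibration slope a must be positive")


@dataclass(frozen=True)
class HeavyWindow:
    """Closed density interval defining 'high density gradient fractions'."""

    lo: float = 1.7125
    hi: float = 1.755

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("heavy window requires lo < hi")

    def contains(self, density: float | np.ndarray) -> bool | np.ndarray:
        return (self.lo <= density) & (density <= self.hi)


def _check_ri(ri: float, name: str) -> None:
    lo, hi = RI_RANGE
    if not lo < ri < hi:
        raise ValueError(f"{name}={ri} outside plausible CsCl range ({lo}, {hi})")


def correct_ri(ri_observed: float, ri_buffer: float, model: DensityModel = DensityModel()) -> float:
    """Subtract the gradient-buffer RI offset relative to water."""
    _check_ri(ri_observed, "ri_observed")
    _check_ri(ri_buffer, "ri_buffer")
    return ri_observed - (ri_buffer - model.ri_water)


def density_from_ri(ri_corrected: float, model: DensityModel = DensityModel()) -> float:
    """rho = a*eta - b. Calibrated for the CsCl range of RI."""
    _check_ri(ri_corrected, "ri_corrected")
    return model.a * ri_corrected - model.b


def ri_from_density(density: float, model: DensityModel = DensityModel()) -> float:
    """Inverse of :func:`density_from_ri`."""
    return (density + model.b) / model.a


def select_heavy(meta_df: pd.DataFrame, window: HeavyWindow = HeavyWindow()) -> list[str]:
    """Sample ids of fractionated samples whose density lies in the window.

    Accepts a metadata frame (``SampleMeta.data`` or a subset); only rows with
    ``is_fractionated`` and a density inside the closed interval are kept.
    The result may be empty; callers decide whether that is an error.
    """
    frac = meta_df[meta_df["is_fractionated"].astype(bool)]
    keep = frac.index[window.contains(frac["density"].to_numpy())]
    return list(keep)


def common_density_range(gradients: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Intersection of the density ranges spanned by each gradient.

    lo = max over gradients of the minimum fraction density; hi = min of the
    maxima. Profile statistics are restricted to this shared range because
    gradients do not span identical densities.
    """
    if len(gradients) < 1:
        raise ValueError("need at least one gradient")
    for g in gradients:
        if len(g) < 2:
            raise ValueError("each gradient needs at least two fractions")
    lo = max(min(g) for g in gradients)
    hi = min(max(g) for g in gradients)
    if not lo < hi:
        raise ValueError(f"no common density range (lo={lo} >= hi={hi})")
    return float(lo), float(hi)


def interpolation_grid(lo: float, hi: float, n: int = 20) -> np.ndarray:
    """n evenly spaced densities including both endpoints."""
    if n < 2:
        raise ValueError("interpolation grid needs n >= 2")
    if not lo < hi:
        raise ValueError("grid requires lo < hi")
    return np.linspace(lo, hi, n)


def interp_profile(
    fraction_densities: Sequence[float],
    rel_abundances: Sequence[float],
    grid: Sequence[float],
) -> np.ndarray:
    """Piecewise-linear interpolation of a density profile onto a grid.

    Duplicate fraction densities have their abundances averaged before
    interpolation (knots must be strictly increasing). Extrapolation is
    refused: every grid point must lie within the observed density range.
    """
    dens = np.asarray(fraction_densities, dtype=float)
    abund = np.asarray(rel_abundances, dtype=float)
    if dens.shape != abund.shape:
        raise ValueError("densities and abundances must have equal length")
    ser = pd.Series(abund).groupby(dens).mean()  # sorts and averages ties
    knots_x = ser.index.to_numpy()
    knots_y = ser.to_numpy()
    if len(knots_x) < 2:
        raise ValueError("need at least two distinct fraction densities")
    grid = np.asarray(grid, dtype=float)
    if grid.min() < knots_x[0] or grid.max() > knots_x[-1]:
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] extends beyond observed "
            f"densities [{knots_x[0]}, {knots_x[-1]}]; no extrapolation"
        )
    return np.interp(grid, knots_x, knots_y)
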