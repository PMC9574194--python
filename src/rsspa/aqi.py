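"""Air-quality index (AQI) computation from pollutant concentrations.

The individual air-quality index (IAQI) of a pollutant is a piecewise-linear
interpolation of its concentration between regulatory breakpoints:

    IAQI = (IAQI_hi - IAQI_lo) / (BP_hi - BP_lo) * (C - BP_lo) + IAQI_lo

where ``(BP_lo, BP_hi)`` is the concentration segment bracketing ``C`` and
``(IAQI_lo, IAQI_hi)`` the aligned sub-index segment. The composite AQI of a
period is the maximum IAQI over all pollutants, and the pollutant(s) attaining
the maximum are the period's primary pollutants.

The packaged default breakpoint grid follows the Chinese ambient air quality
standard (GB 3095-2012) scheme for the six criteria pollutants PM2.5, PM10,
SO2, NO2, CO and O3. Ozone's grid is truncated: no breakpoints are defined
above sub-index 300, so higher concentrations are reported at the top defined
sub-index with a truncation flag rather than extrapolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "Pollutant",
    "POLLUTANTS",
    "BreakpointTable",
    "ConcentrationSeries",
    "IAQIRecord",
    "AQIRecord",
    "AQI_BANDS",
    "compute_iaqi",
    "invert_iaqi",
    "compute_aqi",
    "classify_aqi",
    "coefficient_of_variation",
]


@dataclass(frozen=True)
class Pollutant:
    """A criteria pollutant: code, concentration unit and averaging basis."""

    code: str
    unit: str
    averaging_basis: str

    def __post_init__(self):
        if not self.code:
            raise ValidationError("pollutant code must be non-empty")
        if not self.unit:
            raise ValidationError("pollutant unit must be non-empty")


#: The six criteria pollutants, keyed by canonical code.
POLLUTANTS: Mapping[str, Pollutant] = {
    "PM2.5": Pollutant("PM2.5", "ug/m3", "24-h mean"),
    "PM10": Pollutant("PM10", "ug/m3", "24-h mean"),
    "SO2": Pollutant("SO2", "ug/m3", "24-h mean"),
    "NO2": Pollutant("NO2", "ug/m3", "24-h mean"),
    "CO": Pollutant("CO", "mg/m3", "24-h mean"),
    "O3": Pollutant("O3", "ug/m3", "8-h moving mean"),
}

#: Sub-index grid shared by all pollutants.
IAQI_GRID: tuple[float, ...] = (0, 50, 100, 150, 200, 300, 400, 500)

#: Default per-pollutant concentration limits aligned to IAQI_GRID.
#: O3 has no defined breakpoints above sub-index 300.
DEFAULT_CONC_GRIDS: Mapping[str, tuple[float, ...]] = {
    "SO2": (0, 50, 150, 475, 800, 1600, 2100, 2620),
    "NO2": (0, 40, 80, 180, 280, 565, 750, 940),
    "PM10": (0, 50, 150, 250, 350, 420, 500, 600),
    "CO": (0, 2, 4, 14, 24, 36, 48, 60),
    "O3": (0, 100, 160, 215, 265, 800),
    "PM2.5": (0, 35, 75, 115, 150, 250, 350, 500),
}

#: AQI banding: (upper bound inclusive, level, category, color).
AQI_BANDS: tuple[tuple[float, int, str, str], ...] = (
    (50, 1, "excellent", "green"),
    (100, 2, "good", "yellow"),
    (150, 3, "slightly-pollution", "orange"),
    (200, 4, "moderate-pollution", "red"),
    (300, 5, "severely-pollution", "purple"),
    (math.inf, 6, "seriously-pollution", "maroon"),
)


@dataclass(frozen=True)
class BreakpointTable:
    """Per-pollutant (concentration, sub-index) breakpoint grids.

    ``conc_grids[code]`` is aligned index-by-index with ``iaqi_grid`` and may
    be shorter when upper breakpoints are undefined for that pollutant.
    """

    iaqi_grid: tuple[float, ...] = IAQI_GRID
    conc_grids: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CONC_GRIDS)
    )

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.iaqi_grid, self.iaqi_grid[1:])):
            raise ValidationError("iaqi_grid must be strictly increasing")
        for code, grid in self.conc_grids.items():
            if len(grid) > len(self.iaqi_grid):
                raise ValidationError(
                    f"{code}: concentration grid longer than sub-index grid"
                )
            if len(grid) < 2:
                raise ValidationError(f"{code}: need at least two breakpoints")
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValidationError(
                    f"{code}: concentration grid must be strictly increasing"
                )

    def grids_for(self, code: str) -> tuple[tuple[float, ...], tuple[float, ...]]:
        """Return the aligned (conc_grid, iaqi_grid) pair for a pollutant."""
        try:
            conc = self.conc_grids[code]
        except KeyError:
            raise ValidationError(
                f"unknown pollutant {code!r}; known: {sorted(self.conc_grids)}"
            ) from None
        return conc, self.iaqi_grid[: len(conc)]

    def top_iaqi(self, code: str) -> float:
        """Highest defined sub-index for a pollutant."""
        conc, iaqi = self.grids_for(code)
        return iaqi[-1]


@dataclass(frozen=True)
class ConcentrationSeries:
    """Ordered, equally spaced concentration observations for one pollutant."""

    pollutant: Pollutant
    periods: tuple
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.periods) != len(self.values):
            raise ValidationError("periods and values must have equal length")
        if any(v < 0 for v in self.values):
            raise ValidationError("concentrations must be nonnegative")
        if any(b <= a for a, b in zip(self.periods, self.periods[1:])):
            raise ValidationError("periods must be strictly ordered")


@dataclass(frozen=True)
class IAQIRecord:
    pollutant: str
    period: object
    iaqi: float
    truncated: bool = False


@dataclass(frozen=True)
class AQIRecord:
    period: object
    aqi: float
    primary_pollutants: frozenset[str]
    level: int
    category: str
    color: str


def compute_iaqi(
    conc: float,
    pollutant: str | Pollutant,
    table: BreakpointTable | None = None,
    period=None,
) -> IAQIRecord:
    """Individual air-quality index by breakpoint interpolation.

    Exact at every breakpoint; concentrations above the last defined
    breakpoint return the top defined sub-index with ``truncated`` set.

    Raises
    ------
    ValidationError
        If ``conc`` is negative or the pollutant is not in the table.
    """
    table = table or BreakpointTable()
    code = pollutant.code if isinstance(pollutant, Pollutant) else pollutant
    if not math.isfinite(conc) or conc < 0:
        raise ValidationError(f"concentration must be finite and >= 0, got {conc}")
    conc_grid, iaqi_grid = table.grids_for(code)
    if conc > conc_grid[-1]:
        return IAQIRecord(code, period, iaqi_grid[-1], truncated=True)
    # np.interp is exact at grid nodes and piecewise linear between them
    iaqi = float(np.interp(conc, conc_grid, iaqi_grid))
    return IAQIRecord(code, period, iaqi)


def invert_iaqi(
    iaqi: float, pollutant: str | Pollutant, table: BreakpointTable | None = None
) -> float:
    """Concentration whose sub-index equals ``iaqi`` (inverse interpolation).

    Both grids are strictly increasing so the inverse is unique;
    ``compute_iaqi(invert_iaqi(q))`` round-trips to 1e-9.
    """
    table = table or BreakpointTable()
    code = pollutant.code if isinstance(pollutant, Pollutant) else pollutant
    conc_grid, iaqi_grid = table.grids_for(code)
    if not 0 <= iaqi <= iaqi_grid[-1]:
        raise ValidationError(
            f"{code}: sub-index {iaqi} outside defined range [0, {iaqi_grid[-1]}]"
        )
    return float(np.interp(iaqi, iaqi_grid, conc_grid))


def compute_aqi(iaqis: Sequence[IAQIRecord]) -> AQIRecord:
    """Composite AQI: the maximum IAQI of one period, with its argmax set."""
    if not iaqis:
        raise ValidationError("need at least one IAQI record")
    periods = {r.period for r in iaqis}
    if len(periods) > 1:
        raise ValidationError(f"records span multiple periods: {sorted(map(str, periods))}")
    aqi = max(r.iaqi for r in iaqis)
    primary = frozenset(r.pollutant for r in iaqis if r.iaqi == aqi)
    level, category, color = classify_aqi(aqi)
    return AQIRecord(iaqis[0].period, aqi, primary, level, category, color)


def classify_aqi(aqi: float) -> tuple[int, str, str]:
    """Map an AQI value to its (level, category, color) band.

    Bands are the continuous extension of the integer scheme: level 1 for
    aqi <= 50, level 2 for 50 < aqi <= 100, and so on; > 300 is level 6.
    """
    if not math.isfinite(aqi) or aqi < 0:
        raise ValidationError(f"AQI must be finite and >= 0, got {aqi}")
    for bound, level, category, color in AQI_BANDS:
        if aqi <= bound:
            return level, category, color
    raise AssertionError("unreachable")  # pragma: no cover


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Population standard deviation divided by the mean (dispersion summary).

    Accepts a bare sequence or a :class:`ConcentrationSeries`.
    """
    if isinstance(values, ConcentrationSeries):
        values = values.values
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty series")
    mean = arr.mean()
    if mean <= 0:
        raise ValidationError(f"coefficient of variation needs mean > 0, got {mean}")
    return float(arr.std() / mean)
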