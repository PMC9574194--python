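"""Packaged Hebei 2013-2020 fixtures and synthetic data generation.

The fixture tables carry the published Hebei study values verbatim, including
a handful of internal inconsistencies in the source (flagged in
``data/provenance.json`` rather than silently corrected), so golden tests
compare against exactly what was printed.

Two generators support testing without any download:

- :func:`generate_persistent_series` draws fractional Gaussian noise (fGn)
  with a chosen Hurst parameter via Davies-Harte circulant embedding, the
  standard exact method: the fGn autocovariance is embedded in a circulant
  matrix whose eigenvalues (a real FFT of the first row) are nonnegative for
  all H in (0, 1), so a spectrally weighted complex Gaussian vector
  transforms back into a stationary Gaussian series with exactly the target
  autocovariance. At H = 0.5 the autocovariance collapses to a delta and the
  output is independent Gaussian noise.
- :func:`generate_pollutant_panel` emulates a multi-pollutant panel of
  annual mean concentrations declining linearly at pollutant-specific rates
  (calibrated to the Hebei 2013 -> 2020 endpoints) plus Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .aqi import POLLUTANTS, ConcentrationSeries
from .errors import ValidationError
from .rescaled_range import Series

__all__ = [
    "FIXTURES",
    "load_fixture",
    "fixture_provenance",
    "SyntheticSpec",
    "generate_persistent_series",
    "generate_pollutant_panel",
    "PANEL_PROFILES",
]

#: Registry of packaged fixtures: name -> CSV resource.
FIXTURES: Mapping[str, str] = {
    "table1": "table1_breakpoints.csv",
    "table2": "table2_aqi_bands.csv",
    "table3": "table3_grade_intervals.csv",
    "table4": "table4_iaqi_aqi.csv",
    "table5": "table5_ln_rs.csv",
    "table6": "table6_hurst_r2.csv",
    "table7": "table7_connection_numbers.csv",
    "table8": "table8_degrees.csv",
}


def _data_path(name: str):
    return resources.files("rsspa").joinpath("data", name)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table by registry name (``table1`` ... ``table8``).

    The returned frame carries the table's provenance notes (including any
    ``inconsistent`` flags) in ``df.attrs["provenance"]``.
    """
    try:
        filename = FIXTURES[name]
    except KeyError:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    with _data_path(filename).open() as fh:
        df = pd.read_csv(fh)
    df.attrs["provenance"] = fixture_provenance().get(name, {})
    return df


def fixture_provenance() -> dict:
    """Per-table provenance notes, with machine-readable inconsistency flags."""
    with _data_path("provenance.json").open() as fh:
        return json.load(fh)


# --------------------------------------------------------------------------
# synthetic data


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic generators.

    n
        series length (>= 8).
    persistence
        target Hurst parameter in (0, 1); 0.5 is independent noise.
    trend
        additive linear slope per step for :func:`generate_persistent_series`;
        multiplier on the built-in per-pollutant declines for
        :func:`generate_pollutant_panel` (1.0 = the calibrated declines).
    noise_scale
        standard-deviation multiplier; 0 disables noise (panel only).
    seed
        RNG seed; generators are pure functions of the spec.
    """

    n: int = 256
    persistence: float = 0.5
    trend: float = 0.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 8:
            raise ValidationError(f"n must be >= 8, got {self.n}")
        if not 0 < self.persistence < 1:
            raise ValidationError(
                f"persistence must lie in (0, 1), got {self.persistence}"
            )
        if self.noise_scale < 0:
            raise ValidationError(f"noise_scale must be >= 0, got {self.noise_scale}")


def _fgn_autocov(n: int, h: float) -> np.ndarray:
    k = np.arange(n + 1, dtype=float)
    return 0.5 * (
        np.abs(k - 1) ** (2 * h) - 2 * k ** (2 * h) + (k + 1) ** (2 * h)
    )


def _fgn_davies_harte(n: int, h: float, rng: np.random.Generator) -> np.ndarray:
    gamma = _fgn_autocov(n, h)
    # first row of the circulant embedding, length 2n
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8:  # theoretically nonnegative for fGn; guard anyway
        lam = np.clip(lam, 0.0, None)
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    w[n] = np.sqrt(lam[n] / m) * rng.standard_normal()
    u = rng.standard_normal(n - 1)
    v = rng.standard_normal(n - 1)
    j = np.arange(1, n)
    w[j] = np.sqrt(lam[j] / (2 * m)) * (u + 1j * v)
    w[m - j] = np.conj(w[j])
    return np.fft.fft(w).real[:n]


def generate_persistent_series(spec: SyntheticSpec) -> Series:
    """Seeded fGn series whose theoretical Hurst parameter is
    ``spec.persistence``, scaled by ``noise_scale`` and with an optional
    additive linear trend."""
    rng = np.random.default_rng(spec.seed)
    x = spec.noise_scale * _fgn_davies_harte(spec.n, spec.persistence, rng)
    if spec.trend:
        x = x + spec.trend * np.arange(spec.n)
    return Series(tuple(float(v) for v in x), label=f"fgn(H={spec.persistence})")


#: (start level, per-period slope) per pollutant, calibrated to the Hebei
#: 2013 and 2020 annual means implied by the published sub-indices.
PANEL_PROFILES: Mapping[str, tuple[float, float]] = {
    "PM2.5": (108.0, -7.6),
    "PM10": (190.0, -11.7),
    "O3": (183.0, -1.3),
    "NO2": (62.0, -4.0),
    "CO": (4.3, -0.36),
    "SO2": (98.0, -12.1),
}


def generate_pollutant_panel(spec: SyntheticSpec) -> dict[str, ConcentrationSeries]:
    """Six seeded concentration series declining linearly plus noise.

    Per pollutant the mean path is ``start + trend * slope * t``; Gaussian
    noise has standard deviation ``noise_scale * 5%`` of the start level.
    Values are floored at zero. ``spec.trend`` defaults to 0 in the dataclass
    but a panel with no decline is rarely wanted: pass ``trend=1.0`` for the
    calibrated declines (the CLI's simulate command does).
    """
    rng = np.random.default_rng(spec.seed)
    periods = tuple(range(spec.n))
    trend = spec.trend if spec.trend else 1.0
    panel: dict[str, ConcentrationSeries] = {}
    for code, (start, slope) in PANEL_PROFILES.items():
        mean_path = start + trend * slope * np.arange(spec.n)
        noise = rng.standard_normal(spec.n) * (spec.noise_scale * 0.05 * start)
        values = np.clip(mean_path + noise, 0.0, None)
        panel[code] = ConcentrationSeries(
            POLLUTANTS[code], periods, tuple(float(v) for v in values)
        )
    return panel
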