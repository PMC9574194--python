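"""Rescaled-range (R/S) analysis and Hurst-exponent estimation.

For a window ``x_1 ... x_k`` the rescaled range is the range of the cumulative
mean-deviations divided by the population standard deviation:

    S(k)   = sqrt( (1/k) * sum (x_i - mean)^2 )
    X(t_j) = sum_{i<=j} (x_i - mean)
    R(k)   = max_j X(t_j) - min_j X(t_j)
    R/S    = R(k) / S(k)

For a long-memory series (R/S)_k grows like ``k^H``; the Hurst exponent H is
the OLS slope of ln(R/S) on ln k. H > 0.5 indicates persistence (future trend
continues the past), H = 0.5 an independent series, H < 0.5 anti-persistence.
The V statistic ``V_k = (R/S)_k / sqrt(k)`` is flat for independent series and
slopes upward under persistence; a break in it suggests a cycle length.

Three window policies are supported for forming (R/S)_k at span k:

- ``anchored`` (default): the single window ``x_1 ... x_k`` growing from the
  series start;
- ``partition``: the mean of R/S over the ``floor(n/k)`` disjoint windows;
- ``sliding``: the mean over all ``n - k + 1`` overlapping windows.

Note the cumulative deviation at a window's end is identically zero (the
deviations sum to zero), so the range always brackets zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateWindowError, ValidationError

__all__ = [
    "WindowPolicy",
    "Series",
    "RSTrace",
    "HurstFit",
    "VTrace",
    "rs_statistic",
    "rs_trace",
    "fit_hurst",
    "classify_hurst",
    "v_statistic",
]


class WindowPolicy(str, Enum):
    ANCHORED = "anchored"
    PARTITION = "partition"
    SLIDING = "sliding"


@dataclass(frozen=True)
class Series:
    """A finite real-valued time series of length >= 2."""

    values: tuple[float, ...]
    label: str = ""

    def __post_init__(self):
        if len(self.values) < 2:
            raise ValidationError("series needs at least two observations")
        if not all(math.isfinite(v) for v in self.values):
            raise ValidationError("series values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RSTrace:
    """(R/S)_k over a range of spans, with the (ln k, ln R/S) pairs."""

    spans: tuple[int, ...]
    rs: tuple[float, ...]
    label: str = ""

    def __post_init__(self):
        if len(self.spans) != len(self.rs):
            raise ValidationError("spans and rs must have equal length")
        if any(b <= a for a, b in zip(self.spans, self.spans[1:])):
            raise ValidationError("spans must be strictly increasing")
        if any(r <= 0 for r in self.rs):
            raise ValidationError("R/S values must be positive")

    @property
    def log_pairs(self) -> tuple[tuple[float, float], ...]:
        return tuple((math.log(k), math.log(r)) for k, r in zip(self.spans, self.rs))


@dataclass(frozen=True)
class HurstFit:
    """OLS fit of ln(R/S) on ln k: slope is the Hurst exponent."""

    hurst: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int

    @property
    def persistence(self) -> str:
        return classify_hurst(self.hurst)


@dataclass(frozen=True)
class VTrace:
    """V_k = (R/S)_k / sqrt(k) per span, with a monotonicity diagnostic."""

    spans: tuple[int, ...]
    v: tuple[float, ...]

    @property
    def non_decreasing(self) -> bool:
        """True when V never drops as the span grows (persistent reading)."""
        return all(b >= a - 1e-12 for a, b in zip(self.v, self.v[1:]))


def _window_rs(w: np.ndarray, start: int) -> float:
    s = w.std()  # population (1/k) convention
    if s == 0:
        raise DegenerateWindowError(start, len(w))
    cum = np.cumsum(w - w.mean())
    # cum[-1] == 0 up to rounding; include 0 explicitly so the range always
    # brackets the value attained at the window end
    r = max(cum.max(), 0.0) - min(cum.min(), 0.0)
    return float(r / s)


def rs_statistic(
    series: Series | Sequence[float],
    k: int,
    policy: WindowPolicy | str = WindowPolicy.ANCHORED,
) -> float:
    """(R/S)_k of a series at span ``k`` under a window policy.

    Raises
    ------
    ValidationError
        If ``k`` is outside ``[2, n]``.
    DegenerateWindowError
        If any evaluated window is constant (zero standard deviation).
    """
    values = series.values if isinstance(series, Series) else tuple(series)
    x = np.asarray(values, dtype=float)
    n = x.size
    policy = WindowPolicy(policy)
    if not 2 <= k <= n:
        raise ValidationError(f"span k={k} outside valid range [2, {n}]")
    if policy is WindowPolicy.ANCHORED:
        starts = [0]
    elif policy is WindowPolicy.PARTITION:
        starts = list(range(0, (n // k) * k, k))
    else:
        starts = list(range(0, n - k + 1))
    return float(np.mean([_window_rs(x[s : s + k], s) for s in starts]))


def rs_trace(
    series: Series | Sequence[float],
    k_min: int = 2,
    k_max: int | None = None,
    policy: WindowPolicy | str = WindowPolicy.ANCHORED,
) -> RSTrace:
    """The sequence {(R/S)_k} for k = k_min ... k_max (default: 2 ... n)."""
    values = series.values if isinstance(series, Series) else tuple(series)
    label = series.label if isinstance(series, Series) else ""
    n = len(values)
    if k_max is None:
        k_max = n
    if not 2 <= k_min <= k_max <= n:
        raise ValidationError(f"need 2 <= k_min <= k_max <= n, got ({k_min}, {k_max}, n={n})")
    spans = tuple(range(k_min, k_max + 1))
    rs = tuple(rs_statistic(values, k, policy) for k in spans)
    return RSTrace(spans, rs, label)


def fit_hurst(
    trace: RSTrace | Sequence[tuple[float, float]],
    include_k2: bool = True,
) -> HurstFit:
    """Hurst exponent by OLS of ln(R/S) on ln k.

    Accepts an :class:`RSTrace` or raw (ln k, ln R/S) pairs. ``include_k2``
    keeps or drops the analytically forced k=2 point (ln R/S = 0); it is kept
    by default. R² is the squared Pearson correlation; the p-value is the
    two-sided t test on the slope.
    """
    pairs = trace.log_pairs if isinstance(trace, RSTrace) else tuple(trace)
    if not include_k2:
        pairs = tuple(p for p in pairs if abs(p[0] - math.log(2)) > 1e-12)
    if len(pairs) < 2:
        raise ValidationError("need at least two log pairs to fit")
    lnk, lnrs = zip(*pairs)
    res = stats.linregress(lnk, lnrs)
    return HurstFit(
        hurst=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=len(pairs),
    )


def classify_hurst(h: float, tol: float = 1e-9) -> str:
    """Persistence class: 'persistent' (H > 0.5), 'independent' (H = 0.5),
    'anti-persistent' (H < 0.5)."""
    if not math.isfinite(h):
        raise ValidationError(f"Hurst exponent must be finite, got {h}")
    if abs(h - 0.5) <= tol:
        return "independent"
    return "persistent" if h > 0.5 else "anti-persistent"


def v_statistic(trace: RSTrace) -> VTrace:
    """V statistic V_k = (R/S)_k / sqrt(k) per span of a trace."""
    if not trace.spans:
        raise ValidationError("empty trace")
    v = tuple(r / math.sqrt(k) for k, r in zip(trace.spans, trace.rs))
    return VTrace(trace.spans, v)
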