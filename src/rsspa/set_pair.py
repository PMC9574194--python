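"""Five-element set-pair analysis (SPA) for graded environmental assessment.

SPA describes the relation between an observed indicator set and a grading
standard by a connection number: identity (a), three graded difference
components (b1, b2, b3) and opposition (c), all nonnegative and summing to 1.
For a "smaller-is-better" indicator x with grade thresholds s1 < ... < s5 the
single-index connection number is piecewise linear: x <= s1 is pure identity,
x > s5 pure opposition, and between consecutive thresholds the mass is split
linearly between the two adjacent components.

A panel of indicators is synthesised by a weighted component-wise average, and
the scalar connection degree

    mu = a + b1*lambda + b2*gamma + b3*phi + c*psi

is evaluated with coefficients from the equal-proportion rule on [-1, 1]
(lambda = 0.5, gamma = 0, phi = -0.5, psi = -1 for five grades). The degree is
graded on five safety intervals, the set-pair potential a/c classifies the
trend direction, and partial connection numbers (recursive adjacent ratios,
e.g. da = a/(a+b1)) measure internal drift toward identity, defined to fourth
order for five elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ValidationError

__all__ = [
    "ConnectionNumber",
    "GradeThresholds",
    "CoefficientScheme",
    "WeightVector",
    "GradeJudgment",
    "PotentialClass",
    "PartialConnectionResult",
    "PeriodAssessment",
    "single_index_connection",
    "build_evaluation_matrix",
    "comprehensive_connection",
    "coefficient_scheme",
    "evaluate_connection",
    "judge_grade",
    "set_pair_potential",
    "partial_connection",
    "assess_panel",
    "default_thresholds",
    "GRADE_INTERVALS",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ConnectionNumber:
    """Five nonnegative components (a, b1, b2, b3, c) summing to 1."""

    a: float
    b1: float
    b2: float
    b3: float
    c: float

    def __post_init__(self):
        comps = self.components
        if any(v < -_SUM_TOL for v in comps):
            raise ValidationError(f"components must be nonnegative, got {comps}")
        if abs(sum(comps) - 1.0) > _SUM_TOL:
            raise ValidationError(f"components must sum to 1, got {sum(comps)}")

    @property
    def components(self) -> tuple[float, float, float, float, float]:
        return (self.a, self.b1, self.b2, self.b3, self.c)


@dataclass(frozen=True)
class GradeThresholds:
    """Critical values s1 < s2 < s3 < s4 < s5 separating the five grades."""

    s1: float
    s2: float
    s3: float
    s4: float
    s5: float

    def __post_init__(self):
        s = self.as_tuple
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValidationError(f"thresholds must be strictly increasing, got {s}")

    @property
    def as_tuple(self) -> tuple[float, ...]:
        return (self.s1, self.s2, self.s3, self.s4, self.s5)


@dataclass(frozen=True)
class CoefficientScheme:
    """Evaluation coefficients (lambda, gamma, phi, psi) on [-1, 1]."""

    lambda_: float
    gamma: float
    phi: float
    psi: float = -1.0

    def __post_init__(self):
        if not 1 > self.lambda_ > self.gamma > self.phi > self.psi:
            raise ValidationError(
                "coefficients must satisfy 1 > lambda > gamma > phi > psi"
            )
        if self.psi != -1.0:
            raise ValidationError("psi is fixed at -1")


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative indicator weights summing to 1."""

    weights: tuple[float, ...]

    def __post_init__(self):
        if any(w < 0 for w in self.weights):
            raise ValidationError("weights must be nonnegative")
        if abs(sum(self.weights) - 1.0) > _SUM_TOL:
            raise ValidationError(f"weights must sum to 1, got {sum(self.weights)}")

    @classmethod
    def equal(cls, n: int) -> "WeightVector":
        return cls(tuple(1.0 / n for _ in range(n)))


@dataclass(frozen=True)
class GradeJudgment:
    degree: float
    grade: str  # I ... V
    level: str  # unsafe ... safe


@dataclass(frozen=True)
class PotentialClass:
    """Set-pair potential a/c and its trend label."""

    ratio: float  # inf when c == 0 and a > 0; nan when both are 0
    label: str  # same | balanced | opposite | indeterminate


@dataclass(frozen=True)
class PartialConnectionResult:
    """Partial connection numbers to fourth order (adjacent-ratio recursion)."""

    order1: tuple[float, float, float, float]
    order2: tuple[float, float, float]
    order3: tuple[float, float]
    order4: float


@dataclass(frozen=True)
class PeriodAssessment:
    """Full SPA result for one period of a panel."""

    period: object
    connection: ConnectionNumber
    degree: float
    judgment: GradeJudgment
    potential: PotentialClass
    partials: PartialConnectionResult
    trend: str | None  # improve | decline | steady; None for the first period


#: Degree intervals (lower, upper, grade, level), boundaries assigned upward.
GRADE_INTERVALS: tuple[tuple[float, float, str, str], ...] = (
    (-1.0, -0.6, "I", "unsafe"),
    (-0.6, -0.2, "II", "less safe"),
    (-0.2, 0.2, "III", "critical safe"),
    (0.2, 0.6, "IV", "relatively safe"),
    (0.6, 1.0, "V", "safe"),
)


def single_index_connection(
    x: float, thresholds: GradeThresholds
) -> ConnectionNumber:
    """Connection number of one smaller-is-better indicator value.

    Piecewise linear in x: pure identity at or below s1, pure opposition above
    s5, and a linear split between adjacent components in between. Continuous
    at every threshold.
    """
    s = thresholds.as_tuple
    if not math.isfinite(x):
        raise ValidationError(f"indicator value must be finite, got {x}")
    comps = [0.0] * 5
    if x <= s[0]:
        comps[0] = 1.0
    elif x > s[4]:
        comps[4] = 1.0
    else:
        for i in range(4):
            if s[i] < x <= s[i + 1]:
                frac = (x - s[i]) / (s[i + 1] - s[i])
                comps[i] = 1.0 - frac
                comps[i + 1] = frac
                break
    return ConnectionNumber(*comps)


def build_evaluation_matrix(
    grade_counts: Sequence[Sequence[float]], z: float
) -> list[tuple[float, ...]]:
    """Row-normalised grade-membership frequencies u_js = z_js / z.

    ``grade_counts`` holds per-indicator counts over the five grades; each row
    must sum to ``z`` (the number of graders).
    """
    if z <= 0:
        raise ValidationError(f"total count must be positive, got {z}")
    rows = []
    for j, counts in enumerate(grade_counts):
        if len(counts) != 5:
            raise ValidationError(f"row {j}: expected 5 grade counts, got {len(counts)}")
        if any(v < 0 for v in counts):
            raise ValidationError(f"row {j}: counts must be nonnegative")
        if abs(sum(counts) - z) > _SUM_TOL * max(1.0, z):
            raise ValidationError(f"row {j}: counts sum to {sum(counts)}, expected {z}")
        rows.append(tuple(v / z for v in counts))
    return rows


def comprehensive_connection(
    conns: Sequence[ConnectionNumber], weights: WeightVector | Sequence[float] | None = None
) -> ConnectionNumber:
    """Component-wise weighted average of per-indicator connection numbers."""
    if not conns:
        raise ValidationError("need at least one connection number")
    if weights is None:
        weights = WeightVector.equal(len(conns))
    elif not isinstance(weights, WeightVector):
        weights = WeightVector(tuple(weights))
    if len(weights.weights) != len(conns):
        raise ValidationError(
            f"{len(conns)} connection numbers but {len(weights.weights)} weights"
        )
    comps = [
        sum(w * cn.components[i] for w, cn in zip(weights.weights, conns))
        for i in range(5)
    ]
    return ConnectionNumber(*comps)


def coefficient_scheme(n_grades: int = 5) -> CoefficientScheme:
    """Equal-proportion coefficients on [-1, 1]: i_l = (5 - (2l+1)) / 4.

    Only the five-grade scheme is defined: lambda = 0.5, gamma = 0,
    phi = -0.5, with psi fixed at -1.
    """
    if n_grades != 5:
        raise ValidationError(f"only the 5-grade scheme is defined, got {n_grades}")
    lam, gam, phi = ((5 - (2 * l + 1)) / (5 - 1) for l in (1, 2, 3))
    return CoefficientScheme(lam, gam, phi, -1.0)


def evaluate_connection(
    conn: ConnectionNumber, scheme: CoefficientScheme | None = None
) -> float:
    """Scalar degree a + b1*lambda + b2*gamma + b3*phi + c*psi, in [-1, 1]."""
    scheme = scheme or coefficient_scheme()
    return (
        conn.a
        + conn.b1 * scheme.lambda_
        + conn.b2 * scheme.gamma
        + conn.b3 * scheme.phi
        + conn.c * scheme.psi
    )


def judge_grade(degree: float) -> GradeJudgment:
    """Safety grade of a connection degree; boundary values go to the higher
    (safer) grade."""
    if not -1.0 - _SUM_TOL <= degree <= 1.0 + _SUM_TOL:
        raise ValidationError(f"degree must lie in [-1, 1], got {degree}")
    for lo, hi, grade, level in reversed(GRADE_INTERVALS):
        if degree >= lo:
            return GradeJudgment(degree, grade, level)
    return GradeJudgment(degree, "I", "unsafe")  # degree within tol below -1


def set_pair_potential(conn: ConnectionNumber) -> PotentialClass:
    """Trend potential a/c: > 1 'same' (favorable), = 1 'balanced', < 1
    'opposite'. With c = 0 the ratio degenerates: 'same' when a > 0,
    'indeterminate' when a = 0."""
    a, c = conn.a, conn.c
    if c == 0:
        if a > 0:
            return PotentialClass(math.inf, "same")
        return PotentialClass(math.nan, "indeterminate")
    ratio = a / c
    if ratio > 1:
        label = "same"
    elif ratio == 1:
        label = "balanced"
    else:
        label = "opposite"
    return PotentialClass(ratio, label)


def _adjacent_ratios(comps: Sequence[float]) -> tuple[float, ...]:
    out = []
    for u, v in zip(comps, comps[1:]):
        denom = u + v
        out.append(u / denom if denom > 0 else 0.0)  # 0/0 -> 0 by convention
    return tuple(out)


def partial_connection(conn: ConnectionNumber, order: int = 4) -> PartialConnectionResult:
    """Partial connection numbers up to ``order`` (1-4).

    Order 1 maps (a, b1, b2, b3, c) to the adjacent ratios
    (a/(a+b1), b1/(b1+b2), b2/(b2+b3), b3/(b3+c)); each further order
    re-applies the rule to the previous tuple, losing one entry per order.
    0/0 is taken as 0. Orders above the requested one are filled anyway
    (the recursion is cheap); ``order`` only validates the request.
    """
    if order not in (1, 2, 3, 4):
        raise ValidationError(f"order must be 1-4, got {order}")
    o1 = _adjacent_ratios(conn.components)
    o2 = _adjacent_ratios(o1)
    o3 = _adjacent_ratios(o2)
    o4 = _adjacent_ratios(o3)
    return PartialConnectionResult(o1, o2, o3, o4[0])


def default_thresholds() -> dict[str, GradeThresholds]:
    """Grade thresholds from the breakpoint grid: each pollutant's
    concentration limits at sub-indices 50, 100, 150, 200 and 300 (e.g.
    PM2.5: 35, 75, 115, 150, 250), applied to concentrations."""
    from .aqi import DEFAULT_CONC_GRIDS

    out = {}
    for code, grid in DEFAULT_CONC_GRIDS.items():
        out[code] = GradeThresholds(*grid[1:6])
    return out


def assess_panel(
    panel: Mapping[object, Mapping[str, float]] | Sequence[tuple[object, Mapping[str, float]]],
    thresholds: Mapping[str, GradeThresholds],
    weights: WeightVector | None = None,
    scheme: CoefficientScheme | None = None,
) -> list[PeriodAssessment]:
    """Full SPA pipeline over a multi-indicator panel.

    ``panel`` maps each period to ``{indicator: value}``; all periods must
    carry the same indicator set, each present in ``thresholds``. Per period:
    single-index connection numbers, weighted synthesis, degree, grade,
    potential and partials. Trend labels compare consecutive degrees
    ('improve' when the degree rose, 'decline' when it fell, 'steady'
    otherwise); the first period has none.
    """
    items = list(panel.items()) if isinstance(panel, Mapping) else list(panel)
    if not items:
        raise ValidationError("empty panel")
    scheme = scheme or coefficient_scheme()
    indicators = sorted(items[0][1])
    missing = [i for i in indicators if i not in thresholds]
    if missing:
        raise ValidationError(f"no thresholds for indicators: {missing}")
    if weights is None:
        weights = WeightVector.equal(len(indicators))

    results: list[PeriodAssessment] = []
    prev_degree: float | None = None
    for period, row in items:
        if sorted(row) != indicators:
            raise ValidationError(
                f"period {period!r}: indicators {sorted(row)} differ from {indicators}"
            )
        conns = [single_index_connection(row[i], thresholds[i]) for i in indicators]
        comp = comprehensive_connection(conns, weights)
        degree = evaluate_connection(comp, scheme)
        trend = None
        if prev_degree is not None:
            if degree > prev_degree:
                trend = "improve"
            elif degree < prev_degree:
                trend = "decline"
            else:
                trend = "steady"
        results.append(
            PeriodAssessment(
                period=period,
                connection=comp,
                degree=degree,
                judgment=judge_grade(degree),
                potential=set_pair_potential(comp),
                partials=partial_connection(comp),
                trend=trend,
            )
        )
        prev_degree = degree
    return results
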