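# Methods

## AQI computation

The individual air-quality index of pollutant p with concentration C is the
piecewise-linear interpolation

    IAQI_p = (IAQI_hi − IAQI_lo) / (BP_hi − BP_lo) · (C − BP_lo) + IAQI_lo

on the packaged breakpoint grid (GB 3095-2012 scheme; sub-index grid
0/50/100/150/200/300/400/500). Both grids are strictly increasing, so the map
is continuous, monotone, exact at every breakpoint and invertible
(`invert_iaqi`); the round-trip holds to 1e-9. Ozone has no breakpoints above
sub-index 300: concentrations beyond 800 µg/m³ return the top defined
sub-index with a `truncated` flag rather than an extrapolation, since the
interpolation formula is undefined without a bracketing segment. The
composite AQI of a period is the maximum IAQI; all pollutants attaining the
maximum are reported as primary. Band boundaries are the continuous extension
of the integer bands: level 1 for AQI ≤ 50, level 2 for 50 < AQI ≤ 100, and
so on (141.25 and 112.73 are both level 3). IAQI values are kept at full
floating precision; two-decimal rounding is display-only.

The dispersion summary `coefficient_of_variation` is the population
(divide-by-n) standard deviation over the mean, consistent with the R/S
module's SD convention; it requires a positive mean.

## Rescaled-range analysis

Per window: mean, population SD `S(k)`, cumulative deviations
`X(t_j) = Σ_{i≤j}(x_i − mean)`, range `R(k) = max X − min X`, and
`R/S = R(k)/S(k)`. The deviations of a window sum to zero, so the cumulative
path ends at zero and the range always brackets zero (enforced explicitly for
numerical safety). At k = 2 any non-constant pair gives R/S = 1 exactly, so
ln(R/S) = 0 is analytically forced there.

Three window policies form `(R/S)_k` at span k:

- **anchored** (default) — the single window `x_1 … x_k` grown from the
  series start. This is the convention that reproduces the published Hebei
  trace at its reproducible cells (the k = 2 row and the full-span k = 8
  value, 1.2119 vs the printed 1.21).
- **partition** — the average over `⌊n/k⌋` disjoint windows (the classical
  subset average). Used for the synthetic-recovery tests at n = 256.
- **sliding** — the average over all `n − k + 1` overlapping windows.

The published intermediate-span values (k = 3 … 7) are not exactly
reproducible under any of the three policies (differences up to ~0.08), so
the policy is explicit and configurable and golden tests use only the
reproducible cells plus the printed log–log pairs. Likewise, the upward slope
of the V statistic `V_k = (R/S)_k/√k` holds for the published trace but not
pointwise for the anchored recomputation (V dips at k = 5), so the
monotonicity check is asserted on the published trace.

`fit_hurst` is an OLS regression of ln(R/S) on ln k (natural logs throughout;
slope = H, R² = squared Pearson correlation, p-value from the slope t-test).
The k = 2 point is included by default because the published regression
includes it; `include_k2=False` drops it. Classification: persistent for
H > 0.5, independent at H = 0.5 (tolerance 1e-9), anti-persistent below. A
constant window raises a degeneracy error naming the window rather than
returning infinity.

With only eight annual observations the Hurst regression has seven points,
five of them from overlapping anchored windows; the estimate is descriptive,
not an efficient estimator, and no cycle length is inferred from V (the
original study could not identify one either).

## Set-pair analysis

For a smaller-is-better indicator x with thresholds s₁ < … < s₅ the
five-element connection number is pure identity (1,0,0,0,0) at x ≤ s₁, pure
opposition (0,0,0,0,1) above s₅, and between consecutive thresholds splits
mass linearly between the two adjacent components — continuous in x,
conservative (components ≥ 0, sum = 1), with mass drifting monotonically
toward opposition as x grows. Default thresholds are the breakpoint-grid
concentrations at sub-indices 50/100/150/200/300 per pollutant (PM2.5:
35/75/115/150/250 µg/m³ …); because the thresholds coincide with the
breakpoints, grading concentrations against them is equivalent to grading
IAQI values against 50/100/150/200/300. Thresholds and weights are fully
configurable; packaged weights are equal (1/6).

Synthesis is a component-wise weighted average; the degree
`μ = a + b₁λ + b₂γ + b₃φ + cψ` uses the equal-proportion coefficients
λ = 0.5, γ = 0, φ = −0.5, ψ = −1 (from i_l = (5−(2l+1))/4). The degree is
linear in the synthesis, so the comprehensive degree equals the weighted
average of per-indicator degrees — this is tested and is why the published
degree column can be recomputed either way. Grading uses the five safety
intervals of [−1, 1] with boundary values assigned to the higher (safer)
grade, a deterministic tie-break for intervals that share endpoints as
printed.

Set-pair potential: a/c > 1 "same" (favourable trend), = 1 "balanced",
< 1 "opposite". With c = 0 the ratio degenerates; the label is "same" when
a > 0 (the source applies the a/c > 1 language to such rows) and
"indeterminate" when a = 0.

Partial connection numbers re-apply the adjacent-ratio rule
(∂a = a/(a+b₁), ∂b₁ = b₁/(b₁+b₂), …) to the previous order's tuple, down to
a single fourth-order value; 0/0 is defined as 0 so the pure-identity case
stays total. Note: the published table column labelled "fourth-order partial
relation number" is numerically the evaluated comprehensive degree for every
year, not this recursion; both quantities are computed and reported, and the
golden tests follow the numeric reproduction (the degree).

Trend labels compare consecutive degrees: "improve" when the degree rose,
"decline" when it fell, "steady" otherwise; the first period has no label.

## Fixtures and known source inconsistencies

The eight study tables ship as package CSVs, cell-for-cell as printed, with
machine-readable notes in `data/provenance.json`. Known internal
inconsistencies are carried verbatim and flagged rather than corrected:

- the 2016 PM2.5 sub-index (137.50) breaks the monotone concentration
  decline and disagrees with the 2016 connection number;
- the 2013 comprehensive b₂ (0.325) and 2015 b₁ (0.627) differ from the
  values implied by the per-pollutant table (0.2788, 0.635) — consequently
  the recomputed 2015 degree is 0.6742 vs the printed 0.671, outside ±0.001,
  and the test there uses ±0.005;
- the O3 2015 entry (a bare "Λ") is encoded as a pure-λ term (b₁ = 1);
- PM2.5 2017–2020 repeat identical connection numbers although the
  sub-indices differ (the underlying concentrations were never printed);
- the per-pollutant connection numbers are not all derivable from the
  sub-index table: the study graded raw annual concentrations, which were
  published only as a figure. Golden tests of the SPA synthesis therefore
  start from the connection-number table itself (also accepted by the CLI
  via `rsspa spa --from-connections`).

## Synthetic data

`generate_persistent_series` draws fractional Gaussian noise by Davies–Harte
circulant embedding: the fGn autocovariance
γ(k) = ½(|k−1|^{2H} − 2|k|^{2H} + |k+1|^{2H}) is embedded in a circulant
matrix whose eigenvalues (an FFT of the first row, nonnegative for H ∈ (0,1))
weight a complex Gaussian vector that transforms back into a series with
exactly the target autocovariance. H = 0.5 collapses γ to a delta, i.e.
independent Gaussian noise. Generators are pure functions of their spec
(seed included). Recovery is tested as an ordering property: over 100 seeded
replicates at n = 256 (partition policy, spans 2…64 in octaves), the fitted H
of the H = 0.8 series exceeds that of white noise in ≥ 90 replicates
(observed: 99). The spans-in-octaves choice is the standard R/S practice of
balancing window counts across scales.

`generate_pollutant_panel` emulates six annual-mean series declining
linearly at pollutant-specific rates calibrated to the Hebei 2013 → 2020
endpoints implied by the published sub-indices (e.g. PM2.5 108 → 54.6 µg/m³),
plus Gaussian noise with SD equal to `noise_scale` × 5% of the start level,
floored at zero. What the generators do **not** emulate: seasonality, diurnal
structure, measurement error correlated across pollutants, or regime changes
from policy interventions — passing tests show estimator behaviour under the
stated stochastic models, not performance on real monitoring data.

## Problem sizes and numerical choices

All golden computations are desk-scale (series of length 8, six indicators,
eight periods); the Monte-Carlo recovery check uses 100 replicates of length
256. Tolerances: published two-decimal log values are matched within ±0.005,
Hurst exponents within ±0.01, R² within ±0.005, SPA components and degrees
within ±0.001 (±0.005 for the inconsistent 2015 row); exact identities
(k = 2, conservation, round-trips) within 1e-9–1e-12. Equality comparisons on
connection-number sums use a 1e-9 tolerance.
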