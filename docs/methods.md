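# Methods

## The model

Protection Equality treats a protected-area network as an allocation
problem: a region holds N conservation features with areas a₁…a_N, of
which p₁…p_N are protected, and asks how evenly that protection is
distributed. The protection values — absolute amounts pᵢ for the
fixed-area variant, fractions pᵢ/aᵢ for the proportional variant — are
ranked ascending and accumulated into a discrete Lorenz curve anchored at
the origin, with abscissae i/N. PE is the trapezoid area under the curve
divided by the triangle under the perfect-equality chord, which reduces to
the closed form

    PE = ( ½ Σv + Σ_{i=1}^{N−1} v₍ᵢ₎ (N−i) ) / ( N · ½ Σv ),

identical to 1 − G with G the population Gini (pairwise mean difference
over twice the mean). Both routes are implemented: `pe_fixed` /
`pe_proportional` evaluate the closed form; `pe_from_curve` integrates the
curve with `numpy.trapezoid`. They are required to agree to 1e-12 relative
tolerance, and the Gini duality is property-tested against an independent
pairwise-sum oracle at 1e-10.

The discrete construction floors raw PE at 1/N (a single protected feature
still subtends a triangle of area 1/(2N)), so small regions could never
score near 0. The correction PE_c = (PE − 1/N)·N/(N−1) maps that floor to
0 and fixes PE = 1; it is undefined at N = 1 and raised as a domain error
there. Because raw PE ≥ 1/N for every valid input, PE_c is never negative
and no clamping is applied (an assertion guards this instead).

### Assumptions and input contract

- Areas and protected areas share one unit; PE itself is dimensionless and
  invariant to the unit (fixed) or to joint rescaling of a and p
  (proportional).
- pᵢ = 0 is valid input: real networks contain unprotected features, and
  the summary statistics depend on them. Negative values are rejected.
- pᵢ > aᵢ arises from GIS overlap artifacts; the default is a named
  validation error, with an explicit `clamp=True` mode that truncates to
  aᵢ and records the affected ids — silent clamping would hide data
  errors.
- Zero total protection makes PE a 0/0; it is a domain error rather than a
  conventional 0, so callers cannot mistake "undefined" for "maximally
  unequal". Per-group summaries keep such groups as diagnostic rows.
- Ties in the ranking are irrelevant to PE (it depends only on the sorted
  multiset — property-tested via permutation invariance); a stable sort is
  used anyway so curve output is reproducible.

## Simulations

`run_simulation` sweeps the coefficient of variation (CV) of feature areas
over a grid of feature counts, contrasting two protection policies:
scenario 1 protects a constant fraction C of every feature (default
C = 0.10), which pins proportional PE at 1 and measures fixed-area PE;
scenario 2 protects a constant amount C_p of every feature (default 100,
in the same unit as the areas, against a default mean area of 1000), which
pins fixed-area PE at 1 and measures proportional PE. The pinned identity
is asserted on every replicate draw.

Feature areas are drawn from a gamma distribution with shape 1/CV² and
scale mean·CV², which guarantees positivity and matches the target mean
and CV in expectation; a lognormal with the same two moments is available
via `distribution="lognormal"`. CV = 0 short-circuits to exact copies of
the mean, making both metrics exactly 1. The generator reports the
realized sample CV alongside the nominal one, since at small N the two can
differ noticeably.

Defaults: N ∈ {5, 10, 100, 1000}, CV grid 0–1 in 0.1 steps, 500
replicates per cell. The test suite and acceptance checks run a scaled
sweep (N ∈ {5, 100}, 200 replicates), enough to resolve the monotone
decline of mean PE with CV (checked via Spearman rank correlation ≤ 0)
well above Monte-Carlo noise. Each grid cell gets an independent child
seed stream (`SeedSequence.spawn`), so results are bit-reproducible from
the spec seed and unaffected by grid shape.

### Scenario-2 feasibility

A fixed amount C_p can exceed the smallest drawn area once CV is large
(with gamma areas of mean 1000 and CV ≥ 0.5, some aᵢ < 100 is near-certain
at N = 100). The default is to reject such draws and record the grid cell
as missing with a logged reason; setting `clamp=True` truncates pᵢ to aᵢ
instead. Clamping deliberately alters the policy — a clamped feature is
100% protected rather than C_p-protected — so the PE_f = 1 identity is
only asserted on unclamped draws, and clamped sweeps should be read as
"protect C_p or everything, whichever is smaller".

### Generator dependence of scenario differences

Which scenario loses equality faster, and by how much, depends on the area
distribution, not only its CV. Under gamma areas the scenario-2 ratios
C_p/aᵢ are inverse-gamma distributed; at CV = 1 their population mean
diverges, so the scenario gap *grows* with N (≈0.33 at N = 1000 vs ≈0.08
at N = 5, CV = 1, mean area 10⁶). Under lognormal areas, C_p/aᵢ is
lognormal with the same CV as the areas, and the asymptotic gap vanishes.
The robust qualitative facts — both metrics equal 1 at CV = 0, decline
monotonically with CV, and the fixed-amount policy scores below the
proportional policy at moderate-to-high CV — hold under both generators
and are what the tests assert. Synthetic sweeps say nothing about the
spatial autocorrelation or heavy-tailed size structure of real ecoregion
systems; conclusions about real networks need real (aᵢ, pᵢ) tables.

## Reporting

`summarize` emits one row per group: corrected (and raw) PE_p and PE_f,
totals and means of p and a, mean/median/min/max of pᵢ/aᵢ, the proportion
of the region protected (Σp/Σa), N, and the count of features with any
protection formatted as `count (percent)` with two-decimal percentages
trimmed of trailing zeros (e.g. `6 (100)`, `17 (80.95)`). Note that
mean pᵢ / mean aᵢ equals Σp/Σa whenever every feature is counted; both are
emitted as defined. Curve output carries raw cumulative y and a
standardized column y/y_N so all curves end at (1, 1) — the scale used for
plotting; the metric itself always uses the raw values. Written reports
round-trip at full double precision (`%.17g`); outputs are TSV to avoid
locale decimal issues.

## Numerical choices

- All accumulation is double precision. The closed form is computed with a
  single final division, which keeps the perfect-inequality floor exactly
  at 1/N and the N = 2, 3 minima exact.
- "Pinned" policy identities (PE_p = 1 under proportional protection) are
  exact up to the 1-ulp noise of (C·a)/a division; tests assert them at
  1e-12 absolute.
- The gamma sampler can underflow to 0.0 at extreme CV; areas are floored
  at the smallest positive normal double to preserve the positivity
  contract.

## Known limitations

- No weighting of features by conservation desirability; all features
  count equally.
- The metrics are blind to *how much* is protected overall — a network
  protecting 1% of every feature scores PE = 1. The summary's
  mean(pᵢ/aᵢ) and Σp/Σa columns exist precisely to contextualize this.
- No GIS ingestion: users supply the flat (aᵢ, pᵢ) table; polygon
  intersection is upstream of this package.
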