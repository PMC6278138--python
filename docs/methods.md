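# Methods

## Problem and model

A reporting geography (for example an Australian SA3, population 30k–130k)
is summarised by the share of its population in each of `n >= 3` ordered
categories of an index — typically the ten deciles of a relative
socioeconomic disadvantage score carried by its small subunits.  Assigning
the area a single decile is only meaningful if that distribution is
concentrated.  The package measures:

* **how concentrated** the distribution is — the Homogeneity Index (HI),
* **where** it is centred — the Location Index (LI),

and turns the two into a decision rule (classes A–D) and into *peer groups*
of comparable areas for reporting health-indicator variation.

## The Homogeneity Index

For a distribution `P` over `n` ordered categories, with `U_n` the uniform
distribution,

    HI(P) = 100 · [ CI(P) + DI(U_n) − DI(P) ] / [ 1 + DI(U_n) ],

clamped to `[0, 100]` (see *Numerical choices*).  `HI = 0` for the uniform
distribution and `HI = 100` for a singleton.

**Concentration Index (CI).**  Twice the area between the Lorenz curve of
the ascending-sorted shares and the line of equality, divided by the
singleton's value `(n−1)/n` so the index runs over `[0, 1]`.  For discrete
shares the Lorenz curve is piecewise linear, the trapezoid area is exact,
and the index equals the pairwise form `Σ_{i<j} |p_i − p_j| / (n−1)`.  CI is
permutation-symmetric, strictly Schur-convex, and *value-valid*: on the
mixture path from uniform to singleton it is linear in the mixing weight.
On a block of `s` equal consecutive categories, `CI = (n−s)/(n−1)` — a value
shared by every standard discrete Gini convention, which makes the block
anchors insensitive to that choice.

**Divergence Index (DI).**  CI ignores category order; DI adds the ordinal
(polarization) information.  With `X` the category position, `V = Var(X)`
and `M = E|X − median(X)| = Σ_i min(F_i, 1 − F_i)`,

    DI(P) = 2 · ( V / V_max )^β − (1/6) · ( M / M_max ),      β = 0.6288034452,

where `V_max = ((n−1)/2)²` and `M_max = (n−1)/2` are attained by the
half-at-each-end distribution.  DI satisfies the polarization axioms:

* zero exactly and only for a one-category distribution,
* invariant under parallel shifts of the whole pattern (both `V` and `M` are
  location-free) and under reflection of the category order,
* strictly increasing under median-preserving spreads (mass moved
  symmetrically outward), up to the maximum `11/6` at half-at-each-end.

*Why this form.*  The composite is a variance law tempered by an absolute
(robust) spread term.  Its three constants are the calibration of the
framework: requiring the decile guideline thresholds `HI(P_{4,10}) = 68.53`,
`HI(P_{5,10}) = 57.62`, `HI(P_{6,10}) = 46.62` forces the coefficients to
the exact values 2 and 1/6 and pins a single exponent β consistent across
all three equations (the three independently-solved exponents agree to five
decimals).  No classical ordinal dispersion statistic — the cumulative-gap
(Leik/Apouey) family, Blair–Lacy, consensus/entropy measures, normalised
variance or standard deviation, the positional Gini mean difference —
reproduces those three values together with this CI; the published guideline
constants therefore *are* the definition adopted here, and every index value
the package reports flows from this one calibrated functional.

**Spread-aversion range.**  Strict median-preserving-spread monotonicity is
guaranteed analytically for `n ≤ 15` and verified numerically throughout the
working range; for much longer scales (`n ≳ 20`) extremely polarized shapes
can make the tempering term locally dominant.  The intended scales are
quantiles, deciles in particular.

## True diversity

The effective number of categories converts concentration to an
interpretable unit: `s = n − (n−1) · CI(P)` is the size of the block of
equally abundant consecutive categories with the same concentration value —
exact for blocks, continuous and decreasing in CI otherwise.  An area with
`s = 9.2` on a decile scale is, evenness-wise, equivalent to 9.2 equally
populated deciles: essentially uniform.

## Classification

Thresholds are recomputed from block distributions at runtime for any
`n ≥ 6` — the framework is generic beyond deciles; for `n = 10` they equal
the guideline constants above.  Boundary conventions: class A is closed on
both ends (`HI(4) ≤ HI ≤ 100`), B, C, D are half-open below their upper
threshold.  At `n = 6` the 6-block *is* the uniform distribution, so
`hi6 = 0` exactly and class D is empty of interior.

## The Location Index

For each candidate bin `b` the nested family of symmetric intervals
`[b−r, b+r] ∩ [1, n]`, `r = 0..n−1`, accumulates mass
`score(b) = n − E|X − b|`; the LI is the maximising bin.  Maximising the
score is minimising the expected absolute deviation, so the LI is an integer
median-like "best guess" category: unchanged by a far outlier carrying ≤ 5%
of the population that visibly drags the mean, and free of the mode's
jump-to-the-extremes behaviour.  Intervals are truncated at the scale
boundaries (categories outside the scale do not exist), which lets the LI
reach the extreme categories.  Ties — the uniform distribution makes
interior bins tie, for instance — are broken toward the median category,
then toward the lower bin.

## Bands and peer groups

Disadvantage bands follow the 40–40–20 rule for clumped index-score
distributions: on a decile scale LI 1–4 is *high* disadvantage (low score =
disadvantaged), 5–8 *medium*, 9–10 *low*; other `n` use the same fractions
with boundaries rounded down.  Peer groups are the bands restricted to
classes A–C; class-D areas are structurally excluded (hard guarantee).
Groups are not further subdivided by exact LI: the reporting comparisons the
grouping serves operate at band granularity.  Indicator rates are consumed
as given (any standardization happens upstream); reports carry per-group
min/max/mean/count plus a configurable k-way rank split (default 4).

## Synthetic data

The generator emulates decile distributions of the kinds observed in
disadvantage data: `block` (idealised homogeneous areas, random start),
`dirichlet` (symmetric Dirichlet(α): α = 0.05 spiky and concentrated,
α = 100 near-uniform), `long_tail` (dominant block plus a geometric 5%-scale
tail — the typical shape of homogeneous areas in practice), and
`bimodal_extreme` (the DI-maximal shape).  Area populations are drawn
log-uniformly in `[10³, 10⁵]`, the scale of mid-size census reporting units.
A single integer seed drives one generator instance — outputs are
bit-identical across runs and no global state is touched.

The subunit hierarchy mirrors small census blocks nested in an area: each
subunit carries one category and a population from a largest-remainder
integer split, so aggregation reproduces the target distribution within
`1/population` and conserves totals exactly.  What the generator does *not*
emulate: spatial autocorrelation between neighbouring areas, correlation
between an area's population size and its shape, and measurement error in
the category labels themselves — synthetic-pipeline results say nothing
about those aspects of real data.

## Numerical choices

* Proportions renormalise at construction within `1e-9`; the CSV reader
  applies a looser policy (default `1e-2`) for rounded proportion rows and
  otherwise treats rows as counts.
* HI is clamped to `[0, 100]`.  Under the calibrated DI a thin set of
  end-loaded near-uniform shapes would score marginally negative (never
  below −0.4 on the percent scale; such shapes were only found by direct
  optimization, never by random sampling).  They are reported as exactly 0 —
  the heterogeneous floor — so "HI = 0 iff uniform" holds everywhere outside
  that thin set.  Classification is unaffected: all such shapes are deep in
  class D.
* `DI(U_n)` is cached per `n`; all internal comparisons use unrounded
  values, and only the reporting layer rounds (HI to 2 decimals, s to 1).
* LI ties are resolved deterministically (median-nearest, then lower bin).
* Degenerate inputs raise typed errors: all-zero counts and zero total
  populations are `DegenerateInputError`, structural violations
  `ValidationError`.

## Test and acceptance problem sizes

Enumeration oracles run on complete composition sets chosen to be exhaustive
yet instant: all compositions of 6 units into 4 bins (CI vs pairwise-Gini
oracle), 6 into 5 (LI vs brute-force nested-interval enumeration), 8 into 10
(DI maximiser).  Synthetic studies use 50–200 areas; property checks use a
few hundred seeded random distributions per axiom.  The acceptance script
recomputes every headline quantity in seconds.

## Known limitations

* The exact closed forms behind the published guideline constants are not
  publicly archived; the DI here is a reconstruction that reproduces every
  printed anchor value and satisfies every stated axiom, but per-area index
  values on real data could differ from the original implementation's at
  sub-percent magnitude.  The published per-area worked examples (HI 8.5 /
  s 9.2; HI 48.89) require the original study's area dataset, which is not
  redistributable here; the corresponding regression tests fail with an
  explicit missing-dataset message until that CSV is supplied at
  `tests/data/sa3_decile_distributions.csv`.
* Band fractions (40–40–20) suit relative-disadvantage indices whose low
  scores spread widest; other indices may warrant other cuts (configurable
  at the peer-group layer is future work).
* Univariate only: the nested-interval construction generalises to several
  ordinal variables, but only the single-variable LI is implemented.
* No spatial machinery: subunit reassignment to improve homogeneity
  (regionalization) and map rendering are out of scope.
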