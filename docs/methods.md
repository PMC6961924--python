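# Methods

This note records the statistical model behind each stage, the parameters
that matter, the numerical conventions, and what the synthetic-country tests
do and do not establish about field data.

## Sampling frame

Units are sorted by total census population (descending, ties broken by
`unit_id` ascending for determinism) and cut into three contiguous terciles;
any remainder accrues from the low-density end, so 331 units split
110/110/111 with the largest populations in the *high* stratum. Per-stratum
sample sizes are `round_half_up(fraction × stratum size)` — the half-up rule
is a package convention (25% of 110 → 28), since ordinary banker's rounding
would give 27. Selection is simple random sampling without replacement
within stratum, seeded, and invariant to input row order (members are sorted
before drawing). The deliberate oversampling of dense strata is *not*
design-weighted downstream; see extrapolation.

## Mapping adjustments

The adjustment chain is fixed: mobility first, hidden second, both linear in
the crude count, so per-spot adjustment followed by summation equals
adjusting the sums when parameters are uniform (a tested identity).

A subtlety the implementation is explicit about: the mobility formula
`S2 = S1(1−p1) + S1·p1/m1` is exactly unbiased only when `p1` is the
proportion of *venue encounters* contributed by multi-venue visitors, not
the proportion of individuals who are mobile — venue-intercept interviews
sample attendance events, and a member visiting `m1` venues is encountered
`m1` times. Accordingly `estimate_mobility_params` pools spot-level
`multi_spot` responses weighted by spot attendance (midpoints), and `m1` by
mobile attendance; an unweighted mode exists for sensitivity. With
individual-level generative mobility `p1`, the encounter-level value is
`p1·m1 / (1 − p1 + p1·m1)`, which `SyntheticTruth.true_adjustment_params`
applies. Supplying an individual-level proportion where an encounter-level
one belongs biases `S2` upward by roughly `p1(m1−1)²/m1` relative terms.

`p2` may be a single fraction or a region→fraction mapping with an explicit
unit→region table; when several survey cities must be combined into one
national `p2`, `pooled_hidden_fraction` weights each city by its survey
sample size. This weighting rule is a package choice — nothing in the method
itself dictates how city-specific hidden fractions roll up, and results are
sensitive to it because `1/(1−p2)` is convex in `p2`.

Parameters and defaults: `p1 ∈ [0,1]` (p1 = 1 is well defined, `S2 = S1/m1`),
`m1 ≥ 1`, `p2 ∈ [0,1)` (the correction diverges at 1). Counts stay real
throughout; rounding (half-up) happens only at reporting.

## Extrapolation

Pooling is a ratio of sums, `p = ΣM_i/ΣN_i`, computed separately for the
min, mid and max columns. This is invariant to splitting a unit into
proportional sub-units and weights units by their census size, unlike a mean
of per-unit ratios (both properties are tested). Applying one national `p`
to every level makes rollups conserve exactly before rounding.

The linearity diagnostic is OLS of unit mid-estimates on unit census
populations *with intercept* (so the reported value is the squared Pearson
correlation); a through-origin option reports the uncentred R² of the
proportional model that extrapolation actually assumes — the two can differ
substantially and the default is the conventional, more conservative one.
Constant estimates across units return R² = 0 rather than an undefined 0/0.
A stratum-weighted pooling mode (per-stratum ratios combined by census
share) is provided purely as a sensitivity analysis and warns on use; the
headline method is the simple pooled ratio.

Extrapolation denominators are total census population; prevalence divides
national estimates by a sex-specific adult (15–49) denominator column. Both
are explicit arguments, never inferred.

## Multiplier and RDS estimation

`N = n/p` with interval inversion (`N_low = n/p_high`); estimates where `p̂`
or its lower bound is zero raise rather than return infinities, matching how
unusable service data should be handled (a quality gate, not a number).
Median synthesis is component-wise — point and each bound take independent
medians, with even counts averaging the central pair. Degenerate boundary
proportions (`p̂` of 0 or 1, or a zero-width interval) are flagged on the
estimate, not truncated.

The survey proportion uses RDS-II (Volz–Heckathorn): `p̂ = Σ(y_i/d_i) /
Σ(1/d_i)` with `d_i` the self-reported personal network size (≥ 1,
enforced). The sequential-sampling estimator often used by RDS analysis
software needs a population-size prior that the multiplier setting does not
supply; RDS-II is the fully specified, deterministic design adjustment, and
the multiplier formula is agnostic to which design-adjusted proportion feeds
it. Confidence intervals come from a seeded recruitment-chain bootstrap:
respondents are grouped by the indicator value of their recruiter, synthetic
chains of the observed length are regrown by drawing from the pool matching
the current state (a Markov chain on the indicator, started from a random
seed respondent), and the 2.5/97.5 percentiles over `n_boot` replicate
estimates are taken, clipped to contain the point estimate. Coverage under
the synthetic generator sits near nominal (the acceptance suite requires
90–98% at n = 250); the bootstrap ignores the finite sampling fraction, so
intervals are mildly conservative when the survey covers a large share of
the population.

## Delphi

Component-wise medians over valid ballots; a ballot with inverted bounds is
rejected and reported, never silently fixed. District density codes low/
medium/high as 1/2/3, averages arithmetically, and maps back with thresholds
at 1.5 and 2.5, boundary rounding *up* — the symmetric nearest-code rule,
declared here because the coding scheme itself does not fix it. Further
rounds replace earlier rounds outright; history is retained for audit.

## Synthetic country

The generator emulates the study conditions the pipeline is built for:
331 administrative units with log-uniform populations between 298 and
323,257 (administrative unit sizes are strongly right-skewed), 52% of the
population aged 15–49, a KP prevalence of 0.56% of adult females, hidden
fraction 0.58, encounter mobility from an individual-level `p1 = 0.206` with
mobile members visiting 2 venues, ~5 venues per unit, NGO service coverages
of 0.25/0.30, unique-object coverage 0.05, and a 450-respondent survey with
8 seeds and up to 3 recruits per recruiter. Degrees are 1 plus a negative
binomial (mean 10, shape 2), heavy-tailed as RDS populations typically are.

Mechanics worth knowing when interpreting tests:

* per-unit KP counts are Binomial(adult females, prevalence), so the
  national truth is itself random; unbiasedness checks compare means over
  replicates;
* reporting noise perturbs the min bound down and the max bound up by
  independent Uniform(0, noise) relative errors — brackets always contain
  the truth and midpoints are unbiased up to integer rounding;
* survey respondents are drawn degree-proportionally without replacement
  (Efraimidis–Spirakis keys), then a recruitment forest is assigned; the
  optional `dependence_or` multiplies inclusion weights for members known to
  any service, reproducing the classic source–survey dependence that biases
  multipliers downward (a tested direction);
* everything flows from one generator seeded by `SimConfig.seed`; identical
  configs are bit-identical.

What passing tests do **not** show about field data: the generator has no
informant bias correlated with venue size, no cross-district mobility, no
recruitment homophily, no misreported degrees, and service contact is
independent of venue visibility. Real deviations from those assumptions move
the estimators in ways the synthetic checks cannot detect; the simulation
establishes internal correctness (the estimators recover what the formulas
define) rather than field validity.

## Problem sizes used in the test and acceptance runs

Simulation-heavy checks run at reduced scale chosen to keep Monte-Carlo
error well inside the asserted tolerances: parameter-recovery uses 300
replicates of ~500-member countries; multiplier unbiasedness 500 replicates
of ~2,500-member countries with 250-respondent surveys (a ~10% sampling
fraction, typical of a city-level survey); bootstrap coverage 500 replicates
at 200 bootstrap chains. The acceptance script runs the full 331-unit
country once per seed.

## Known limitations

* The chain bootstrap conditions on the observed degree distribution; very
  small seed counts or strong indicator-recruiter clustering would widen its
  coverage error.
* Regional `p2` requires the caller to supply the unit→region mapping; no
  geography is inferred.
* Extrapolation propagates only the min/mid/max bracket — it is a range, not
  a confidence interval, and carries no sampling variance for the unit draw.
* The Delphi stage aggregates judgments; it inherits whatever biases the
  panel holds and the package deliberately reports medians without any
  convergence statistic beyond per-round history.
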