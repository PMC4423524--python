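# Methods

## Shared-responsibility (EFR) initiation rates

A respondent who reports being present at k initiations in the past year,
with m other established injectors present at the most recent one, is
assigned the per-annum rate k/(m+1): responsibility for each event is
divided equally among the m+1 established injectors present, so shares sum
to one across attendees.  This is equivalent in expectation to attributing
each event wholly to one attendee chosen uniformly at random — a property
the test suite checks by Monte Carlo.  Two assumptions are inherited from
the survey design: the others-present count at the *most recent* event
stands in for all of the respondent's past-year events, and the count of
initiations and the count of others present are treated as independent
across respondents only through their observed joint pair (the bootstrap
resamples the pair jointly).

Subgroup rates are means over all matching respondents, zeros included.
Initiators whose others-present count is missing have no defined share and
are removed from both numerator and denominator (the count is reported per
subgroup); this mirrors the convention that a headline table built from
~2,500 usable respondents excludes the ~2% of initiators with the item
missing.  Respondents who did not inject in the past year are retained by
default — some of them report initiations — and an `exclude_non_past_year`
switch removes them for sensitivity analysis, which is how "treating their
responsibility as zero" is operationalised.

Confidence intervals are percentile intervals from a nonparametric
bootstrap (default 5,000 replicates) resampling respondents within the
subgroup.  Percentile rather than BCa was chosen as the simplest defensible
interval; the downstream regression consumes the variance of ln λ across
replicates, so the same bootstrap pass yields both.  Replicates with zero
rate have no finite log and are dropped from that variance (their count is
reported); subgroups where *all* replicates are zero raise rather than
return an undefined interval.

## Precision-weighted subgroup regression

The 12 sex × career-bin × incarceration subgroups give one observation
each: response ln λ_EFR, indicator terms for male, career 6–10, career ≥11
and ever-incarcerated (baselines female / 0–5 / never), and weights equal
to the bootstrap precision 1/Var(ln λ).  The fit is ordinary weighted
least squares (delegated to statsmodels' WLS, which matches the
weighted-normal-equation solve the tests verify against), with t-based
p-values on n − p = 7 degrees of freedom.  A subgroup with λ = 0 is a hard
error instructing the caller to exclude or merge it: silently dropping
rows would change the design without the analyst noticing.  Weights from
the variance of log-replicates (rather than a delta-method transform of
the rate-scale variance) keep ln λ finite and were adopted as the
cleaner of the two readings; the choice only rescales weights modestly.

## Piecewise incarceration model

P(X > t) multiplies per-annum survival factors (1−p_k) across the three
career segments (breakpoints fixed at 5 and 10 whole years).  The law is
read as a survival function throughout: P(X > 0) = 1, and the
ever-incarcerated likelihood term is 1 − P(X > t).  A respondent reporting
ever-incarcerated at career length 0 is impossible under the model
(first incarceration takes at least one career year) and is rejected
explicitly rather than dropped.

The likelihood is maximised over [10⁻⁶, 1−10⁻⁶]³ by cyclic coordinate-wise
1-D search (scipy's bounded Brent per coordinate), iterated to an absolute
objective tolerance of 10⁻⁹ and restarted from three corners of the cube;
the surface is smooth and nearly separable across segments, and a dense
3-D grid search in the tests guards against ridge stalls.  Profile 95%
CIs bisect for the parameter value where the log-likelihood, re-maximised
over the other two rates, falls χ²₁(0.95)/2 ≈ 1.92 below the optimum.
Segments that no respondent's career reaches are unidentified: they are
flagged and their CIs reported as [0, 1].  The "overall" fit pools
respondents of both sexes rather than averaging sex-specific fits.

## Replacement rate

Career years are indexed t = 0, 1, 2, …, with career bin 0–5 covering
t ∈ {0..5}; this zero-based convention is fixed because it is the one
under which the published overall replacement rates are reproduced
exactly.  R sums P(IC > t) times the bin-appropriate EFR rate, split
between the never and ever columns by P(X > t).  The t ≥ 11 tail is two
geometric series (ratios (1−c) and (1−c)(1−p₃)) summed in closed form, so
R is exact to floating point; an explicit truncated triple-sum mode exists
purely as a cross-check and agrees to ~10⁻¹⁰.  c = 0 is rejected (infinite
expected career).  R is exactly proportional to (1−q), which gives the
closed-form unit-replacement quit rate q′ = 1 − (1−c)/R(c, p, q=c); a
negative q′ (population already below replacement) is returned with a
flag, not clamped.

Multi-stratum calls (e.g. by sex) evaluate each stratum with its own
incarceration rates and combine by respondent-count weights.  Bootstrap
CIs for R resample respondents and, in the default joint mode, refit both
the EFR table and the incarceration MLE per replicate (profile CIs are
skipped inside replicates — only the point estimate feeds R); an EFR-only
mode holds incarceration rates at the full-data fit.  How uncertainty was
propagated into the published replacement-rate CIs is not recorded, so
both modes are provided with joint as the default (the more honest
propagation).  Replicates that empty a subgroup cell are dropped and
counted, with a warning above 5% failures.

## Synthetic cohorts

The generator emulates a cross-sectional anonymous injector survey, one
row per respondent: sex, region, age group, whole-year injecting career,
ever-incarcerated, injected-in-past-year, past-year initiation count, and
others-present at the most recent initiation.  Defaults are calibrated to
the published NESI 2008–2009 summary tables: initiator fractions and mean
initiation counts per career-bin × prison cell (overall initiator fraction
≈ 18%), sex-specific incarceration rates (0.07, 0.06, 0.04 female; 0.19,
0.05, 0.03 male), a female share of 0.281, and a mean others-present count
of 2.5.

Distributional choices where the survey reports none:

- **Career length** is a truncated geometric with a free per-annum
  parameter (default 0.08, cap 40 years).  The surveyed career-length
  distribution is known to be distorted by the sampling design, so this is
  a knob, not an estimate.
- **Initiation counts** among initiators are shifted-geometric on
  {1, 2, …} — a one-parameter overdispersed law matching the long right
  tail of reported counts (range 1–100) and calibrated by its mean.
- **Others-present** is Poisson with mean 2.5, independent of the
  initiation count.  Real data suggest a mild positive association
  between heavy initiators and larger groups; keeping them independent is
  a documented simplification that leaves every estimator unbiased for its
  subgroup mean but slightly understates within-subgroup EFR variance.
- **Missingness** is completely at random: ~1.6% of initiators' others
  counts (matching the survey's 7/450) and ~1% of the age-group covariate.
  Age group is the only covariate subject to missingness because no
  downstream stage consumes it; sex, region and career are required by
  every analysis.
- **Initiator propensities** are keyed by (sex, bin, prison) but default
  to sex-identical values, since initiator *status* showed no sex effect;
  sex differences enter through incarceration exposure.

Ground truth is returned with every cohort, including analytic subgroup
expectations (for K ~ Poisson(μ), E[1/(K+1)] = (1−e^{−μ})/μ), so recovery
tests compare sample statistics against closed forms rather than against
other simulations.  What passing tests on these cohorts do *not*
establish: robustness to recruitment-site clustering, to the fixed
current:former sampling ratio, to informative missingness, or to the
initiations/others dependence — none of which the generator emulates.

## Problem sizes and numerical conventions

Default test problem sizes: calibration checks use one 50,000-respondent
cohort; MLE recovery uses 40 cohorts of 2,500 (matching the survey scale);
bootstrap coverage checks use 1,000-respondent cohorts with 60 joint
replicates over 8 seeds; the Monte-Carlo career oracle simulates 10⁶
careers.  These sizes put Monte-Carlo error well below the tolerances
asserted while keeping the default suite brisk.

Display rounding in CLI reports follows the field's table conventions
(rates to 2 decimals, replacement rates to 1); all comparisons in code and
tests use full precision with explicit tolerances.  Report bundles are
canonicalised (fixed line terminators, no timestamps) so identical
configurations are byte-identical.

## Known limitations

- Sex of the initiated novice is not modelled (no data), so sex-specific
  replacement rates assume novices inherit the stratum of the initiator.
- Cessation conflates stopping and death; calendar-time trends in
  initiation rates are out of scope.
- The incarceration model covers first incarceration only — repeat
  spells and in-prison initiation dynamics are not represented.
- Logistic models of *who* initiates, capture–recapture prevalence
  estimation, and reweighting to a target current:former ratio are outside
  the package's scope.
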