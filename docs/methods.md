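# Methods

## Problem and estimand

A water body's chemical status is *good* only if, for every monitored
priority substance, the annual mean concentration does not exceed the
AA-EQS and the annual maximum does not exceed the MAC-EQS; one failing
indicator downgrades the whole water body (one-out-all-out). Both
statistics come from small annual samples (n ≈ 4–12), so the assigned
class is a random outcome. The estimand is P_om: the probability that the
assigned class differs from the true one — a type-II-error probability
taken from the perspective of the class actually assigned. Misreadings in
both directions matter operationally: a false *good* suppresses remedial
action, a false *below good* triggers needless and costly measures.

## Censored data and the two standard deviations

Readings below the limit of quantification (LOQ) enter the mean as LOQ/2,
per Directive 2009/90/EC. The package computes two spread estimates from
one series:

- conventional: the sample standard deviation (divisor n−1) of the
  substituted values;
- modified: deviations are taken from the same half-LOQ mean x̄, but each
  censored reading contributes 0 instead of LOQ/2 to the deviation sum,
  again with divisor n−1.

Setting the censored value to 0 maximizes its distance from x̄ (using the
LOQ itself would give the same distance), so censoring inflates rather
than deflates reported spread. For n identical censored readings at LOQ L
the closed forms are: conventional = 0, modified = √(n/(n−1))·L/2.

Divisor choice: the defining formula for the modified estimator is
sometimes quoted with a 1/N factor, but the fully worked six-observation
reference calculation divides the deviation sum by 5, and every reference
standard deviation we reproduce is the n−1 form; the package implements
n−1 for both estimators and treats the 1/N print as an erratum.

A series with n = 1 has a defined mean and maximum but no spread
information; both standard deviations are reported missing, the indicator
is still classified, and its P_om is undefined (NaN) and skipped in the
hierarchy maximum.

The maximum is taken over substituted values, so an all-censored series
has maximum LOQ/2. Heterogeneous LOQs within a series are supported; each
censored reading uses its own LOQ.

## Criterion probabilities

**Mean criterion.** The sampling distribution of the annual mean is
approximated by a Student t with n−1 degrees of freedom, location x̄ and
scale s/√n (the moment identities E(x̄)=E(x), σ(x̄)=σ(x)/√n; measurement
bias assumed zero). With F the corresponding CDF:
P_om = 1 − F(AA-EQS) when the mean criterion put the indicator in *good*,
and F(AA-EQS) when it put it *below good*. With s = 0 the distribution is
a point mass at x̄ and P_om = 0 — exactly the degenerate behaviour the
modified estimator repairs. The class interval's lower limit is −∞ by
default; an optional mode renormalizes the t over [0, ∞) to respect
non-negative concentrations. The difference is negligible unless
x̄ ≲ 2·s/√n; the untruncated form is the default because the class limits
are otherwise unspecified.

**Maximum criterion.** The annual maximum is modelled by a right-hand
Gumbel (type I extreme value). Default fit is by moments from the series
mean and the *selected* standard deviation variant: β = s√6/π, location
x̄ − γβ (γ ≈ 0.5772). This is deliberate: routing the conventional/modified
choice through the Gumbel scale is the only reading under which that
choice can affect the maximum criterion, and it keeps the degenerate
all-censored case consistent (s = 0 → point mass → P_om = 0
conventionally, positive under the modified variant). A maximum-likelihood
fit to the substituted values is available (`fit_method="mle"`); identical
values make the MLE degenerate, which falls back to a point mass with a
warning.

**Known discrepancy.** The published comparison table prints criterion
probabilities (e.g. 0.80/0.81 for the benzo(a)pyrene example) that cannot
be reproduced from the stated t construction, which gives ≈ 0.48 for those
inputs; the original analysis used library "fit" calls whose parameters
were not reported. This package implements the stated construction. The
summary-statistics rows, the degenerate zeros, and the level-3 composition
of that table are all reproduced exactly and are used as test oracles; the
probability cells are not.

## Classification and hierarchy

"Exceeds" is strict: a mean exactly at the AA-EQS (or a maximum at the
MAC-EQS) is still good. The four cases (i: neither exceeded … iv: both)
partition the outcomes. Per indicator, Level 3 of the hierarchy is:
case i → max(P_om mean, P_om max); case ii → P_om mean; case iii →
P_om max; case iv → the product (both errors must occur together — an
independence assumption; correlation between the mean and maximum errors,
like correlation between indicators, is not modelled). Level 4 takes the
highest Level-3 value — over all indicators for a good water body, over
the below-good (decisive) indicators only otherwise, since good indicators
cannot have caused a below-good call. Ties resolve to the
lexicographically smallest indicator id for deterministic reports. For a
below-good status with several decisive indicators a joint-error product
could be argued instead of the maximum; the maximum is implemented as the
procedure defines it.

Status P_oms are reported in four intervals. The first is closed,
[0, 0.1]; the rest are half-open (a, b], so the bins partition [0, 1] and
a boundary value such as 0.1 falls in the lower bin.

The pesticide sum-group (aldrin, dieldrin, endrin, isodrin) is classified
against the threshold on the per-date sum of member concentrations:
censored member readings contribute LOQ/2 to the sum (consistent with the
mean-substitution rule) and 0 inside the modified deviation sum. Summing
per date rather than summing annual means is a choice — the regulation
does not specify it — made because it preserves a genuine maximum
criterion for the group. Members are aligned by date when dates are
present (the date sets must coincide), positionally otherwise, requiring
equal counts. Incomplete indicator sets are assessed from what is
available; absent indicators are never imputed.

## Synthetic data and what validation shows

No national monitoring database is public, so validation runs on
generated data. Each indicator's true concentration model is a lognormal
(the standard positive-support choice for strongly right-skewed pollutant
concentrations) with parameters (log-mean, log-sd) in log-µg/l; draws
below the configured LOQ are emitted as censored tokens. Defaults follow
the monitoring design: 12 observations per year (the legislated monthly
frequency), independent water bodies, a single seed fixing the output
byte-for-byte. A log-sd of 0 gives a degenerate constant for edge-case
tests. The truth table stores each indicator's distributional mean and
the class it implies against the AA-EQS.

The calibration experiments use log-sd 0.3 (moderate environmental
variability, ≈ 31 % coefficient of variation), an AA-EQS of 0.005 µg/l on
the scale of a typical pesticide standard, and MAC set far above the
distribution so the mean criterion drives the class. The study sizes —
2000 water bodies for the at-threshold experiment, 7 true-mean ratios
(0.5–2.5 × AA-EQS) × 300 water bodies for bin calibration — keep binomial
noise well below the effects being checked. Observed in the shipped
suite: at-threshold misclassification frequency ≈ 0.53 (theoretical 0.5
up to lognormal sample-mean skew), and per-bin empirical error rates
rising ≈ 0.03 → 0.25 → 0.53 across the first three P_om intervals.

What the generator does *not* emulate: seasonality, serial correlation
within a year, correlation between indicators, measurement bias, and
reporting-limit changes mid-year. Passing tests therefore demonstrate
correctness of the procedure and its calibration under independent
lognormal sampling, not the accuracy of national-scale percentages, which
depend on the real monitoring database.

Under the untruncated t construction an internally consistent mean
criterion can never exceed P_om = 0.5 (the assessed class always holds at
least half the mass), so the top interval (0.5, 1] is reachable mainly
through the maximum criterion or data inconsistencies; in the synthetic
experiments it is empty.

## Numerical choices

- Probabilities are clipped to [0, 1] against CDF rounding; full precision
  is kept everywhere, with 2-significant-figure rounding (`round_sig`)
  applied only for display.
- A constant substituted series short-circuits to mean = value and
  conventional stdev = 0 exactly, so the degenerate case is not blurred by
  summation rounding; deviation sums use compensated summation
  (`math.fsum`) otherwise.
- Censored-token parsing accepts `<x` and `< x`, decimal point only; a
  decimal comma raises, keeping parsing locale-independent.
- Units are fixed to µg/l; a `unit` column, if present, must literally be
  `µg/l` or `ug/l`.

## Limitations

- The modified standard deviation is a conservative repair of the
  substitution estimator, not a censored-likelihood method; Kaplan–Meier,
  regression-on-order-statistics or censored MLE estimators are out of
  scope by design.
- Indicator and criterion errors are treated as independent.
- The Gumbel moments fit reuses the full-sample mean and standard
  deviation rather than block-maxima statistics; with 4–12 observations
  per year a genuine extreme-value fit is not estimable, and this choice
  follows the procedure being implemented.
- Ecological status, combined status, biota and passive monitoring are
  out of scope.
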