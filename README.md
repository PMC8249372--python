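# pomstat

**Probability of misclassification of surface-water chemical status from
censored monitoring series.**

Under the EU Water Framework Directive every river and lake water body gets
a binary *chemical status* — *good* or *below good* — by comparing, for each
priority substance, the annual mean concentration with the AA-EQS
(annual-average environmental quality standard) and the annual maximum with
the MAC-EQS (maximum allowable concentration). Both the mean and the
maximum are computed from a handful of noisy measurements (typically 12 per
year), so the assigned class can simply be wrong. `pomstat` quantifies that
risk as **P_om**, the probability of misclassification, for every
indicator and every water body — and it does so in a way that stays honest
when the data are left-censored.

Most priority substances occur near or below the laboratory limit of
quantification (LOQ). Regulation (Directive 2009/90/EC) replaces each
censored reading by LOQ/2 before averaging, which makes an all-censored
year a list of identical numbers: the standard deviation is exactly zero
and the classification looks *perfectly certain*, although the truth could
be anywhere between 0 and the LOQ. `pomstat` therefore carries **two
spread estimates** through the whole analysis:

- the **conventional** sample standard deviation of the substituted values, and
- the **modified** standard deviation, which keeps the half-LOQ mean x̄ but
  sets each censored reading to 0 inside the deviation sum:

  mod stdev = √( Σᵢ (xᵢ − x̄)² / (n−1) ),  with xᵢ = 0 whenever xᵢ < LOQ.

This maximizes the deviation of a censored reading from the half-LOQ mean
and keeps reported uncertainty strictly positive whenever data are censored.

## The model

For one indicator the annual mean x̄ is treated as a Student-t random
variable with n−1 degrees of freedom, location x̄ and scale s/√n. For an
indicator assessed good by the mean criterion,

    P_om(mean) = 1 − F_t(AA-EQS),

and symmetrically F_t(AA-EQS) for a below-good mean. The annual maximum is
modelled by a right-hand Gumbel (type I extreme-value) distribution, by
default fitted by moments (β = s·√6/π, location x̄ − γβ), giving
P_om(max) = 1 − G(MAC-EQS) for a good maximum. Per indicator the two
criterion probabilities combine by classification case:
good → the larger of the two; below-good via the mean (case ii) or maximum
(case iii) → the decisive criterion's P_om; both exceeded (case iv) → their
product. Per water body the one-out-all-out rule sets the status, and the
four-level hierarchy takes the highest per-indicator P_om (over the
below-good indicators only, when status is below good) as the **status
P_om**, binned into the reporting intervals [0, 0.1], (0.1, 0.3],
(0.3, 0.5], (0.5, 1].

The pesticides aldrin, dieldrin, endrin and isodrin are judged against a
threshold on the *sum* of their concentrations; `pomstat` forms the
per-date sum series (LOQ/2 per censored member) and treats it like a single
indicator.

## Worked example

The classic pathology is a PAH series with four of six readings censored
(water body PLLW10035, benzo(a)pyrene, AA-EQS 1.7×10⁻⁴ µg/l,
MAC-EQS 0.27 µg/l):

```python
from pomstat import (EqsStandard, IndicatorSeries, parse_observation,
                     series_stats, classify_indicator, indicator_level3,
                     substituted_values)

tokens = ["< 0.00005", "0.0008", "0.00008", "< 0.00005", "< 0.00005", "< 0.00005"]
series = IndicatorSeries("PLLW10035", "benzo(a)pyrene", 2017,
                         tuple(parse_observation(t) for t in tokens))
eqs = EqsStandard("benzo(a)pyrene", aa_eqs=1.7e-4, mac_eqs=0.27)

stats = series_stats(series)
print(f"mean {stats.mean:.3g}  max {stats.maximum:.3g}  "
      f"conv stdev {stats.stdev_conventional:.3g}  mod stdev {stats.stdev_modified:.3g}")

cls = classify_indicator(stats, eqs)
print(f"class: {cls.status.value} (case {cls.case.value})")

for variant in ("conventional", "modified"):
    pm, px, level3 = indicator_level3(cls, substituted_values(series),
                                      stdev_variant=variant)
    print(f"{variant:>12}: P_om(mean) = {pm.p_om:.3f}, "
          f"P_om(max) = {px.p_om:.2e}, level-3 P_om = {level3:.3f}")
```

prints

```
mean 0.000163  max 0.0008  conv stdev 0.000313  mod stdev 0.000322
class: good (case i)
conventional: P_om(mean) = 0.480, P_om(max) = 0.00e+00, level-3 P_om = 0.480
    modified: P_om(mean) = 0.481, P_om(max) = 0.00e+00, level-3 P_om = 0.481
```

The mean 1.6×10⁻⁴ sits just below the AA-EQS of 1.7×10⁻⁴ while the scale
of its sampling distribution (s/√6 ≈ 1.3×10⁻⁴) dwarfs that margin, so the
*good* call is nearly a coin flip: P_om ≈ 0.48. The maximum, three orders
of magnitude below the MAC-EQS, contributes nothing. For a fully censored
series the conventional column would report P_om = 0 — spurious certainty —
while the modified column stays positive; that contrast is the point of the
modified standard deviation.

## Command line

```bash
# seeded synthetic monitoring data with known truth
pomstat simulate --config sim.yaml --out-dir data/

# classification + P_om hierarchy, both stdev variants
pomstat assess --measurements data/measurements.csv --eqs data/eqs.csv \
    --stdev both --gumbel moments --out results.csv --summary summary.csv

# interval percentages by any grouping
pomstat summarize --results results.csv --by stdev_variant,status
```

`measurements.csv` is long format (`wb_id, indicator, year, date, value`)
with censored tokens like `< 0.001`; `eqs.csv` holds `indicator, aa_eqs,
mac_eqs, sum_group`. All concentrations are µg/l.

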