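"""Per-criterion and per-indicator probabilities of misclassification.

The annual mean x̄ of a chemical indicator is a random variable; its
sampling distribution is approximated by a Student's t with n−1 degrees of
freedom, location x̄ and scale s/√n (measurement bias is assumed
negligible).  For an indicator assessed *good* by the mean criterion the
misclassification probability is the t-mass above the AA-EQS,

    P_om(mean, good) = 1 − F_t(AA-EQS),

and symmetrically F_t(AA-EQS) when the mean criterion put the indicator
below good.  The maximum criterion uses a right-hand Gumbel (type I
extreme-value) model for the annual maximum; by default it is fitted by
moments, β = s·√6/π and location = x̄ − γ·β (γ Euler–Mascheroni), with the
same choice of conventional or modified standard deviation as the mean
criterion — which is how the censored-data stdev correction propagates into
the maximum criterion.  A maximum-likelihood fit to the substituted values
is available as an alternative.

Per indicator the two criterion probabilities combine by case:
good (i) → the larger of the two; below good via the mean (ii) → the mean
one; via the maximum (iii) → the maximum one; via both (iv) → their
product (two independent errors must co-occur).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .classification import Case, IndicatorClass, Status
from .censored_stats import SeriesStats

__all__ = [
    "CriterionPom",
    "pom_mean",
    "pom_max",
    "indicator_pom",
    "select_stdev",
    "indicator_level3",
]

EULER_GAMMA = float(np.euler_gamma)

STDEV_VARIANTS = ("conventional", "modified")
GUMBEL_FITS = ("moments", "mle")


@dataclass(frozen=True)
class CriterionPom:
    """P(correct class) and P(misclassification) for one criterion."""

    criterion: str  # "mean" | "max"
    p_class: float
    p_om: float
    stdev_variant: str


def _clip01(p: float) -> float:
    return min(1.0, max(0.0, p))


def select_stdev(stats: SeriesStats, variant: str) -> float | None:
    if variant not in STDEV_VARIANTS:
        raise ValueError(f"unknown stdev variant {variant!r}")
    return stats.stdev_conventional if variant == "conventional" else stats.stdev_modified


def pom_mean(
    mean: float,
    stdev: float,
    n: int,
    aa_eqs: float,
    assessed: Status,
    *,
    stdev_variant: str = "modified",
    truncate_support: bool = False,
) -> CriterionPom:
    """Misclassification probability of the mean criterion.

    ``assessed`` is the class implied by the mean criterion itself
    (good iff mean ≤ AA-EQS); passing the opposite raises, since that is a
    caller inconsistency, not a data condition.  ``truncate_support``
    renormalizes the t distribution over [0, ∞) to respect non-negative
    concentrations; the default leaves the lower class limit at −∞.
    """
    if n < 2:
        raise ValueError(f"mean-criterion P_om needs n >= 2, got n={n}")
    if stdev < 0:
        raise ValueError(f"negative stdev {stdev!r}")
    good_by_mean = mean <= aa_eqs
    if (assessed is Status.GOOD) != good_by_mean:
        raise ValueError(
            f"assessed {assessed.value} inconsistent with mean {mean} vs AA-EQS {aa_eqs}"
        )
    if stdev == 0.0:
        # Point mass at the mean: the assessed class is certain.
        return CriterionPom("mean", 1.0, 0.0, stdev_variant)
    dist = sps.t(df=n - 1, loc=mean, scale=stdev / math.sqrt(n))
    mass_good = dist.cdf(aa_eqs)
    if truncate_support:
        below_zero = dist.cdf(0.0)
        mass_good = (mass_good - below_zero) / (1.0 - below_zero)
    mass_good = _clip01(float(mass_good))
    p_class = mass_good if assessed is Status.GOOD else 1.0 - mass_good
    return CriterionPom("mean", p_class, 1.0 - p_class, stdev_variant)


def _gumbel_cdf_point_mass(maximum: float, mac_eqs: float) -> float:
    return 1.0 if maximum <= mac_eqs else 0.0


def pom_max(
    values: Sequence[float],
    stats: SeriesStats,
    mac_eqs: float,
    assessed: Status,
    *,
    fit_method: str = "moments",
    stdev_variant: str = "modified",
) -> CriterionPom:
    """Misclassification probability of the maximum criterion.

    ``values`` are the substituted concentrations.  ``assessed`` is the class
    implied by the maximum criterion itself (good iff maximum ≤ MAC-EQS).
    """
    if fit_method not in GUMBEL_FITS:
        raise ValueError(f"unknown Gumbel fit method {fit_method!r}")
    if len(values) < 2:
        raise ValueError("maximum-criterion P_om needs at least 2 values")
    if mac_eqs <= 0:
        raise ValueError(f"MAC-EQS must be positive, got {mac_eqs!r}")
    good_by_max = stats.maximum <= mac_eqs
    if (assessed is Status.GOOD) != good_by_max:
        raise ValueError(
            f"assessed {assessed.value} inconsistent with maximum "
            f"{stats.maximum} vs MAC-EQS {mac_eqs}"
        )

    if fit_method == "moments":
        s = select_stdev(stats, stdev_variant)
        if s is None:
            raise ValueError("stdev undefined (n = 1); cannot fit Gumbel by moments")
        if s == 0.0:
            cdf = _gumbel_cdf_point_mass(stats.maximum, mac_eqs)
        else:
            beta = s * math.sqrt(6.0) / math.pi
            loc = stats.mean - EULER_GAMMA * beta
            cdf = float(sps.gumbel_r.cdf(mac_eqs, loc=loc, scale=beta))
    else:  # mle
        arr = np.asarray(values, dtype=float)
        if float(np.ptp(arr)) == 0.0:
            warnings.warn(
                "all values identical; Gumbel MLE degenerate, using a point mass",
                RuntimeWarning,
                stacklevel=2,
            )
            cdf = _gumbel_cdf_point_mass(stats.maximum, mac_eqs)
        else:
            loc, beta = sps.gumbel_r.fit(arr)
            cdf = float(sps.gumbel_r.cdf(mac_eqs, loc=loc, scale=beta))

    cdf = _clip01(cdf)
    p_class = cdf if assessed is Status.GOOD else 1.0 - cdf
    return CriterionPom("max", p_class, 1.0 - p_class, stdev_variant)


def indicator_pom(cls: IndicatorClass, pm: CriterionPom, px: CriterionPom) -> float:
    """Combine the two criterion P_oms into the indicator's Level-3 value."""
    if pm.criterion != "mean" or px.criterion != "max":
        raise ValueError("expected a mean-criterion and a max-criterion result")
    if pm.stdev_variant != px.stdev_variant:
        raise ValueError("criterion results use different stdev variants")
    if cls.case is Case.I:
        return max(pm.p_om, px.p_om)
    if cls.case is Case.II:
        return pm.p_om
    if cls.case is Case.III:
        return px.p_om
    return pm.p_om * px.p_om  # case iv: both errors must co-occur


def indicator_level3(
    cls: IndicatorClass,
    values: Sequence[float],
    *,
    stdev_variant: str = "modified",
    gumbel_fit: str = "moments",
    truncate_support: bool = False,
) -> tuple[CriterionPom, CriterionPom, float] | None:
    """Full per-indicator probability assessment for one stdev variant.

    Returns (mean-criterion, max-criterion, Level-3 P_om), or ``None`` when
    the standard deviations are undefined (single-observation series).
    """
    stdev = select_stdev(cls.stats, stdev_variant)
    if stdev is None:
        return None
    assessed_mean = Status.GOOD if cls.mean <= cls.aa_eqs else Status.BELOW_GOOD
    assessed_max = Status.GOOD if cls.maximum <= cls.mac_eqs else Status.BELOW_GOOD
    pm = pom_mean(
        cls.mean,
        stdev,
        cls.stats.n,
        cls.aa_eqs,
        assessed_mean,
        stdev_variant=stdev_variant,
        truncate_support=truncate_support,
    )
    px = pom_max(
        values,
        cls.stats,
        cls.mac_eqs,
        assessed_max,
        fit_method=gumbel_fit,
        stdev_variant=stdev_variant,
    )
    return pm, px, indicator_pom(cls, pm, px)
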