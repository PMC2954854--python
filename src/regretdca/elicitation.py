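"""Preference elicitation from regret ratings and acceptable-regret scenarios.

A decision maker rates, on paired 0-100 visual analog scales, the anticipated
regret of two kinds of error:

* **omission** -- failing to give a treatment that was needed (the loss of the
  treatment's benefit, U1 - U3 in utility terms);
* **commission** -- giving a treatment that was not needed (the harm of an
  unnecessary intervention, U4 - U2).

The ratio of the two ratings determines the treatment threshold probability

    Pt = 1 / (1 + omission / commission),

the disease probability at which the decision maker is indifferent between
treating and not treating.  A commission rating of zero means unnecessary
treatment carries no regret, in which case treatment is justified only at
certainty (Pt = 1).

Acceptable regret is elicited indirectly, through a hypothetical cohort of
patients sharing the current patient's risk: the decision maker states how
many wrong calls of a given kind they could tolerate.  The tolerated fraction
``r`` times the rescaled regret rating yields the regret budget ``rg0``;
strategies whose expected-regret gap is within the budget are "equivalent in
regret".  The same fractions bound the comfort region on the probability
scale: withholding treatment is tolerable below ``r_b``, treating possibly
unnecessarily is tolerable above ``1 - r_h``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "RegretAssessment",
    "ThresholdProbability",
    "AcceptableRegret",
    "ComfortBounds",
    "threshold_from_regrets",
    "acceptable_regret_from_scenario",
    "scenario_arm_sizes",
    "comfort_bounds",
    "truncated_percent",
    "format_percent",
]

#: Thresholds at or above this are treated as certainty: the odds weight
#: Pt/(1-Pt) diverges and expected regrets are undefined.
CERTAINTY_CUTOFF = 1.0 - 1e-9


def _check_rating(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or not 0.0 <= value <= 100.0:
        raise ValueError(f"{name} rating must lie in [0, 100], got {value!r}")
    return value


@dataclass(frozen=True)
class RegretAssessment:
    """Dual visual-analog-scale regret ratings.

    Parameters
    ----------
    omission : float
        Regret of failing to give needed treatment, on a 0-100 scale.
    commission : float
        Regret of giving unnecessary treatment, on a 0-100 scale.

    At least one rating must be positive: rating both errors zero expresses
    total indifference, from which no threshold can be defined.
    """

    omission: float
    commission: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "omission", _check_rating(self.omission, "omission"))
        object.__setattr__(self, "commission", _check_rating(self.commission, "commission"))
        if self.omission == 0.0 and self.commission == 0.0:
            raise ValueError(
                "both regret ratings are zero: total indifference does not "
                "define a treatment threshold"
            )


@dataclass(frozen=True)
class ThresholdProbability:
    """A treatment threshold probability and its odds weight Pt/(1-Pt)."""

    value: float

    def __post_init__(self) -> None:
        value = float(self.value)
        if not math.isfinite(value) or not 0.0 <= value <= 1.0:
            raise ValueError(f"threshold probability must lie in [0, 1], got {value!r}")
        object.__setattr__(self, "value", value)

    @property
    def is_certain(self) -> bool:
        """True when the threshold is (numerically) 1: treat only at certainty."""
        return self.value >= CERTAINTY_CUTOFF

    @property
    def weight(self) -> float:
        """The odds Pt/(1-Pt); infinite at certainty."""
        if self.is_certain:
            return math.inf
        return self.value / (1.0 - self.value)

    def percent(self, truncate: bool = True) -> float:
        return truncated_percent(self.value) if truncate else 100.0 * self.value


@dataclass(frozen=True)
class AcceptableRegret:
    """Tolerated-error fraction and the regret budget it implies.

    ``basis='benefits'`` quantifies tolerance for withholding needed treatment
    (fraction ``r_b`` of the benefit forgone); ``basis='harms'`` quantifies
    tolerance for unnecessary treatment (fraction ``r_h`` of the harm
    incurred).  The budget is ``rg0 = r * rating/100`` under the default
    (literal) convention, or ``rg0 = r`` under the normalized convention in
    which all regrets are already expressed in benefit units.
    """

    basis: str
    tolerated: int
    denominator: int
    rating: float  # rescaled to [0, 1]
    r: float = field(init=False)
    rg0: float = field(init=False)
    convention: str = "literal"

    def __post_init__(self) -> None:
        if self.basis not in ("benefits", "harms"):
            raise ValueError(f"basis must be 'benefits' or 'harms', got {self.basis!r}")
        if self.convention not in ("literal", "normalized"):
            raise ValueError(
                f"convention must be 'literal' or 'normalized', got {self.convention!r}"
            )
        if self.denominator <= 0:
            raise ValueError("scenario denominator must be a positive count")
        if not 0 <= self.tolerated <= self.denominator:
            raise ValueError(
                f"tolerated count {self.tolerated} must lie in [0, {self.denominator}]"
            )
        if not 0.0 <= self.rating <= 1.0:
            raise ValueError(f"rescaled rating must lie in [0, 1], got {self.rating!r}")
        r = self.tolerated / self.denominator
        rg0 = r if self.convention == "normalized" else r * self.rating
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "rg0", rg0)


@dataclass(frozen=True)
class ComfortBounds:
    """Probability bounds of the comfort region.

    ``p_treat_none``: below this disease probability, withholding treatment is
    tolerable even if wrong (equals ``r_b``).  ``p_treat_all``: above this
    probability, a possibly unnecessary treatment is tolerable (equals
    ``1 - r_h``).  Either bound may be absent when the matching scenario was
    not elicited.
    """

    p_treat_none: Optional[float] = None
    p_treat_all: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("p_treat_none", "p_treat_all"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def threshold_from_regrets(assessment: RegretAssessment) -> ThresholdProbability:
    """Treatment threshold implied by the dual regret ratings.

    ``Pt = 1/(1 + omission/commission)``.  With commission zero the ratio is
    undefined and the threshold is exactly 1: treatment is justified only at
    certainty of disease.  Symmetric ratings give 0.5.

    Examples
    --------
    >>> threshold_from_regrets(RegretAssessment(omission=60, commission=30)).value
    0.3333333333333333
    """
    if assessment.commission == 0.0:
        return ThresholdProbability(1.0)
    return ThresholdProbability(1.0 / (1.0 + assessment.omission / assessment.commission))


def acceptable_regret_from_scenario(
    tolerated: int,
    denominator: int,
    rating: float,
    basis: str,
    convention: str = "literal",
) -> AcceptableRegret:
    """Convert a tolerated-error scenario answer into an acceptable-regret budget.

    Parameters
    ----------
    tolerated, denominator : int
        "Out of ``denominator`` patients for whom the call could be wrong,
        how many wrong calls would you tolerate?" -> ``tolerated``.
    rating : float
        The matching 0-100 VAS rating: the omission rating when
        ``basis='benefits'``, the commission rating when ``basis='harms'``.
    basis : {'benefits', 'harms'}
    convention : {'literal', 'normalized'}
        ``literal`` (default): ``rg0 = r * rating/100``.
        ``normalized``: ``rg0 = r``, matching curves expressed in rescaled
        (benefit-unit) regret.
    """
    rating = _check_rating(rating, "scenario")
    return AcceptableRegret(
        basis=basis,
        tolerated=int(tolerated),
        denominator=int(denominator),
        rating=rating / 100.0,
        convention=convention,
    )


def scenario_arm_sizes(cohort_size: int, disease_probability: float) -> tuple[int, int]:
    """Split a hypothetical scenario cohort into should-treat / should-not-treat arms.

    With 100 patients at 20% risk, 20 should be treated and 80 should not;
    these arm sizes phrase the two acceptable-regret questions.  Rounds half
    up.
    """
    cohort_size = int(cohort_size)
    if cohort_size <= 0:
        raise ValueError("scenario cohort size must be positive")
    if not 0.0 <= disease_probability <= 1.0:
        raise ValueError("disease probability must lie in [0, 1]")
    should_treat = int(math.floor(cohort_size * disease_probability + 0.5))
    return should_treat, cohort_size - should_treat


def comfort_bounds(
    r_b: Optional[float] = None, r_h: Optional[float] = None
) -> ComfortBounds:
    """Comfort-region probability bounds from tolerated-error fractions.

    ``p_treat_none = r_b`` and ``p_treat_all = 1 - r_h``; an absent fraction
    yields an absent bound.  At least one fraction must be supplied.
    """
    if r_b is None and r_h is None:
        raise ValueError("at least one of r_b, r_h must be provided")
    for name, value in (("r_b", r_b), ("r_h", r_h)):
        if value is not None and not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return ComfortBounds(
        p_treat_none=r_b if r_b is not None else None,
        p_treat_all=1.0 - r_h if r_h is not None else None,
    )


def truncated_percent(value: float) -> int:
    """Probability as a floor-truncated whole percent (1/6 -> 16, 1/3 -> 33).

    A small epsilon guards values that are whole percents up to float
    rounding.
    """
    return int(math.floor(100.0 * value + 1e-9))


def format_percent(value: float) -> str:
    """Render a probability as a truncated whole-percent string, e.g. '16%'."""
    return f"{truncated_percent(value)}%"
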