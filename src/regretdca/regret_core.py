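"""Expected regret and NERD computations on a cohort at a treatment threshold.

A cohort is a set of patients with model-predicted disease risks and observed
binary outcomes.  At a threshold ``Pt`` the rule "treat if risk >= Pt" splits
the cohort into true/false positives/negatives.  With regrets rescaled so the
benefit of needed treatment (U1 - U3) equals 1, the commission regret becomes
the odds weight ``w = Pt/(1-Pt)`` and the three strategies have expected
regret per patient:

* model:      ``fn/n + (fp/n) * w``  (missed cases plus weighted overtreatment)
* treat all:  ``(1 - prevalence) * w``
* treat none: ``prevalence``

The Net Expected Regret Difference (NERD) of a strategy pair is the first
strategy's expected regret minus the second's: positive favours the second
strategy, negative the first, zero is indifference.  NERD(treat none, model)
coincides exactly with the classic decision-curve net benefit
``tp/n - (fp/n) * w``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .elicitation import CERTAINTY_CUTOFF, ThresholdProbability

__all__ = [
    "Cohort",
    "ConfusionCounts",
    "RegretCurvePoint",
    "classify_cohort",
    "expected_regrets",
    "nerd_pair",
    "net_benefit",
]

ThresholdLike = Union[float, ThresholdProbability]

STRATEGIES = ("treat_none", "treat_all", "model")

_SHORT = {"none": "treat_none", "all": "treat_all", "model": "model"}


def as_threshold(threshold: ThresholdLike) -> ThresholdProbability:
    if isinstance(threshold, ThresholdProbability):
        return threshold
    return ThresholdProbability(float(threshold))


def _finite_weight(threshold: ThresholdProbability) -> float:
    if threshold.value >= CERTAINTY_CUTOFF:
        raise ValueError(
            "threshold is (numerically) 1: the odds weight Pt/(1-Pt) diverges "
            "and expected regret is undefined; treatment at certainty only"
        )
    return threshold.weight


@dataclass(frozen=True)
class Cohort:
    """Per-patient predicted risks and observed binary disease outcomes."""

    risks: np.ndarray
    outcomes: np.ndarray

    def __post_init__(self) -> None:
        risks = np.asarray(self.risks, dtype=float)
        outcomes = np.asarray(self.outcomes)
        if risks.ndim != 1 or outcomes.ndim != 1 or risks.shape != outcomes.shape:
            raise ValueError("risks and outcomes must be equal-length 1-d sequences")
        if risks.size == 0:
            raise ValueError("cohort is empty")
        if np.any(~np.isfinite(risks)) or risks.min() < 0.0 or risks.max() > 1.0:
            raise ValueError("every risk must lie in [0, 1]")
        if not np.isin(outcomes, (0, 1)).all():
            raise ValueError("every outcome must be 0 or 1")
        object.__setattr__(self, "risks", risks)
        object.__setattr__(self, "outcomes", outcomes.astype(np.int64))

    @classmethod
    def from_records(cls, records: Iterable[tuple[float, int]]) -> "Cohort":
        pairs = list(records)
        if not pairs:
            raise ValueError("cohort is empty")
        risks, outcomes = zip(*pairs)
        return cls(np.asarray(risks, dtype=float), np.asarray(outcomes))

    @property
    def n(self) -> int:
        return int(self.risks.size)

    @property
    def diseased(self) -> int:
        return int(self.outcomes.sum())

    @property
    def prevalence(self) -> float:
        return self.diseased / self.n

    def to_frame(self, ids: Sequence | None = None) -> pd.DataFrame:
        if ids is None:
            ids = np.arange(1, self.n + 1)
        return pd.DataFrame({"id": ids, "risk": self.risks, "outcome": self.outcomes})


@dataclass(frozen=True)
class ConfusionCounts:
    """Treat/no-treat classification counts at a threshold.

    tp: treated and diseased; fp: treated and healthy; tn: untreated and
    healthy; fn: untreated and diseased.  ``tp/n`` etc. estimate the joint
    probabilities P(risk >= Pt and D+), P(risk >= Pt and D-), ...
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
            object.__setattr__(self, name, int(value))
        if self.n == 0:
            raise ValueError("confusion counts sum to zero")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def diseased(self) -> int:
        return self.tp + self.fn

    @property
    def prevalence(self) -> float:
        return self.diseased / self.n


def classify_cohort(cohort: Cohort, threshold: ThresholdLike) -> ConfusionCounts:
    """Apply the rule "treat if risk >= Pt" and count the four cells.

    A risk exactly equal to the threshold is treated (>= rule).
    """
    pt = as_threshold(threshold).value
    treat = cohort.risks >= pt
    disease = cohort.outcomes.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(treat & disease)),
        fp=int(np.count_nonzero(treat & ~disease)),
        tn=int(np.count_nonzero(~treat & ~disease)),
        fn=int(np.count_nonzero(~treat & disease)),
    )


def expected_regrets(
    counts: ConfusionCounts, threshold: ThresholdLike
) -> tuple[float, float, float]:
    """Expected regret per patient for (model, treat all, treat none).

    Values are in rescaled units where the benefit of needed treatment equals
    1; multiply by the 0-1 omission rating to restore VAS units.  Raises for
    thresholds at certainty (weight undefined).
    """
    threshold = as_threshold(threshold)
    w = _finite_weight(threshold)
    n = counts.n
    erg_model = counts.fn / n + (counts.fp / n) * w
    erg_treat_all = ((counts.fp + counts.tn) / n) * w
    erg_treat_none = counts.diseased / n
    return erg_model, erg_treat_all, erg_treat_none


def _canonical_nerd(counts: ConfusionCounts, w: float, first: str, second: str) -> float:
    n = counts.n
    if (first, second) == ("treat_none", "model"):
        return counts.tp / n - (counts.fp / n) * w
    if (first, second) == ("treat_none", "treat_all"):
        return counts.diseased / n - ((counts.fp + counts.tn) / n) * w
    if (first, second) == ("treat_all", "model"):
        # Algebraically (tn/n)*w - fn/n; computed as the difference of the two
        # treat-none comparisons so the additivity identity is exact.
        return _canonical_nerd(counts, w, "treat_none", "model") - _canonical_nerd(
            counts, w, "treat_none", "treat_all"
        )
    raise AssertionError(f"not a canonical pair: {(first, second)!r}")


def _parse_pair(pair: str) -> tuple[str, str]:
    try:
        first, second = pair.split("_vs_")
        return _SHORT[first], _SHORT[second]
    except (ValueError, KeyError):
        raise ValueError(
            f"pair must be '<a>_vs_<b>' with a, b in {sorted(_SHORT)}, got {pair!r}"
        ) from None


def nerd_pair(counts: ConfusionCounts, threshold: ThresholdLike, pair: str) -> float:
    """Net expected regret difference for a strategy pair.

    ``pair`` names the comparison, e.g. ``'none_vs_model'``: the value is
    ERg(first) - ERg(second), so positive means the second strategy inflicts
    less regret.  A strategy against itself is exactly zero; reversing a pair
    negates the value.
    """
    threshold = as_threshold(threshold)
    w = _finite_weight(threshold)
    first, second = _parse_pair(pair)
    if first == second:
        return 0.0
    if (first, second) in (
        ("treat_none", "model"),
        ("treat_none", "treat_all"),
        ("treat_all", "model"),
    ):
        return _canonical_nerd(counts, w, first, second)
    return -_canonical_nerd(counts, w, second, first)


def net_benefit(counts: ConfusionCounts, threshold: ThresholdLike) -> float:
    """Classic decision-curve net benefit of the model strategy.

    ``tp/n - (fp/n) * Pt/(1-Pt)``.  Identical, by construction, to
    ``nerd_pair(counts, threshold, 'none_vs_model')``; it exists as the
    explicit cross-check of that equivalence.
    """
    threshold = as_threshold(threshold)
    w = _finite_weight(threshold)
    return counts.tp / counts.n - (counts.fp / counts.n) * w


@dataclass(frozen=True)
class RegretCurvePoint:
    """Expected regrets and NERDs of the three strategies at one threshold."""

    threshold: ThresholdProbability
    erg_model: float
    erg_treat_all: float
    erg_treat_none: float
    nerd_none_model: float
    nerd_none_all: float
    nerd_all_model: float

    @classmethod
    def from_counts(
        cls, counts: ConfusionCounts, threshold: ThresholdLike
    ) -> "RegretCurvePoint":
        threshold = as_threshold(threshold)
        erg_model, erg_all, erg_none = expected_regrets(counts, threshold)
        nm = nerd_pair(counts, threshold, "none_vs_model")
        na = nerd_pair(counts, threshold, "none_vs_all")
        am = nerd_pair(counts, threshold, "all_vs_model")
        return cls(
            threshold=threshold,
            erg_model=erg_model,
            erg_treat_all=erg_all,
            erg_treat_none=erg_none,
            nerd_none_model=nm,
            nerd_none_all=na,
            nerd_all_model=am,
        )

    def nerd(self, first: str, second: str) -> float:
        """Signed NERD between any two named strategies at this point."""
        if first == second:
            return 0.0
        table = {
            ("treat_none", "model"): self.nerd_none_model,
            ("treat_none", "treat_all"): self.nerd_none_all,
            ("treat_all", "model"): self.nerd_all_model,
        }
        if (first, second) in table:
            return table[(first, second)]
        if (second, first) in table:
            return -table[(second, first)]
        raise ValueError(f"unknown strategies: {first!r}, {second!r}")
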