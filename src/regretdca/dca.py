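"""Regret decision curve analysis: threshold sweep, strategy selection, workflow.

The central object is :class:`RegretDCA`, a model built from a cohort of
predicted risks and observed outcomes.  Its :meth:`~RegretDCA.fit` sweeps a
threshold grid, computing at each threshold the confusion counts, the three
expected regrets and the three pairwise NERDs, and returns a
:class:`RegretDCAResults` carrying the curve together with strategy
selection, acceptable-regret equivalence, plotting and a summary table.

Strategy selection is purely ordinal: the signs of the three NERDs order the
strategies (positive NERD favours the second strategy of the pair), and the
transitive maximum is the optimal set.  With an acceptable-regret budget
``rg0``, any strategy whose absolute NERD against an optimal strategy is
within the budget is *equivalent in regret*; among equivalent strategies the
recommendation prefers the least burdensome (treat none, then treat all, then
model — running a model that changes nothing is superfluous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .elicitation import (
    AcceptableRegret,
    ComfortBounds,
    RegretAssessment,
    ThresholdProbability,
    acceptable_regret_from_scenario,
    comfort_bounds,
    format_percent,
    threshold_from_regrets,
)
from .regret_core import (
    STRATEGIES,
    Cohort,
    RegretCurvePoint,
    ThresholdLike,
    as_threshold,
    classify_cohort,
)

__all__ = [
    "RegretCurve",
    "StrategyDecision",
    "RegretDCA",
    "RegretDCAResults",
    "build_curve",
    "select_strategy",
    "decide",
    "default_grid",
]

#: Absolute tolerance separating algebraic NERD ties from float noise.
TIE_TOL = 1e-12

#: Recommendation preference among equally acceptable strategies: least
#: intervention first, model last (model overhead is superfluous if a default
#: strategy is equivalent).
PREFERENCE_ORDER = ("treat_none", "treat_all", "model")

_CANONICAL_PAIRS = (
    ("treat_none", "model"),
    ("treat_none", "treat_all"),
    ("treat_all", "model"),
)


def default_grid(step: float = 0.01) -> np.ndarray:
    """Threshold grid 0.00, step, ..., up to but excluding 1."""
    return np.round(np.arange(0.0, 1.0 - step / 2, step), 10)


@dataclass(frozen=True)
class RegretCurve:
    """Ordered regret-curve points over a strictly increasing threshold grid."""

    points: tuple[RegretCurvePoint, ...]
    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "points", tuple(self.points))
        if len(self.points) != grid.size:
            raise ValueError("one curve point per grid value required")

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        """Curve as a DataFrame in the standard column order."""
        return pd.DataFrame(
            {
                "threshold": [p.threshold.value for p in self.points],
                "erg_none": [p.erg_treat_none for p in self.points],
                "erg_all": [p.erg_treat_all for p in self.points],
                "erg_model": [p.erg_model for p in self.points],
                "nerd_none_model": [p.nerd_none_model for p in self.points],
                "nerd_none_all": [p.nerd_none_all for p in self.points],
                "nerd_all_model": [p.nerd_all_model for p in self.points],
            }
        )


@dataclass(frozen=True)
class StrategyDecision:
    """Outcome of comparing the three strategies at one threshold.

    ``optimal`` is the transitive-maximum set from the NERD signs;
    ``equivalent_in_regret`` additionally admits strategies within the
    acceptable-regret budget of an optimal one (it equals ``optimal`` when no
    budget was supplied); ``recommendation`` is the preferred member of the
    admissible set; ``narrative`` lists the three pairwise comparisons.
    """

    optimal: tuple[str, ...]
    equivalent_in_regret: tuple[str, ...]
    recommendation: str
    narrative: tuple[dict, ...]
    rg0: Optional[float] = None


def _validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("threshold grid must be a non-empty 1-d sequence")
    if grid.min() < 0.0 or grid.max() >= 1.0:
        raise ValueError("grid thresholds must lie in [0, 1); Pt = 1 has no finite weight")
    if np.any(np.diff(grid) <= 0.0):
        raise ValueError("threshold grid must be strictly increasing")
    return grid


def build_curve(cohort: Cohort, grid: Sequence[float]) -> RegretCurve:
    """Sweep the threshold grid: classify, compute regrets and NERDs per point."""
    grid = _validate_grid(grid)
    points = [
        RegretCurvePoint.from_counts(classify_cohort(cohort, pt), pt) for pt in grid
    ]
    return RegretCurve(points=tuple(points), grid=grid)


def select_strategy(
    point: RegretCurvePoint,
    rg0: Optional[float] = None,
    tol: float = TIE_TOL,
) -> StrategyDecision:
    """Pick the regret-minimizing strategy (or strategies) at one threshold.

    The three pairwise NERDs order the strategies; ties within ``tol`` make
    both co-optimal.  With ``rg0`` given, strategies whose |NERD| against an
    optimal strategy does not exceed the budget join the admissible set, and
    the recommendation is its least-burdensome member.
    """
    if rg0 is not None and rg0 < 0.0:
        raise ValueError("acceptable regret budget rg0 must be non-negative")

    narrative = []
    beaten: set[str] = set()
    for first, second in _CANONICAL_PAIRS:
        value = point.nerd(first, second)
        if value > tol:
            preferred = second
            beaten.add(first)
        elif value < -tol:
            preferred = first
            beaten.add(second)
        else:
            preferred = "tie"
        narrative.append({"pair": f"{first}_vs_{second}", "nerd": value, "preferred": preferred})

    optimal = tuple(s for s in STRATEGIES if s not in beaten)
    if not optimal:  # degenerate float cycle; fall back to minimum expected regret
        ergs = {
            "treat_none": point.erg_treat_none,
            "treat_all": point.erg_treat_all,
            "model": point.erg_model,
        }
        best = min(ergs.values())
        optimal = tuple(s for s in STRATEGIES if ergs[s] <= best + tol)

    if rg0 is None:
        equivalent = optimal
    else:
        equivalent = tuple(
            s
            for s in STRATEGIES
            if s in optimal or any(abs(point.nerd(s, o)) <= rg0 for o in optimal)
        )

    recommendation = next(s for s in PREFERENCE_ORDER if s in equivalent)
    # Order the reported tuples canonically.
    optimal = tuple(s for s in PREFERENCE_ORDER if s in optimal)
    equivalent = tuple(s for s in PREFERENCE_ORDER if s in equivalent)
    return StrategyDecision(
        optimal=optimal,
        equivalent_in_regret=equivalent,
        recommendation=recommendation,
        narrative=tuple(narrative),
        rg0=rg0,
    )


class RegretDCA:
    """Regret-based decision curve analysis model over a cohort.

    Parameters
    ----------
    risks : array-like of float in [0, 1]
        Model-predicted disease probabilities, one per patient.
    outcomes : array-like of {0, 1}
        Observed disease status.

    Examples
    --------
    >>> model = RegretDCA([0.9, 0.6, 0.3, 0.1], [1, 0, 1, 0])
    >>> res = model.fit()
    >>> res.at_threshold(0.25).nerd_none_all  # doctest: +ELLIPSIS
    0.333...
    """

    def __init__(self, risks, outcomes) -> None:
        self.cohort = Cohort(np.asarray(risks, dtype=float), np.asarray(outcomes))

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "RegretDCA":
        model = cls.__new__(cls)
        model.cohort = cohort
        return model

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, risk_col: str = "risk", outcome_col: str = "outcome"
    ) -> "RegretDCA":
        return cls(frame[risk_col].to_numpy(), frame[outcome_col].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "RegretDCA":
        from .io_reporting import read_cohort

        return cls.from_cohort(read_cohort(path))

    def fit(self, grid: Optional[Sequence[float]] = None) -> "RegretDCAResults":
        """Build the regret curve over ``grid`` (default 0.00..0.99 step 0.01)."""
        if grid is None:
            grid = default_grid()
        return RegretDCAResults(self, build_curve(self.cohort, grid))


class RegretDCAResults:
    """Fitted regret decision curve with selection and reporting methods."""

    def __init__(self, model: RegretDCA, curve: RegretCurve) -> None:
        self.model = model
        self.curve = curve

    @property
    def frame(self) -> pd.DataFrame:
        return self.curve.to_frame()

    def at_threshold(self, threshold: ThresholdLike) -> RegretCurvePoint:
        """Curve point at an arbitrary threshold, recomputed exactly.

        Elicited thresholds (e.g. 6/13) rarely fall on the grid, so the point
        is recomputed from the cohort rather than interpolated.
        """
        threshold = as_threshold(threshold)
        counts = classify_cohort(self.model.cohort, threshold)
        return RegretCurvePoint.from_counts(counts, threshold)

    def select_strategy(
        self, threshold: ThresholdLike, rg0: Optional[float] = None
    ) -> StrategyDecision:
        return select_strategy(self.at_threshold(threshold), rg0=rg0)

    def decide(
        self,
        assessment: RegretAssessment,
        patient_risk: float,
        scenario: Optional[dict] = None,
        convention: str = "literal",
    ) -> dict:
        return decide(
            assessment,
            self,
            patient_risk,
            scenario=scenario,
            convention=convention,
        )

    def optimal_bands(self) -> list[dict]:
        """Contiguous grid ranges sharing the same optimal strategy set."""
        bands: list[dict] = []
        for pt, point in zip(self.curve.grid, self.curve.points):
            optimal = select_strategy(point).optimal
            if bands and bands[-1]["optimal"] == optimal:
                bands[-1]["stop"] = float(pt)
            else:
                bands.append({"start": float(pt), "stop": float(pt), "optimal": optimal})
        return bands

    def summary(self) -> str:
        cohort = self.model.cohort
        grid = self.curve.grid
        lines = [
            "Regret Decision Curve Analysis Results",
            "=" * 54,
            f"No. patients:        {cohort.n}",
            f"Diseased:            {cohort.diseased} (prevalence {cohort.prevalence:.4f})",
            f"Threshold grid:      [{grid[0]:.2f}, {grid[-1]:.2f}] ({grid.size} points)",
            "",
            "Optimal strategy by threshold band (sign of NERDs):",
        ]
        for band in self.optimal_bands():
            label = " + ".join(band["optimal"])
            lines.append(f"  Pt in [{band['start']:.2f}, {band['stop']:.2f}]: {label}")
        return "\n".join(lines)

    def plot(self, rg0: Optional[float] = None, ax=None):
        """Plot the three NERD series against threshold probability.

        Dashed horizontal lines mark the +/- ``rg0`` acceptable-regret band
        when a budget is given.  Returns the matplotlib axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        frame = self.frame
        ax.plot(frame["threshold"], frame["nerd_none_all"], lw=0.9, label="NERD(treat none, treat all)")
        ax.plot(frame["threshold"], frame["nerd_none_model"], lw=1.6, label="NERD(treat none, model)")
        ax.plot(frame["threshold"], frame["nerd_all_model"], ls="--", label="NERD(treat all, model)")
        if rg0 is not None:
            ax.axhline(rg0, color="grey", ls=":", lw=1)
            ax.axhline(-rg0, color="grey", ls=":", lw=1)
        ax.axhline(0.0, color="black", lw=0.6)
        ax.set_xlabel("Threshold probability $P_t$")
        ax.set_ylabel("Net expected regret difference")
        ax.legend(loc="best", fontsize=8)
        return ax


def decide(
    assessment: RegretAssessment,
    data: Union[Cohort, RegretDCA, RegretDCAResults],
    patient_risk: float,
    scenario: Optional[dict] = None,
    convention: str = "literal",
    grid: Optional[Sequence[float]] = None,
) -> dict:
    """Run the full decision workflow for one patient and one decision maker.

    Steps: (1) elicit the threshold from the regret ratings; (2) select the
    optimal strategy at that threshold from the cohort; (3) if the model
    strategy is in play, treat iff ``patient_risk >= Pt``; (4) with an
    acceptable-regret scenario (keys ``tolerated``, ``denominator``,
    ``basis``; the matching VAS rating is taken from the assessment),
    re-evaluate equivalence under the regret budget; (5) report the comfort
    bound for the elicited side.  The returned dict records every
    intermediate quantity and is JSON-serializable.
    """
    if not 0.0 <= float(patient_risk) <= 1.0:
        raise ValueError(f"patient risk must lie in [0, 1], got {patient_risk!r}")

    if isinstance(data, RegretDCAResults):
        results = data
    elif isinstance(data, RegretDCA):
        results = data.fit(grid)
    elif isinstance(data, Cohort):
        results = RegretDCA.from_cohort(data).fit(grid)
    else:
        raise TypeError("data must be a Cohort, RegretDCA, or RegretDCAResults")

    # Step 1: threshold from the dual regret ratings.
    threshold = threshold_from_regrets(assessment)

    # Step 2: strategy comparison at the elicited threshold (exact recompute).
    point = results.at_threshold(threshold)
    decision = select_strategy(point)

    # Step 3: patient-level call, meaningful when the model strategy is in play.
    treat = float(patient_risk) >= threshold.value

    # Step 4: acceptable regret, if a scenario was elicited.
    acceptable: Optional[AcceptableRegret] = None
    decision_with_budget: Optional[StrategyDecision] = None
    if scenario is not None:
        basis = scenario["basis"]
        rating = assessment.omission if basis == "benefits" else assessment.commission
        acceptable = acceptable_regret_from_scenario(
            scenario["tolerated"],
            scenario["denominator"],
            rating,
            basis,
            convention=convention,
        )
        decision_with_budget = select_strategy(point, rg0=acceptable.rg0)

    # Step 5: comfort bound on the elicited side.
    bounds: Optional[ComfortBounds] = None
    if acceptable is not None:
        if acceptable.basis == "benefits":
            bounds = comfort_bounds(r_b=acceptable.r)
        else:
            bounds = comfort_bounds(r_h=acceptable.r)

    final = decision_with_budget if decision_with_budget is not None else decision
    report = {
        "assessment": {
            "omission": assessment.omission,
            "commission": assessment.commission,
        },
        "threshold": {
            "value": threshold.value,
            "percent": format_percent(threshold.value),
            "weight": None if threshold.is_certain else threshold.weight,
        },
        "expected_regrets": {
            "model": point.erg_model,
            "treat_all": point.erg_treat_all,
            "treat_none": point.erg_treat_none,
        },
        "nerds": {
            "none_vs_model": point.nerd_none_model,
            "none_vs_all": point.nerd_none_all,
            "all_vs_model": point.nerd_all_model,
        },
        "strategy": {
            "optimal": list(decision.optimal),
            "narrative": [dict(entry) for entry in decision.narrative],
        },
        "patient": {
            "risk": float(patient_risk),
            "treat_if_model_used": bool(treat),
            "model_in_play": "model" in final.equivalent_in_regret
            or "model" in final.optimal,
        },
        "acceptable_regret": None,
        "comfort_bounds": None,
        "recommendation": final.recommendation,
    }
    if acceptable is not None:
        assert decision_with_budget is not None
        report["acceptable_regret"] = {
            "basis": acceptable.basis,
            "tolerated": acceptable.tolerated,
            "denominator": acceptable.denominator,
            "r": acceptable.r,
            "rating": acceptable.rating,
            "rg0": acceptable.rg0,
            "convention": acceptable.convention,
            "equivalent_in_regret": list(decision_with_budget.equivalent_in_regret),
            "model_superfluous": (
                "model" in decision_with_budget.equivalent_in_regret
                and decision_with_budget.recommendation != "model"
            ),
        }
    if bounds is not None:
        report["comfort_bounds"] = {
            "p_treat_none": bounds.p_treat_none,
            "p_treat_all": bounds.p_treat_all,
        }
    return report
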