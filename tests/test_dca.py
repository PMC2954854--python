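"""Curve building, strategy selection, and the five-step decision workflow."""

import numpy as np
import pytest

from regretdca import (
    Cohort,
    RegretAssessment,
    RegretCurvePoint,
    RegretDCA,
    ThresholdProbability,
    build_curve,
    decide,
    default_grid,
    select_strategy,
)


def make_point(pt, nm, na, ergs=(0.0, 0.0, 0.0)):
    """Construct a curve point from the two free NERDs (am is additive)."""
    erg_model, erg_all, erg_none = ergs
    return RegretCurvePoint(
        threshold=ThresholdProbability(pt),
        erg_model=erg_model,
        erg_treat_all=erg_all,
        erg_treat_none=erg_none,
        nerd_none_model=nm,
        nerd_none_all=na,
        nerd_all_model=nm - na,
    )


@pytest.fixture
def perfect_cohort():
    """Perfectly discriminating, prevalence 0.2."""
    return Cohort.from_records([(0.98, 1)] * 20 + [(0.02, 0)] * 80)


@pytest.fixture
def near_tie_cohort():
    """Weak model: at high thresholds the model barely loses to treat-none.

    20 diseased at risk 0.3, 79 healthy at 0.1, one healthy at 0.5; at
    Pt = 6/13 the model biopsies one healthy patient and no diseased one.
    """
    records = [(0.3, 1)] * 20 + [(0.1, 0)] * 79 + [(0.5, 0)]
    return Cohort.from_records(records)


class TestBuildCurve:
    def test_perfect_model_nerd_is_prevalence_everywhere(self, perfect_cohort):
        curve = build_curve(perfect_cohort, np.linspace(0.05, 0.85, 17))
        for point in curve.points:
            assert point.nerd_none_model == pytest.approx(0.2)

    def test_single_point_grid(self, toy_cohort):
        curve = build_curve(toy_cohort, [0.25])
        assert len(curve) == 1
        assert curve.points[0].nerd_none_all == pytest.approx(0.5 - 0.5 / 3)

    @pytest.mark.parametrize("grid", [[], [0.5, 0.2], [0.2, 0.2], [0.5, 1.0]])
    def test_bad_grids_rejected(self, toy_cohort, grid):
        with pytest.raises(ValueError):
            build_curve(toy_cohort, grid)

    def test_default_grid_spans_unit_interval_open(self):
        grid = default_grid()
        assert grid[0] == 0.0 and grid[-1] == pytest.approx(0.99)
        assert grid.size == 100


class TestSelectStrategy:
    def test_all_positive_nerds_select_model(self):
        point = make_point(0.15, nm=0.08, na=0.05)
        decision = select_strategy(point)
        assert decision.optimal == ("model",)
        assert decision.recommendation == "model"
        assert [e["preferred"] for e in decision.narrative] == ["model", "treat_all", "model"]

    def test_small_nerd_within_budget_makes_model_superfluous(self):
        # model wins on signs, but by less than the acceptable-regret budget
        point = make_point(0.20, nm=0.005, na=-0.1)
        decision = select_strategy(point, rg0=0.01)
        assert decision.optimal == ("model",)
        assert decision.equivalent_in_regret == ("treat_none", "model")
        assert decision.recommendation == "treat_none"

    def test_all_zero_nerds_are_total_indifference(self):
        decision = select_strategy(make_point(0.3, nm=0.0, na=0.0))
        assert decision.optimal == ("treat_none", "treat_all", "model")

    def test_depends_only_on_nerds_not_regret_levels(self):
        a = select_strategy(make_point(0.4, nm=0.02, na=-0.3, ergs=(0.1, 0.4, 0.12)))
        b = select_strategy(make_point(0.4, nm=0.02, na=-0.3, ergs=(1.1, 1.4, 1.12)))
        assert a.optimal == b.optimal and a.recommendation == b.recommendation

    def test_zero_budget_adds_nothing_beyond_ties(self):
        point = make_point(0.2, nm=0.005, na=-0.1)
        decision = select_strategy(point, rg0=0.0)
        assert decision.equivalent_in_regret == decision.optimal

    def test_negative_budget_rejected(self):
        with pytest.raises(ValueError):
            select_strategy(make_point(0.2, nm=0.1, na=0.0), rg0=-0.1)

    def test_perfect_model_optimal_across_interior(self, perfect_cohort):
        results = RegretDCA.from_cohort(perfect_cohort).fit()
        for pt in (0.05, 0.2, 0.5, 0.9):
            assert "model" in results.select_strategy(pt).optimal


class TestDecideWorkflow:
    def test_first_physician_flow(self, perfect_cohort):
        """Strong omission aversion, discriminating model: use it and treat."""
        report = decide(
            RegretAssessment(omission=50, commission=10),
            perfect_cohort,
            patient_risk=0.20,
            scenario={"tolerated": 1, "denominator": 20, "basis": "benefits"},
        )
        assert report["threshold"]["value"] == pytest.approx(1 / 6)
        assert report["threshold"]["percent"] == "16%"
        assert report["strategy"]["optimal"] == ["model"]
        assert report["patient"]["treat_if_model_used"] is True
        ar = report["acceptable_regret"]
        assert ar["r"] == pytest.approx(0.05)
        assert ar["rg0"] == pytest.approx(0.025)
        # every NERD exceeds the budget: the model stays uniquely recommended
        assert ar["equivalent_in_regret"] == ["model"]
        assert ar["model_superfluous"] is False
        assert report["recommendation"] == "model"
        assert report["comfort_bounds"]["p_treat_none"] == pytest.approx(0.05)
        assert report["comfort_bounds"]["p_treat_all"] is None

    def test_second_physician_flow(self, near_tie_cohort):
        """High threshold, weak model: treat none, model equivalent in regret."""
        report = decide(
            RegretAssessment(omission=70, commission=60),
            near_tie_cohort,
            patient_risk=0.20,
            scenario={"tolerated": 40, "denominator": 80, "basis": "harms"},
        )
        assert report["threshold"]["value"] == pytest.approx(6 / 13)
        assert report["threshold"]["percent"] == "46%"
        assert report["strategy"]["optimal"] == ["treat_none"]
        ar = report["acceptable_regret"]
        assert ar["r"] == pytest.approx(0.5)
        assert ar["rg0"] == pytest.approx(0.3)
        assert ar["equivalent_in_regret"] == ["treat_none", "model"]
        assert ar["model_superfluous"] is True
        assert report["recommendation"] == "treat_none"
        assert report["comfort_bounds"]["p_treat_all"] == pytest.approx(0.50)

    def test_boundary_risk_is_treated(self, perfect_cohort):
        report = decide(
            RegretAssessment(60, 30), perfect_cohort, patient_risk=1 / 3
        )
        assert report["patient"]["treat_if_model_used"] is True

    def test_invalid_patient_risk(self, perfect_cohort):
        with pytest.raises(ValueError):
            decide(RegretAssessment(60, 30), perfect_cohort, patient_risk=1.2)

    def test_accepts_fitted_results(self, perfect_cohort):
        results = RegretDCA.from_cohort(perfect_cohort).fit()
        report = decide(RegretAssessment(60, 30), results, patient_risk=0.5)
        assert report["strategy"]["optimal"] == ["model"]


class TestResultsObject:
    def test_exact_recompute_off_grid(self, toy_cohort):
        results = RegretDCA.from_cohort(toy_cohort).fit()
        point = results.at_threshold(6 / 13)  # falls between grid points
        assert point.threshold.value == pytest.approx(6 / 13)

    def test_from_dataframe_round_trip(self, toy_cohort):
        model = RegretDCA.from_dataframe(toy_cohort.to_frame())
        assert np.array_equal(model.cohort.risks, toy_cohort.risks)

    def test_summary_mentions_cohort_and_bands(self, toy_cohort):
        text = RegretDCA.from_cohort(toy_cohort).fit().summary()
        assert "prevalence 0.5000" in text
        assert "Pt in [" in text

    def test_nerd_none_all_root_tracks_prevalence(self):
        # the treat-all vs treat-none break-even threshold is the prevalence
        cohort = Cohort.from_records([(0.8, 1)] * 30 + [(0.2, 0)] * 70)
        frame = RegretDCA.from_cohort(cohort).fit().frame
        signs = np.sign(frame["nerd_none_all"].to_numpy())
        crossing = frame["threshold"].to_numpy()[np.flatnonzero(np.diff(signs) < 0)[0]]
        assert abs(crossing - cohort.prevalence) <= 0.01 + 1e-9

    def test_plot_draws_three_series_and_budget_lines(self, toy_cohort):
        ax = RegretDCA.from_cohort(toy_cohort).fit().plot(rg0=0.05)
        assert len(ax.get_legend().get_texts()) == 3
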