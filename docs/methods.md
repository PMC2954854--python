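# Methods

## Decision problem and regret model

A binary treatment decision under a probabilistic prediction model has four
outcomes: treat/not-treat crossed with diseased/healthy. Regret attaches to
the two errors only: omission (not treating a diseased patient) costs the
forgone benefit `U1−U3`; commission (treating a healthy patient) costs the
harm `U4−U2`; correct decisions carry zero regret. All regrets are rescaled
by `U1−U3`, so the omission regret is 1 and the commission regret is the
odds weight `w = Pt/(1−Pt)` — the substitution that makes the threshold
`Pt` the single preference parameter. An optional multiplier
(omission rating / 100) restores raw VAS units for display; nothing in the
strategy comparison depends on it, because only regret *differences* matter.

Expected regrets per patient over a cohort with `n` patients, `d` diseased
(prevalence `p = d/n`), classified treat/no-treat by `risk ≥ Pt`:

* model: `FN/n + (FP/n)·w`
* treat all: `(1−p)·w`
* treat none: `p`

The joint-count estimators (`TP/n ≈ P(risk≥Pt ∩ D+)`, etc.) are the
canonical form; prevalence is always taken from the cohort, never injected
externally, so the three formulas share one empirical measure.

## Elicitation

The dual visual analog scale asks for two 0–100 ratings (omission,
commission), treated as linear with no re-anchoring. `Pt =
1/(1 + omission/commission)`; a zero commission rating gives `Pt = 1`
(treat only at certainty), and rating both errors zero is rejected as
undefined indifference. Reported percents are floor-truncated
(`1/6 → 16%`), matching the convention of the interview reports the
package emits; internal values keep full precision.

Acceptable regret is elicited through a scenario: out of the arm of a
hypothetical 100-patient cohort for whom a given call would be wrong, how
many wrong calls could the decision maker tolerate? The fraction `r`
(benefits side `r_b`, harms side `r_h`) times the matching rescaled rating
gives the budget `rg0`. Two conventions are exposed because the rescaled
NERD curves are in benefit units while the literal budget arithmetic mixes
scales on the harms side: `literal` (default) computes
`rg0 = r · rating/100`, reproducing the interview arithmetic verbatim;
`normalized` sets `rg0 = r`, dimensionally consistent with the curves. The
choice is a config switch (`--regret-scale`); the default favours fidelity
to the published arithmetic. Scenario arm sizes round half up; comfort
bounds are `P_treat_none = r_b` and `P_treat_all = 1 − r_h`.

## Strategy selection

At a threshold, the three pairwise NERDs order the strategies; the
transitive maximum is the optimal set. Ties are declared below an absolute
tolerance of 1e-12 — small enough to separate float noise from algebraic
ties, with acceptable regret serving as the intended *coarse* equivalence.
With a budget, any strategy within `rg0` of an optimal one joins the
admissible set, and the recommendation is its least burdensome member
(treat none, then treat all, then model): when a default strategy is
equivalent in regret to the model, running the model is superfluous.

Numerical choices: `NERD[treat none, model]` and `net_benefit` are the same
expression (`TP/n − (FP/n)·w`), so their equivalence is exact;
`NERD[treat all, model]` is computed as the difference of the two
treat-none comparisons, making the additivity identity bit-exact, and is
cross-checked against the direct count form `(TN/n)·w − FN/n` in tests.
Thresholds within 1e-9 of 1 are rejected (the weight diverges). A risk
exactly equal to the threshold is treated (≥ rule). Elicited thresholds are
evaluated by exact recomputation from the cohort, not grid interpolation,
since values like 6/13 fall between grid points. The default grid is 0.00
to 0.99 in steps of 0.01; `Pt = 1` is excluded.

## Synthetic cohorts

The generator emulates the role of a fitted risk model without fitting one;
only risk distributions are simulated.

* **calibrated** mode draws true risks `q ~ Beta(a, b)` and outcomes
  `Bernoulli(q)`: reported risks are perfectly calibrated by construction,
  prevalence is `a/(a+b)`. Defaults `a=2, b=5` (prevalence 2/7 ≈ 0.29, a
  typical moderately low-prevalence screening setting).
* **two_group** mode draws outcomes `Bernoulli(prevalence)` first and risks
  from group-specific Betas — diseased `Beta(a1, b1)`, healthy
  `Beta(a0, b0)`. Defaults (prevalence 0.25, diseased Beta(4,2), healthy
  Beta(2,5)) give a discriminating but imperfect model; heavier overlap
  (e.g. Beta(3,2) vs Beta(3,4)) reproduces the realistic band structure in
  which treat-all dominates near zero, the model in an interior threshold
  band, and treat-none at high thresholds.
* an optional **miscalibration** transform distorts reported risks on the
  log-odds scale (`logit(reported) = scale·logit(true) + shift`) without
  touching outcome generation; risks are clipped to `[1e-9, 1−1e-9]` first
  so the transform is total. Because thresholding the *true* risk is
  pointwise regret-optimal, any decision flipped by the distorted report
  weakly increases expected regret — the property the tests assert.

Randomness: two named child streams (risks, outcomes) are spawned from the
seed, and Beta draws are inverse-CDF transforms of uniforms, so the first
`k` patients are identical for any cohort size `n ≥ k` and a seed fully
determines the cohort.

What the generator does *not* emulate: covariate structure, risk estimates
correlated with unmodeled patient features, and sampling of model-fitting
error. Passing tests therefore validate the decision arithmetic and its
statistical convergence, not the behaviour of any particular clinical model.

## Verification strategy and problem sizes

Exact worked examples (thresholds, budgets, bounds) are asserted to machine
precision. The net-benefit equivalence and the brute-force expected-regret
oracle run over 1,000 random cohorts of up to 50 patients at 1e-12.
Parameter recovery uses calibrated cohorts of 10,000 patients at a fixed
seed, comparing empirical NERD curves with their closed forms under the
Beta law within three Monte-Carlo standard errors of the plug-in estimator
(the variance accounts for the Bernoulli outcome noise, second moment
`q + (1−q)w²` on the treated region). These sizes keep the whole suite
under a few seconds while leaving the Monte-Carlo bands far smaller than
the effects checked.

## Limitations

* Holistic elicitation only: no per-endpoint regret decomposition, no
  standard-gamble or time-trade-off instruments.
* Three strategies; multi-model comparison and harms of testing itself are
  out of scope.
* No bootstrap or analytic uncertainty bands around the NERD curves.
* Single decision maker, single time point; repeated or shared decisions
  are not modelled.
* Whether VAS answers should be re-elicited per patient or reused across
  similar patients is an empirical question the package does not decide; it
  simply recomputes everything per interview.
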