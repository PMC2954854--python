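# regretdca

Regret-based decision curve analysis for clinical prediction models.

Clinicians deciding whether to treat (or biopsy, or test) a patient face
three options: treat everyone, treat no one, or consult a prediction model
and treat when the predicted disease probability `p` reaches a threshold
`P_t`. Classic decision curve analysis (DCA) ranks these strategies by net
benefit. This package implements the regret-theoretic reformulation of DCA:
preferences are elicited as anticipated *regret* on a dual 0–100 visual
analog scale, strategies are compared by their expected regret, and a
decision maker's tolerance for wrong calls ("acceptable regret") determines
when a near-optimal default makes running the model superfluous. It is aimed
at biostatisticians evaluating prediction models and at builders of
decision-support tools.

## The model

Let `U1−U3` be the regret of *omission* (withholding needed treatment, the
benefit forgone) and `U4−U2` the regret of *commission* (unnecessary
treatment, the harm incurred), each rated 0–100. The treatment threshold is

    P_t = 1 / (1 + (U1−U3)/(U4−U2)),

the probability of disease at which treating and not treating carry equal
expected regret. With regrets rescaled so `U1−U3 = 1` and writing
`w = P_t/(1−P_t)`, a cohort of `n` patients with predicted risks and
observed outcomes gives, at each threshold,

    ERg[model]      = FN/n + (FP/n)·w
    ERg[treat all]  = (1 − prevalence)·w
    ERg[treat none] = prevalence

where patients are classified treat/no-treat by `p ≥ P_t`. The **Net
Expected Regret Difference** of a strategy pair, `NERD[s1, s2] =
ERg[s1] − ERg[s2]`, is positive when the second strategy inflicts less
regret; `NERD[treat none, model] = TP/n − (FP/n)·w` is exactly the classic
DCA net benefit. An acceptable-regret budget `Rg0 = r · rating/100` — with
`r` the tolerated fraction of wrong calls elicited through a hypothetical
100-patient scenario — declares strategies with `|NERD| ≤ Rg0` *equivalent
in regret*, and yields comfort bounds `P_treat_none = r_b` and
`P_treat_all = 1 − r_h` on the probability scale.

## Worked example

Simulate a cohort of 1,000 patients from an imperfect risk model
(two-group mode: prevalence 25%, diseased risks ~Beta(3,2), non-diseased
~Beta(3,4)), then run the five-step workflow for a physician who rates
regret of omission 50 and commission 10, sees a patient at 20% predicted
risk, and would tolerate missing 1 of 20 needed treatments:

```sh
regret-dca simulate --n 1000 --mode two_group --prevalence 0.25 \
    --a1 3 --b1 2 --a0 3 --b0 4 --seed 17 --out cohort.csv
regret-dca decide --omission 50 --commission 10 --cohort cohort.csv \
    --risk 0.20 --tolerated 1 --denominator 20 --basis benefits --format text
```

prints

```
Regret DCA decision report
----------------------------------------
Step 1 - threshold elicitation
  regret of omission rating:   50
  regret of commission rating: 10
  threshold: 16% (exact 0.166667, weight 0.2)
Step 2 - strategy comparison at the threshold
  NERD[treat_none, model] = +0.1126 -> model
  NERD[treat_none, treat_all] = +0.1096 -> treat_all
  NERD[treat_all, model] = +0.003 -> model
  optimal: model
Step 3 - patient-level call
  predicted risk 20% >= threshold 16% -> treat (under the model strategy)
Step 4 - acceptable regret
  basis benefits: tolerated 1 of 20 -> r = 0.05, rg0 = 0.025
  equivalent in regret: treat_all, model
  the model is equivalent in regret to a default strategy: its use is superfluous
Step 5 - comfort bounds
  tolerate withholding treatment below risk 5%
Recommendation: treat_all
```

Reading: rating omission five times worse than commission puts the
threshold at `1/6 ≈ 16%`. All three NERDs are positive, so by transitivity
the model is the regret-optimal strategy, and the patient's 20% risk clears
the threshold. But the model beats treat-all by only 0.003 expected-regret
units — less than the elicited budget of 0.025 — so for this physician
treating everyone is equivalent in regret and the model adds no actionable
information; the comfort bound says withholding treatment is only tolerable
below a 5% risk. The same analysis is available programmatically:

```python
from regretdca import RegretDCA, RegretAssessment

res = RegretDCA.from_csv("cohort.csv").fit()     # 0.00..0.99 threshold sweep
print(res.summary())                             # optimal-strategy bands
report = res.decide(RegretAssessment(50, 10), patient_risk=0.20,
                    scenario={"tolerated": 1, "denominator": 20,
                              "basis": "benefits"})
res.plot(rg0=0.025)                              # NERD curves + budget band
```

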