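"""Synthetic cohorts with controllable prevalence, discrimination, calibration.

The decision-curve machinery needs per-patient predicted risks paired with
binary outcomes.  This module simulates such cohorts in two modes:

* ``calibrated`` — true risks are drawn from a Beta(a, b) distribution and
  outcomes are Bernoulli in the true risk, so the reported risks are
  perfectly calibrated by construction.  Prevalence is the Beta mean
  a/(a+b); discrimination is governed by the spread of the Beta.
* ``two_group`` — outcomes are Bernoulli(prevalence) first, and risks are
  drawn from group-specific Beta distributions (a1, b1 for diseased, a0, b0
  for non-diseased).  Separated group distributions give a discriminating
  but generally miscalibrated risk model.

An optional miscalibration transform distorts the *reported* risk on the
log-odds scale (``logit(reported) = scale * logit(true) + shift``) without
touching outcome generation, emulating an over/under-confident or biased
model.

Randomness uses two named child streams (risks, outcomes) spawned from the
seed, with Beta draws obtained by inverse-CDF transformation of uniforms, so
the first ``k`` patients are identical for any cohort size ``n >= k``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist

from .regret_core import Cohort

__all__ = ["SyntheticSpec", "generate"]

_RISK_CLIP = 1e-9  # keep the log-odds transform total at risk 0 and 1


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort draw.

    Calibrated mode uses ``a, b``; two-group mode uses ``prevalence`` with
    ``(a1, b1)`` for the diseased and ``(a0, b0)`` for the non-diseased
    group.  ``miscalibration`` is an optional ``(shift, scale)`` pair applied
    to reported risks on the log-odds scale.
    """

    n: int
    mode: str = "calibrated"
    a: float = 2.0
    b: float = 5.0
    prevalence: float = 0.25
    a1: float = 4.0
    b1: float = 2.0
    a0: float = 2.0
    b0: float = 5.0
    miscalibration: Optional[tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n) < 1:
            raise ValueError("cohort size n must be >= 1")
        if self.mode not in ("calibrated", "two_group"):
            raise ValueError(f"mode must be 'calibrated' or 'two_group', got {self.mode!r}")
        params = (
            (self.a, self.b)
            if self.mode == "calibrated"
            else (self.a1, self.b1, self.a0, self.b0)
        )
        if any(p <= 0 for p in params):
            raise ValueError("Beta shape parameters must be positive")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.miscalibration is not None:
            shift, scale = self.miscalibration
            if not np.isfinite(shift) or not np.isfinite(scale) or scale <= 0:
                raise ValueError("miscalibration requires finite shift and positive scale")


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    risks_ss, outcomes_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(risks_ss), np.random.default_rng(outcomes_ss)


def _miscalibrate(risk: np.ndarray, shift: float, scale: float) -> np.ndarray:
    clipped = np.clip(risk, _RISK_CLIP, 1.0 - _RISK_CLIP)
    return expit(scale * logit(clipped) + shift)


def generate(spec: SyntheticSpec) -> Cohort:
    """Draw a cohort per the spec; fully determined by ``spec.seed``."""
    rng_risk, rng_out = _streams(spec.seed)
    u_risk = rng_risk.random(spec.n)
    u_out = rng_out.random(spec.n)

    if spec.mode == "calibrated":
        true_risk = beta_dist.ppf(u_risk, spec.a, spec.b)
        outcomes = (u_out < true_risk).astype(np.int64)
    else:
        outcomes = (u_out < spec.prevalence).astype(np.int64)
        risk_if_diseased = beta_dist.ppf(u_risk, spec.a1, spec.b1)
        risk_if_healthy = beta_dist.ppf(u_risk, spec.a0, spec.b0)
        true_risk = np.where(outcomes == 1, risk_if_diseased, risk_if_healthy)

    reported = true_risk
    if spec.miscalibration is not None:
        reported = _miscalibrate(true_risk, *spec.miscalibration)

    return Cohort(reported, outcomes)
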