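"""Cohort CSV I/O, curve TSV output, grid parsing, and decision reports.

File contracts:

* cohort CSV — header ``id,risk,outcome``; ``risk`` a decimal in [0, 1],
  ``outcome`` 0 or 1, ``id`` unique.  Risks are written with 10 significant
  digits so a write/read round trip reproduces a cohort exactly.
* curve TSV — columns ``threshold, erg_none, erg_all, erg_model,
  nerd_none_model, nerd_none_all, nerd_all_model``.
* decision report — JSON (schema-stable, loss-less round trip) or a text
  rendering that mirrors the five-step interview workflow.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .regret_core import Cohort
from .dca import RegretCurve

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_curve_tsv",
    "parse_grid",
    "report_to_json",
    "report_to_text",
    "write_report",
    "session_record",
    "RunConfig",
]

logger = logging.getLogger("regretdca")

COHORT_COLUMNS = ("id", "risk", "outcome")

#: Interview scripts, in the package's own wording, recorded in session files
#: so an elicitation run can be audited.
QUESTION_OMISSION = (
    "On a scale from 0 (no regret) to 100 (maximum regret), how strongly "
    "would you regret failing to give a treatment that, in retrospect, your "
    "patient needed?"
)
QUESTION_COMMISSION = (
    "On a scale from 0 (no regret) to 100 (maximum regret), how strongly "
    "would you regret giving a treatment that, in retrospect, your patient "
    "did not need?"
)
QUESTION_TOLERATE_HARMS = (
    "Imagine {arm} patients with the same predicted risk as yours who should "
    "NOT be treated. Because no model is perfectly accurate, some will be "
    "treated anyway. How many unnecessary treatments could you tolerate?"
)
QUESTION_TOLERATE_BENEFITS = (
    "Imagine {arm} patients with the same predicted risk as yours who SHOULD "
    "be treated. Because no model is perfectly accurate, some will be missed. "
    "How many missed treatments could you tolerate?"
)


def read_cohort(path) -> Cohort:
    """Read and validate a cohort CSV (header ``id,risk,outcome``)."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV must have columns id,risk,outcome "
                         f"(missing {missing})")
    if len(frame) == 0:
        raise ValueError(f"{path}: cohort CSV contains a header but no patients")
    if frame["id"].duplicated().any():
        dupes = frame.loc[frame["id"].duplicated(), "id"].unique()[:5]
        raise ValueError(f"{path}: duplicate patient ids {list(dupes)}")
    risks = pd.to_numeric(frame["risk"], errors="coerce")
    bad = risks.isna() | (risks < 0.0) | (risks > 1.0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based incl. header
        raise ValueError(
            f"{path}: risk out of [0, 1] (or non-numeric) at line {row}: "
            f"{frame['risk'].iloc[row - 2]!r}"
        )
    outcomes = frame["outcome"]
    if not outcomes.isin((0, 1)).all():
        row = int(np.flatnonzero(~outcomes.isin((0, 1)).to_numpy())[0]) + 2
        raise ValueError(
            f"{path}: outcome must be 0 or 1 at line {row}: {outcomes.iloc[row - 2]!r}"
        )
    cohort = Cohort(risks.to_numpy(dtype=float), outcomes.to_numpy(dtype=np.int64))
    logger.info(
        "read cohort %s: n=%d, prevalence=%.4f", path, cohort.n, cohort.prevalence
    )
    return cohort


def write_cohort(cohort: Cohort, path, ids=None) -> None:
    """Write the standard cohort CSV.

    Risks carry 17 significant digits, the shortest precision guaranteeing a
    bit-exact write/read round trip for double-precision values.
    """
    frame = cohort.to_frame(ids=ids)
    frame.to_csv(path, index=False, float_format="%.17g")


def write_curve_tsv(curve: RegretCurve, path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def parse_grid(spec: str) -> np.ndarray:
    """Parse ``start:stop:step`` into a strictly increasing grid within [0, 1)."""
    try:
        start, stop, step = (float(part) for part in spec.split(":"))
    except ValueError:
        raise ValueError(f"grid spec must be 'start:stop:step', got {spec!r}") from None
    if step <= 0:
        raise ValueError("grid step must be positive")
    count = int(np.floor((stop - start) / step + 1e-9)) + 1
    if count < 1:
        raise ValueError(f"grid spec {spec!r} produces no thresholds")
    grid = np.round(start + step * np.arange(count), 10)
    if grid[0] < 0.0 or grid[-1] >= 1.0:
        raise ValueError("grid thresholds must lie in [0, 1)")
    return grid


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2)


def _pct(value: float) -> str:
    from .elicitation import format_percent

    return format_percent(value)


def report_to_text(report: dict) -> str:
    """Render a decision report mirroring the five-step interview workflow."""
    lines = ["Regret DCA decision report", "-" * 40]

    lines.append("Step 1 - threshold elicitation")
    if "assessment" in report and report["assessment"]:
        a = report["assessment"]
        lines.append(f"  regret of omission rating:   {a['omission']:g}")
        lines.append(f"  regret of commission rating: {a['commission']:g}")
    t = report["threshold"]
    weight = "infinite" if t["weight"] is None else f"{t['weight']:.6g}"
    lines.append(f"  threshold: {t['percent']} (exact {t['value']:.6g}, weight {weight})")

    lines.append("Step 2 - strategy comparison at the threshold")
    for entry in report["strategy"]["narrative"]:
        lines.append(
            f"  NERD[{entry['pair'].replace('_vs_', ', ')}] = "
            f"{entry['nerd']:+.6g} -> {entry['preferred']}"
        )
    lines.append("  optimal: " + ", ".join(report["strategy"]["optimal"]))

    lines.append("Step 3 - patient-level call")
    p = report["patient"]
    symbol = ">=" if p["treat_if_model_used"] else "<"
    action = "treat" if p["treat_if_model_used"] else "do not treat"
    lines.append(
        f"  predicted risk {_pct(p['risk'])} {symbol} threshold {t['percent']} "
        f"-> {action} (under the model strategy)"
    )

    ar = report.get("acceptable_regret")
    if ar is not None:
        lines.append("Step 4 - acceptable regret")
        lines.append(
            f"  basis {ar['basis']}: tolerated {ar['tolerated']} of "
            f"{ar['denominator']} -> r = {ar['r']:.6g}, rg0 = {ar['rg0']:.6g}"
        )
        lines.append("  equivalent in regret: " + ", ".join(ar["equivalent_in_regret"]))
        if ar["model_superfluous"]:
            lines.append("  the model is equivalent in regret to a default strategy: "
                         "its use is superfluous")

    cb = report.get("comfort_bounds")
    if cb is not None:
        lines.append("Step 5 - comfort bounds")
        if cb["p_treat_none"] is not None:
            lines.append(
                f"  tolerate withholding treatment below risk {_pct(cb['p_treat_none'])}"
            )
        if cb["p_treat_all"] is not None:
            lines.append(
                f"  tolerate possibly unnecessary treatment above risk "
                f"{_pct(cb['p_treat_all'])}"
            )

    lines.append(f"Recommendation: {report['recommendation']}")
    return "\n".join(lines) + "\n"


def write_report(report: dict, path=None, format: str = "json") -> str:
    """Serialize a decision report; write to ``path`` when given."""
    if format == "json":
        text = report_to_json(report)
    elif format == "text":
        text = report_to_text(report)
    else:
        raise ValueError(f"format must be 'json' or 'text', got {format!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


def session_record(answers: dict) -> dict:
    """Question/answer transcript of an elicitation session, for audit files."""
    record = {"questions": [], "answers": answers}
    if "omission" in answers:
        record["questions"].append({"id": "omission", "text": QUESTION_OMISSION})
    if "commission" in answers:
        record["questions"].append({"id": "commission", "text": QUESTION_COMMISSION})
    if "tolerated" in answers:
        template = (
            QUESTION_TOLERATE_BENEFITS
            if answers.get("basis") == "benefits"
            else QUESTION_TOLERATE_HARMS
        )
        record["questions"].append(
            {
                "id": "tolerated",
                "text": template.format(arm=answers.get("denominator", "N")),
            }
        )
    return record


@dataclass
class RunConfig:
    """Resolved configuration of a CLI run."""

    cohort: Optional[str] = None
    grid: str = "0:0.99:0.01"
    regret_scale: str = "literal"
    out: Optional[str] = None
    plot: Optional[str] = None
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.regret_scale not in ("literal", "normalized"):
            raise ValueError(
                f"regret_scale must be 'literal' or 'normalized', got {self.regret_scale!r}"
            )
        parse_grid(self.grid)  # fail fast on malformed grids

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def grid_values(self) -> np.ndarray:
        return parse_grid(self.grid)
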