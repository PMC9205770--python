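"""Percent-change effect estimates relative to the pre-pandemic mean.

The two headline quantities of the analysis are the immediate level change
at pandemic onset and the level difference remaining in the resumption
quarter, both expressed as a percentage of the average unit-month count
over the baseline period:

    percent change = 100 * beta / baseline_mean

with the coefficient's confidence bounds divided by the same denominator
(the baseline mean is treated as fixed, so the transformation is a pure
rescaling and the p value carries over unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .timeline import StudyTimeline

EFFECT_TERMS = {"immediate": "X", "resumption": "W"}


@dataclass(frozen=True)
class EffectEstimate:
    indicator: str
    effect_kind: str            # "immediate" (shock level) or "resumption"
    percent_change: float
    ci_low_pct: float
    ci_high_pct: float
    p_value: float
    baseline_mean: float
    coefficient: float

    def __post_init__(self) -> None:
        if not (self.ci_low_pct <= self.percent_change <= self.ci_high_pct):
            raise ValueError("effect CI does not bracket the estimate")


def baseline_mean(unit_panel: pd.DataFrame,
                  timeline: StudyTimeline | None = None,
                  mode: str = "unit_month") -> float:
    """Average count over the pre-pandemic months.

    ``mode="unit_month"`` (default) averages over unit-month observations —
    the scale on which the regression coefficients live.  ``mode="national"``
    averages the national monthly totals instead, for display alongside
    country-level trend plots; on balanced panels the two differ by a factor
    of the number of units.
    """
    timeline = timeline or StudyTimeline()
    obs = unit_panel[unit_panel["count"].notna()]
    base = obs[obs["month"] <= timeline.baseline_months]
    if base.empty:
        raise ValueError("no baseline observations")
    if mode == "unit_month":
        value = float(base["count"].mean())
    elif mode == "national":
        value = float(base.groupby("month")["count"].sum().mean())
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    if value == 0:
        raise ValueError("baseline mean is zero; percent change undefined")
    return value


def percent_change(table: pd.DataFrame, which: str, baseline: float,
                   indicator: str = "service") -> EffectEstimate:
    """Express a level-change coefficient as percent of the baseline mean.

    ``which`` is ``"immediate"`` (the shock-window level term) or
    ``"resumption"`` (the remaining level change in the final quarter).
    """
    if which not in EFFECT_TERMS:
        raise ValueError(
            f"which must be one of {sorted(EFFECT_TERMS)}, got {which!r}")
    if baseline <= 0:
        raise ValueError("baseline mean must be positive")
    row = table.loc[EFFECT_TERMS[which]]
    scale = 100.0 / baseline
    return EffectEstimate(
        indicator=indicator,
        effect_kind=which,
        percent_change=float(row["estimate"] * scale),
        ci_low_pct=float(row["ci_low"] * scale),
        ci_high_pct=float(row["ci_high"] * scale),
        p_value=float(row["p"]),
        baseline_mean=float(baseline),
        coefficient=float(row["estimate"]),
    )


def effects_table(estimates: list[EffectEstimate],
                  label: str = "") -> pd.DataFrame:
    """Forest-plot-ready table: one row per indicator per effect kind."""
    return pd.DataFrame([{
        "indicator": e.indicator,
        "label": label,
        "effect_kind": e.effect_kind,
        "percent_change": e.percent_change,
        "ci_low": e.ci_low_pct,
        "ci_high": e.ci_high_pct,
        "p": e.p_value,
        "baseline_mean": e.baseline_mean,
        "coefficient": e.coefficient,
    } for e in estimates])
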