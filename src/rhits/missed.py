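"""Cumulative missed care against the seasonality-adjusted counterfactual.

For every post-baseline month the fitted model is evaluated with the
pandemic terms (shock level, shock slope, resumption level) switched off —
keeping the secular trend, seasonal pattern and unit effects — and the
observed count is subtracted.  Summing these monthly deficits over the
pandemic window estimates how many visits or services never happened.
Negative totals are meaningful: more care was delivered than the
pre-pandemic trajectory predicted.

Totals are normalized per 1,000 annual births (maternal, newborn and child
services) or per 1,000 population (chronic care), with annual births
estimated as population x crude birth rate / 1,000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .its import ItsFit
from .panel import DesignMatrix


@dataclass(frozen=True)
class DenominatorSpec:
    """Population basis for cross-country comparable rates."""

    population: float
    crude_birth_rate: float | None = None   # births per 1,000 persons/year
    basis: str = "births"                   # "births" or "population"

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError("population must be positive")
        if self.basis not in ("births", "population"):
            raise ValueError("basis must be 'births' or 'population'")
        if self.basis == "births":
            if self.crude_birth_rate is None or self.crude_birth_rate <= 0:
                raise ValueError(
                    "births basis requires a positive crude_birth_rate")

    @property
    def annual_births(self) -> float:
        if self.basis != "births":
            raise ValueError("annual_births undefined for population basis")
        return self.population * self.crude_birth_rate / 1000.0


@dataclass
class MissedCareResult:
    indicator: str
    monthly_deficits: pd.Series        # indexed by month; predicted - observed
    cumulative: float
    rate_per_1000: float | None = None
    rate_basis: str | None = None
    group_label: str | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if not self.monthly_deficits.empty:
            total = float(self.monthly_deficits.sum())
            if not np.isclose(total, self.cumulative, rtol=1e-9, atol=1e-9):
                raise ValueError("cumulative != sum of monthly deficits")


def counterfactual_series(fit: ItsFit, design: DesignMatrix) -> pd.DataFrame:
    """Predicted no-pandemic counts for observed pandemic unit-months.

    Returns one row per observed unit-month in the pandemic window with
    columns ``unit_id, month, observed, predicted``.  Predictions are not
    floored at zero; negatives (possible under a strong negative trend) are
    surfaced in a ``negative_prediction`` flag column instead of being
    clipped, which would bias deficits downward.
    """
    predicted = fit.predict(design.pandemic_terms_zeroed())
    months = design.months.to_numpy()
    pandemic = months > design.timeline.baseline_months
    out = pd.DataFrame({
        "unit_id": design.clusters.to_numpy()[pandemic],
        "month": months[pandemic],
        "observed": design.y.to_numpy()[pandemic],
        "predicted": predicted[pandemic],
    })
    out["negative_prediction"] = out["predicted"] < 0
    return out.reset_index(drop=True)


def cumulative_missed(counterfactual: pd.DataFrame,
                      window: range | list[int] | None = None,
                      indicator: str = "service") -> MissedCareResult:
    """Sum (predicted - observed) over units, month by month, then total.

    ``window`` defaults to every pandemic month present in the
    counterfactual table (the April–December analogue on the default
    timeline).  Only unit-months with an observed value enter, so observed
    and predicted sums are always like-for-like.
    """
    if counterfactual.empty:
        raise ValueError("counterfactual table is empty")
    available = set(counterfactual["month"].unique())
    if window is None:
        window = sorted(available)
    window = list(window)
    if not window:
        raise ValueError("missed-care window is empty")
    outside = sorted(set(window) - available)
    if outside:
        raise ValueError(
            f"window months {outside} have no pandemic observations")
    sub = counterfactual[counterfactual["month"].isin(window)]
    monthly = (sub.groupby("month")
               .apply(lambda g: g["predicted"].sum() - g["observed"].sum(),
                      include_groups=False)
               .rename("deficit"))
    return MissedCareResult(indicator=indicator, monthly_deficits=monthly,
                            cumulative=float(monthly.sum()))


def normalize(result: MissedCareResult,
              denom: DenominatorSpec) -> MissedCareResult:
    """Attach a per-1,000 rate on the births or population basis."""
    if denom.basis == "births":
        per_1000 = denom.annual_births / 1000.0
    else:
        per_1000 = denom.population / 1000.0
    if per_1000 == 0:
        raise ValueError("zero denominator")
    result.rate_per_1000 = result.cumulative / per_1000
    result.rate_basis = denom.basis
    return result


def group_services(results: dict[str, MissedCareResult],
                   grouping: dict[str, list[str]],
                   known_indicators: set[str] | None = None,
                   ) -> list[MissedCareResult]:
    """Sum per-indicator deficits into service groups before normalization.

    A group any of whose members is absent from ``results`` is returned
    with ``excluded=True`` and no total (the cross-country comparability
    rule: a partial sum would understate the group).  Member names that are
    not recognized indicators at all raise.
    """
    if not grouping:
        raise ValueError("grouping is empty")
    known = known_indicators if known_indicators is not None else set(results)
    grouped = []
    for label, members in grouping.items():
        if not members:
            raise ValueError(f"group {label!r} has no members")
        unknown = [m for m in members if m not in known]
        if unknown:
            raise ValueError(f"group {label!r} names unknown indicators "
                             f"{unknown}")
        if any(m not in results for m in members):
            grouped.append(MissedCareResult(
                indicator=label, monthly_deficits=pd.Series(dtype=float),
                cumulative=float("nan"), group_label=label, excluded=True))
            continue
        monthly = sum(results[m].monthly_deficits for m in members)
        grouped.append(MissedCareResult(
            indicator=label, monthly_deficits=monthly,
            cumulative=float(monthly.sum()), group_label=label))
    return grouped


def missed_care_table(results: list[MissedCareResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "indicator": r.indicator,
        "group": r.group_label or "",
        "cumulative_missed": r.cumulative,
        "rate_per_1000": r.rate_per_1000,
        "rate_basis": r.rate_basis or "",
        "excluded": r.excluded,
    } for r in results])
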