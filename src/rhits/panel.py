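"""Aggregate facility data to sub-national units and build the ITS design.

The regression observes unit-month totals Y_it.  Facility counts are summed
within unit and month over non-missing reports only; a unit-month with no
reporting facility is absent from the panel (absence is not a zero), and
such rows simply drop out of the complete-case OLS fit.

The design matrix encodes the segmented impact model

    Y_it = b0 + b1*T + b2*X_t + b3*Z + b4*W + season dummies + unit dummies

with T the month index, X_t an indicator for the six-month shock window,
Z the months elapsed since the shock began (1..6 inside the window, 0
elsewhere — including the resumption quarter, so the resumption level term
b4 alone measures the remaining gap from the continued pre-pandemic trend),
and W an indicator for the resumption quarter.  Reference levels (first
season and first unit in sorted order) are dropped for full rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .panels import UNIT_COLUMNS, validate_facility_panel
from .timeline import StudyTimeline, default_season_map

CORE_TERMS = ["intercept", "T", "X", "Z", "W"]


def aggregate_to_units(panel: pd.DataFrame) -> pd.DataFrame:
    """Sum non-missing facility counts to unit-month totals.

    Raises if any record lacks a unit id; records whose count is missing
    contribute neither to the total nor to ``n_facilities``.
    """
    validate_facility_panel(panel)
    if panel["unit_id"].isna().any() or (panel["unit_id"] == "").any():
        bad = panel.loc[panel["unit_id"].isna()
                        | (panel["unit_id"] == ""), "facility_id"].unique()
        raise ValueError(f"facilities with unknown unit_id: {list(bad)[:5]}")
    obs = panel[panel["count"].notna()]
    unit = (obs.groupby(["unit_id", "indicator", "month"], as_index=False)
            .agg(count=("count", "sum"),
                 n_facilities=("facility_id", "nunique")))
    return unit[UNIT_COLUMNS].sort_values(
        ["indicator", "unit_id", "month"]).reset_index(drop=True)


@dataclass
class DesignMatrix:
    """Full-rank ITS design aligned with a response vector.

    Attributes
    ----------
    X : DataFrame
        One row per unit-month observation; columns ``intercept, T, X, Z, W``
        then season dummies (``season_<name>``) and unit dummies
        (``unit_<id>``), reference levels dropped.
    y : Series
        Observed unit-month counts, row-aligned with ``X``.
    clusters : Series
        Unit id per row; the clustering variable for robust inference.
    months : Series
        Month index per row (used for counterfactual windows).
    timeline : StudyTimeline
    """

    X: pd.DataFrame
    y: pd.Series
    clusters: pd.Series
    months: pd.Series
    timeline: StudyTimeline

    @property
    def n_units(self) -> int:
        return self.clusters.nunique()

    def pandemic_terms_zeroed(self) -> pd.DataFrame:
        """Copy of X with the shock/resumption columns forced to zero.

        This is the counterfactual design: trend, seasonality and unit
        effects retained, pandemic terms switched off.
        """
        Xc = self.X.copy()
        Xc[["X", "Z", "W"]] = 0.0
        return Xc

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out.insert(0, "unit_id", self.clusters.values)
        out.insert(1, "month", self.months.values)
        out["y"] = self.y.values
        return out


def build_design(unit_panel: pd.DataFrame,
                 timeline: StudyTimeline | None = None,
                 season_map: Mapping[int, str] | None = None,
                 ) -> DesignMatrix:
    """Construct the segmented-regression design from a unit panel.

    Requires at least two units (inference uses G-2 degrees of freedom) and
    a season map covering every study month.  Raises with the offending
    columns if the resulting matrix is rank deficient.
    """
    timeline = timeline or StudyTimeline()
    season_map = season_map or default_season_map(timeline.total_months)
    missing_months = [t for t in range(1, timeline.total_months + 1)
                      if t not in season_map]
    if missing_months:
        raise ValueError(f"season_map lacks months {missing_months}")
    obs = unit_panel[unit_panel["count"].notna()].reset_index(drop=True)
    if obs.empty:
        raise ValueError("unit panel has no observations")
    if obs["month"].max() > timeline.total_months:
        raise ValueError("panel months exceed timeline.total_months")
    n_units = obs["unit_id"].nunique()
    if n_units < 2:
        raise ValueError(
            f"need at least 2 sub-national units for G-2 df inference, "
            f"got G={n_units}")

    months = obs["month"].astype(int)
    X = pd.DataFrame({
        "intercept": 1.0,
        "T": months.astype(float),
        "X": [float(timeline.shock_indicator(t)) for t in months],
        "Z": [float(timeline.months_since_shock(t)) for t in months],
        "W": [float(timeline.resumption_indicator(t)) for t in months],
    })

    seasons = pd.Categorical([season_map[t] for t in months])
    season_levels = sorted(seasons.categories)
    for level in season_levels[1:]:  # first level is the reference
        X[f"season_{level}"] = (seasons == level).astype(float)
    unit_levels = sorted(obs["unit_id"].unique())
    for level in unit_levels[1:]:
        X[f"unit_{level}"] = (obs["unit_id"] == level).astype(float)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        dependent = _collinear_columns(X)
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"offending columns: {dependent}")

    return DesignMatrix(X=X, y=obs["count"].astype(float),
                        clusters=obs["unit_id"], months=months,
                        timeline=timeline)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (greedy scan)."""
    arr = X.to_numpy()
    offenders = []
    base_rank = np.linalg.matrix_rank(arr)
    for j, col in enumerate(X.columns):
        reduced = np.delete(arr, j, axis=1)
        if np.linalg.matrix_rank(reduced) == base_rank:
            offenders.append(col)
    return offenders
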