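"""Synthetic RHIS facility-month count panels with known ground truth.

The generator runs the segmented-regression impact model *forward*: each
facility-month mean is the linear predictor

    mu = beta0 + beta1*T + beta2*X_t + beta3*Z + beta4*W + season + unit

with the shock indicator ``X_t``, months-since-shock ``Z`` and resumption
indicator ``W`` coded exactly as the analysis design matrix codes them, so
the estimand of the downstream OLS fit is the generating parameter vector
itself.  Counts are drawn from a negative-binomial distribution
parameterized by mean and dispersion (variance ``mu * (1 + dispersion*mu)``),
approaching Poisson as dispersion shrinks; ``dispersion = 0`` switches noise
off entirely and emits the rounded linear predictor, which is what exact
recovery tests rely on.

A separate corruption step emulates the reporting-quality threats the
cleaning module exists to correct: missing monthly reports (worse during
the pandemic) and sporadic extreme high outliers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panels import FACILITY_COLUMNS, validate_facility_panel, write_facility_panel
from .timeline import StudyTimeline, default_season_map

SEASONS = ("winter", "spring", "summer", "fall")


@dataclass
class GeneratingModel:
    """Ground-truth parameters of a synthetic facility-month panel.

    Coefficients are on the facility-month scale.  After aggregation of
    ``facilities_per_unit`` identical-mean facilities to the unit level, the
    unit-level coefficients the regression estimates are these values
    multiplied by ``facilities_per_unit``.
    """

    n_units: int = 10
    facilities_per_unit: int = 20
    timeline: StudyTimeline = field(default_factory=StudyTimeline)
    beta0: float = 100.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    beta4: float = 0.0
    season_effects: Mapping[str, float] | None = None
    unit_effects: Sequence[float] | None = None
    dispersion: float = 0.0
    seed: int = 0
    indicator: str = "service"
    season_map: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.facilities_per_unit < 1:
            raise ValueError("n_units and facilities_per_unit must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.season_effects is None:
            self.season_effects = {s: 0.0 for s in SEASONS}
        if set(self.season_effects) != set(SEASONS):
            raise ValueError(
                f"season_effects must have exactly the keys {SEASONS}")
        if self.unit_effects is None:
            self.unit_effects = [0.0] * self.n_units
        if len(self.unit_effects) != self.n_units:
            raise ValueError("unit_effects length must equal n_units")
        if self.season_map is None:
            self.season_map = default_season_map(self.timeline.total_months)
        season1 = self.season_map[1]
        for u in range(self.n_units):
            mu1 = (self.beta0 + self.beta1 * 1
                   + self.season_effects[season1] + self.unit_effects[u])
            if mu1 <= 0:
                raise ValueError(
                    f"expected count at month 1 is {mu1} <= 0 for unit index "
                    f"{u}; adjust beta0 / unit_effects / season_effects")

    def unit_ids(self) -> list[str]:
        return [f"U{u:02d}" for u in range(self.n_units)]

    def linear_predictor(self, unit_index: int, month: int) -> float:
        """Facility-month mean mu for one cell of the design."""
        tl = self.timeline
        season = self.season_map[month]
        return (self.beta0
                + self.beta1 * month
                + self.beta2 * tl.shock_indicator(month)
                + self.beta3 * tl.months_since_shock(month)
                + self.beta4 * tl.resumption_indicator(month)
                + self.season_effects[season]
                + self.unit_effects[unit_index])

    def unit_level_truth(self) -> dict[str, float]:
        """Coefficients on the aggregated unit-month scale."""
        f = self.facilities_per_unit
        return {"beta1": self.beta1 * f, "beta2": self.beta2 * f,
                "beta3": self.beta3 * f, "beta4": self.beta4 * f}

    def to_dict(self) -> dict:
        return {
            "n_units": self.n_units,
            "facilities_per_unit": self.facilities_per_unit,
            "timeline": {"total_months": self.timeline.total_months,
                         "baseline_months": self.timeline.baseline_months,
                         "shock_months": self.timeline.shock_months},
            "beta0": self.beta0, "beta1": self.beta1, "beta2": self.beta2,
            "beta3": self.beta3, "beta4": self.beta4,
            "season_effects": dict(self.season_effects),
            "unit_effects": list(self.unit_effects),
            "dispersion": self.dispersion, "seed": self.seed,
            "indicator": self.indicator,
        }


@dataclass
class CorruptionSpec:
    """Reporting-quality degradation applied to a clean synthetic panel."""

    dropout_rate: float = 0.0
    pandemic_dropout_multiplier: float = 1.0
    outlier_rate: float = 0.0
    outlier_scale: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "outlier_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.pandemic_dropout_multiplier < 1.0:
            raise ValueError("pandemic_dropout_multiplier must be >= 1")
        if self.outlier_scale <= 0:
            raise ValueError("outlier_scale must be positive")


def simulate_panel(model: GeneratingModel) -> pd.DataFrame:
    """Generate one facility-month record per facility x month.

    Counts are NB(mean=mu, var=mu*(1+dispersion*mu)) draws, or round(mu)
    when dispersion is 0.  A negative linear predictor at any cell is a
    configuration error (silently clipping it would shift the estimand);
    only the final noisy draw is floored at zero.
    """
    tl = model.timeline
    rng = np.random.default_rng(model.seed)
    months = np.arange(1, tl.total_months + 1)

    mu_by_unit = np.empty((model.n_units, tl.total_months))
    for u in range(model.n_units):
        for t in months:
            mu = model.linear_predictor(u, int(t))
            if mu < 0:
                raise ValueError(
                    f"negative expected count mu={mu:.4g} at unit index {u}, "
                    f"month {t}; the generating model is misconfigured")
            mu_by_unit[u, t - 1] = mu

    records = []
    for u, unit_id in enumerate(model.unit_ids()):
        for f in range(model.facilities_per_unit):
            facility_id = f"{unit_id}-F{f:03d}"
            mu = mu_by_unit[u]
            if model.dispersion == 0:
                counts = np.round(mu)
            else:
                # NB with size n = 1/dispersion, p = n / (n + mu): mean mu,
                # variance mu * (1 + dispersion * mu).
                n = 1.0 / model.dispersion
                p = n / (n + mu)
                counts = rng.negative_binomial(n, p).astype(float)
            counts = np.maximum(counts, 0.0)
            records.append(pd.DataFrame({
                "facility_id": facility_id,
                "unit_id": unit_id,
                "indicator": model.indicator,
                "month": months,
                "count": counts,
            }))
    panel = pd.concat(records, ignore_index=True)[FACILITY_COLUMNS]
    return validate_facility_panel(panel)


def corrupt_panel(panel: pd.DataFrame, spec: CorruptionSpec,
                  timeline: StudyTimeline | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject missing reports and extreme high outliers.

    Returns ``(corrupted, log)`` where the log records every altered cell
    with its original value and the action taken.  Dropout probability is
    multiplied by ``pandemic_dropout_multiplier`` (capped at 1) for months
    after the baseline period.  Outliers replace a reported value with
    ``outlier_scale`` times that facility's mean count for the indicator.
    """
    if panel.empty:
        raise ValueError("cannot corrupt an empty panel")
    validate_facility_panel(panel)
    timeline = timeline or StudyTimeline()
    rng = np.random.default_rng(spec.seed)
    out = panel.copy(deep=True).reset_index(drop=True)

    p_drop = np.full(len(out), spec.dropout_rate)
    pandemic = out["month"] > timeline.baseline_months
    p_drop[pandemic.to_numpy()] = min(
        1.0, spec.dropout_rate * spec.pandemic_dropout_multiplier)

    reported = out["count"].notna().to_numpy()
    drop = (rng.random(len(out)) < p_drop) & reported
    facility_means = (out.groupby(["facility_id", "indicator"])["count"]
                      .transform("mean"))
    make_outlier = ((rng.random(len(out)) < spec.outlier_rate)
                    & reported & ~drop & facility_means.notna().to_numpy())

    log_parts = []
    if drop.any():
        log_parts.append(pd.DataFrame({
            "facility_id": out.loc[drop, "facility_id"],
            "unit_id": out.loc[drop, "unit_id"],
            "indicator": out.loc[drop, "indicator"],
            "month": out.loc[drop, "month"],
            "original": out.loc[drop, "count"],
            "action": "dropped",
            "new_value": np.nan,
        }))
        out.loc[drop, "count"] = np.nan
    if make_outlier.any():
        new_vals = np.round(spec.outlier_scale * facility_means[make_outlier])
        log_parts.append(pd.DataFrame({
            "facility_id": out.loc[make_outlier, "facility_id"],
            "unit_id": out.loc[make_outlier, "unit_id"],
            "indicator": out.loc[make_outlier, "indicator"],
            "month": out.loc[make_outlier, "month"],
            "original": out.loc[make_outlier, "count"],
            "action": "outlier",
            "new_value": new_vals,
        }))
        out.loc[make_outlier, "count"] = new_vals

    log_columns = ["facility_id", "unit_id", "indicator", "month",
                   "original", "action", "new_value"]
    log = (pd.concat(log_parts, ignore_index=True)[log_columns]
           if log_parts else pd.DataFrame(columns=log_columns))
    return out, log.sort_values(["facility_id", "month"]).reset_index(drop=True)


def write_panel_with_sidecar(panel: pd.DataFrame, model: GeneratingModel,
                             csv_path: str | Path,
                             spec: CorruptionSpec | None = None) -> None:
    """CSV panel plus a JSON sidecar recording the full generating recipe."""
    csv_path = Path(csv_path)
    write_facility_panel(panel, csv_path)
    sidecar = {"generating_model": model.to_dict()}
    if spec is not None:
        sidecar["corruption"] = {
            "dropout_rate": spec.dropout_rate,
            "pandemic_dropout_multiplier": spec.pandemic_dropout_multiplier,
            "outlier_rate": spec.outlier_rate,
            "outlier_scale": spec.outlier_scale,
            "seed": spec.seed,
        }
    csv_path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
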