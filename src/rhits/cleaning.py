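"""Two-step facility-level data cleaning and the raw-vs-cleaned audit.

Step 1 guards against pandemic-induced reporting decay: for each indicator,
only facilities that reported at least ``min_months_reported`` of the study
months are retained, so a facility that silently stopped reporting cannot
masquerade as a collapse in service volume.  A reported zero counts as a
report; only an absent/NaN month is non-reporting.

Step 2 removes implausibly high values: any count exceeding the facility's
own mean by more than ``outlier_z`` standard deviations is set to missing.
Low outliers are deliberately retained — service use may genuinely have
fallen to very low levels during the pandemic, and removing low values
would bias disruption estimates toward zero.

The audit compares per-indicator totals before and after cleaning so that
an over-aggressive configuration is visible as a low retention ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .panels import validate_facility_panel


@dataclass(frozen=True)
class CleaningConfig:
    min_months_reported: int = 15
    total_months: int = 24
    outlier_z: float = 3.5
    remove_low_outliers: bool = False
    iterate_outliers: bool = False  # recompute mean/SD after each removal pass

    def __post_init__(self) -> None:
        if not 1 <= self.min_months_reported <= self.total_months:
            raise ValueError(
                "min_months_reported must be in [1, total_months]")
        if self.outlier_z <= 0:
            raise ValueError("outlier_z must be positive")


@dataclass
class CleaningReport:
    """Accumulated record of what cleaning did, serializable to CSV/JSON."""

    exclusions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["indicator", "facility_id", "months_reported", "threshold"]))
    retained_counts: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["indicator", "facilities_retained", "facilities_excluded"]))
    outliers: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["indicator", "facility_id", "month", "original",
                 "facility_mean", "facility_sd", "z"]))
    retention: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["indicator", "raw_sum", "cleaned_sum", "ratio",
                 "undefined_ratio"]))
    monthly_reporting: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["indicator", "month", "facilities_raw",
                     "facilities_cleaned"]))

    def write(self, directory: str | Path, prefix: str = "cleaning") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.exclusions.to_csv(directory / f"{prefix}_exclusions.csv",
                               index=False)
        self.outliers.to_csv(directory / f"{prefix}_outliers.csv",
                             index=False)
        self.retention.to_csv(directory / f"{prefix}_retention.csv",
                              index=False)
        self.monthly_reporting.to_csv(
            directory / f"{prefix}_monthly_reporting.csv", index=False)
        summary = {
            "facilities_excluded": int(len(self.exclusions)),
            "outliers_flagged": int(len(self.outliers)),
            "retention_ratio_by_indicator": {
                str(r.indicator): (None if r.undefined_ratio else float(r.ratio))
                for r in self.retention.itertuples()},
        }
        (directory / f"{prefix}_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")


def _months_reported(panel: pd.DataFrame) -> pd.DataFrame:
    obs = panel[panel["count"].notna()]
    return (obs.groupby(["indicator", "facility_id"])["month"]
            .nunique().rename("months_reported").reset_index())


def filter_reporting_completeness(
        panel: pd.DataFrame, config: CleaningConfig,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop, per indicator, facilities reporting fewer than the threshold.

    The threshold is inclusive: a facility reporting exactly
    ``min_months_reported`` months is retained.
    """
    validate_facility_panel(panel)
    if len(panel) and panel["month"].max() > config.total_months:
        raise ValueError("panel contains months beyond config.total_months")

    counts = _months_reported(panel)
    all_pairs = panel[["indicator", "facility_id"]].drop_duplicates()
    counts = all_pairs.merge(counts, how="left",
                             on=["indicator", "facility_id"])
    counts["months_reported"] = (counts["months_reported"]
                                 .fillna(0).astype(int))
    keep = counts["months_reported"] >= config.min_months_reported

    excluded = counts[~keep].copy()
    excluded["threshold"] = config.min_months_reported
    report = CleaningReport()
    report.exclusions = excluded[["indicator", "facility_id",
                                  "months_reported", "threshold"]]
    report.retained_counts = (
        counts.assign(retained=keep)
        .groupby("indicator")["retained"]
        .agg(facilities_retained="sum",
             facilities_excluded=lambda s: (~s).sum())
        .reset_index())

    kept_pairs = counts[keep][["indicator", "facility_id"]]
    cleaned = panel.merge(kept_pairs, on=["indicator", "facility_id"],
                          how="inner").reset_index(drop=True)
    return cleaned, report


def _flag_once(panel: pd.DataFrame, config: CleaningConfig) -> pd.DataFrame:
    """One pass of the z-rule; returns the outlier log for this pass."""
    grp = panel.groupby(["indicator", "facility_id"])["count"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # sample SD (ddof=1); NaN for n=1, no flag then
    with np.errstate(invalid="ignore"):
        high = panel["count"] > mean + config.outlier_z * sd
        low = panel["count"] < mean - config.outlier_z * sd
    flag = high.fillna(False)
    if config.remove_low_outliers:
        flag |= low.fillna(False)
    flagged = panel[flag]
    z = (flagged["count"] - mean[flag]) / sd[flag]
    return pd.DataFrame({
        "indicator": flagged["indicator"],
        "facility_id": flagged["facility_id"],
        "month": flagged["month"],
        "original": flagged["count"],
        "facility_mean": mean[flag],
        "facility_sd": sd[flag],
        "z": z,
    })


def flag_high_outliers(panel: pd.DataFrame, config: CleaningConfig,
                       ) -> tuple[pd.DataFrame, CleaningReport]:
    """Set counts more than ``outlier_z`` SDs above the facility mean to missing.

    Mean and SD are computed over the facility's non-missing months,
    including the candidate point.  A constant series has SD 0 and flags
    nothing.  By default the rule is applied in a single pass; with
    ``iterate_outliers`` the mean/SD are recomputed after each pass until
    no new point is flagged.
    """
    validate_facility_panel(panel)
    cleaned = panel.copy(deep=True).reset_index(drop=True)
    logs = []
    while True:
        log = _flag_once(cleaned, config)
        if not log.empty:
            cleaned.loc[log.index, "count"] = np.nan
            logs.append(log)
        if log.empty or not config.iterate_outliers:
            break
    report = CleaningReport()
    if logs:
        report.outliers = pd.concat(logs).reset_index(drop=True)
    return cleaned, report


def clean_panel(panel: pd.DataFrame, config: CleaningConfig,
                ) -> tuple[pd.DataFrame, CleaningReport]:
    """Full two-step procedure: completeness filter, then outlier flagging."""
    step1, rep1 = filter_reporting_completeness(panel, config)
    step2, rep2 = flag_high_outliers(step1, config)
    report = audit_retention(panel, step2)
    report.exclusions = rep1.exclusions
    report.retained_counts = rep1.retained_counts
    report.outliers = rep2.outliers
    return step2, report


def audit_retention(raw: pd.DataFrame, cleaned: pd.DataFrame,
                    ) -> CleaningReport:
    """Per-indicator cleaned/raw sum ratios and monthly reporting counts."""
    raw_sum = raw.groupby("indicator")["count"].sum(min_count=1)
    cleaned_sum = cleaned.groupby("indicator")["count"].sum(min_count=1)
    retention = pd.DataFrame({
        "raw_sum": raw_sum,
        "cleaned_sum": cleaned_sum.reindex(raw_sum.index).fillna(0.0),
    }).reset_index()
    retention["undefined_ratio"] = (retention["raw_sum"].isna()
                                    | (retention["raw_sum"] == 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        retention["ratio"] = np.where(
            retention["undefined_ratio"], np.nan,
            retention["cleaned_sum"] / retention["raw_sum"])

    def monthly(p: pd.DataFrame, name: str) -> pd.DataFrame:
        obs = p[p["count"].notna()]
        return (obs.groupby(["indicator", "month"])["facility_id"]
                .nunique().rename(name).reset_index())

    monthly_rep = monthly(raw, "facilities_raw").merge(
        monthly(cleaned, "facilities_cleaned"),
        on=["indicator", "month"], how="left")
    monthly_rep["facilities_cleaned"] = (monthly_rep["facilities_cleaned"]
                                         .fillna(0).astype(int))

    report = CleaningReport()
    report.retention = retention[["indicator", "raw_sum", "cleaned_sum",
                                  "ratio", "undefined_ratio"]]
    report.monthly_reporting = monthly_rep
    return report


def threshold_sweep(panel: pd.DataFrame, thresholds: list[int] | None = None,
                    config: CleaningConfig | None = None) -> pd.DataFrame:
    """Rerun the two-step cleaning at several completeness thresholds.

    Mirrors the reporting-completeness sensitivity analysis: default sweep
    is {12, 15, 18, total_months}.  Returns one row per indicator per
    threshold with the retention ratio and retained-facility count.
    """
    config = config or CleaningConfig()
    if thresholds is None:
        thresholds = [12, 15, 18, config.total_months]
    if not thresholds:
        raise ValueError("thresholds list is empty")
    rows = []
    for thr in sorted(set(thresholds)):
        cfg = CleaningConfig(min_months_reported=thr,
                             total_months=config.total_months,
                             outlier_z=config.outlier_z,
                             remove_low_outliers=config.remove_low_outliers)
        _, report = clean_panel(panel, cfg)
        merged = report.retention.merge(report.retained_counts,
                                        on="indicator", how="left")
        merged.insert(0, "threshold", thr)
        rows.append(merged[["threshold", "indicator", "ratio",
                            "facilities_retained", "facilities_excluded"]])
    return pd.concat(rows, ignore_index=True)
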