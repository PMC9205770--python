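import json

import numpy as np
import pandas as pd
import pytest

from rhits import (CleaningConfig, CorruptionSpec, GeneratingModel,
                   audit_retention, clean_panel, corrupt_panel,
                   filter_reporting_completeness, flag_high_outliers,
                   simulate_panel, threshold_sweep)


def panel_with_reporting(months_by_facility: dict[str, int],
                         count: float = 100.0) -> pd.DataFrame:
    """One-unit panel where each facility reports its first k months."""
    rows = []
    for fac, k in months_by_facility.items():
        for month in range(1, 25):
            rows.append({"facility_id": fac, "unit_id": "U0",
                         "indicator": "svc", "month": month,
                         "count": count if month <= k else np.nan})
    return pd.DataFrame(rows)


class TestCompletenessFilter:
    @pytest.mark.parametrize("months_reported, retained", [
        (24, True),   # full reporter
        (15, True),   # boundary: 'at least 15 of 24' is inclusive
        (14, False),  # one short of the threshold
        (0, False),
    ])
    def test_15_of_24_threshold_boundary(self, months_reported, retained):
        panel = panel_with_reporting({"F1": months_reported, "F2": 24})
        cleaned, report = filter_reporting_completeness(
            panel, CleaningConfig())
        assert ("F1" in set(cleaned["facility_id"])) is retained
        excluded = set(report.exclusions["facility_id"])
        assert ("F1" in excluded) is not retained

    def test_reported_zero_counts_as_reporting(self):
        panel = panel_with_reporting({"F1": 24})
        panel.loc[panel["month"] <= 20, "count"] = 0.0  # zeros, not gaps
        cleaned, _ = filter_reporting_completeness(panel, CleaningConfig())
        assert len(cleaned) == 24

    def test_filter_is_per_indicator(self):
        good = panel_with_reporting({"F1": 24})
        bad = panel_with_reporting({"F1": 10})
        bad["indicator"] = "other"
        cleaned, report = filter_reporting_completeness(
            pd.concat([good, bad], ignore_index=True), CleaningConfig())
        assert set(cleaned["indicator"]) == {"svc"}
        assert report.retained_counts.set_index("indicator").loc[
            "other", "facilities_excluded"] == 1

    def test_raising_threshold_never_retains_more(self):
        rng = np.random.default_rng(0)
        panel = panel_with_reporting(
            {f"F{i}": int(rng.integers(6, 25)) for i in range(30)})
        sizes = []
        for thr in (6, 12, 15, 18, 24):
            cleaned, _ = filter_reporting_completeness(
                panel, CleaningConfig(min_months_reported=thr))
            sizes.append(cleaned["facility_id"].nunique())
        assert sizes == sorted(sizes, reverse=True)


def series_with_value(value: float, n: int = 24,
                      base: list[float] | None = None) -> pd.DataFrame:
    """23 varied baseline values plus one candidate value at month 24."""
    if base is None:
        base = [90 + (i % 7) * 3 for i in range(n - 1)]
    counts = base + [value]
    return pd.DataFrame({"facility_id": "F1", "unit_id": "U0",
                         "indicator": "svc",
                         "month": range(1, len(counts) + 1),
                         "count": counts})


class TestOutlierRule:
    def test_constant_series_flags_nothing(self):
        panel = series_with_value(100.0, base=[100.0] * 23)
        cleaned, report = flag_high_outliers(panel, CleaningConfig())
        assert report.outliers.empty
        assert cleaned["count"].notna().all()

    def test_value_4_sd_above_mean_is_removed(self):
        base = [90 + (i % 7) * 3 for i in range(23)]
        # place the candidate exactly 4 SD above the mean of the full series;
        # solve for v: v = mean(base + [v]) + 4 * sd(base + [v]) numerically
        v = 200.0
        for _ in range(200):
            s = pd.Series(base + [v])
            v_new = s.mean() + 4 * s.std()
            if abs(v_new - v) < 1e-10:
                break
            v = v_new
        panel = series_with_value(v, base=base)
        s = pd.Series(base + [v])
        assert (v - s.mean()) / s.std() > 3.5  # sanity on the construction
        cleaned, report = flag_high_outliers(panel, CleaningConfig())
        assert len(report.outliers) == 1
        assert report.outliers.iloc[0]["month"] == 24
        assert cleaned.loc[cleaned["month"] == 24, "count"].isna().all()

    def test_low_outlier_retained_by_default_removed_on_request(self):
        base = [100.0 + (i % 5) for i in range(23)]
        panel = series_with_value(0.0, base=base)  # collapse-to-zero month
        s = pd.Series(base + [0.0])
        assert (s.mean() - 0.0) / s.std() > 3.5
        cleaned, report = flag_high_outliers(panel, CleaningConfig())
        assert report.outliers.empty  # legitimate pandemic-era low value
        cleaned2, report2 = flag_high_outliers(
            panel, CleaningConfig(remove_low_outliers=True))
        assert len(report2.outliers) == 1
        assert cleaned2.loc[cleaned2["month"] == 24, "count"].isna().all()

    def test_untouched_cells_keep_exact_values(self):
        panel = series_with_value(1000.0)
        cleaned, report = flag_high_outliers(panel, CleaningConfig())
        kept = cleaned[cleaned["count"].notna()]
        original = panel.set_index("month")["count"]
        assert (kept["count"] == original[kept["month"]].values).all()

    def test_single_pass_reports_no_cascade_on_rerun_stats(self):
        # After removing the flagged point the rule may fire again if the
        # statistics are recomputed; default single-pass leaves that to the
        # iterated mode, which must terminate and flag a superset.
        rng = np.random.default_rng(4)
        base = list(rng.normal(100, 5, 22))
        panel = series_with_value(400.0, base=base + [180.0])
        once, rep_once = flag_high_outliers(panel, CleaningConfig())
        again, rep_again = flag_high_outliers(once, CleaningConfig())
        iterated, rep_iter = flag_high_outliers(
            panel, CleaningConfig(iterate_outliers=True))
        assert len(rep_iter.outliers) >= len(rep_once.outliers)
        combined = len(rep_once.outliers) + len(rep_again.outliers)
        assert len(rep_iter.outliers) == combined

    def test_injected_outliers_recovered_with_low_false_flag_rate(self):
        # One 5x-mean injection in each of 300 facilities on an
        # overdispersed panel.  A single injection among 24 points sits at
        # z ~ 4.6 and must be caught (>=95% bound leaves room for sampling
        # error); false flags on the ~19k clean NB cells must stay <1%.
        # (Two extreme outliers in one series mask each other — the max
        # attainable z with k outliers among n points is sqrt((n-1)/k),
        # i.e. ~3.4 < 3.5 for k=2 — so the detection guarantee is stated
        # for sparse, one-per-facility contamination.)
        model = GeneratingModel(n_units=8, facilities_per_unit=100,
                                beta0=200.0, dispersion=0.02, seed=21)
        panel = simulate_panel(model).reset_index(drop=True)
        rng = np.random.default_rng(22)
        facilities = rng.choice(panel["facility_id"].unique(), size=300,
                                replace=False)
        corrupted = panel.copy()
        injected = set()
        means = panel.groupby("facility_id")["count"].mean()
        for fac in facilities:
            month = int(rng.integers(1, 25))
            idx = corrupted.index[(corrupted["facility_id"] == fac)
                                  & (corrupted["month"] == month)][0]
            corrupted.loc[idx, "count"] = round(5.0 * means[fac])
            injected.add((fac, month))
        cleaned, report = flag_high_outliers(corrupted, CleaningConfig())
        flagged = set(zip(report.outliers["facility_id"],
                          report.outliers["month"]))
        recall = len(injected & flagged) / len(injected)
        false_flags = len(flagged - injected)
        clean_cells = len(panel) - len(injected)
        assert recall >= 0.95
        assert false_flags / clean_cells < 0.01


class TestAuditAndSweep:
    def test_identity_cleaning_gives_unit_ratios(self):
        panel = panel_with_reporting({"F1": 24, "F2": 24})
        report = audit_retention(panel, panel)
        assert (report.retention["ratio"] == 1.0).all()

    def test_dropping_10pct_contributor_gives_ratio_0p9(self):
        big = panel_with_reporting({"F1": 24}, count=90.0)
        small = panel_with_reporting({"F2": 24}, count=10.0)
        raw = pd.concat([big, small], ignore_index=True)
        report = audit_retention(raw, big)
        assert report.retention.iloc[0]["ratio"] == pytest.approx(0.9)

    def test_zero_raw_sum_flagged_undefined(self):
        raw = panel_with_reporting({"F1": 24}, count=0.0)
        report = audit_retention(raw, raw)
        assert bool(report.retention.iloc[0]["undefined_ratio"])

    def test_monthly_reporting_counts_track_facilities(self):
        panel = panel_with_reporting({"F1": 24, "F2": 12})
        cleaned, _ = filter_reporting_completeness(panel, CleaningConfig())
        report = audit_retention(panel, cleaned)
        m = report.monthly_reporting.set_index("month")
        assert m.loc[1, "facilities_raw"] == 2
        assert m.loc[1, "facilities_cleaned"] == 1   # F2 excluded
        assert m.loc[20, "facilities_raw"] == 1

    def test_threshold_sweep_retention_monotone_non_increasing(self):
        rng = np.random.default_rng(1)
        panel = panel_with_reporting(
            {f"F{i}": int(rng.integers(8, 25)) for i in range(40)})
        sweep = threshold_sweep(panel, [12, 15, 18, 24])
        ratios = sweep.sort_values("threshold")["ratio"].to_numpy()
        assert (np.diff(ratios) <= 1e-12).all()

    def test_sweep_rejects_empty_threshold_list(self):
        with pytest.raises(ValueError):
            threshold_sweep(panel_with_reporting({"F1": 24}), [])


def test_full_clean_report_serializes_csv_and_json(tmp_path):
    panel = panel_with_reporting({"F1": 24, "F2": 10})
    panel.loc[(panel["facility_id"] == "F1") & (panel["month"] == 5),
              "count"] = 10_000.0
    cleaned, report = clean_panel(panel, CleaningConfig())
    report.write(tmp_path)
    assert (tmp_path / "cleaning_exclusions.csv").exists()
    outliers = pd.read_csv(tmp_path / "cleaning_outliers.csv")
    assert list(outliers["month"]) == [5]
    summary = json.loads((tmp_path / "cleaning_summary.json").read_text())
    assert summary["facilities_excluded"] == 1
    assert summary["outliers_flagged"] == 1
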