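"""End-to-end orchestration: cleaning -> aggregation -> ITS -> effects -> missed care.

A single :class:`RunConfig` describes one analysis run — either a CSV of
real facility-month counts or a synthetic generating recipe — together
with the cleaning rules, study timeline, effect settings, service
groupings and denominators.  ``run_pipeline`` executes every stage for
every indicator, logs record counts in and out of each stage (cleaning
attrition is the classic silent-failure mode of RHIS analysis), and writes
plain-CSV artifacts plus a JSON manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cleaning import CleaningConfig, clean_panel, threshold_sweep
from .effects import baseline_mean, effects_table, percent_change
from .its import fit_and_infer
from .missed import (DenominatorSpec, counterfactual_series, cumulative_missed,
                     group_services, missed_care_table, normalize)
from .panel import aggregate_to_units, build_design
from .panels import read_facility_panel, write_facility_panel, write_unit_panel
from .synthetic import CorruptionSpec, GeneratingModel, corrupt_panel, simulate_panel
from .timeline import StudyTimeline, default_season_map

logger = logging.getLogger("rhits")


@dataclass
class RunConfig:
    """Everything one reproducible analysis run needs."""

    input_csv: str | None = None
    synthetic_models: list[GeneratingModel] | None = None
    corruption: CorruptionSpec | None = None
    cleaning: CleaningConfig = dc_field(default_factory=CleaningConfig)
    timeline: StudyTimeline = dc_field(default_factory=StudyTimeline)
    season_map: Mapping[int, str] | None = None
    groupings: dict[str, list[str]] = dc_field(default_factory=dict)
    denominators: dict[str, DenominatorSpec] = dc_field(default_factory=dict)
    unit_subset: list[str] | None = None
    alpha: float = 0.05
    baseline_mode: str = "unit_month"
    small_sample: str = "stata"
    skip_cleaning: bool = False
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic_models is None):
            raise ValueError(
                "exactly one of input_csv / synthetic_models is required")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_manifest(self) -> dict:
        return {
            "version": __version__,
            "seed": self.seed,
            "input_csv": self.input_csv,
            "synthetic_models": ([m.to_dict() for m in self.synthetic_models]
                                 if self.synthetic_models else None),
            "corruption": (vars(self.corruption).copy()
                           if self.corruption else None),
            "cleaning": {"min_months_reported": self.cleaning.min_months_reported,
                         "total_months": self.cleaning.total_months,
                         "outlier_z": self.cleaning.outlier_z,
                         "remove_low_outliers": self.cleaning.remove_low_outliers},
            "timeline": {"total_months": self.timeline.total_months,
                         "baseline_months": self.timeline.baseline_months,
                         "shock_months": self.timeline.shock_months},
            "groupings": self.groupings,
            "denominators": {k: vars(v).copy()
                             for k, v in self.denominators.items()},
            "unit_subset": self.unit_subset,
            "alpha": self.alpha,
            "baseline_mode": self.baseline_mode,
            "small_sample": self.small_sample,
            "skip_cleaning": self.skip_cleaning,
        }


@dataclass
class RunArtifacts:
    """In-memory results of a pipeline run (files are written alongside)."""

    cleaned_panel: pd.DataFrame
    cleaning_report: object
    unit_panel: pd.DataFrame
    coefficient_tables: dict[str, pd.DataFrame]
    effects: pd.DataFrame
    missed_care: pd.DataFrame
    trend_data: pd.DataFrame
    manifest: dict


def _stage(name: str, indicator: str | None = None):
    label = f"{name}" + (f" [{indicator}]" if indicator else "")

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{label}' failed: {exc}"
                                   ) from exc
            return False

    return _Ctx()


def _load_input(config: RunConfig) -> pd.DataFrame:
    if config.input_csv is not None:
        return read_facility_panel(config.input_csv)
    # re-seed the generating models deterministically from the run seed
    children = np.random.SeedSequence(config.seed).spawn(
        len(config.synthetic_models) + 1)
    panels = []
    for model, ss in zip(config.synthetic_models, children):
        model.seed = int(ss.generate_state(1)[0] % (2 ** 31))
        panels.append(simulate_panel(model))
    panel = pd.concat(panels, ignore_index=True)
    if config.corruption is not None:
        spec = CorruptionSpec(**{**vars(config.corruption),
                                 "seed": int(children[-1].generate_state(1)[0]
                                             % (2 ** 31))})
        panel, _ = corrupt_panel(panel, spec, timeline=config.timeline)
    return panel


def run_pipeline(config: RunConfig) -> RunArtifacts:
    """Execute the full analysis; any stage failure names the stage."""
    with _stage("load_input"):
        raw = _load_input(config)
        logger.info("input: %d records, %d indicators", len(raw),
                    raw["indicator"].nunique())

    if config.unit_subset is not None:
        with _stage("unit_subset"):
            raw = raw[raw["unit_id"].isin(config.unit_subset)]
            if raw.empty:
                raise ValueError("unit subset matches no records")

    with _stage("cleaning"):
        if config.skip_cleaning:
            cleaned, report = raw, None
        else:
            cleaned, report = clean_panel(raw, config.cleaning)
        logger.info("cleaning: %d -> %d records", len(raw), len(cleaned))

    with _stage("aggregation"):
        unit_panel = aggregate_to_units(cleaned)
        logger.info("aggregation: %d unit-month rows", len(unit_panel))

    season_map = config.season_map or default_season_map(
        config.timeline.total_months)
    coefficient_tables: dict[str, pd.DataFrame] = {}
    all_effects = []
    missed_results = {}
    trend_rows = []

    for indicator in sorted(unit_panel["indicator"].unique()):
        sub = unit_panel[unit_panel["indicator"] == indicator]
        with _stage("its_fit", indicator):
            design = build_design(sub, config.timeline, season_map)
            fit, vcov, table = fit_and_infer(
                design, alpha=config.alpha,
                small_sample=config.small_sample)
            coefficient_tables[indicator] = table
        with _stage("effects", indicator):
            bmean = baseline_mean(sub, config.timeline,
                                  mode=config.baseline_mode)
            for kind in ("immediate", "resumption"):
                all_effects.append(
                    percent_change(table, kind, bmean, indicator=indicator))
        with _stage("missed_care", indicator):
            cf = counterfactual_series(fit, design)
            missed_results[indicator] = cumulative_missed(
                cf, indicator=indicator)
        with _stage("trend_data", indicator):
            observed = (sub[sub["count"].notna()]
                        .groupby("month")["count"].sum())
            fitted = pd.Series(fit.predict(), index=design.months.values)
            counterfac = pd.Series(
                fit.predict(design.pandemic_terms_zeroed()),
                index=design.months.values)
            trend_rows.append(pd.DataFrame({
                "indicator": indicator,
                "month": observed.index,
                "observed_total": observed.values,
                "fitted_total": fitted.groupby(level=0).sum()
                                      .reindex(observed.index).values,
                "counterfactual_total": counterfac.groupby(level=0).sum()
                                                  .reindex(observed.index)
                                                  .values,
            }))

    with _stage("grouping"):
        results = list(missed_results.values())
        if config.groupings:
            grouped = group_services(
                missed_results, config.groupings,
                known_indicators=set(raw["indicator"].unique()))
            for g in grouped:
                denom = config.denominators.get(g.group_label)
                if denom is not None and not g.excluded:
                    normalize(g, denom)
            results += grouped
        missed_df = missed_care_table(results)

    effects_df = effects_table(all_effects)
    trend_df = (pd.concat(trend_rows, ignore_index=True)
                if trend_rows else pd.DataFrame())
    artifacts = RunArtifacts(
        cleaned_panel=cleaned,
        cleaning_report=report,
        unit_panel=unit_panel,
        coefficient_tables=coefficient_tables,
        effects=effects_df,
        missed_care=missed_df,
        trend_data=trend_df,
        manifest=config.to_manifest(),
    )
    if config.output_dir is not None:
        _write_artifacts(artifacts, Path(config.output_dir))
    return artifacts


def _write_artifacts(a: RunArtifacts, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_facility_panel(a.cleaned_panel, outdir / "cleaned_panel.csv")
    if a.cleaning_report is not None:
        a.cleaning_report.write(outdir)
    write_unit_panel(a.unit_panel, outdir / "unit_panel.csv")
    for indicator, table in a.coefficient_tables.items():
        table.to_csv(outdir / f"coefficients_{indicator}.csv")
    a.effects.to_csv(outdir / "effects.csv", index=False)
    a.missed_care.to_csv(outdir / "missed_care.csv", index=False)
    a.trend_data.to_csv(outdir / "trend_data.csv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(a.manifest, indent=2, sort_keys=True) + "\n")


def threshold_sensitivity(config: RunConfig,
                          thresholds: list[int]) -> pd.DataFrame:
    """Effect estimates side by side across completeness thresholds.

    Reruns the whole pipeline at each ``min_months_reported`` value and
    joins the per-indicator retention counts, mirroring the published
    sensitivity analysis over 12-, 15- and 18-month thresholds.
    """
    if not thresholds:
        raise ValueError("thresholds list is empty")
    bad = [t for t in thresholds
           if not 1 <= t <= config.cleaning.total_months]
    if bad:
        raise ValueError(f"thresholds out of range: {bad}")
    rows = []
    for thr in sorted(set(thresholds)):
        cfg_clean = CleaningConfig(
            min_months_reported=thr,
            total_months=config.cleaning.total_months,
            outlier_z=config.cleaning.outlier_z,
            remove_low_outliers=config.cleaning.remove_low_outliers)
        run_cfg = RunConfig(
            input_csv=None, synthetic_models=config.synthetic_models,
            corruption=config.corruption, cleaning=cfg_clean,
            timeline=config.timeline, season_map=config.season_map,
            alpha=config.alpha, baseline_mode=config.baseline_mode,
            small_sample=config.small_sample, output_dir=None,
            seed=config.seed,
        ) if config.input_csv is None else RunConfig(
            input_csv=config.input_csv, cleaning=cfg_clean,
            timeline=config.timeline, season_map=config.season_map,
            alpha=config.alpha, baseline_mode=config.baseline_mode,
            small_sample=config.small_sample, output_dir=None,
            seed=config.seed,
        )
        artifacts = run_pipeline(run_cfg)
        eff = artifacts.effects.copy()
        eff.insert(0, "threshold", thr)
        retained = (artifacts.cleaning_report.retained_counts
                    if artifacts.cleaning_report is not None else None)
        if retained is not None:
            eff = eff.merge(retained, on="indicator", how="left")
        rows.append(eff)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# declarative configuration file

def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML (or JSON) file.

    See ``examples/config_synthetic.yaml`` for the schema; all analysis
    defaults (15/24-month completeness, 3.5 SD outliers, 6-month shock,
    final-quarter resumption, alpha 0.05) apply when a key is omitted.
    """
    raw = yaml.safe_load(Path(path).read_text())
    tl = StudyTimeline(**raw.get("timeline", {}))
    models = None
    if "synthetic_models" in raw:
        models = []
        for m in raw["synthetic_models"]:
            m = dict(m)
            m.pop("timeline", None)
            season_effects = m.pop("season_effects", None)
            models.append(GeneratingModel(
                timeline=tl, season_effects=season_effects, **m))
    corruption = (CorruptionSpec(**raw["corruption"])
                  if "corruption" in raw else None)
    cleaning = CleaningConfig(**raw.get("cleaning", {}))
    denominators = {k: DenominatorSpec(**v)
                    for k, v in raw.get("denominators", {}).items()}
    season_map = ({int(k): v for k, v in raw["season_map"].items()}
                  if "season_map" in raw else None)
    return RunConfig(
        input_csv=raw.get("input_csv"),
        synthetic_models=models,
        corruption=corruption,
        cleaning=cleaning,
        timeline=tl,
        season_map=season_map,
        groupings=raw.get("groupings", {}),
        denominators=denominators,
        unit_subset=raw.get("unit_subset"),
        alpha=raw.get("alpha", 0.05),
        baseline_mode=raw.get("baseline_mode", "unit_month"),
        small_sample=raw.get("small_sample", "stata"),
        skip_cleaning=raw.get("skip_cleaning", False),
        output_dir=raw.get("output_dir"),
        seed=raw.get("seed", 0),
    )
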