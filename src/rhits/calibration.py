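"""Monte-Carlo calibration studies for the clustered t(G-2) inference.

These studies answer the two questions a practitioner should ask before
trusting the pipeline's intervals on real data of this shape: does the 95%
CI for the pandemic level change cover the generating truth about 95% of
the time, and is the test size near its nominal 5% when there is no effect?

The replicate design mirrors the default study conditions: 10 sub-national
units observed for 24 months (15 baseline), negative-binomial count noise,
seasonal cycles and unit heterogeneity, and an immediate level drop of 20%
of the baseline level when an effect is present.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .effects import baseline_mean
from .its import fit_and_infer
from .panel import aggregate_to_units, build_design
from .synthetic import GeneratingModel, simulate_panel
from .timeline import StudyTimeline


def replicate_model(seed: int, null: bool = False) -> GeneratingModel:
    """One draw of the calibration-study generating model.

    beta2 is -20% of the baseline level unless ``null``, in which case all
    pandemic coefficients are zero.
    """
    beta0 = 500.0
    return GeneratingModel(
        n_units=10, facilities_per_unit=1,
        timeline=StudyTimeline(),
        beta0=beta0, beta1=2.0,
        beta2=0.0 if null else -0.20 * beta0,
        beta3=0.0, beta4=0.0 if null else -0.05 * beta0,
        season_effects={"winter": -20.0, "spring": 10.0,
                        "summer": 20.0, "fall": -10.0},
        unit_effects=[float(v) for v in
                      np.linspace(-60.0, 60.0, 10)],
        dispersion=0.01,
        seed=seed,
    )


def calibration_study(n_reps: int, seed: int, null: bool = False,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Fit the full pipeline on ``n_reps`` independent synthetic panels.

    Returns one row per replicate with the shock-level estimate, its CI,
    p value, the generating truth, and convenience flags ``covered``
    (CI contains truth) and ``rejected`` (p < alpha).
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2 ** 31)
    rows = []
    for s in seeds:
        model = replicate_model(int(s), null=null)
        unit = aggregate_to_units(simulate_panel(model))
        design = build_design(unit, model.timeline)
        _, _, table = fit_and_infer(design, alpha=alpha)
        truth = model.unit_level_truth()["beta2"]
        est = table.loc["X"]
        rows.append({
            "estimate": est["estimate"],
            "ci_low": est["ci_low"],
            "ci_high": est["ci_high"],
            "p": est["p"],
            "truth": truth,
            "baseline_mean": baseline_mean(unit, model.timeline),
            "covered": bool(est["ci_low"] <= truth <= est["ci_high"]),
            "rejected": bool(est["p"] < alpha),
        })
    return pd.DataFrame(rows)
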