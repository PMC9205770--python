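"""Long-format panel containers and their CSV round-trips.

Two tables drive everything:

* **facility panel** — one row per facility x indicator x month with columns
  ``facility_id, unit_id, indicator, month, count``.  ``count`` is a float
  with NaN meaning *no report* for that month (a DHIS2-style missing report,
  not a zero — reported zeros are legitimate data).  A month wholly absent
  from the table is equivalent to a NaN row.
* **unit panel** — one row per sub-national unit x indicator x month with
  columns ``unit_id, indicator, month, count, n_facilities``; the
  observation unit of the segmented regression.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FACILITY_COLUMNS = ["facility_id", "unit_id", "indicator", "month", "count"]
UNIT_COLUMNS = ["unit_id", "indicator", "month", "count", "n_facilities"]


def validate_facility_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check schema and basic sanity of a facility panel; returns the panel."""
    missing = [c for c in FACILITY_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"facility panel missing columns: {missing}")
    if len(panel) and panel["month"].min() < 1:
        raise ValueError("month indices must be 1-based")
    observed = panel["count"].dropna()
    if (observed < 0).any():
        raise ValueError("negative counts in facility panel")
    return panel


def write_facility_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Write long-format CSV; missing counts become empty fields."""
    validate_facility_panel(panel)
    panel.to_csv(path, index=False, columns=FACILITY_COLUMNS,
                 float_format="%.10g")


def read_facility_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(
        path,
        dtype={"facility_id": str, "unit_id": str, "indicator": str,
               "month": int, "count": float},
    )
    return validate_facility_panel(panel)


def write_unit_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index=False, columns=UNIT_COLUMNS,
                 float_format="%.10g")


def read_unit_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(
        path,
        dtype={"unit_id": str, "indicator": str, "month": int,
               "count": float, "n_facilities": int},
    )
    missing = [c for c in UNIT_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"unit panel missing columns: {missing}")
    return panel
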