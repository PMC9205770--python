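"""Study timeline: month indexing of baseline, shock window and resumption.

Months are an abstract 1-based index anchored at January 2019 by default, so
month 1..15 is the pre-pandemic baseline (Jan 2019 – Mar 2020), months 16..21
the six-month shock window (Apr–Sep 2020), and months 22..24 the resumption
quarter (Oct–Dec 2020).  Countries with a shifted fiscal calendar (e.g. a
14-month baseline and 10-month pandemic period) are handled purely through
the field values, never through calendar arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def default_season_map(total_months: int = 24) -> dict[int, str]:
    """Meteorological Northern-Hemisphere seasons on a Jan-anchored index.

    Months {12,1,2} -> winter, {3,4,5} -> spring, {6,7,8} -> summer,
    {9,10,11} -> fall, repeating with a 12-month period.  Southern-Hemisphere
    analyses should pass their own mapping.
    """
    names = {12: "winter", 1: "winter", 2: "winter",
             3: "spring", 4: "spring", 5: "spring",
             6: "summer", 7: "summer", 8: "summer",
             9: "fall", 10: "fall", 11: "fall"}
    return {t: names[(t - 1) % 12 + 1] for t in range(1, total_months + 1)}


@dataclass(frozen=True)
class StudyTimeline:
    """Partition of the study months into baseline / shock / resumption.

    Parameters
    ----------
    total_months
        Length of the study series (default 24).
    baseline_months
        Number of pre-pandemic months (default 15; 14 for the Nepali
        calendar variant).
    shock_months
        Length of the immediate-disruption window after the pandemic
        declaration (default 6).

    The resumption period runs from ``baseline_months + shock_months + 1``
    through ``total_months``.
    """

    total_months: int = 24
    baseline_months: int = 15
    shock_months: int = 6

    def __post_init__(self) -> None:
        if self.total_months < 3:
            raise ValueError("total_months must be at least 3")
        if not (1 <= self.baseline_months < self.total_months):
            raise ValueError("baseline_months must lie in [1, total_months)")
        if self.shock_months < 1:
            raise ValueError("shock_months must be positive")
        if self.baseline_months + self.shock_months >= self.total_months:
            raise ValueError(
                "baseline + shock windows must leave at least one "
                "resumption month")

    @property
    def resumption_start(self) -> int:
        return self.baseline_months + self.shock_months + 1

    @property
    def pandemic_months(self) -> range:
        """All post-baseline months (shock window plus resumption)."""
        return range(self.baseline_months + 1, self.total_months + 1)

    @property
    def shock_window(self) -> range:
        return range(self.baseline_months + 1, self.resumption_start)

    def regime(self, month: int) -> str:
        """Return 'baseline', 'shock' or 'resumption' for a month index."""
        if not 1 <= month <= self.total_months:
            raise ValueError(f"month {month} outside 1..{self.total_months}")
        if month <= self.baseline_months:
            return "baseline"
        if month < self.resumption_start:
            return "shock"
        return "resumption"

    # ITS design codings -------------------------------------------------

    def shock_indicator(self, month: int) -> int:
        """X_t: 1 during the shock window, else 0."""
        return int(self.regime(month) == "shock")

    def months_since_shock(self, month: int) -> int:
        """Z: 1..shock_months inside the shock window, else 0.

        Deliberately 0 in the resumption quarter so the resumption level
        term alone measures the remaining gap from the continued
        pre-pandemic trend.
        """
        return month - self.baseline_months if self.regime(month) == "shock" else 0

    def resumption_indicator(self, month: int) -> int:
        """W: 1 from the resumption quarter onward, else 0."""
        return int(self.regime(month) == "resumption")
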