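"""Future projection of body condition: sensitivity x exposure, summed.

The projected change in percent body condition by 2050 is

    dB/dT = sum_i  (dB/dC_i) * (dC_i/dT)

where dB/dC_i is a percent-scale sensitivity to climate variable i and
dC_i/dT its projected change ("exposure") under a scenario. Exposure is
matched to the meteorological season(s) the variable's climate window
occupies; a window spanning several seasons gets the unweighted mean of
their projected changes. Wind has a single annual exposure. Exposures are
treated as error-free, so the projection SE propagates sensitivity SEs only.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEASONS = ("winter", "spring", "summer", "autumn")

#: meteorological seasons by calendar month
_MONTH_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

#: non-leap reference year used to map window offsets to calendar months
_REF_YEAR = 2001


@dataclass
class ExposureScenario:
    """Projected change per climate variable per season to 2050."""

    table: pd.DataFrame  # columns: variable, season, change

    def __post_init__(self):
        need = {"variable", "season", "change"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"scenario table needs columns {sorted(need)}")
        if "sunshine" in set(self.table["variable"]):
            raise ValueError("scenario must not define sunshine (no projection exists)")

    def variables(self) -> set[str]:
        return set(self.table["variable"])

    def change(self, variable: str, season: str) -> float:
        sel = self.table[
            (self.table["variable"] == variable) & (self.table["season"] == season)
        ]
        if sel.empty:
            raise KeyError(f"no scenario entry for {variable!r} in {season!r}")
        return float(sel["change"].iloc[0])


@dataclass
class ProjectionEstimate:
    """Per-variable contributions and their sum for one species or site."""

    level: str                       # "species" or "site"
    species: str
    site: str | None = None
    contributions: dict[str, float] = field(default_factory=dict)  # % by 2050
    exposures: dict[str, float] = field(default_factory=dict)
    total: float = 0.0
    se: float = 0.0


def window_seasons(window: tuple[int, int]) -> set[str]:
    """Meteorological seasons touched by an offset window before 15 August."""
    start, end = window
    if not (start >= end >= 1):
        raise ValueError(f"invalid window {window}")
    ref = dt.date(_REF_YEAR, 8, 15)
    months = set()
    first = ref - dt.timedelta(days=int(start))
    last = ref - dt.timedelta(days=int(end))
    d = first
    while d <= last:
        months.add(d.month)
        # jump to the first of the next month
        d = (d.replace(day=1) + dt.timedelta(days=32)).replace(day=1)
    months.add(last.month)
    return {_MONTH_SEASON[m] for m in months}


def match_exposure(variable: str, seasons: set[str], scenario: ExposureScenario) -> float:
    """Season-matched exposure for one variable.

    Averages the projected changes of the seasons the window spans. Wind
    returns its annual value regardless of seasons; sunshine contributes 0
    (no projection exists) with a logged warning.
    """
    if variable == "sunshine":
        warnings.warn("sunshine has no exposure scenario; contribution set to 0")
        logger.warning("sunshine exposure requested; returning 0")
        return 0.0
    if variable not in scenario.variables():
        raise KeyError(f"scenario does not define variable {variable!r}")
    if variable == "wind":
        vals = scenario.table.loc[scenario.table["variable"] == "wind", "change"]
        return float(vals.iloc[0])
    if not seasons:
        raise ValueError("empty season set")
    return float(np.mean([scenario.change(variable, s) for s in sorted(seasons)]))


def project(
    sensitivities: pd.DataFrame,
    scenario: ExposureScenario,
    windows: dict[str, tuple[int, int]],
) -> pd.DataFrame:
    """Project percent body-condition change by 2050 per species or site.

    Parameters
    ----------
    sensitivities : tidy table with columns
        level, species, site, variable, s_pct, se_pct (site empty/NaN at
        species level). Percent scale (% condition per climate unit).
    scenario : the exposure scenario.
    windows : per climate variable, the best window (used only for season
        matching).

    Returns one row per (level, species, site) with one contribution column
    per variable (``contrib_<var>``), the exposure used (``exposure_<var>``),
    the total projection (% by 2050) and its SE. The total is exactly the
    sum of the contribution columns.
    """
    need = {"level", "species", "site", "variable", "s_pct", "se_pct"}
    if not need.issubset(sensitivities.columns):
        raise ValueError(f"sensitivity table needs columns {sorted(need)}")

    exposures = {
        var: match_exposure(var, window_seasons(win), scenario)
        for var, win in windows.items()
    }
    out_rows = []
    grouped = sensitivities.groupby(["level", "species", "site"], dropna=False, sort=True)
    for (level, sp, site), grp in grouped:
        row: dict[str, object] = {"level": level, "species": sp, "site": site}
        total = 0.0
        var_se2 = 0.0
        for r in grp.itertuples():
            if r.variable not in exposures:
                raise KeyError(f"no window/exposure for variable {r.variable!r}")
            e = exposures[r.variable]
            contrib = float(r.s_pct) * e
            row[f"exposure_{r.variable}"] = e
            row[f"contrib_{r.variable}"] = contrib
            total += contrib
            var_se2 += (e * float(r.se_pct)) ** 2
        row["total"] = total
        row["se"] = float(np.sqrt(var_se2))
        out_rows.append(row)
    return pd.DataFrame(out_rows)
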