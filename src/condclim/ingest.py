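"""Reading study tables and computing size-corrected body condition.

Body condition is the residual from a per-species ordinary least-squares
regression of body mass (g) on wing length (mm): a capture heavier than the
mass predicted from its structural size is in positive condition. The module
also matches ringing sites to their nearest weather station (great-circle
distance) and converts capture dates to a day-of-season index relative to
the constant-effort season (12 April - 14 August).
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: First and last day of the constant-effort capture season (month, day).
SEASON_START = (4, 12)
SEASON_END = (8, 14)
#: Reference date anchoring climate-window offsets (month, day): the day
#: after the season closes; offset 1 = 14 August.
REFERENCE_DATE = (8, 15)

#: Length of the capture season in days (non-leap calendar, inclusive).
SEASON_LENGTH = 125

CLIMATE_VARIABLES = ("temp", "rain", "wind", "humidity", "sunshine", "dtr")

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# calendar helpers


def season_bounds(year: int) -> tuple[dt.date, dt.date]:
    """Inclusive (start, end) dates of the capture season for ``year``."""
    return dt.date(year, *SEASON_START), dt.date(year, *SEASON_END)


def reference_date(year: int) -> dt.date:
    """Season-end anchor from which window offsets are counted back."""
    return dt.date(year, *REFERENCE_DATE)


def day_of_season(date: dt.date | str | pd.Timestamp) -> int:
    """1-based day index within the capture season (12 April = day 1)."""
    date = pd.Timestamp(date).date()
    start, end = season_bounds(date.year)
    if not (start <= date <= end):
        raise ValueError(
            f"{date.isoformat()} is outside the capture season "
            f"({start.isoformat()} - {end.isoformat()})"
        )
    return (date - start).days + 1


# ---------------------------------------------------------------------------
# geography


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points given in decimal degrees."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def match_station(site_lat: float, site_lon: float, stations: pd.DataFrame) -> str:
    """Nearest weather station to a site by great-circle distance.

    ``stations`` needs columns ``station``, ``lat``, ``lon``. Ties are broken
    deterministically by lexicographic station id.
    """
    if stations.empty:
        raise ValueError("no stations supplied")
    if stations[["lat", "lon"]].isna().any().any() or pd.isna(site_lat) or pd.isna(site_lon):
        raise ValueError("missing coordinates in station matching")
    d = haversine_km(site_lat, site_lon, stations["lat"].to_numpy(), stations["lon"].to_numpy())
    # round to the millimetre so geometrically exact ties break by id
    order = sorted(zip(np.round(d, 6), stations["station"].astype(str)))
    return order[0][1]


# ---------------------------------------------------------------------------
# condition


def compute_condition(captures: pd.DataFrame) -> pd.DataFrame:
    """Add size-corrected body condition to a capture table.

    Per species, mass is regressed on wing length (OLS, pooled across sites,
    years, ages and sexes) and the residual is the condition index ``condition``
    in grams. Also adds ``day_of_season`` and the species mean mass
    ``species_mean_mass`` (used later for percent scaling).

    Raises
    ------
    ValueError
        If any species has fewer than 3 distinct wing lengths (the residual
        regression would be singular or exactly saturated).
    """
    required = {"site", "species", "individual", "date", "time", "mass", "wing", "age", "sex"}
    missing = required - set(captures.columns)
    if missing:
        raise ValueError(f"capture table missing columns: {sorted(missing)}")
    if (captures["mass"] <= 0).any() or (captures["wing"] <= 0).any():
        raise ValueError("mass and wing must be positive")

    out = captures.copy()
    out["sex"] = out["sex"].fillna("unknown")
    out["day_of_season"] = [day_of_season(d) for d in out["date"]]
    out["condition"] = np.nan
    out["species_mean_mass"] = np.nan

    for sp, grp in out.groupby("species"):
        wing = grp["wing"].to_numpy(float)
        mass = grp["mass"].to_numpy(float)
        if np.unique(wing).size < 3:
            raise ValueError(
                f"species {sp!r}: need >= 3 distinct wing lengths for the "
                "mass-wing regression"
            )
        X = np.column_stack([np.ones_like(wing), wing])
        coef, *_ = np.linalg.lstsq(X, mass, rcond=None)
        resid = mass - X @ coef
        out.loc[grp.index, "condition"] = resid
        out.loc[grp.index, "species_mean_mass"] = mass.mean()
        logger.info("condition: species=%s n=%d slope=%.4f g/mm", sp, len(grp), coef[1])
    return out


def wing_trend(captures: pd.DataFrame) -> pd.DataFrame:
    """Diagnostic: per-species OLS trend of wing length over calendar year.

    A systematic drift in wing length over the study would contaminate the
    residual condition index; this reports slope (mm/yr) with its SE.
    """
    rows = []
    years = pd.DatetimeIndex(pd.to_datetime(captures["date"])).year.to_numpy(float)
    for sp, idx in captures.groupby("species").groups.items():
        y = captures.loc[idx, "wing"].to_numpy(float)
        x = years[captures.index.get_indexer(idx)]
        if np.unique(x).size < 2:
            rows.append({"species": sp, "slope": np.nan, "se": np.nan, "n": len(idx)})
            continue
        X = np.column_stack([np.ones_like(x), x - x.mean()])
        coef, rss_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = max(len(x) - 2, 1)
        sigma2 = float(resid @ resid) / dof
        se = float(np.sqrt(sigma2 / ((X[:, 1] ** 2).sum() or np.inf)))
        rows.append({"species": sp, "slope": float(coef[1]), "se": se, "n": len(idx)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers (schemas are those written by condclim.synthetic)


def read_captures(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", parse_dates=["date"])
    logger.info("read %d capture rows from %s", len(df), path)
    return df


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    logger.info("read %d sites from %s", len(df), path)
    return df


def read_species(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    logger.info("read %d species from %s", len(df), path)
    return df


def read_climate(path) -> pd.DataFrame:
    """Read a long-format daily climate table (station, variable, date, value)."""
    df = pd.read_csv(path, comment="#", parse_dates=["date"])
    bad = set(df["variable"]) - set(CLIMATE_VARIABLES)
    if bad:
        raise ValueError(f"unknown climate variables in {path}: {sorted(bad)}")
    rng = df.groupby("variable")["value"]
    checks = {
        "humidity": lambda s: ((s < 0) | (s > 100)).any(),
        "sunshine": lambda s: ((s < 0) | (s > 100)).any(),
        "rain": lambda s: (s < 0).any(),
        "dtr": lambda s: (s < 0).any(),
    }
    for var, check in checks.items():
        if var in rng.groups and check(df.loc[df["variable"] == var, "value"]):
            raise ValueError(f"climate variable {var} out of physical range in {path}")
    logger.info("read %d daily climate rows from %s", len(df), path)
    return df
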