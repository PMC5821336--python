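"""Synthetic constant-effort-site (CES) dataset generator with known truth.

Emulates the structure of a national mist-netting scheme: fixed sites
operated 12 times per season (12 April - 14 August), repeat captures of
ringed individuals, daily climate at a handful of weather stations, and
body-mass responses to climate acting through planted consecutive-day
windows. Every stochastic element is driven by a single integer seed, and
the planted truth (windows, effect sizes, among-species / among-population
variance of slopes) is exposed so downstream stages can be scored against
ground truth.

Climate responses are planted on the gram scale: for an active effect the
window-aggregated climate x (centred at its grand mean over all site-years)
adds ``beta1 * x + beta2 * x**2`` to body mass, with the realized linear
slope varying by species and by site within species according to the
configured standard deviations. The ratio
``species_sd**2 / (species_sd**2 + population_sd**2)`` is therefore the true
intraclass correlation ("species signal") of site-level sensitivities.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import random
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .ingest import CLIMATE_VARIABLES, SEASON_LENGTH, reference_date, season_bounds
from .projection import ExposureScenario, SEASONS

__all__ = [
    "ClimateEffect",
    "CovariateEffects",
    "TruthSpec",
    "StudyDesign",
    "default_design",
    "default_truth",
    "gen_climate",
    "gen_captures",
    "gen_scenario",
    "default_scenario",
    "realized_slopes",
    "window_aggregates",
    "gen_site_sensitivities",
    "write_dataset",
]


# ---------------------------------------------------------------------------
# truth specification


@dataclass
class ClimateEffect:
    """Planted effect of one climate variable on body mass.

    The window is an inclusive pair of day offsets counted backwards from
    the 15 August reference date (offset 1 = 14 August); ``beta1`` is in
    g per climate unit, ``beta2`` in g per unit^2 (0 for a linear effect).
    ``species_sd`` and ``population_sd`` are the standard deviations of the
    species- and site-level deviations of the realized linear slope.
    """

    variable: str
    active: bool = True
    window: tuple[int, int] = (100, 40)  # (start_offset, end_offset)
    beta1: float = 0.0
    beta2: float = 0.0
    species_sd: float = 0.0
    population_sd: float = 0.0

    def __post_init__(self):
        if self.variable not in CLIMATE_VARIABLES:
            raise ValueError(f"unknown climate variable {self.variable!r}")
        start, end = self.window
        if not (start >= end >= 1):
            raise ValueError(f"window must satisfy start >= end >= 1, got {self.window}")
        if min(self.species_sd, self.population_sd) < 0:
            raise ValueError("slope SDs must be >= 0")
        if not self.active and (self.beta1 != 0 or self.beta2 != 0):
            raise ValueError("inactive effect must have beta1 = beta2 = 0")


@dataclass
class CovariateEffects:
    """Additive covariate effects on body mass (grams)."""

    juvenile: float = -0.5       # juveniles lighter than adults
    male: float = 0.3            # males vs females
    time_of_day: float = 0.05    # g per hour since 09:00
    season: float = 0.004        # g per day-of-season (centred)
    season2: float = -0.00005    # g per day-of-season^2 (centred)


@dataclass
class TruthSpec:
    """Full ground truth of a synthetic dataset."""

    effects: list[ClimateEffect] = field(default_factory=list)
    baseline_mass: dict[str, float] = field(default_factory=dict)
    allometry: float = 0.25      # g per mm wing, within species
    individual_sd: float = 0.3   # SD of individual random intercept (g)
    residual_sd: float = 0.8     # residual SD of mass (g)
    covariates: CovariateEffects = field(default_factory=CovariateEffects)
    recapture_prob: float = 0.2  # probability a capture is of a ringed bird

    def __post_init__(self):
        if min(self.individual_sd, self.residual_sd) < 0:
            raise ValueError("SDs must be >= 0")
        seen = set()
        for e in self.effects:
            if e.variable in seen:
                raise ValueError(f"duplicate effect for variable {e.variable!r}")
            seen.add(e.variable)

    def active_effects(self) -> list[ClimateEffect]:
        return [e for e in self.effects if e.active]


# ---------------------------------------------------------------------------
# study design


@dataclass
class StudyDesign:
    """Sites, species, weather stations and the species phylogeny."""

    sites: pd.DataFrame      # site, lat, lon, habitat, station, year_start, year_end
    species: pd.DataFrame    # species, mean_mass, mean_wing, migration, habitat_pref, life_expectancy
    stations: pd.DataFrame   # station, lat, lon
    tree: dendropy.Tree

    def __post_init__(self):
        if not set(self.sites["station"]).issubset(set(self.stations["station"])):
            raise ValueError("every site must map to a known station")
        tips = {t.label for t in self.tree.taxon_namespace}
        if tips != set(self.species["species"]):
            raise ValueError("tree tips must equal the species ids exactly")

    def site_years(self) -> pd.DataFrame:
        """One row per (site, year) the site was operated."""
        rows = [
            {"site": r.site, "year": y}
            for r in self.sites.itertuples()
            for y in range(int(r.year_start), int(r.year_end) + 1)
        ]
        return pd.DataFrame(rows)

    @property
    def years(self) -> list[int]:
        return sorted(
            set(
                y
                for r in self.sites.itertuples()
                for y in range(int(r.year_start), int(r.year_end) + 1)
            )
        )


_MIGRATIONS = ("resident", "short", "long")
_HABITAT_PREFS = ("urban", "woodland", "wet", "open")


def _random_ultrametric_tree(species: list[str], seed: int) -> dendropy.Tree:
    """Random ultrametric coalescent-style tree, branch lengths in Myr."""
    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace(species)
    tree = dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=taxa, pop_size=10.0, rng=rng
    )
    return tree


def default_design(
    n_species: int = 5,
    n_sites: int = 6,
    n_years: int = 10,
    n_stations: int = 2,
    first_year: int = 2000,
    seed: int = 0,
) -> StudyDesign:
    """A compact Dutch-like study design.

    Sites sit on a small lat/lon grid (51.5-53.3 N, 4-7 E), alternate
    wet/dry habitat, and are matched to the nearest of ``n_stations``
    weather stations. All sites run all years by default; species mean
    masses span 9-35 g (typical passerines).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    species_ids = [f"sp{i+1:02d}" for i in range(n_species)]
    mean_mass = np.round(np.linspace(9.0, 35.0, n_species), 1)
    species = pd.DataFrame(
        {
            "species": species_ids,
            "mean_mass": mean_mass,
            "mean_wing": np.round(45.0 + 1.8 * mean_mass, 1),
            "migration": [_MIGRATIONS[i % 3] for i in range(n_species)],
            "habitat_pref": [_HABITAT_PREFS[i % 4] for i in range(n_species)],
            "life_expectancy": np.round(1.0 / rng.uniform(0.3, 0.7, n_species), 2),
        }
    )

    st_ids = [f"st{i+1:02d}" for i in range(n_stations)]
    stations = pd.DataFrame(
        {
            "station": st_ids,
            "lat": np.round(rng.uniform(51.5, 53.3, n_stations), 3),
            "lon": np.round(rng.uniform(4.0, 7.0, n_stations), 3),
        }
    )

    lat = np.round(rng.uniform(51.5, 53.3, n_sites), 3)
    lon = np.round(rng.uniform(4.0, 7.0, n_sites), 3)
    from .ingest import match_station

    sites = pd.DataFrame(
        {
            "site": [f"site{i+1:02d}" for i in range(n_sites)],
            "lat": lat,
            "lon": lon,
            "habitat": ["wet" if i % 2 == 0 else "dry" for i in range(n_sites)],
            "year_start": first_year,
            "year_end": first_year + n_years - 1,
        }
    )
    sites["station"] = [match_station(a, o, stations) for a, o in zip(lat, lon)]

    tree = _random_ultrametric_tree(species_ids, seed + 7)
    return StudyDesign(sites=sites, species=species, stations=stations, tree=tree)


def default_truth(
    design: StudyDesign,
    effects: list[ClimateEffect] | None = None,
    **kwargs,
) -> TruthSpec:
    """TruthSpec with baseline masses taken from the design's species table."""
    return TruthSpec(
        effects=list(effects or []),
        baseline_mass=dict(zip(design.species["species"], design.species["mean_mass"])),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# climate generation

#: Per-variable climate process parameters:
#: (annual mean, seasonal amplitude, day-of-year of seasonal peak,
#:  between-year SD, daily AR(1) innovation SD, AR(1) coefficient,
#:  between-station SD, (lo, hi) physical clip range).
#: Units follow the input convention: temp degC, rain 0.1 mm/day,
#: wind 0.1 m/s, humidity %, sunshine % of possible duration, dtr degC.
DEFAULT_CLIMATE_CONFIG: dict[str, tuple] = {
    "temp": (10.0, 7.5, 205, 0.6, 2.0, 0.7, 0.4, (-30.0, 45.0)),
    "rain": (20.0, 4.0, 20, 3.0, 12.0, 0.2, 2.0, (0.0, None)),
    "wind": (40.0, 8.0, 15, 2.5, 8.0, 0.5, 3.0, (0.0, None)),
    "humidity": (81.0, 7.0, 350, 1.5, 4.0, 0.6, 1.0, (0.0, 100.0)),
    "sunshine": (38.0, 16.0, 170, 2.5, 12.0, 0.3, 2.0, (0.0, 100.0)),
    "dtr": (8.0, 2.5, 160, 0.5, 1.8, 0.4, 0.5, (0.0, None)),
}


def gen_climate(
    design: StudyDesign,
    years: list[int] | None = None,
    seed: int = 0,
    config: dict[str, tuple] | None = None,
    variables: tuple[str, ...] = CLIMATE_VARIABLES,
) -> pd.DataFrame:
    """Daily climate per station: seasonal sinusoid + year anomaly + AR(1) noise.

    Covers 1 January of the year before the first study year through
    31 December of the last, so every 365-day window before a 15 August
    reference date is available. Returns a long table
    (station, variable, date, value); deterministic given ``seed``.
    """
    if design.stations.empty:
        raise ValueError("design has no stations")
    years = sorted(years or design.years)
    if not years:
        raise ValueError("no years requested")
    config = {**DEFAULT_CLIMATE_CONFIG, **(config or {})}

    dates = pd.date_range(
        dt.date(years[0] - 1, 1, 1), dt.date(years[-1], 12, 31), freq="D"
    )
    doy = dates.dayofyear.to_numpy(float)
    cal_years = dates.year.to_numpy()
    uniq_years = np.unique(cal_years)
    n = len(dates)

    frames = []
    for vi, var in enumerate(variables):
        mean, amp, peak, year_sd, noise_sd, ar1, station_sd, clip = config[var]
        seasonal = mean + amp * np.cos(2 * np.pi * (doy - peak) / 365.25)
        rng_y = np.random.default_rng(np.random.SeedSequence([seed, 200 + vi]))
        anomalies = dict(zip(uniq_years, rng_y.normal(0.0, year_sd, len(uniq_years))))
        year_term = np.array([anomalies[y] for y in cal_years])
        n_st = len(design.stations)
        offsets = rng_y.normal(0.0, station_sd, n_st)
        if n_st > 1:  # stations vary around the regional mean
            offsets -= offsets.mean()
        for si, st in enumerate(design.stations["station"]):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + vi, si]))
            offset = offsets[si]
            innov = rng.normal(0.0, noise_sd, n)
            noise = np.empty(n)
            acc = 0.0
            for i in range(n):  # AR(1); short series, loop is fine
                acc = ar1 * acc + innov[i]
                noise[i] = acc
            vals = seasonal + year_term + offset + noise
            lo, hi = clip
            vals = np.clip(vals, lo, hi)
            frames.append(
                pd.DataFrame(
                    {"station": st, "variable": var, "date": dates, "value": vals}
                )
            )
    return pd.concat(frames, ignore_index=True)


def _station_series(climate: pd.DataFrame, station: str, variable: str) -> pd.Series:
    sel = climate[(climate["station"] == station) & (climate["variable"] == variable)]
    if sel.empty:
        raise ValueError(f"no climate for station={station!r} variable={variable!r}")
    s = pd.Series(sel["value"].to_numpy(), index=pd.DatetimeIndex(sel["date"]))
    return s.sort_index()


def window_aggregates(
    design: StudyDesign, climate: pd.DataFrame, variable: str, window: tuple[int, int]
) -> pd.DataFrame:
    """Mean climate in an offset window per (site, year) the site operated.

    Offsets count back from 15 August of the year (offset 1 = 14 August);
    the window is inclusive on both ends. Adds the grand mean over all
    site-years as column ``center`` (same value in every row).
    """
    start, end = window
    rows = []
    for r in design.sites.itertuples():
        series = _station_series(climate, r.station, variable)
        for year in range(int(r.year_start), int(r.year_end) + 1):
            ref = pd.Timestamp(reference_date(year))
            lo, hi = ref - pd.Timedelta(days=int(start)), ref - pd.Timedelta(days=int(end))
            chunk = series.loc[lo:hi]
            expected = int(start) - int(end) + 1
            if len(chunk) != expected:
                raise ValueError(
                    f"climate for {variable} does not cover window {window} "
                    f"before {ref.date()} at station {r.station}"
                )
            rows.append({"site": r.site, "year": year, "value": float(chunk.mean())})
    out = pd.DataFrame(rows)
    out["center"] = out["value"].mean()
    return out


# ---------------------------------------------------------------------------
# capture generation


def realized_slopes(design: StudyDesign, truth: TruthSpec, seed: int = 0) -> pd.DataFrame:
    """True linear slope per (variable, species, site).

    slope = beta1 + species deviation + site-within-species deviation, the
    deviations drawn with the effect's ``species_sd`` / ``population_sd``.
    Deterministic given the seed, and identical to the slopes used by
    :func:`gen_captures` with the same seed.
    """
    rows = []
    species = list(design.species["species"])
    sites = list(design.sites["site"])
    for ei, eff in enumerate(truth.active_effects()):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 300 + ei]))
        dev_sp = rng.normal(0.0, eff.species_sd, len(species))
        dev_site = rng.normal(0.0, eff.population_sd, (len(species), len(sites)))
        for i, sp in enumerate(species):
            for j, st in enumerate(sites):
                rows.append(
                    {
                        "variable": eff.variable,
                        "species": sp,
                        "site": st,
                        "beta1": eff.beta1 + dev_sp[i] + dev_site[i, j],
                        "beta2": eff.beta2,
                    }
                )
    return pd.DataFrame(rows, columns=["variable", "species", "site", "beta1", "beta2"])


def _visit_days(n_visits: int) -> np.ndarray:
    """Evenly spaced distinct day-of-season indices for the visits."""
    return np.unique(np.round(np.linspace(1, SEASON_LENGTH, n_visits)).astype(int))


def gen_captures(
    design: StudyDesign,
    climate: pd.DataFrame,
    truth: TruthSpec,
    seed: int = 0,
    visits_per_year: int = 12,
    captures_per_visit: float = 2.0,
    wing_sd: float = 2.0,
    sex_unknown_prob: float = 0.1,
) -> pd.DataFrame:
    """Simulate the capture table.

    Each operated (site, year) gets ``visits_per_year`` evenly spaced visit
    dates; each visit catches at least one bird per species (1 + Poisson
    extras, mean ``captures_per_visit``). A capture is a ringed (previously
    caught at that site) individual with probability ``truth.recapture_prob``.
    Mass combines baseline, wing allometry, planted climate effects
    (slopes from :func:`realized_slopes`), covariate effects, the
    individual's random intercept and residual noise — all in grams.
    """
    if captures_per_visit < 1:
        raise ValueError("captures_per_visit must be >= 1")
    slopes = realized_slopes(design, truth, seed)
    # per active effect: (site, year) -> centred aggregate
    agg = {}
    for eff in truth.active_effects():
        try:
            table = window_aggregates(design, climate, eff.variable, eff.window)
        except ValueError as exc:
            raise ValueError(f"truth effect on {eff.variable!r}: {exc}") from exc
        table["x"] = table["value"] - table["center"]
        agg[eff.variable] = table.set_index(["site", "year"])["x"]

    cov = truth.covariates
    rng = np.random.default_rng(np.random.SeedSequence([seed, 400]))
    visit_days = _visit_days(visits_per_year)
    species = design.species.set_index("species")
    slope_idx = (
        slopes.set_index(["variable", "species", "site"])["beta1"]
        if not slopes.empty
        else None
    )

    rows = []
    for r in design.sites.itertuples():
        for year in range(int(r.year_start), int(r.year_end) + 1):
            start, _ = season_bounds(year)
            for sp in species.index:
                pool: list[tuple[str, float, float]] = []  # (id, indiv effect, wing)
                n_new = 0
                mu = truth.baseline_mass.get(sp, float(species.loc[sp, "mean_mass"]))
                mean_wing = float(species.loc[sp, "mean_wing"])
                clim_term_lin = 0.0
                clim_term = 0.0
                for eff in truth.active_effects():
                    x = float(agg[eff.variable].loc[(r.site, year)])
                    b1 = float(slope_idx.loc[(eff.variable, sp, r.site)])
                    clim_term += b1 * x + eff.beta2 * x * x
                for day in visit_days:
                    date = start + dt.timedelta(days=int(day) - 1)
                    n_birds = 1 + rng.poisson(captures_per_visit - 1.0)
                    for _ in range(n_birds):
                        if pool and rng.random() < truth.recapture_prob:
                            ind_id, ind_eff, wing = pool[rng.integers(len(pool))]
                        else:
                            n_new += 1
                            ind_id = f"{r.site}-{sp}-{year}-{n_new:04d}"
                            ind_eff = rng.normal(0.0, truth.individual_sd)
                            # wing recorded (and used) at 0.1 mm resolution
                            wing = round(max(rng.normal(mean_wing, wing_sd), 1.0), 1)
                            pool.append((ind_id, ind_eff, wing))
                        age = "juvenile" if rng.random() < 0.5 else "adult"
                        u = rng.random()
                        sex = (
                            "unknown"
                            if u < sex_unknown_prob
                            else ("M" if u < sex_unknown_prob + 0.45 else "F")
                        )
                        time_h = rng.uniform(5.0, 13.0)
                        dos = float(day)
                        mass = (
                            mu
                            + truth.allometry * (wing - mean_wing)
                            + clim_term
                            + (cov.juvenile if age == "juvenile" else 0.0)
                            + (cov.male if sex == "M" else 0.0)
                            + cov.time_of_day * (time_h - 9.0)
                            + cov.season * (dos - 63.0)
                            + cov.season2 * (dos - 63.0) ** 2
                            + ind_eff
                            + rng.normal(0.0, truth.residual_sd)
                        )
                        rows.append(
                            {
                                "site": r.site,
                                "species": sp,
                                "individual": ind_id,
                                "date": pd.Timestamp(date),
                                "time": round(time_h, 2),
                                "mass": mass,
                                "wing": wing,
                                "age": age,
                                "sex": sex,
                            }
                        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exposure scenario


def gen_scenario(config: dict[str, object]) -> ExposureScenario:
    """Build an exposure scenario from per-variable projected changes to 2050.

    ``config[var]`` is either a mapping season -> change or (for wind) a
    single annual number replicated across seasons. Supplying sunshine
    raises a warning (no projection exists for it) and is ignored.
    """
    rows = []
    for var, val in config.items():
        if var == "sunshine":
            warnings.warn("no exposure scenario exists for sunshine; ignored")
            continue
        if var not in CLIMATE_VARIABLES:
            raise ValueError(f"unknown climate variable {var!r} in scenario")
        if isinstance(val, (int, float)):
            for season in SEASONS:
                rows.append({"variable": var, "season": season, "change": float(val)})
        else:
            missing = set(SEASONS) - set(val)
            if missing:
                raise ValueError(f"scenario for {var!r} missing seasons {sorted(missing)}")
            for season in SEASONS:
                rows.append({"variable": var, "season": season, "change": float(val[season])})
    return ExposureScenario(pd.DataFrame(rows))


def default_scenario() -> ExposureScenario:
    """A warm, windier, drier-air scenario for 2050 (WH-like shape).

    Temperature and wind rise in all seasons, humidity falls, daily
    temperature range falls except in summer, rainfall rises except in
    summer. Magnitudes are plausible for ~2 degC of warming by 2050; units
    match the climate tables (temp degC, rain 0.1 mm, wind 0.1 m/s,
    humidity %, dtr degC).
    """
    return gen_scenario(
        {
            "temp": {"winter": 2.0, "spring": 1.8, "summer": 2.2, "autumn": 1.9},
            "wind": 1.5,
            "humidity": {"winter": -1.5, "spring": -2.0, "summer": -2.5, "autumn": -1.0},
            "dtr": {"winter": -0.5, "spring": -0.3, "summer": 0.4, "autumn": -0.2},
            "rain": {"winter": 3.0, "spring": 1.5, "summer": -2.5, "autumn": 2.0},
        }
    )


# ---------------------------------------------------------------------------
# direct site-sensitivity generator (for variance-decomposition studies)


def gen_site_sensitivities(
    n_species: int,
    n_sites: int,
    species_sd: float,
    population_sd: float,
    estimate_se: float = 0.02,
    grand_mean: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Site-level sensitivity estimates with a known species signal.

    true s(sp, site) = grand_mean + N(0, species_sd^2)_sp + N(0, population_sd^2)_site;
    the observed estimate adds N(0, estimate_se^2) sampling noise and carries
    ``se = estimate_se``. The true intraclass correlation is
    species_sd^2 / (species_sd^2 + population_sd^2).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 500]))
    rows = []
    for i in range(n_species):
        sp_dev = rng.normal(0.0, species_sd)
        for j in range(n_sites):
            true = grand_mean + sp_dev + rng.normal(0.0, population_sd)
            rows.append(
                {
                    "species": f"sp{i+1:02d}",
                    "site": f"site{j+1:02d}",
                    "estimate": true + rng.normal(0.0, estimate_se),
                    "se": estimate_se,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers


def write_dataset(outdir, design: StudyDesign, climate: pd.DataFrame,
                  captures: pd.DataFrame, truth: TruthSpec,
                  scenario: ExposureScenario | None = None) -> None:
    """Write the dataset as plain-text files (CSV / newick / YAML truth sidecar)."""
    import pathlib

    import yaml

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cap = captures.copy()
    cap["date"] = pd.DatetimeIndex(cap["date"]).strftime("%Y-%m-%d")
    cap.to_csv(outdir / "captures.csv", index=False)
    design.sites.to_csv(outdir / "sites.csv", index=False)
    design.species.to_csv(outdir / "species.csv", index=False)
    for st, grp in climate.groupby("station"):
        g = grp.copy()
        g["date"] = pd.DatetimeIndex(g["date"]).strftime("%Y-%m-%d")
        g.to_csv(outdir / f"climate_{st}.csv", index=False)
    design.tree.write(path=str(outdir / "tree.nwk"), schema="newick")
    truth_dict = {
        "effects": [dataclasses.asdict(e) for e in truth.effects],
        "baseline_mass": {k: float(v) for k, v in truth.baseline_mass.items()},
        "allometry": truth.allometry,
        "individual_sd": truth.individual_sd,
        "residual_sd": truth.residual_sd,
        "covariates": dataclasses.asdict(truth.covariates),
        "recapture_prob": truth.recapture_prob,
    }
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth_dict, fh, sort_keys=True)
    if scenario is not None:
        scenario.table.to_csv(outdir / "scenario.csv", index=False)
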