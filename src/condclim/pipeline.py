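"""End-to-end orchestration: scan -> combine -> sensitivity -> project -> signal -> traits.

Species are processed independently (their window scans and multi-climate
models share nothing), then site-level sensitivity estimates from all
species are pooled for the variance decomposition, trait models and
distance-dissimilarity analyses. Every output table carries the config hash
and seed in a comment header so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import combine as combine_mod
from . import comparative, projection, signal
from .ingest import CLIMATE_VARIABLES, compute_condition
from .sensitivity import filter_extrapolating_sites, make_estimate, sensitivity_table
from .windows import randomization_test

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    stride: int = 1
    max_lag: int = 365
    n_rand: int = 100
    alpha: float = 0.05
    delta_aicc: float = 2.0
    collinearity_r: float = 0.6
    weighting: str = "inverse-se"
    scan_method: str = "ols"        # "ols" | "mixed" | "auto"
    combine_method: str = "ols"     # "ols" | "mixed"
    min_sites: int = 7              # species excluded from pooled analyses below this
    min_species: int = 5            # needed for a variance decomposition
    variables: tuple[str, ...] = CLIMATE_VARIABLES
    seed: int = 0

    def __post_init__(self):
        if min(self.stride, self.n_rand) < 1 or self.alpha <= 0 or self.delta_aicc <= 0:
            raise ValueError("thresholds must be positive")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    windows: pd.DataFrame           # per species x variable scan outcomes
    model_sets: pd.DataFrame        # per species candidate-model table
    sensitivities: pd.DataFrame     # tidy species- and site-level estimates
    projections: pd.DataFrame
    variance_ratios: pd.DataFrame
    traits: pd.DataFrame
    distance_slopes: pd.DataFrame
    concordance: pd.DataFrame
    config: RunConfig
    species_windows: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-species stages


def scan_species(cond_sp, climate, site_to_station, config: RunConfig):
    """Window scan + randomization test for every climate variable."""
    results = {}
    for vi, var in enumerate(config.variables):
        res = randomization_test(
            cond_sp,
            climate,
            variable=var,
            site_to_station=site_to_station,
            n_rand=config.n_rand,
            seed=int((config.seed * 1009 + vi * 131) % 2**31),
            alpha=config.alpha,
            stride=config.stride,
            max_lag=config.max_lag,
            method=config.scan_method,
        )
        results[var] = res
        logger.info(
            "scan %s: window=%s shape=%s dAICc=%.2f p=%.3f",
            var, res.window, res.shape, res.delta_aicc, res.p_value,
        )
    return results


def combine_species(cond_sp, climate, scans, site_to_station, config: RunConfig):
    """Multi-climate model for the signal-bearing variables of one species.

    Returns (averaged species-level model, averaged site-level model,
    model-set table, per-site-year aggregates per variable) or None when no
    variable carries a signal.
    """
    sig = {
        v: r
        for v, r in scans.items()
        if r.p_value is not None and r.p_value < config.alpha and r.delta_aicc > 0
    }
    if not sig:
        return None
    shapes = {v: r.shape for v, r in sig.items()}
    per_row, per_sy, centers = combine_mod.climate_columns(
        cond_sp, climate, sig, site_to_station
    )
    groups = combine_mod.collinear_groups(
        per_sy[list(sig)], threshold=config.collinearity_r
    )
    ms = combine_mod.all_subsets(
        cond_sp, per_row, shapes, groups, method=config.combine_method
    )
    avg = combine_mod.prune_and_average(ms, delta=config.delta_aicc, centers=centers)
    site_avg = None
    if avg.retained and cond_sp["site"].nunique() >= 2:
        site_avg = combine_mod.site_interaction_fit(
            cond_sp, per_row, shapes, avg.retained, groups,
            method=config.combine_method, delta=config.delta_aicc,
        )
    return avg, site_avg, ms.table(), per_sy, shapes


def sensitivities_for_species(sp, cond_sp, avg, site_avg, per_sy, config: RunConfig):
    """Tangent-at-mean sensitivities (gram and percent scales) for one species."""
    mean_mass = float(cond_sp["species_mean_mass"].iloc[0])
    n_years_total = int(cond_sp["year"].nunique())
    site_years = cond_sp.groupby("site")["year"].nunique()
    ests = []
    for var in avg.retained:
        b = avg.coefficients[var]
        C = avg.covariances[var]
        ests.append(
            make_estimate(
                "species", sp, var, b[0], b[1], C, mean_mass, n_years=n_years_total
            )
        )
        if site_avg is None:
            continue
        sy = per_sy.rename(columns={var: "value"})[["site", "year", "value"]]
        retained_sites, _ = filter_extrapolating_sites(sy)
        for key, bs in site_avg.coefficients.items():
            v, site = key
            if v != var or site not in retained_sites:
                continue
            ests.append(
                make_estimate(
                    "site", sp, var, bs[0], bs[1], site_avg.covariances[key],
                    mean_mass, site=site, n_years=int(site_years.get(site, 0)),
                )
            )
    return sensitivity_table(ests)


# ---------------------------------------------------------------------------
# full run


def run_pipeline(
    captures: pd.DataFrame,
    climate: pd.DataFrame,
    sites: pd.DataFrame,
    species_table: pd.DataFrame,
    tree,
    scenario: projection.ExposureScenario | None,
    config: RunConfig,
) -> PipelineResult:
    condition = compute_condition(captures)
    condition["year"] = pd.DatetimeIndex(condition["date"]).year
    site_to_station = dict(zip(sites["site"], sites["station"]))

    window_rows, modelset_frames, sens_frames = [], [], []
    species_windows: dict[str, dict[str, tuple[int, int]]] = {}
    for sp in sorted(condition["species"].unique()):
        cond_sp = condition[condition["species"] == sp].reset_index(drop=True)
        try:
            scans = scan_species(cond_sp, climate, site_to_station, config)
        except Exception as exc:
            raise RuntimeError(f"stage 'scan' failed for species {sp!r}: {exc}") from exc
        for var, r in scans.items():
            window_rows.append(
                {
                    "species": sp, "variable": var,
                    "start": r.window[0], "end": r.window[1],
                    "shape": r.shape, "beta1": r.beta1, "beta2": r.beta2,
                    "delta_aicc": r.delta_aicc, "p_value": r.p_value,
                    "signal": bool(r.p_value < config.alpha and r.delta_aicc > 0),
                }
            )
        try:
            combined = combine_species(cond_sp, climate, scans, site_to_station, config)
        except Exception as exc:
            raise RuntimeError(f"stage 'combine' failed for species {sp!r}: {exc}") from exc
        if combined is None:
            continue
        avg, site_avg, ms_table, per_sy, shapes = combined
        ms_table.insert(0, "species", sp)
        modelset_frames.append(ms_table)
        species_windows[sp] = {v: scans[v].window for v in avg.retained}
        sens_frames.append(
            sensitivities_for_species(sp, cond_sp, avg, site_avg, per_sy, config)
        )

    windows_df = pd.DataFrame(window_rows)
    model_sets = (
        pd.concat(modelset_frames, ignore_index=True) if modelset_frames else pd.DataFrame()
    )
    sens = (
        pd.concat(sens_frames, ignore_index=True)
        if sens_frames
        else pd.DataFrame(
            columns=["level", "species", "site", "variable", "cbar",
                     "s_gram", "se_gram", "s_pct", "se_pct", "n_years"]
        )
    )

    # projections (per species, with its own windows for season matching)
    proj_frames = []
    if scenario is not None:
        for sp, wins in species_windows.items():
            sub = sens[sens["species"] == sp].rename(columns={"se_pct": "se_pct"})
            if sub.empty:
                continue
            proj_frames.append(projection.project(sub, scenario, wins))
    projections_df = (
        pd.concat(proj_frames, ignore_index=True) if proj_frames else pd.DataFrame()
    )

    # species signal: variance decomposition per variable + projections
    site_sens = sens[sens["level"] == "site"].rename(
        columns={"s_pct": "estimate", "se_pct": "se"}
    )
    site_sens = signal.species_exclusion_filter(site_sens, min_sites=config.min_sites)
    decomps = []
    sampling_checks: dict[str, float] = {}
    for var, grp in site_sens.groupby("variable"):
        try:
            decomps.append(
                signal.fit_variance_components(
                    grp, variable=var, weighting=config.weighting,
                    min_species=config.min_species,
                )
            )
        except ValueError as exc:
            logger.warning("variance decomposition skipped for %s: %s", var, exc)
            continue
        # diagnostic: does estimate scatter depend on years sampled per site?
        if grp["n_years"].nunique() > 1:
            sampling_checks[var] = signal.sampling_variance_check(grp)
    if not projections_df.empty:
        proj_sites = projections_df[projections_df["level"] == "site"].rename(
            columns={"total": "estimate", "se": "se"}
        )
        proj_sites = signal.species_exclusion_filter(proj_sites, min_sites=config.min_sites)
        try:
            decomps.append(
                signal.fit_variance_components(
                    proj_sites, variable="projection", weighting=config.weighting,
                    min_species=config.min_species,
                )
            )
        except ValueError as exc:
            logger.warning("variance decomposition skipped for projections: %s", exc)
    variance_df = signal.decomposition_table(decomps)
    if not variance_df.empty:
        variance_df["sampling_check_delta_aicc"] = variance_df["variable"].map(
            sampling_checks
        )

    # trait models
    trait_rows = []
    sp_sens = sens[sens["level"] == "species"].rename(
        columns={"s_pct": "estimate", "se_pct": "se"}
    )
    sp_traits = species_table.rename(columns={"species": "species"})
    for var, grp in sp_sens.groupby("variable"):
        merged = grp.merge(sp_traits, on="species", how="left")
        for trait in ("mean_mass", "migration", "habitat_pref", "life_expectancy"):
            if trait not in merged.columns:
                continue
            try:
                r = comparative.fit_trait_model(
                    merged, trait, level="species", response=f"sensitivity({var})",
                    weighting=config.weighting,
                )
                trait_rows.append(_trait_row(r))
            except ValueError as exc:
                logger.warning("trait model %s/%s skipped: %s", trait, var, exc)
    site_merged_cache = site_sens.merge(
        sites[["site", "habitat"]], on="site", how="left"
    )
    for var, grp in site_merged_cache.groupby("variable"):
        try:
            r = comparative.fit_trait_model(
                grp, "habitat", level="site", response=f"sensitivity({var})",
                weighting=config.weighting,
            )
            trait_rows.append(_trait_row(r))
        except ValueError as exc:
            logger.warning("site trait model habitat/%s skipped: %s", var, exc)
    traits_df = pd.DataFrame(trait_rows)

    # distance-dissimilarity analyses
    dist_rows = []
    try:
        phylo = comparative.phylo_distance(tree, sorted(sp_sens["species"].unique()))
    except ValueError:
        phylo = pd.DataFrame(columns=["a", "b", "distance"])
    for var, grp in sp_sens.groupby("variable"):
        sub = grp[["species", "estimate"]]
        pp = phylo[phylo["a"].isin(sub["species"]) & phylo["b"].isin(sub["species"])]
        if len(pp) >= 3:
            pairs = comparative.dissimilarity_pairs(sub, "species", pp)
            r = comparative.distance_dissimilarity_regression(pairs)
            dist_rows.append(_dist_row("species-phylo", var, None, r))
    geo = comparative.geo_distance(sites)
    for (sp, var), grp in site_sens.groupby(["species", "variable"]):
        sub = grp[["site", "estimate"]]
        gg = geo[geo["a"].isin(sub["site"]) & geo["b"].isin(sub["site"])]
        if len(gg) >= 3:
            pairs = comparative.dissimilarity_pairs(sub, "site", gg)
            try:
                r = comparative.distance_dissimilarity_regression(pairs)
            except ValueError:
                continue
            dist_rows.append(_dist_row("site-geo", var, sp, r))
    distance_df = pd.DataFrame(dist_rows)

    conc_rows = []
    if not windows_df.empty and len(phylo) >= 3:
        for var, grp in windows_df.groupby("variable"):
            flags = grp.rename(columns={"signal": "affected"})[["species", "affected"]]
            flags = flags[flags["species"].isin(set(phylo["a"]) | set(phylo["b"]))]
            if flags["species"].nunique() < 3:
                continue
            pp = phylo[
                phylo["a"].isin(flags["species"]) & phylo["b"].isin(flags["species"])
            ]
            c = comparative.concordance_vs_phylo(flags, pp, variable=var)
            conc_rows.append(
                {
                    "variable": c.variable, "slope": c.slope, "se": c.se,
                    "n_pairs": c.n_pairs, "separation": c.separation,
                }
            )
    concordance_df = pd.DataFrame(conc_rows)

    return PipelineResult(
        windows=windows_df,
        model_sets=model_sets,
        sensitivities=sens,
        projections=projections_df,
        variance_ratios=variance_df,
        traits=traits_df,
        distance_slopes=distance_df,
        concordance=concordance_df,
        config=config,
        species_windows=species_windows,
    )


def _trait_row(r: comparative.TraitModelResult) -> dict:
    return {
        "trait": r.trait,
        "level": r.level,
        "response": r.response,
        "coef": float(r.coef[1]) if len(r.coef) > 1 else np.nan,
        "se": float(r.se[1]) if len(r.se) > 1 else np.nan,
        "aicc_model": r.aicc_model,
        "aicc_null": r.aicc_null,
        "delta_aicc": r.delta_aicc,
    }


def _dist_row(pair_type, var, sp, r: comparative.DistanceRegressionResult) -> dict:
    return {
        "pair_type": pair_type,
        "variable": var,
        "species": sp,
        "slope": r.slope,
        "se": r.se,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "n_pairs": r.n_pairs,
        "significant_positive": r.significant_positive,
    }


# ---------------------------------------------------------------------------
# output


_OUTPUTS = (
    "windows", "model_sets", "sensitivities", "projections",
    "variance_ratios", "traits", "distance_slopes", "concordance",
)


def write_outputs(result: PipelineResult, outdir) -> list[pathlib.Path]:
    """Write every result table as CSV with a config-hash + seed header."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={result.config.hash()} seed={result.config.seed}\n"
    written = []
    for name in _OUTPUTS:
        df: pd.DataFrame = getattr(result, name)
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        written.append(path)
    summary = {
        "config_hash": result.config.hash(),
        "seed": result.config.seed,
        "n_species_scanned": int(result.windows["species"].nunique())
        if not result.windows.empty
        else 0,
        "species_windows": {
            sp: {v: list(w) for v, w in wins.items()}
            for sp, wins in result.species_windows.items()
        },
    }
    path = outdir / "summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(path)
    return written


# ---------------------------------------------------------------------------
# dataset loading (the schemas written by condclim.synthetic)


def load_dataset(datadir):
    """Load a dataset directory into (captures, climate, sites, species, tree, scenario)."""
    import dendropy

    from . import ingest

    datadir = pathlib.Path(datadir)
    captures = ingest.read_captures(datadir / "captures.csv")
    sites = ingest.read_sites(datadir / "sites.csv")
    species = ingest.read_species(datadir / "species.csv")
    climate = pd.concat(
        [ingest.read_climate(p) for p in sorted(datadir.glob("climate_*.csv"))],
        ignore_index=True,
    )
    tree = dendropy.Tree.get(path=str(datadir / "tree.nwk"), schema="newick")
    scenario = None
    scen_path = datadir / "scenario.csv"
    if scen_path.exists():
        scenario = projection.ExposureScenario(pd.read_csv(scen_path, comment="#"))
    return captures, climate, sites, species, tree, scenario
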