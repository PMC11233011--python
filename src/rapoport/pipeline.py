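"""End-to-end orchestration of the two-level range-size analysis.

The pipeline runs: occurrence cleaning → range polygons → equal-area
presence–absence matrix → species and assemblage tables → (a) univariate
latitude ("Rapoport") regressions per level and model, (b) environmental
multiple regressions — AICc multimodel averaging at the cross-species
level, full-model fits at the assemblage level, (c) phylogenetic signal
of every species attribute, and (d) spreading-dye null distributions
with one-tailed percentile tests for every observed slope.  All outputs
are plain CSV plus a run log, fully reproducible from the configured
seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, gridding, nullmodels, stats
from .errors import SchemaError
from .geometry import OccurrenceSet
from .gridding import AlbersParams, EnvLayerSet, Grid, PresenceAbsenceMatrix
from .phylo import Phylogeny
from .synthetic import SimulationConfig, write_world

logger = logging.getLogger(__name__)

#: Predicted sign of each environmental hypothesis (the hypothesis table):
#: climatic extremes (min_temp, −), elevation (−), historical climatic
#: stability (velocity, +), climatic variability (temp_annual_range, +).
DEFAULT_HYPOTHESES = {
    "min_temp": "negative",
    "elevation": "negative",
    "velocity": "positive",
    "temp_annual_range": "positive",
}


@dataclass
class PipelineConfig:
    """Configuration for a full run; defaults mirror the standard design
    (50 km grid and buffer, 100 null replicates, directional hypothesis
    table)."""

    # inputs (any may be None when objects are passed to run_pipeline)
    occurrences_path: str | None = None
    tree_path: str | None = None
    env_raster_paths: dict = field(default_factory=dict)  # layer name -> path
    output_dir: str = "rapoport_out"
    crs: str = "projected-km"
    albers: AlbersParams | None = None
    # grid
    grid_extent: tuple | None = None  # (xmin, ymin, xmax, ymax) km
    cell_size: float = 50.0
    # cleaning
    thinning_resolution: float | None = 18.5
    outlier_multiplier: float = 2.0
    # ranges
    range_method: str = "alpha_hull"
    buffer_km: float = 50.0
    alpha0: float = 10.0
    alpha_growth: float = 1.5
    compare_methods: bool = False
    # analysis
    absolute_latitude: bool = False
    hypotheses: dict = field(default_factory=lambda: dict(DEFAULT_HYPOTHESES))
    models: tuple = ("ols", "pgls", "sar")
    null_models: tuple = ("ols", "pgls", "sar")
    null_levels: tuple = ("cross_species", "assemblage")
    null_analyses: tuple = ("rapoport", "environment")
    sar_schemes: tuple = (
        "row_standardized", "globally_standardized", "variance_stabilizing"
    )
    neighbor_threshold_km: float = 50.0
    velocity_delta_t_years: float = 21000.0
    signal_n_perm: int = 999
    n_rep: int = 100
    adjacency: str = "queen"
    seed: int = 0
    # synthetic block (for the simulate command)
    simulation: SimulationConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "albers" in kwargs and kwargs["albers"] is not None:
            kwargs["albers"] = AlbersParams(**kwargs["albers"])
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            sim = dict(kwargs["simulation"])
            if "domain_extent" in sim:
                sim["domain_extent"] = tuple(sim["domain_extent"])
            kwargs["simulation"] = SimulationConfig(**sim)
        for key in ("models", "null_models", "sar_schemes", "null_levels",
                    "null_analyses"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if "grid_extent" in kwargs and kwargs["grid_extent"] is not None:
            kwargs["grid_extent"] = tuple(kwargs["grid_extent"])
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**kwargs)
        for pred, sign in cfg.hypotheses.items():
            if sign not in {"positive", "negative", "+", "-"}:
                raise SchemaError(
                    f"hypothesis sign for {pred!r} must be +/- (got {sign!r})"
                )
        cfg.hypotheses = {
            k: {"+": "positive", "-": "negative"}.get(v, v)
            for k, v in cfg.hypotheses.items()
        }
        return cfg


@dataclass
class RunReport:
    """Observed and null-tested regression results of one pipeline run."""

    results: pd.DataFrame
    signal: pd.DataFrame
    counts: dict
    vif: pd.Series | None = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out / "regression_results.csv", index=False,
                            float_format="%.10g")
        self.signal.to_csv(out / "phylogenetic_signal.csv", index=False,
                           float_format="%.10g")
        if self.vif is not None:
            self.vif.to_csv(out / "vif.csv", float_format="%.10g")
        pd.Series(self.counts, name="count").to_csv(out / "stage_counts.csv")


# ----------------------------------------------------------------- file input
def read_occurrences(path, crs: str = "projected-km") -> OccurrenceSet:
    """Read an occurrence CSV with columns species and x/longitude,
    y/latitude; reports offending line numbers for bad coordinates."""
    df = pd.read_csv(path, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "species" not in cols:
        raise SchemaError(f"{path}: missing required column 'species'")
    xcol = cols.get("x") or cols.get("longitude") or cols.get("lon")
    ycol = cols.get("y") or cols.get("latitude") or cols.get("lat")
    if xcol is None or ycol is None:
        raise SchemaError(
            f"{path}: need coordinate columns x/longitude and y/latitude"
        )
    x = pd.to_numeric(df[xcol], errors="coerce")
    y = pd.to_numeric(df[ycol], errors="coerce")
    bad = (x.isna() & df[xcol].notna()) | (y.isna() & df[ycol].notna())
    if bad.any():
        lines = (bad[bad].index + 2).tolist()  # 1-based + header row
        raise SchemaError(
            f"{path}: unparseable coordinates on lines {lines[:20]}"
        )
    table = pd.DataFrame({"species": df[cols["species"]], "x": x, "y": y})
    return OccurrenceSet(table, crs=crs)


def read_tree(path) -> Phylogeny:
    """Read a rooted Newick tree (polytomies resolved to zero-length
    bifurcations)."""
    return Phylogeny.from_newick(Path(path))


def load_env_layers(paths: dict, grid: Grid) -> EnvLayerSet:
    """Read ESRI ASCII rasters and align them to the analysis grid,
    block-averaging any finer raster onto it."""
    layers = {}
    for name, p in paths.items():
        values, fine = gridding.read_ascii_grid(p)
        if (fine.origin == grid.origin and fine.cell_size == grid.cell_size
                and fine.n_rows == grid.n_rows and fine.n_cols == grid.n_cols):
            layers[name] = values
        else:
            layers[name] = gridding.resample_env_to_grid(values, fine, grid)
    return EnvLayerSet(grid, layers)


def prepare_env(env: EnvLayerSet, cfg: PipelineConfig) -> EnvLayerSet:
    """Derive the velocity layer from present/past mean annual temperature
    when it is not supplied directly."""
    layers = dict(env.layers)
    if "velocity" not in layers and "mat" in layers and "mat_past" in layers:
        layers["velocity"] = gridding.climate_change_velocity(
            layers["mat"], layers["mat_past"], cfg.velocity_delta_t_years,
            env.grid.cell_size,
        )
    layers.pop("mat", None)
    layers.pop("mat_past", None)
    return EnvLayerSet(env.grid, layers)


# ------------------------------------------------------------- fitting helpers
def _standardize_frame(df: pd.DataFrame, cols) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for c in cols:
        out[c] = stats.zscore(df[c].to_numpy(dtype=float))
    return out


def _slope_row(level, analysis, model, predictor, fitted, slope, extra=None):
    row = {
        "level": level,
        "analysis": analysis,
        "model": model,
        "predictor": predictor,
        "slope": slope,
        "r2": getattr(fitted, "r2_", np.nan) if fitted is not None else np.nan,
        "lambda": getattr(fitted, "lambda_", np.nan) if fitted is not None else np.nan,
        "rho": getattr(fitted, "rho_", np.nan) if fitted is not None else np.nan,
        "aicc": getattr(fitted, "aicc_", np.nan) if fitted is not None else np.nan,
        "p_value": np.nan,
        "weight_scheme": "",
    }
    if extra:
        row.update(extra)
    return row


def _best_sar(y, X, coords, cfg: PipelineConfig):
    """OLS plus the three SAR weight schemes; return (tag, fitted dict,
    chosen name) under the lowest-AIC / highest-R² rule."""
    cand = {"ols": stats.OLS().fit(X, y)}
    for scheme in cfg.sar_schemes:
        w = stats.build_spatial_weights(
            coords, threshold_km=cfg.neighbor_threshold_km, scheme=scheme
        )
        cand[f"sar_{scheme}"] = stats.SARError(weights=w).fit(X, y)
    choice = stats.select_spatial_model(cand)
    return cand, choice


# --------------------------------------------------------------- main driver
def run_pipeline(
    cfg: PipelineConfig,
    occ: OccurrenceSet | None = None,
    tree: Phylogeny | None = None,
    env: EnvLayerSet | None = None,
    grid: Grid | None = None,
) -> RunReport:
    """Execute the full two-level analysis.

    Inputs may be passed directly (synthetic runs, tests) or read from
    the paths in ``cfg``.  Returns a :class:`RunReport` and writes all
    tables to ``cfg.output_dir``.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    counts: dict[str, int] = {}

    def log(msg):
        logger.info(msg)
        log_lines.append(msg)

    # ---- occurrences
    if occ is None:
        if cfg.occurrences_path is None:
            raise ValueError("no occurrences provided")
        occ = read_occurrences(cfg.occurrences_path, crs=cfg.crs)
    counts["records_raw"] = len(occ)
    counts["species_raw"] = len(occ.species)
    log(f"stage=read records={len(occ)} species={len(occ.species)}")

    if occ.crs == "lonlat-degrees":
        if cfg.albers is None:
            raise ValueError("lonlat occurrences require Albers parameters")
        x, y = gridding.project_lonlat(
            occ.table["x"].to_numpy(), occ.table["y"].to_numpy(), cfg.albers
        )
        occ = OccurrenceSet(
            pd.DataFrame({"species": occ.table["species"], "x": x, "y": y}),
            crs="projected-km",
        )
        log("stage=project crs=projected-km")

    # ---- cleaning
    occ = geometry.dedupe_records(occ)
    counts["records_deduped"] = len(occ)
    if cfg.thinning_resolution:
        occ = geometry.thin_to_grid(occ, cfg.thinning_resolution)
    counts["records_thinned"] = len(occ)
    occ = geometry.remove_spatial_outliers(occ, cfg.outlier_multiplier)
    counts["records_clean"] = len(occ)
    counts["species_clean"] = len(occ.species)
    log(
        f"stage=clean records={len(occ)} species={len(occ.species)} "
        f"(dedupe->{counts['records_deduped']} thin->{counts['records_thinned']})"
    )

    # ---- ranges
    ranges, skipped = geometry.build_ranges(
        occ, method=cfg.range_method, buffer_km=cfg.buffer_km,
        alpha0=cfg.alpha0, growth=cfg.alpha_growth,
    )
    counts["species_with_range"] = len(ranges)
    log(f"stage=ranges method={cfg.range_method} built={len(ranges)} "
        f"skipped={len(skipped)}")
    geometry.write_ranges_geojson(ranges, out_dir / "ranges.geojson")
    geometry.ranges_summary_table(ranges).to_csv(
        out_dir / "range_sizes.csv", index=False, float_format="%.10g"
    )
    if cfg.compare_methods:
        other = "convex_hull" if cfg.range_method == "alpha_hull" else "alpha_hull"
        ranges_b, _ = geometry.build_ranges(
            occ, method=other, buffer_km=cfg.buffer_km,
            alpha0=cfg.alpha0, growth=cfg.alpha_growth,
        )
        sizes = pd.DataFrame(
            {
                cfg.range_method: {r.species: r.area_km2 for r in ranges},
                other: {r.species: r.area_km2 for r in ranges_b},
            }
        )
        geometry.compare_range_methods(sizes).to_csv(
            out_dir / "method_spearman.csv", float_format="%.10g"
        )

    # ---- grid + PAM
    if grid is None:
        if cfg.grid_extent is not None:
            grid = Grid.from_extent(cfg.grid_extent, cfg.cell_size)
        else:
            bounds = np.array([r.geometry.bounds for r in ranges])
            extent = (
                bounds[:, 0].min(), bounds[:, 1].min(),
                bounds[:, 2].max(), bounds[:, 3].max(),
            )
            grid = Grid.from_extent(extent, cfg.cell_size)
    pam = gridding.rasterize_ranges(ranges, grid)
    counts["species_in_pam"] = pam.n_species
    counts["sites_occupied"] = int(pam.occupied_sites().size)
    log(f"stage=grid cells={grid.n_cells} occupied={counts['sites_occupied']} "
        f"species={pam.n_species}")
    pam.write_csv(out_dir / "pam.csv")

    # ---- environment
    if env is None and cfg.env_raster_paths:
        env = load_env_layers(cfg.env_raster_paths, grid)
    if env is not None:
        env = prepare_env(env, cfg)
        predictors = [p for p in cfg.hypotheses if p in env]
    else:
        predictors = []

    # ---- tables
    species_table = gridding.build_species_table(
        pam, env, absolute_latitude=cfg.absolute_latitude
    )
    species_table.to_csv(out_dir / "species_table.csv", float_format="%.10g")
    assemblage = gridding.assemblage_median_log_range(
        pam, species_table, env, absolute_latitude=cfg.absolute_latitude
    )
    assemblage.to_csv(out_dir / "assemblage_table.csv", float_format="%.10g")

    # ---- tree matching
    if tree is None and cfg.tree_path is not None:
        tree = read_tree(cfg.tree_path)
    pgls_species: list[str] = []
    if tree is not None:
        tips = set(tree.tip_labels)
        pgls_species = [s for s in species_table.index if s in tips]
        extra_tips = tips - set(species_table.index)
        if extra_tips:
            log(f"stage=tree pruned_tips={len(extra_tips)}")
            tree = tree.prune_to(pgls_species)
        dropped = [s for s in species_table.index if s not in tips]
        if dropped:
            log(f"stage=tree species_without_tips={len(dropped)} "
                f"(excluded from PGLS/signal)")
        counts["species_in_tree"] = len(pgls_species)

    results: list[dict] = []
    use_pgls = tree is not None and "pgls" in cfg.models and len(pgls_species) >= 4
    use_sar = "sar" in cfg.models

    # responses standardized before fitting (asserted in the run log)
    log("response: cross_species=z(log_range_size) "
        "assemblage=z(median_log_range)")

    # ---- Rapoport: univariate latitude regressions
    z_sp = _standardize_frame(species_table, ["log_range_size", "midpoint_lat"])
    ols_rap = stats.OLS().fit(z_sp[["midpoint_lat"]].to_numpy(),
                              z_sp["log_range_size"].to_numpy())
    results.append(_slope_row(
        "cross_species", "rapoport", "ols", "midpoint_lat", ols_rap,
        float(ols_rap.coef_[0]),
        {"p_value": float(ols_rap.pvalues_[0]) if hasattr(ols_rap, "pvalues_")
         else np.nan},
    ))
    if use_pgls:
        sub = species_table.loc[pgls_species]
        zs = _standardize_frame(sub, ["log_range_size", "midpoint_lat"])
        pg = stats.PGLS(tree=tree).fit(
            zs[["midpoint_lat"]].to_numpy(), zs["log_range_size"].to_numpy(),
            species=pgls_species,
        )
        results.append(_slope_row(
            "cross_species", "rapoport", "pgls", "midpoint_lat", pg,
            float(pg.coef_[0]),
        ))
    z_as = _standardize_frame(assemblage, ["median_log_range", "lat"])
    coords = assemblage[["x", "y"]].to_numpy()
    ols_as = stats.OLS().fit(z_as[["lat"]].to_numpy(),
                             z_as["median_log_range"].to_numpy())
    results.append(_slope_row(
        "assemblage", "rapoport", "ols", "lat", ols_as, float(ols_as.coef_[0])
    ))
    if use_sar:
        cand, choice = _best_sar(
            z_as["median_log_range"].to_numpy(), z_as[["lat"]].to_numpy(),
            coords, cfg,
        )
        sar_name = choice if choice.startswith("sar") else max(
            (k for k in cand if k.startswith("sar")),
            key=lambda k: cand[k].loglik_,
        )
        sar_fit = cand[sar_name]
        results.append(_slope_row(
            "assemblage", "rapoport", "sar", "lat", sar_fit,
            float(sar_fit.coef_[0]),
            {"weight_scheme": sar_name.replace("sar_", ""),
             "model_choice": choice},
        ))

    # ---- environmental hypotheses
    vif_series = None
    if predictors:
        sp_env = species_table.dropna(subset=predictors + ["log_range_size"])
        n_dropped = len(species_table) - len(sp_env)
        if n_dropped:
            log(f"stage=env dropped_species_with_masked_env={n_dropped}")
        z_env = _standardize_frame(sp_env, ["log_range_size"] + predictors)
        vif_series = pd.Series(
            stats.vif(z_env[predictors].to_numpy()), index=predictors, name="vif"
        )
        log("vif: " + " ".join(f"{k}={v:.3g}" for k, v in vif_series.items()))
        # cross-species: all-subsets AICc averaging
        if "ols" in cfg.models:
            ms = stats.multimodel_inference(
                z_env["log_range_size"].to_numpy(), z_env[predictors]
            )
            for p in predictors:
                results.append(_slope_row(
                    "cross_species", "environment", "ols", p, None,
                    float(ms.averaged[p]), {"averaged": True},
                ))
        if use_pgls:
            sub = sp_env.loc[[s for s in pgls_species if s in sp_env.index]]
            tree_env = tree.prune_to(list(sub.index)) \
                if len(sub) < len(pgls_species) else tree
            zp = _standardize_frame(sub, ["log_range_size"] + predictors)
            fitter = lambda Xs, ys: stats.PGLS(tree=tree_env).fit(
                Xs, ys, species=list(sub.index))
            ms = stats.multimodel_inference(
                zp["log_range_size"].to_numpy(), zp[predictors], fitter=fitter
            )
            for p in predictors:
                results.append(_slope_row(
                    "cross_species", "environment", "pgls", p, None,
                    float(ms.averaged[p]), {"averaged": True},
                ))
        # assemblage: full model (no averaging), OLS + best SAR
        as_env = assemblage.dropna(subset=predictors + ["median_log_range"])
        za = _standardize_frame(as_env, ["median_log_range"] + predictors)
        ols_full = stats.OLS().fit(za[predictors].to_numpy(),
                                   za["median_log_range"].to_numpy())
        for i, p in enumerate(predictors):
            results.append(_slope_row(
                "assemblage", "environment", "ols", p, ols_full,
                float(ols_full.coef_[i]),
            ))
        if use_sar:
            cand, choice = _best_sar(
                za["median_log_range"].to_numpy(), za[predictors].to_numpy(),
                as_env[["x", "y"]].to_numpy(), cfg,
            )
            sar_name = choice if choice.startswith("sar") else max(
                (k for k in cand if k.startswith("sar")),
                key=lambda k: cand[k].loglik_,
            )
            sar_fit = cand[sar_name]
            for i, p in enumerate(predictors):
                results.append(_slope_row(
                    "assemblage", "environment", "sar", p, sar_fit,
                    float(sar_fit.coef_[i]),
                    {"weight_scheme": sar_name.replace("sar_", ""),
                     "model_choice": choice},
                ))

    # ---- phylogenetic signal on species attributes
    signal_rows = []
    if tree is not None and len(pgls_species) >= 4:
        sub = species_table.loc[pgls_species]
        attrs = ["midpoint_lat", "log_range_size"] + predictors
        for i, attr in enumerate(attrs):
            vals = sub[attr].to_numpy(dtype=float)
            good = np.isfinite(vals)
            if good.sum() < 4 or np.unique(vals[good]).size < 2:
                continue
            keep = [s for s, g in zip(pgls_species, good) if g]
            t_attr = tree.prune_to(keep) if good.sum() < len(pgls_species) else tree
            res = stats.phylogenetic_signal(
                vals[good], t_attr, n_perm=cfg.signal_n_perm,
                seed=cfg.seed + 1000 + i, species=keep,
            )
            signal_rows.append({
                "trait": attr, "K": res.K, "p_K": res.p_K,
                "lambda": res.lam, "p_lambda": res.p_lambda,
            })
    signal = pd.DataFrame(
        signal_rows, columns=["trait", "K", "p_K", "lambda", "p_lambda"]
    )

    # ---- null models
    results_df = pd.DataFrame(results)
    results_df = _attach_nulls(
        results_df, cfg, pam, env, tree, pgls_species, predictors
    )

    report = RunReport(results=results_df, signal=signal, counts=counts,
                       vif=vif_series)
    report.write(out_dir)
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return report


# ------------------------------------------------------------- null machinery
def _attach_nulls(results, cfg, pam, env, tree, pgls_species, predictors):
    """Compute a spreading-dye null distribution and one-tailed test for
    every observed slope row whose model is in cfg.null_models."""
    results = results.copy()
    results["null_cutoff"] = np.nan
    results["null_mean"] = np.nan
    results["null_sd"] = np.nan
    results["significant"] = pd.array([None] * len(results), dtype="boolean")
    results["predicted_sign"] = ""
    domain = pam.occupied_sites()
    null_records = []
    for ridx, row in results.iterrows():
        model = row["model"]
        if (model not in cfg.null_models
                or row["level"] not in cfg.null_levels
                or row["analysis"] not in cfg.null_analyses):
            continue
        if row["analysis"] == "rapoport":
            sign = "positive"
        else:
            sign = cfg.hypotheses.get(row["predictor"])
        if sign is None:
            continue
        fit_fn = _make_rebuilder(row, cfg, env, tree, pgls_species, predictors)
        if fit_fn is None:
            continue
        dist = nullmodels.null_slope_distribution(
            pam, fit_fn, predictor=row["predictor"], n_rep=cfg.n_rep,
            seed=cfg.seed + 7919 * (ridx + 1), domain=domain,
            adjacency=cfg.adjacency, predicted_sign=sign,
            label=f"{row['level']}|{row['model']}|{row['predictor']}",
        )
        # the observed slope was already fitted; keep the reported value
        dist.observed = float(row["slope"])
        nullmodels.one_tailed_test(dist)
        results.loc[ridx, "null_cutoff"] = dist.cutoff
        results.loc[ridx, "null_mean"] = float(dist.replicates.mean())
        results.loc[ridx, "null_sd"] = float(dist.replicates.std(ddof=1))
        results.loc[ridx, "significant"] = dist.significant
        results.loc[ridx, "predicted_sign"] = sign
        for rep_i, slope in enumerate(dist.replicates):
            null_records.append({
                "level": row["level"], "analysis": row["analysis"],
                "model": model, "predictor": row["predictor"],
                "replicate": rep_i, "slope": slope,
            })
    if null_records:
        pd.DataFrame(null_records).to_csv(
            Path(cfg.output_dir) / "null_slopes.csv", index=False,
            float_format="%.10g",
        )
    return results


def _make_rebuilder(row, cfg, env, tree, pgls_species, predictors):
    """Closure recomputing the row's standardized slope from a (possibly
    randomized) PAM; environmental layers stay fixed."""
    level = row["level"]
    analysis = row["analysis"]
    model = row["model"]
    predictor = row["predictor"]

    def species_frame(p):
        return gridding.build_species_table(
            p, env, absolute_latitude=cfg.absolute_latitude
        )

    if level == "cross_species" and analysis == "rapoport":
        if model == "ols":
            def fn(p):
                t = species_frame(p)
                z = _standardize_frame(t, ["log_range_size", "midpoint_lat"])
                f = stats.OLS().fit(z[["midpoint_lat"]].to_numpy(),
                                    z["log_range_size"].to_numpy())
                return f.coef_[0]
            return fn
        if model == "pgls" and tree is not None:
            def fn(p):
                t = species_frame(p)
                keep = [s for s in pgls_species if s in t.index]
                sub = t.loc[keep]
                z = _standardize_frame(sub, ["log_range_size", "midpoint_lat"])
                f = stats.PGLS(tree=tree).fit(
                    z[["midpoint_lat"]].to_numpy(),
                    z["log_range_size"].to_numpy(), species=keep,
                )
                return f.coef_[0]
            return fn
    if level == "cross_species" and analysis == "environment":
        if model == "ols":
            def fn(p):
                t = species_frame(p).dropna(subset=predictors + ["log_range_size"])
                z = _standardize_frame(t, ["log_range_size"] + predictors)
                ms = stats.multimodel_inference(
                    z["log_range_size"].to_numpy(), z[predictors]
                )
                return ms.averaged[predictor]
            return fn
        if model == "pgls" and tree is not None:
            def fn(p):
                t = species_frame(p)
                keep = [s for s in pgls_species if s in t.index]
                sub = t.loc[keep].dropna(subset=predictors + ["log_range_size"])
                keep = list(sub.index)
                t_sub = tree.prune_to(keep) if len(keep) < len(pgls_species) else tree
                z = _standardize_frame(sub, ["log_range_size"] + predictors)
                fitter = lambda Xs, ys: stats.PGLS(tree=t_sub).fit(
                    Xs, ys, species=keep)
                ms = stats.multimodel_inference(
                    z["log_range_size"].to_numpy(), z[predictors], fitter=fitter
                )
                return ms.averaged[predictor]
            return fn
    if level == "assemblage":
        scheme = row.get("weight_scheme", "") or "row_standardized"

        def assemble(p):
            t = species_frame(p)
            a = gridding.assemblage_median_log_range(
                p, t, env, absolute_latitude=cfg.absolute_latitude
            )
            return a

        if analysis == "rapoport":
            resp, cols = "median_log_range", ["lat"]
        else:
            resp, cols = "median_log_range", predictors

        if model == "ols":
            def fn(p):
                a = assemble(p).dropna(subset=cols + [resp])
                z = _standardize_frame(a, [resp] + cols)
                f = stats.OLS().fit(z[cols].to_numpy(), z[resp].to_numpy())
                return f.coef_[cols.index(predictor)] if predictor in cols \
                    else f.coef_[0]
            return fn
        if model == "sar":
            def fn(p):
                a = assemble(p).dropna(subset=cols + [resp])
                z = _standardize_frame(a, [resp] + cols)
                w = stats.build_spatial_weights(
                    a[["x", "y"]].to_numpy(),
                    threshold_km=cfg.neighbor_threshold_km, scheme=scheme,
                )
                f = stats.SARError(weights=w).fit(
                    z[cols].to_numpy(), z[resp].to_numpy()
                )
                return f.coef_[cols.index(predictor)] if predictor in cols \
                    else f.coef_[0]
            return fn
    return None


# ------------------------------------------------------------------- simulate
def simulate_command(cfg: PipelineConfig) -> list[Path]:
    """Write the synthetic world (occurrences, truth, tree, env rasters)
    described by the config's simulation block."""
    if cfg.simulation is None:
        raise ValueError("config has no 'simulation' block")
    return write_world(cfg.simulation, cfg.output_dir)
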