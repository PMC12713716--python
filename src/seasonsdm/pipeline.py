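"""End-to-end pipeline: simulate -> screen -> pseudo-absences -> fit -> map -> niche.

A single :class:`PipelineConfig` drives the full synthetic study: landscape and
virtual-species generation, the seasonal collinearity screen, both
pseudo-absence methods, the factorial model design with cross-validation,
monthly suitability maps with interval classification and range polygons, the
optima summary and the niche-dynamics comparison.  Every stage derives its own
seed deterministically from the master seed (CRC-32 of the stage name), so a
rerun with the same config and seed reproduces byte-identical tabular outputs
and individual stages can be rerun in isolation.  A manifest lists every
output file, every stage seed, library versions and the model count.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from seasonsdm.envio import (
    DEFAULT_SEASON_BINS,
    EnvStack,
    ScreenConfig,
    month_to_bin,
    pearson_screen,
    thin_occurrences,
)
from seasonsdm.mapper import (
    average_maps,
    classify_map,
    min_convex_polygon,
    optima_summary,
    predict_map,
)
from seasonsdm.nichedyn import (
    OUTBREAK_MONTHS,
    buffer_background,
    density_grid,
    fit_niche_space,
    niche_dynamics,
    variable_occupancy,
)
from seasonsdm.pabs import SamplerConfig, sample_rs, sample_rsep
from seasonsdm.sdmfit import build_model_dataset, run_design
from seasonsdm.synthgrid import (
    LandscapeConfig,
    default_virtual_species,
    generate_env_stack,
    sample_occurrences,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "screen", "pabs", "fit", "predict", "niche")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic pipeline run."""

    outdir: str = "pipeline_output"
    seed: int = 0
    # landscape / species
    n_rows: int = 60
    n_cols: int = 60
    cell_size_km: float = 25.0
    years: tuple[int, ...] = (2014, 2015, 2016)
    n_per_month: int = 50  # presences per month per year
    # pseudo-absences
    methods: tuple[str, ...] = ("RS", "RSEP")
    n_sets: int = 5
    radius_km: float = 500.0
    candidates_per_presence: int = 30
    # screen
    r_threshold: float = 0.8
    # modelling / validation
    run_cv: bool = True
    cv_folds: int = 5
    # maps
    map_months: tuple[int, ...] = tuple(range(1, 13))
    map_method: str = "RSEP"
    n_bins: int = 10
    # niche
    outbreak_months: tuple[int, ...] = OUTBREAK_MONTHS
    occupancy_threshold: float = 0.05
    season_bins: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: dict(DEFAULT_SEASON_BINS)
    )

    def landscape_config(self, seed: int) -> LandscapeConfig:
        return LandscapeConfig(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            cell_size_km=self.cell_size_km,
            years=tuple(self.years),
            seed=seed,
        )

    def sampler_config(self, seed: int) -> SamplerConfig:
        return SamplerConfig(
            radius_km=self.radius_km,
            n_sets=self.n_sets,
            candidates_per_presence=self.candidates_per_presence,
            seed=seed,
            season_bins=dict(self.season_bins),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("years", "methods", "map_months", "outbreak_months"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "season_bins" in raw:
            raw["season_bins"] = {k: tuple(v) for k, v in raw["season_bins"].items()}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["season_bins"] = {k: list(v) for k, v in d["season_bins"].items()}
        for key in ("years", "methods", "map_months", "outbreak_months"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _write_csv(df: pd.DataFrame, path: Path, manifest_files: list[str]) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest_files.append(path.name)


def run_pipeline(config: PipelineConfig, stages: Sequence[str] = ALL_STAGES) -> dict:
    """Execute the requested pipeline stages in order and return the manifest.

    Stages not requested are still executed in memory when a later stage needs
    their products (everything is deterministic from the master seed), but only
    requested stages write their output files.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    files: list[str] = []
    seeds = {s: stage_seed(config.seed, s) for s in ALL_STAGES}
    manifest: dict = {"config": json.loads(json.dumps(asdict(config), default=list)),
                      "seeds": seeds, "stages_run": stages}

    # ---------------------------------------------------------------- simulate
    logger.info("stage simulate: generating landscape and occurrences")
    land = config.landscape_config(seeds["simulate"])
    stack = generate_env_stack(land)
    species = default_virtual_species()
    raw_occ = sample_occurrences(
        species, stack, {m: config.n_per_month for m in range(1, 13)}, seeds["simulate"] + 1
    )
    presences = thin_occurrences(raw_occ, stack.grid)
    if "simulate" in stages:
        stack.to_netcdf(outdir / "stack.nc")
        files.append("stack.nc")
        _write_csv(presences[["lon", "lat", "year", "month"]], outdir / "occurrences.csv", files)
    presences = thin_occurrences(presences, stack.grid)  # ensures cell ids present
    all_variables = [v for v in stack.variables]

    # ------------------------------------------------------------------ screen
    logger.info("stage screen: seasonal Pearson collinearity screen")
    screen_cfg = ScreenConfig(r_threshold=config.r_threshold,
                              season_bins=dict(config.season_bins))
    rs_cfg = config.sampler_config(seeds["screen"])
    rs_sets_screen = sample_rs(presences, stack, rs_cfg)
    datasets_by_bin: dict[str, list[pd.DataFrame]] = {b: [] for b in config.season_bins}
    for pa in rs_sets_screen:
        for subset, months in config.season_bins.items():
            ds = build_model_dataset(presences, pa, stack, all_variables, subset, months)
            datasets_by_bin[subset].append(ds)
    selected, matrices = pearson_screen(datasets_by_bin, screen_cfg, variables=all_variables)
    manifest["screen"] = {"selected_variables": selected,
                          "n_matrices": len(matrices)}
    if "screen" in stages:
        for bin_name, mat in matrices.items():
            p = outdir / f"pearson_{bin_name}.csv"
            mat.to_csv(p, float_format="%.10g")
            files.append(p.name)
        (outdir / "selected_variables.json").write_text(json.dumps(selected, indent=1))
        files.append("selected_variables.json")

    # -------------------------------------------------------------------- pabs
    sampler_cfg = config.sampler_config(seeds["pabs"])
    if "pabs" in stages:
        logger.info("stage pabs: writing pseudo-absence sets")
        for method in config.methods:
            sets = (
                sample_rs(presences, stack, sampler_cfg)
                if method == "RS"
                else sample_rsep(presences, stack, selected, sampler_cfg)
            )
            for pa in sets:
                p = outdir / f"pabs_{method}_{pa.attrs['set_id']}.csv"
                _write_csv(pa, p, files)

    # --------------------------------------------------------------------- fit
    logger.info("stage fit: %d methods x %d sets x %d subsets",
                len(config.methods), config.n_sets, len(config.season_bins))
    design = run_design(
        presences,
        stack,
        selected,
        methods=config.methods,
        sampler_config=sampler_cfg,
        season_bins=config.season_bins,
        run_cv=config.run_cv,
        cv_folds=config.cv_folds,
        seed=seeds["fit"],
    )
    manifest["n_models"] = design.n_models
    if "fit" in stages:
        models_json = {
            f"{m}|set{s}|{sub}": fitted.to_dict()
            for (m, s, sub), fitted in sorted(design.models.items())
        }
        (outdir / "models.json").write_text(json.dumps(models_json, indent=1, sort_keys=True))
        files.append("models.json")
        _write_csv(design.variable_frequency, outdir / "variable_frequency.csv", files)
        common = pd.DataFrame(
            [{"method": m, "subset": s, "common_variables": ",".join(v)}
             for (m, s), v in sorted(design.common_variables.items())]
        )
        _write_csv(common, outdir / "common_variables.csv", files)
        if design.cv_report is not None:
            _write_csv(design.cv_report, outdir / "cv_report.csv", files)

    # ----------------------------------------------------------------- predict
    if "predict" in stages:
        map_method = (
            config.map_method if config.map_method in config.methods else config.methods[-1]
        )
        logger.info("stage predict: monthly suitability maps (%s)", map_method)
        m2b = month_to_bin(config.season_bins)
        import xarray as xr

        xs, ys = stack.grid.cell_centers()
        data_vars = {}
        for month in config.map_months:
            subset = m2b[month]
            sub_models = design.models_for(map_method, subset)
            maps = [
                predict_map(model, stack, month, year)
                for model in sub_models
                for year in config.years
            ]
            avg = average_maps(maps)
            data_vars[f"suitability_{month:02d}"] = (("y", "x"), avg.values)
            data_vars[f"bins_{month:02d}"] = (("y", "x"), classify_map(avg, config.n_bins))
        ds = xr.Dataset(data_vars, coords={"x": xs, "y": ys})
        ds.to_netcdf(outdir / "suitability.nc", engine="scipy")
        files.append("suitability.nc")

        # minimum convex polygons per month with >= 3 distinct presence cells
        polys = {}
        for month in config.map_months:
            sub = presences[presences["month"] == month]
            if len(sub.drop_duplicates("cell_id")) >= 3:
                try:
                    verts = min_convex_polygon(sub)
                except Exception:
                    continue
                polys[str(month)] = verts.tolist()
        geojson = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"month": int(m)},
                    "geometry": {"type": "Polygon",
                                 "coordinates": [v + [v[0]]]},
                }
                for m, v in polys.items()
            ],
        }
        (outdir / "mcp.geojson").write_text(json.dumps(geojson))
        files.append("mcp.geojson")

        period_models = {
            subset: design.models_for(map_method, subset)
            for subset in config.season_bins
        }
        optima = optima_summary(period_models, stack, presences, selected,
                                config.season_bins)
        _write_csv(optima, outdir / "optima.csv", files)

    # ------------------------------------------------------------------- niche
    if "niche" in stages:
        logger.info("stage niche: PCA niche dynamics")
        background = buffer_background(presences, stack, selected, config.radius_km)
        space = fit_niche_space(background, selected)
        from seasonsdm.envio import extract_env

        pres_cov = extract_env(stack, presences, selected)
        is_out_p = pres_cov["month"].isin(config.outbreak_months)
        is_out_b = background["month"].isin(config.outbreak_months)
        bg_scores = space.transform(background)
        grids = {}
        for period, pmask, bmask in (
            ("outbreak", is_out_p, is_out_b),
            ("non_outbreak", ~is_out_p, ~is_out_b),
        ):
            grids[period] = density_grid(
                space.transform(pres_cov[pmask]),
                bg_scores[bmask.to_numpy()],
                period=period,
                seed=seeds["niche"],
                window_scores=bg_scores,  # shared pooled window
            )
        indices = niche_dynamics(
            grids["outbreak"], grids["non_outbreak"],
            occupancy_threshold=config.occupancy_threshold,
        )
        (outdir / "niche_indices.json").write_text(
            json.dumps(indices.as_dict(), indent=1)
        )
        files.append("niche_indices.json")

        curve_rows = []
        for var in selected:
            try:
                curves = variable_occupancy(
                    {
                        "outbreak": pres_cov.loc[is_out_p, var].to_numpy(),
                        "non_outbreak": pres_cov.loc[~is_out_p, var].to_numpy(),
                    },
                    {
                        "outbreak": background.loc[is_out_b, var].to_numpy(),
                        "non_outbreak": background.loc[~is_out_b, var].to_numpy(),
                    },
                    var,
                )
            except Exception as exc:
                logger.warning("variable_occupancy(%s) skipped: %s", var, exc)
                continue
            for period in ("outbreak", "non_outbreak"):
                curve_rows.append(
                    pd.DataFrame(
                        {
                            "variable": var,
                            "period": period,
                            "x": curves.x,
                            "availability": curves.availability[period],
                            "occupancy": curves.occupancy[period],
                        }
                    )
                )
        if curve_rows:
            _write_csv(pd.concat(curve_rows, ignore_index=True),
                       outdir / "occupancy_curves.csv", files)
        manifest["niche_indices"] = indices.as_dict()

    # ---------------------------------------------------------------- manifest
    import scipy
    import sklearn
    import statsmodels

    import seasonsdm

    manifest["files"] = files
    manifest["versions"] = {
        "seasonsdm": seasonsdm.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
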