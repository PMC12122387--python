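"""End-to-end orchestration: simulate/load -> size-correct -> morphospace ->
vectors/theta -> reference-effect and distance-decay models, with every table
written to a run directory and a manifest recording settings, versions and
seed so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mfdiv import geo_env, models, morphospace, preprocess, simulate, vectors
from mfdiv.morphospace import PANMICTIC

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"  # 12 significant digits so byte-identity is meaningful


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Settings of one full analysis run (synthetic by default)."""

    outdir: str = "results/run"
    seed: int = 0
    sim: simulate.SimConfig | None = None  # None -> defaults with this seed
    specimens_csv: str | None = None  # load instead of simulate
    metadata_csv: str | None = None
    climate_csv: str | None = None
    raster_ascii: str | None = None
    allometry_grouping: str = "per_population"  # or "common"
    exempt_plates_globally: bool = False
    levene_center: str = "median"
    pca_scale: bool = True
    vector_axes: list | None = None  # None -> all PCs
    divergence_axis: str = "PC1"
    percent_change_normalize: str = "max"
    connectivity: int = 8
    raster_shape: tuple = (60, 60)
    raster_resolution_km: float = 5.0
    climate_threshold: float = 0.80
    env_axes: tuple = ("PC1", "PC2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = simulate.SimConfig(**sim)
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FMT)


def _model_summary_rows(name: str, fit: models.LmmFit) -> pd.DataFrame:
    coef = fit.coefficients.copy()
    coef.insert(0, "model", name)
    coef["random_intercept_variance"] = (
        np.nan if fit.random_intercept_variance is None
        else fit.random_intercept_variance
    )
    coef["random_intercept_se"] = (
        np.nan if fit.random_intercept_se is None else fit.random_intercept_se
    )
    coef["residual_variance"] = fit.residual_variance
    coef["method"] = fit.method
    coef["converged"] = fit.converged
    return coef


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis; returns a result bundle and writes all tables
    plus ``manifest.json`` under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    seedseq = np.random.SeedSequence(config.seed)
    seeds = seedseq.generate_state(4)  # per-module streams

    # ---- stage: data -------------------------------------------------
    stage = "data"
    try:
        if config.specimens_csv is not None:
            specimens = pd.read_csv(config.specimens_csv)
            metadata = pd.read_csv(config.metadata_csv)
            truth = None
        else:
            sim = config.sim or simulate.SimConfig(seed=int(seeds[0] % 2**31))
            specimens, metadata, truth = simulate.generate_specimens(sim)
            results["sim_config"] = sim
        results["specimens"] = specimens
        results["metadata"] = metadata
        results["truth"] = truth
        _write(specimens, out / "specimens_raw.csv")
        _write(metadata, out / "site_metadata.csv")
    except Exception as e:  # noqa: BLE001 - rewrap with stage name
        raise PipelineError(stage, e) from e

    # ---- stage: preprocess -------------------------------------------
    stage = "preprocess"
    try:
        exemptions = list(preprocess.DEFAULT_EXEMPTIONS)
        if config.exempt_plates_globally:
            exemptions = [("gill_raker_number", None), ("lateral_plate_number", None)]
        fits = preprocess.fit_all_allometries(
            specimens, grouping=config.allometry_grouping
        )
        corrected = preprocess.size_correct(specimens, fits, exemptions=exemptions)
        levene = preprocess.habitat_variance_table(
            corrected, center=config.levene_center
        )
        results["corrected"] = corrected
        results["levene"] = levene
        results["allometry"] = fits
        _write(corrected, out / "specimens_corrected.csv")
        _write(preprocess.allometry_audit(fits), out / "allometry_audit.csv")
        _write(levene, out / "levene_table.csv")
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- stage: morphospace ------------------------------------------
    stage = "morphospace"
    try:
        pca = morphospace.run_pca(corrected, scale=config.pca_scale)
        centroids = morphospace.site_centroids(pca)
        pan_sites = morphospace.pool_panmictic(corrected)["site"]
        centroids_pan = morphospace.site_centroids(pca, sites=pan_sites)
        results["pca"] = pca
        results["centroids"] = centroids
        results["centroids_panmictic"] = centroids_pan
        _write(pca.loadings, out / "pca_loadings.csv", index=True)
        _write(pca.scores, out / "pca_scores.csv", index=True)
        _write(pca.pct_variance.to_frame(), out / "pca_pct_variance.csv", index=True)
        _write(centroids, out / "centroids.csv", index=True)
        _write(centroids_pan, out / "centroids_panmictic.csv", index=True)
    except Exception as e:
        raise PipelineError(stage, e) from e

    marine_sites = metadata.loc[metadata["habitat"] == "marine", "site"].tolist()
    fresh_sites = metadata.loc[metadata["habitat"] == "freshwater", "site"].tolist()

    # ---- stage: vectors ----------------------------------------------
    stage = "vectors"
    try:
        axes = config.vector_axes
        div_pc1 = vectors.divergence_estimates(
            centroids, marine_sites, fresh_sites, "pc_axis_diff",
            axis=config.divergence_axis,
        )
        div_len = vectors.divergence_estimates(
            centroids, marine_sites, fresh_sites, "vector_length", axes=axes
        )
        thetas = vectors.all_theta_records(centroids, marine_sites, fresh_sites, axes)
        div_pc1_pan = vectors.divergence_estimates(
            centroids_pan, [PANMICTIC], fresh_sites, "pc_axis_diff",
            axis=config.divergence_axis,
        )
        thetas_pan = vectors.theta_set(centroids_pan, PANMICTIC, fresh_sites, axes)
        results.update(
            divergence_pc1=div_pc1, divergence_length=div_len, thetas=thetas,
            divergence_pc1_panmictic=div_pc1_pan, thetas_panmictic=thetas_pan,
        )
        _write(div_pc1, out / "divergence_pc1.csv")
        _write(div_len, out / "divergence_vector_length.csv")
        _write(thetas, out / "theta_records.csv")
        _write(div_pc1_pan, out / "divergence_pc1_panmictic.csv")
        _write(thetas_pan, out / "theta_records_panmictic.csv")
        _write(
            vectors.per_reference_summary(thetas), out / "theta_summary.csv"
        )
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- stage: models -----------------------------------------------
    stage = "models"
    try:
        ref_pc1 = models.reference_effect_test(div_pc1)
        ref_len = models.reference_effect_test(div_len)
        theta_long = thetas.assign(
            freshwater=thetas["freshwater_a"] + "|" + thetas["freshwater_b"]
        )[["freshwater", "marine", "theta_deg"]]
        ref_theta = models.reference_effect_test(theta_long, value_col="theta_deg")
        pct = models.percent_change_by_reference(
            div_pc1, normalize=config.percent_change_normalize
        )
        results.update(
            reference_effect_pc1=ref_pc1, reference_effect_length=ref_len,
            reference_effect_theta=ref_theta, percent_change=pct,
        )
        _write(
            pd.concat(
                [
                    ref_pc1.anova.assign(model="pc1_divergence"),
                    ref_len.anova.assign(model="vector_length"),
                    ref_theta.anova.assign(model="theta"),
                ]
            ),
            out / "reference_effect_anova.csv",
        )
        _write(pct.reset_index(), out / "percent_change.csv")
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- stage: geography / environment ------------------------------
    stage = "geo_env"
    try:
        if config.raster_ascii is not None:
            raster = geo_env.WaterRaster.from_ascii(config.raster_ascii)
            if "cell_row" not in metadata.columns:
                raise ValueError(
                    "an external raster needs cell_row/cell_col in metadata"
                )
            site_cells = {
                r["site"]: (int(r["cell_row"]), int(r["cell_col"]))
                for _, r in metadata.iterrows()
            }
        else:
            raster, site_cells = simulate.synthetic_geography(
                metadata, shape=config.raster_shape,
                resolution_km=config.raster_resolution_km,
            )
        raster.to_ascii(out / "water_raster.txt")
        dists = geo_env.distance_matrix(
            raster, site_cells, connectivity=config.connectivity
        )
        _write(dists, out / "waterway_distances_km.csv", index=True)

        if config.climate_csv is not None:
            climate = pd.read_csv(config.climate_csv)
        else:
            climate = simulate.generate_climate(metadata, seed=int(seeds[1] % 2**31))
        _write(climate, out / "climate.csv")
        retained = geo_env.prune_climate_variables(
            climate, threshold=config.climate_threshold
        )
        (out / "retained_climate_variables.txt").write_text("\n".join(retained) + "\n")
        climate_pca = geo_env.climate_pca(climate, retained)
        env_diff = geo_env.environment_difference(
            climate, retained, axes=config.env_axes, metadata=metadata
        )
        _write(env_diff, out / "environment_difference.csv")
        results.update(
            raster=raster, site_cells=site_cells, distances=dists,
            climate=climate, retained_climate=retained,
            climate_pca=climate_pca, env_diff=env_diff,
        )
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- stage: distance decay ---------------------------------------
    stage = "distance_decay"
    try:
        dd = div_pc1.copy()
        dd["distance_km"] = [
            dists.loc[m, f] for m, f in zip(dd["marine"], dd["freshwater"])
        ]
        dd = dd.merge(env_diff, on=["marine", "freshwater"])
        # standardize predictors so slopes are per-SD, comparable across models
        for col in ["distance_km"] + [f"abs_diff_{ax}" for ax in config.env_axes]:
            sd = dd[col].std(ddof=1)
            dd[f"z_{col}"] = (dd[col] - dd[col].mean()) / (sd if sd > 0 else 1.0)
        fit_geo = models.fit_lmm(dd, "value", ["z_distance_km"], "freshwater")
        env_col = f"z_abs_diff_{config.env_axes[-1]}"
        fit_env = models.fit_lmm(dd, "value", [env_col], "freshwater")

        # marine-only: pairwise morphological distance among marine sites
        # against waterway distance, simple regression (no random effect)
        rows = []
        for i, a in enumerate(marine_sites):
            for b in marine_sites[i + 1:]:
                rows.append(
                    {
                        "site_a": a, "site_b": b,
                        "value": morphospace.axis_divergence(
                            centroids, a, b, config.divergence_axis
                        ),
                        "distance_km": dists.loc[a, b],
                    }
                )
        marine_pairs = pd.DataFrame(rows)
        sd = marine_pairs["distance_km"].std(ddof=1)
        marine_pairs["z_distance_km"] = (
            marine_pairs["distance_km"] - marine_pairs["distance_km"].mean()
        ) / (sd if sd > 0 else 1.0)
        fit_marine = models.fit_lmm(marine_pairs, "value", ["z_distance_km"], None)

        results.update(
            distance_decay=dd, fit_geo=fit_geo, fit_env=fit_env,
            marine_pairs=marine_pairs, fit_marine=fit_marine,
        )
        _write(dd, out / "distance_decay_data.csv")
        _write(
            pd.concat(
                [
                    _model_summary_rows("divergence~distance", fit_geo),
                    _model_summary_rows("divergence~environment", fit_env),
                    _model_summary_rows("marine_only~distance", fit_marine),
                ]
            ),
            out / "distance_decay_models.csv",
        )
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- manifest -----------------------------------------------------
    manifest = {
        "seed": config.seed,
        "settings": config.to_jsonable(),
        "versions": _versions(),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results


def _versions() -> dict:
    import scipy
    import statsmodels

    import mfdiv

    return {
        "mfdiv": mfdiv.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
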