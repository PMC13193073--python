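"""End-to-end orchestration: simulate/ingest -> interpolate -> assign
exposures -> dose -> prepare biomarkers -> fit models -> report.

A run is configured by :class:`PipelineConfig` (YAML-loadable). In
simulation mode the generating model's parameters are recorded alongside all
outputs, so every downstream estimate can be scored against ground truth.
Each exposure method enters its own regression model per biomarker, mirroring
the separate-models-per-method comparison design.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarker import flag_outliers, log_standardize
from .domain import rectangle_domain
from .dose import DoseParameters, dose_table, residence_sensitivity
from .interpolation import (
    INTERPOLATION_METHODS,
    make_estimator,
    make_grid_surfaces,
    select_best_method,
)
from .proximity import PROXIMITY_METHODS, assign_proximity
from .simulate import (
    SimulationTruth,
    generate_biomarkers,
    generate_cohort,
    generate_soil_field,
    write_dataset,
)
from .spatial import ModelFit, correlation_screen, knn_weights, screen_and_fit

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run", "render_model_table"]

#: default per-biomarker covariate sets, echoing the per-metal model choices
#: (diet fruit + vacancy for Pb; air-Hg + sodium/protein diet terms for Hg)
DEFAULT_FORMULAS = {
    "blood_pb": {
        "metal": "Pb",
        "covariates": [
            "race", "gender", "ses_score", "dist_highway_m", "bmi_percentile",
            "age", "parent_smokes", "hei_fruit", "vacancy_pct", "max_temp_c",
        ],
    },
    "blood_hg": {
        "metal": "Hg",
        "covariates": [
            "race", "gender", "ses_score", "dist_highway_m", "bmi_percentile",
            "age", "parent_smokes", "max_temp_c", "hg_air", "hei_sodium",
            "hei_protein",
        ],
    },
    "urine_co": {
        "metal": "Co",
        "covariates": [
            "race", "gender", "ses_score", "dist_highway_m", "bmi_percentile",
            "age", "parent_smokes", "max_temp_c",
        ],
    },
}


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-serializable).

    Exactly one of ``input_dir`` (CSV/GeoJSON study inputs) or ``simulation``
    (a SimulationTruth block plus sizes) drives a run.
    """

    seed: int = 0
    outdir: str | None = None
    # --- simulation mode ---
    simulation: dict = field(default_factory=dict)   # SimulationTruth kwargs
    n_soil_samples: int = 1000
    n_cohort: int = 281
    domain_size_m: float = 4000.0
    generating_method: str = "OK"    # exposure that drives the generated biomarker
    # --- ingestion mode ---
    input_dir: str | None = None
    # --- analysis ---
    metals: tuple = ("Pb",)
    biomarkers: dict = field(default_factory=lambda: {"blood_pb": DEFAULT_FORMULAS["blood_pb"]})
    radii: tuple = (90.0, 275.0)
    grid_spacing: float = 50.0
    make_surfaces: bool = False
    interpolation_methods: tuple = INTERPOLATION_METHODS
    select_best: bool = True
    k_folds: int = 5
    dose_method: str = "OK"          # used when select_best is False
    intake_rate: float = 60.0
    moran_threshold: float = 0.2
    knn_k: int = 1
    outlier_sensitivity: bool = True
    residence_thresholds: tuple = ()
    max_neighbors: int = 16

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def __post_init__(self):
        # YAML round-trips sequences as lists; normalize to tuples
        for name in ("metals", "radii", "interpolation_methods", "residence_thresholds"):
            setattr(self, name, tuple(getattr(self, name)))
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if self.input_dir and self.simulation:
            raise ValueError("configure either input_dir or simulation, not both")


@dataclass
class PipelineResult:
    truth: SimulationTruth | None
    domain: object
    soil: dict                     # metal -> DataFrame
    cohort: pd.DataFrame
    exposures: pd.DataFrame        # long: participant_id, metal, method, value
    rmse_tables: dict              # metal -> DataFrame
    selected_method: dict          # metal -> label
    dose_tables: dict              # metal -> DataFrame
    correlation_r: pd.DataFrame
    correlation_p: pd.DataFrame
    fits: dict                     # (biomarker, method) -> ModelFit
    model_table: pd.DataFrame
    sensitivity: dict
    run_log: dict


def _simulate_inputs(cfg: PipelineConfig):
    truth = SimulationTruth(seed=cfg.seed, **{k: v for k, v in cfg.simulation.items() if k != "seed"})
    domain = rectangle_domain(cfg.domain_size_m, cfg.domain_size_m)
    soil = {m: generate_soil_field(domain, cfg.n_soil_samples, truth, metal=m)
            for m in cfg.metals}
    cohort_seed = np.random.SeedSequence(truth.seed).spawn(3)[1]
    cohort = generate_cohort(cfg.n_cohort, domain, seed=cohort_seed)
    return truth, domain, soil, cohort


def _load_inputs(cfg: PipelineConfig):
    from .domain import domain_from_geojson

    d = Path(cfg.input_dir)
    soil_all = pd.read_csv(d / "soil_samples.csv")
    soil = {m: soil_all[soil_all["metal"] == m].reset_index(drop=True) for m in cfg.metals}
    cohort = pd.read_csv(d / "cohort.csv")
    domain = domain_from_geojson(d / "domain.geojson")
    return None, domain, soil, cohort


def run(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full analysis chain for one configuration."""
    stage = "setup"
    counts = {}
    try:
        stage = "inputs"
        if cfg.input_dir:
            truth, domain, soil, cohort = _load_inputs(cfg)
        else:
            truth, domain, soil, cohort = _simulate_inputs(cfg)
        counts["cohort_enrolled"] = len(cohort)
        for m, df in soil.items():
            counts[f"soil_samples_{m}"] = len(df)

        stage = "interpolation"
        rmse_tables, selected, fitted = {}, {}, {}
        for m, df in soil.items():
            coords = df[["x", "y"]].to_numpy(dtype=float)
            vals = df["concentration"].to_numpy(dtype=float)
            if cfg.select_best:
                best, table = select_best_method(
                    df, cfg.interpolation_methods, cfg.k_folds, cfg.seed,
                )
            else:
                best, table = cfg.dose_method, pd.DataFrame(
                    {"method": [cfg.dose_method], "rmse": [np.nan]}
                )
            rmse_tables[m], selected[m] = table, best
            ests = {}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for meth in cfg.interpolation_methods:
                    ests[meth] = make_estimator(meth).fit(coords, vals)
            fitted[m] = ests

        surfaces = {}
        if cfg.make_surfaces:
            stage = "surfaces"
            surfaces = make_grid_surfaces(domain, fitted, cfg.grid_spacing)

        stage = "exposure"
        exp_frames = []
        homes = cohort[["x", "y"]].to_numpy(dtype=float)
        excluded_ids = set()
        for m, df in soil.items():
            prox = assign_proximity(cohort, df, cfg.radii)
            excluded_ids |= set(prox.loc[prox["excluded"], "participant_id"].unique())
            exp_frames.append(prox.drop(columns="excluded"))
            for meth, est in fitted[m].items():
                pred = est.predict(homes)
                exp_frames.append(pd.DataFrame({
                    "participant_id": cohort["participant_id"],
                    "metal": m, "method": meth,
                    "value": np.maximum(pred, 0.0),
                    "n_support": len(df),
                }))
        exposures = pd.concat(exp_frames, ignore_index=True)
        counts["excluded_over_275m"] = len(excluded_ids)

        stage = "dose"
        dose_tables_ = {}
        for m, df in soil.items():
            c_city = float(df["concentration"].mean())
            sel = exposures[(exposures["metal"] == m) & (exposures["method"] == selected[m])]
            conc = (
                sel.set_index("participant_id")["value"]
                .reindex(cohort["participant_id"]).to_numpy()
            )
            dt = dose_table(cohort, np.nan_to_num(conc), c_city, metal=m,
                            params=DoseParameters(intake_rate=cfg.intake_rate))
            dose_tables_[m] = dt
            exp_frames.append(pd.DataFrame({
                "participant_id": dt["participant_id"], "metal": m,
                "method": "dose", "value": dt["dose_ug_kg_day"],
                "n_support": len(df),
            }))
        exposures = pd.concat(exp_frames, ignore_index=True)

        stage = "biomarkers"
        if truth is not None:
            w = knn_weights(homes, k=max(cfg.knn_k, 1))
            for bname, spec in cfg.biomarkers.items():
                m = spec["metal"]
                gsel = exposures[(exposures["metal"] == m)
                                 & (exposures["method"] == cfg.generating_method)]
                gen = (
                    gsel.set_index("participant_id")["value"]
                    .reindex(cohort["participant_id"]).to_numpy()
                )
                cohort = generate_biomarkers(cohort, np.nan_to_num(gen), truth, w,
                                             biomarker=bname)

        # drop participants beyond the outer buffer from every downstream table
        stage = "exclusion"
        analysis_cohort = cohort[~cohort["participant_id"].isin(excluded_ids)].reset_index(drop=True)
        counts["cohort_analyzed"] = len(analysis_cohort)
        exposures = exposures[~exposures["participant_id"].isin(excluded_ids)]

        stage = "correlation"
        bio_cols = ["participant_id"] + list(cfg.biomarkers)
        have = [c for c in bio_cols if c in analysis_cohort.columns]
        corr_r, corr_p = correlation_screen(
            exposures[["participant_id", "method", "value"]], analysis_cohort[have]
        )

        stage = "models"
        fits: dict = {}
        method_order = [mm for mm in
                        ("dose",) + tuple(INTERPOLATION_METHODS) + tuple(PROXIMITY_METHODS)
                        if mm == "dose" or mm in set(exposures["method"])]
        for bname, spec in cfg.biomarkers.items():
            if bname not in analysis_cohort.columns:
                continue
            m = spec["metal"]
            covs = spec["covariates"]
            for meth in method_order:
                sub = exposures.loc[
                    (exposures["metal"] == m) & (exposures["method"] == meth),
                    ["participant_id", "value"],
                ].rename(columns={"value": "exposure"})
                tab = analysis_cohort.merge(sub, on="participant_id")
                tab = tab.dropna(subset=["exposure", bname] + covs)
                tab = tab[tab[bname] > 0]
                if len(tab) < len(covs) + 5:
                    continue
                prepared, _ = log_standardize(tab, bname, ["exposure"] + covs)
                fit = screen_and_fit(
                    prepared[f"log_{bname}"].to_numpy(),
                    prepared[["exposure"] + covs],
                    tab[["x", "y"]].to_numpy(dtype=float),
                    p_threshold=cfg.moran_threshold,
                    k=cfg.knn_k,
                )
                fits[(bname, meth)] = fit

        stage = "sensitivity"
        sensitivity: dict = {}
        if cfg.outlier_sensitivity:
            refits = {}
            for (bname, meth), fit in fits.items():
                spec = cfg.biomarkers[bname]
                sub = exposures.loc[
                    (exposures["metal"] == spec["metal"]) & (exposures["method"] == meth),
                    ["participant_id", "value"],
                ].rename(columns={"value": "exposure"})
                tab = analysis_cohort.merge(sub, on="participant_id")
                tab = tab.dropna(subset=["exposure", bname] + spec["covariates"])
                tab = tab[tab[bname] > 0]
                if len(tab) < 8:
                    continue
                mask = flag_outliers(tab[bname].to_numpy())
                kept = tab[~mask]
                if len(kept) < len(spec["covariates"]) + 5:
                    continue
                prepared, _ = log_standardize(kept, bname, ["exposure"] + spec["covariates"])
                refits[(bname, meth)] = {
                    "n_outliers_removed": int(mask.sum()),
                    "fit": screen_and_fit(
                        prepared[f"log_{bname}"].to_numpy(),
                        prepared[["exposure"] + spec["covariates"]],
                        kept[["x", "y"]].to_numpy(dtype=float),
                        p_threshold=cfg.moran_threshold, k=cfg.knn_k,
                    ),
                }
            sensitivity["outliers_removed"] = refits
        if cfg.residence_thresholds:
            res = {}
            for bname, spec in cfg.biomarkers.items():
                if bname not in analysis_cohort.columns:
                    continue
                m = spec["metal"]
                sub = exposures.loc[
                    (exposures["metal"] == m) & (exposures["method"] == "dose"),
                    ["participant_id", "value"],
                ].rename(columns={"value": "exposure"})
                tab = analysis_cohort.merge(sub, on="participant_id")
                res[bname] = residence_sensitivity(
                    tab, "exposure", bname, spec["covariates"],
                    cfg.residence_thresholds, k=cfg.knn_k,
                    moran_threshold=cfg.moran_threshold,
                )
            sensitivity["residence"] = res

        stage = "report"
        model_table = render_model_table(fits)
        run_log = {
            "seed": cfg.seed,
            "soil2bio_version": __version__,
            "counts": counts,
            "selected_method": selected,
            "stages_completed": "all",
        }
        result = PipelineResult(
            truth=truth, domain=domain, soil=soil, cohort=analysis_cohort,
            exposures=exposures.reset_index(drop=True), rmse_tables=rmse_tables,
            selected_method=selected, dose_tables=dose_tables_,
            correlation_r=corr_r, correlation_p=corr_p, fits=fits,
            model_table=model_table, sensitivity=sensitivity, run_log=run_log,
        )
        if cfg.outdir:
            _write_outputs(cfg, result, surfaces)
        return result
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r} (counts so far: {counts})"
        ) from err


def render_model_table(fits: dict) -> pd.DataFrame:
    """Render fits as a wide table: one column per (biomarker, method) model,
    rows = predictors as 'est (se)' strings plus R2, n, lambda, Moran rows."""
    cols = {}
    for (bname, meth), fit in fits.items():
        col = {}
        for name in fit.params.index:
            stars = "***" if fit.pvalues[name] < 0.01 else (
                "**" if fit.pvalues[name] < 0.05 else ("*" if fit.pvalues[name] < 0.1 else ""))
            col[name] = f"{fit.params[name]:.3f}{stars} ({fit.bse[name]:.3f})"
        col["R2"] = f"{fit.r2:.3f}"
        col["n"] = str(fit.n)
        col["model"] = fit.method
        if fit.lam is not None:
            col["lambda"] = f"{fit.lam:.3f}"
        if fit.moran is not None:
            col["moran_I"] = f"{fit.moran.I:.3f}"
            col["moran_z"] = f"{fit.moran.z:.3f}"
        cols[f"{bname}:{meth}"] = col
    return pd.DataFrame(cols)


def _write_outputs(cfg: PipelineConfig, result: PipelineResult, surfaces: dict) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if result.truth is not None:
        write_dataset(out / "inputs", result.truth, result.domain,
                      pd.concat(result.soil.values(), ignore_index=True), result.cohort)
    result.exposures.to_csv(out / "exposures.csv", index=False)
    for m, t in result.rmse_tables.items():
        t.to_csv(out / f"rmse_{m}.csv", index=False)
    for m, t in result.dose_tables.items():
        t.to_csv(out / f"dose_{m}.csv", index=False)
    result.correlation_r.to_csv(out / "correlation_r.csv")
    result.correlation_p.to_csv(out / "correlation_p.csv")
    result.model_table.to_csv(out / "model_table.csv")
    for name, surf in surfaces.items():
        surf.to_csv(out / f"surface_{name}.csv", index=False)
    with open(out / "run_log.json", "w") as fh:
        json.dump(result.run_log, fh, indent=2)
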