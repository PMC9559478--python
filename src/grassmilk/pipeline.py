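"""One-command end-to-end pipeline.

Stage order: simulate → label → split by farm → select latent variables →
fit PLS-DA per scheme → cross-validated and external validation metrics →
monthly probability curves → meteorology correlations → farm typology.
Every artefact is written under the configured output directory with the
configuration hash and root seed embedded; a rerun with the same
configuration is bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, labeling, meteo, plsda, simdata, typology
from .config import PipelineConfig
from .io import write_table
from .schema import default_schema

__all__ = ["run_pipeline", "run_study", "StudyResult", "derive_group_map"]

logger = logging.getLogger(__name__)


def _stage(name: str, n_in: int | None = None, n_out: int | None = None) -> None:
    logger.info("stage %-12s in=%s out=%s", name, n_in, n_out)


def derive_group_map(
    solution: typology.ClusterSolution, flagged: list[int]
) -> dict[int, int]:
    """Default intensive/extensive mapping of clusters.

    Clusters whose mean annual GRASS probability is below the median over
    non-flagged clusters are treated as intensive (−1, less grass in the
    ration), the rest as extensive (+1).  The mapping is configurable
    because it is an interpretation step, not a computation.
    """
    curves = solution.monthly_curves.set_index("cluster")
    level = curves[typology.MONTH_COLUMNS].mean(axis=1)
    level = level[~level.index.isin(flagged)]
    median = float(level.median())
    return {int(c): (-1 if v < median else 1) for c, v in level.items()}


from dataclasses import dataclass, field


@dataclass
class StudyResult:
    """In-memory result of the modelling stages, for downstream analyses."""

    records: pd.DataFrame
    meteo: pd.DataFrame
    farms: list
    calibration: pd.DataFrame
    validation: pd.DataFrame
    models: dict = field(default_factory=dict)           # scheme -> PlsDaModel
    selection: dict = field(default_factory=dict)        # scheme -> (A*, cv curve)
    cv: dict = field(default_factory=dict)               # scheme -> CvResult
    validation_accuracy: dict = field(default_factory=dict)  # scheme -> (acc, n)
    probabilities: dict = field(default_factory=dict)    # scheme -> P(GRASS) on validation
    vip: dict = field(default_factory=dict)              # scheme -> VipTable
    curve: pd.DataFrame | None = None                    # monthly curve, scheme 1
    meteo_correlations: pd.Series | None = None


def run_study(
    n_farms: int = 200,
    n_years: int = 3,
    seed: int = 0,
    schemes: tuple[int, ...] = (1, 2, 3),
    max_components: int = 30,
    folds: int = 10,
    calibration_fraction: float = 0.30,
    archetype_mix: dict[str, float] | None = None,
    schema=None,
) -> StudyResult:
    """Simulate, split, train and validate — returning live objects.

    This is the modelling backbone shared by the analysis drivers; it stops
    before the typology stage (run that on the validation probabilities).
    """
    if schema is None:
        schema = default_schema()
    records, meteo_df, farms = simdata.generate_dataset(
        n_farms, n_years, archetype_mix=archetype_mix, schema=schema, seed=seed
    )
    calibration, validation = labeling.split_by_farm(
        records, calibration_fraction, seed=seed
    )
    result = StudyResult(records, meteo_df, farms, calibration, validation)
    trait_cols = schema.names
    for scheme in schemes:
        subset = labeling.build_modeling_subset(
            labeling.label_records(calibration, scheme)
        )
        X = subset[trait_cols]
        y = subset["target"].to_numpy()
        a_star, cv_curve = plsda.select_n_components(
            X, y, max_components, k=folds, seed=seed
        )
        result.selection[scheme] = (a_star, cv_curve)
        result.cv[scheme] = evaluation.cross_validate(X, y, a_star, k=folds, seed=seed)
        model = plsda.fit_pls(X, y, a_star)
        result.models[scheme] = model
        result.vip[scheme] = plsda.compute_vip(model)
        result.validation_accuracy[scheme] = evaluation.external_validation_accuracy(
            model, validation
        )
        result.probabilities[scheme] = model.predict_grass_probability(
            validation[trait_cols]
        )
    first = schemes[0]
    pred = validation[["farm_id", "year", "month"]].copy()
    pred["probability"] = result.probabilities[first]
    result.curve = evaluation.monthly_probability_curve(pred)
    result.meteo_correlations = meteo.correlate_with_meteo(result.curve, meteo_df)
    return result


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Execute the full pipeline; returns the report dictionary."""
    config.validate()
    chash = config.config_hash()
    seed = config.simulation.seed
    outdir = Path(config.output_dir)
    report: dict = {"config_hash": chash, "seed": seed, "stages": {}}

    def emit(df: pd.DataFrame, name: str) -> None:
        if write:
            write_table(df, outdir / name, config_hash=chash, seed=seed)

    # --- simulate -----------------------------------------------------
    schema = default_schema()
    records, meteo_df, farms = simdata.generate_dataset(
        n_farms=config.simulation.n_farms,
        n_years=config.simulation.n_years,
        archetype_mix=config.simulation.archetype_mix,
        schema=schema,
        seed=seed,
        transition_width=config.simulation.transition_width,
        fa_noise_rho=config.simulation.fa_noise_rho,
    )
    _stage("simulate", None, len(records))
    report["stages"]["simulate"] = {
        "n_records": len(records),
        "n_farms": config.simulation.n_farms,
        "n_years": config.simulation.n_years,
    }
    emit(records, "records.csv")
    emit(meteo_df, "meteo.csv")
    emit(
        pd.DataFrame(
            [
                {
                    "farm_id": f.farm_id,
                    "archetype": f.archetype,
                    "grass_amplitude": f.grass_amplitude,
                }
                for f in farms
            ]
        ),
        "farms.csv",
    )

    # --- split once, shared by all schemes ----------------------------
    calibration, validation = labeling.split_by_farm(
        records, config.labeling.calibration_fraction, seed=seed
    )
    _stage("split", len(records), len(calibration))
    report["stages"]["split"] = {
        "n_calibration": len(calibration),
        "n_validation": len(validation),
        "n_calibration_farms": calibration["farm_id"].nunique(),
        "n_validation_farms": validation["farm_id"].nunique(),
    }

    trait_cols = schema.names
    models: dict[int, plsda.PlsDaModel] = {}
    probs: dict[int, np.ndarray] = {}
    report["models"] = {}
    for scheme in config.labeling.schemes:
        labeled = labeling.label_records(calibration, scheme)
        subset = labeling.build_modeling_subset(labeled)
        _stage(f"label-s{scheme}", len(labeled), len(subset))
        X = subset[trait_cols]
        y = subset["target"].to_numpy()
        a_star, cv_curve = plsda.select_n_components(
            X, y, config.model.max_components, k=config.model.folds, seed=seed
        )
        cv = evaluation.cross_validate(
            X, y, a_star, k=config.model.folds, seed=seed
        )
        model = plsda.fit_pls(X, y, a_star)
        vip = plsda.compute_vip(model)
        retained = plsda.reduce_by_vip(vip, config.model.vip_threshold)
        acc, n_used = evaluation.external_validation_accuracy(model, validation)
        prob = model.predict_grass_probability(validation[trait_cols])
        models[scheme] = model
        probs[scheme] = prob
        report["models"][f"GRASS{scheme}"] = {
            "n_training": len(subset),
            "n_components": a_star,
            "cv": cv.summary(),
            "validation_accuracy": acc,
            "n_validation_used": n_used,
            "n_vip_retained": len(retained),
        }
        if write:
            plsda.save_model(model, outdir / f"model_grass{scheme}.json")
            emit(vip.to_frame(), f"vip_grass{scheme}.csv")
        _stage(f"model-s{scheme}", len(subset), a_star)

    # --- inter-model correlations -------------------------------------
    if len(probs) > 1:
        schemes = sorted(probs)
        corr = evaluation.intermodel_probability_correlation(
            *[probs[s] for s in schemes]
        )
        report["intermodel_correlation"] = {
            "schemes": schemes,
            "matrix": corr.tolist(),
        }

    # --- probability curves and meteorology ---------------------------
    t_scheme = config.typology.scheme
    pred = validation[["farm_id", "year", "month"]].copy()
    pred["probability"] = probs[t_scheme]
    curve = evaluation.monthly_probability_curve(pred)
    emit(curve, "monthly_curve.csv")
    meteo_r = meteo.correlate_with_meteo(curve, meteo_df)
    report["meteo_correlations"] = meteo_r.to_dict()
    emit(meteo_r.rename_axis("trait").reset_index(), "meteo_correlations.csv")
    _stage("curve", len(pred), len(curve))

    # --- typology ------------------------------------------------------
    profile_set = typology.build_profiles(pred)
    k = min(config.typology.k, len(profile_set))
    tree = typology.ward_d2_cluster(profile_set)
    solution = typology.cut_and_summarize(tree, k, profile_set, records=validation)
    flagged = typology.flag_skimmed(solution, config.typology.fat_threshold)
    group_map = config.typology.group_map or derive_group_map(solution, flagged)
    index = typology.intensity_index(solution.assignments, group_map, flagged)
    categories = index["category"].value_counts().to_dict()
    report["typology"] = {
        "n_profiles": len(profile_set),
        "n_excluded_farm_years": profile_set.n_excluded,
        "k": k,
        "flagged_clusters": flagged,
        "group_map": {str(c): v for c, v in sorted(group_map.items())},
        "category_counts": categories,
        "fraction_always_intensive": categories.get("always-intensive", 0) / max(len(index), 1),
        "fraction_always_extensive": categories.get("always-extensive", 0) / max(len(index), 1),
    }
    emit(solution.assignments, "typology_assignments.csv")
    emit(solution.monthly_curves, "typology_curves.csv")
    emit(solution.trait_summary, "typology_summary.csv")
    emit(index, "intensity_index.csv")
    if write:
        merges = pd.DataFrame(
            solution.linkage, columns=["left", "right", "height", "size"]
        )
        emit(merges, "dendrogram_merges.csv")
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    _stage("typology", len(profile_set), k)

    return report
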