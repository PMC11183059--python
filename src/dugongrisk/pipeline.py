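"""End-to-end orchestration: two-stage suitability -> risk -> CDH report.

Stage 1 fits the seagrass suitability model from the abiotic predictor
stack; its logistic output joins the dugong predictor stack as the biotic
layer.  Stage 2 fits per-season dugong models (settings chosen by least
AICc over a candidate grid), falling back to a single annual model when any
season is too data-poor after rarefaction.  The risk stage averages the
seasonal suitability maps, multiplies by normalized fishing pressure,
classifies risk, extracts Critical Dugong Habitat and accounts the MPA gap,
then cross-checks against the boat-survey IDW threat surface.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import maxent, selection
from .geo import Grid, PointSet, PolygonSet, minmax_normalize, rasterize, write_grid
from .maxent import FeatureExpansion
from .overlap import overlap_matrix
from .prep import SeasonDefinition, ani_seasons, kde_bias_surface, rarefy, screen_predictors, split_by_season
from .risk import (
    RISK_HIGH,
    classify_risk,
    classify_suitability,
    combine_seasons,
    extract_cdh,
    mpa_gap_report,
    risk_surface,
)
from .synthetic import Scenario, ScenarioConfig, generate_scenario
from .validation import IDWConfig, agreement, classify_threat, idw, select_power

__all__ = [
    "PipelineConfig",
    "default_candidates",
    "fit_suitability",
    "run_two_stage",
    "run_risk_report",
    "run_all",
]


def default_candidates() -> list:
    """Compact settings grid: L, LQ, LQH expansions at multipliers 1 and 2."""
    grid = []
    for classes in (("linear",), ("linear", "quadratic"), ("linear", "quadratic", "hinge")):
        for mult in (1.0, 2.0):
            grid.append((FeatureExpansion(classes), mult))
    return grid


@dataclass
class PipelineConfig:
    site: str = "synthetic"
    scenario: ScenarioConfig = dc_field(default_factory=ScenarioConfig)
    seasons: SeasonDefinition = dc_field(default_factory=ani_seasons)
    candidates: list = dc_field(default_factory=default_candidates)
    collinearity_threshold: float = 0.7
    # About half the sea cells of the default 100x100 scenario: sampling
    # (rather than enumerating) the background keeps the bias file active.
    background_n: int = 5000
    use_bias: bool = True
    min_seasonal_points: int = 15
    cdh_suitability_cutoff: float = 0.75
    idw: IDWConfig = dc_field(default_factory=IDWConfig)
    seed: int = 0
    max_iter: int = 500
    select_settings: bool = True


def _seed_stream(seed: int, n: int) -> list[int]:
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def presence_cells(points: PointSet, template: Grid) -> np.ndarray:
    rows, cols = points.cells(template)
    return rows * template.shape[1] + cols


def fit_suitability(
    stack: dict,
    points: PointSet,
    seed: int,
    expansion: FeatureExpansion | None = None,
    reg_multiplier: float = 1.0,
    background_n: int = maxent.DEFAULT_BACKGROUND_SIZE,
    bias: Grid | None = None,
    max_iter: int = 500,
):
    """Rarefy, sample background (optionally bias-weighted), fit, predict.

    Returns ``(model, logistic suitability grid, rarefied points)``.
    """
    template = next(iter(stack.values()))
    rare = rarefy(points, template, seed=seed)
    bg = maxent.sample_background(template, bias, background_n, seed=seed + 1)
    cells = presence_cells(rare, template)
    model = maxent.fit(
        stack, cells, bg, expansion or FeatureExpansion(("linear", "quadratic")), reg_multiplier,
        max_iter=max_iter,
    )
    suit = maxent.predict_logistic(model, stack)
    return model, suit, rare


def run_two_stage(config: PipelineConfig, scenario: Scenario | None = None, outdir=None) -> dict:
    """Two-stage suitability modelling; returns artifacts plus a manifest."""
    t0 = time.time()
    scenario = scenario or generate_scenario(config.scenario)
    seeds = _seed_stream(config.seed, 8)
    template = scenario.land_mask.with_values(
        np.zeros(scenario.land_mask.shape), mask=scenario.sea_mask
    )

    retained, corr_table = screen_predictors(scenario.env_stack, config.collinearity_threshold)
    abiotic = {n: scenario.env_stack[n] for n in retained}

    # Stage 1: seagrass from abiotic predictors.
    sg_points = scenario.seagrass_occurrences
    sg_bias = None
    if config.use_bias and len(sg_points) >= 2:
        sg_bias = kde_bias_surface(sg_points, template)
    sg_model, sg_suit, sg_rare = fit_suitability(
        abiotic,
        sg_points,
        seed=seeds[0],
        expansion=FeatureExpansion(("linear", "quadratic", "hinge")),
        background_n=config.background_n,
        bias=sg_bias,
        max_iter=config.max_iter,
    )

    # Stage 2: dugong stack = screened abiotics from the reduced dugong
    # predictor set, plus the stage-1 seagrass suitability layer.
    allowed = set(config.scenario.dugong_predictors)
    dugong_stack = {n: g for n, g in abiotic.items() if n in allowed}
    if not dugong_stack:
        dugong_stack = dict(abiotic)
    dugong_stack["seagrass"] = sg_suit

    all_points = PointSet(
        pd.concat([ps.df for ps in scenario.occurrences.values()], ignore_index=True)
    )
    by_season, n_excluded = split_by_season(all_points, config.seasons)
    rarefied = {
        s: rarefy(ps, template, seed=seeds[1]) for s, ps in by_season.items() if len(ps)
    }
    annual_mode = any(len(ps) < config.min_seasonal_points for ps in rarefied.values()) or not rarefied
    season_sets = {"annual": all_points} if annual_mode else by_season

    models, suitability, eval_tables, season_meta = {}, {}, {}, {}
    for i, (season, points) in enumerate(season_sets.items()):
        rare = rarefy(points, template, seed=seeds[2] + i)
        bias = None
        if config.use_bias and len(rare) >= 2:
            bias = kde_bias_surface(rare, template)
        bg = maxent.sample_background(template, bias, config.background_n, seed=seeds[3] + i)
        cells = presence_cells(rare, template)
        if config.select_settings and len(config.candidates) > 1:
            best, table = selection.select(
                config.candidates, rare, bg, dugong_stack, seed=seeds[4] + i,
                max_iter=config.max_iter,
            )
            expansion = FeatureExpansion(best.classes)
            mult = best.reg_multiplier
            eval_tables[season] = table
            auc_mean, auc_sd = best.mean_test_AUC, best.sd_test_AUC
        else:
            expansion, mult = config.candidates[0]
            folds = selection.partition(rare, seed=seeds[4] + i)
            aucs = []
            for f in np.unique(folds):
                tr, te = cells[folds != f], cells[folds == f]
                if tr.size < 3:
                    continue
                m_f = maxent.fit(dugong_stack, tr, bg, expansion, mult, max_iter=config.max_iter)
                aucs.append(
                    maxent.auc(
                        maxent._model_scores(m_f, dugong_stack, te),
                        maxent._model_scores(m_f, dugong_stack, bg),
                    )
                )
            auc_mean = float(np.mean(aucs)) if aucs else float("nan")
            auc_sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
        model = maxent.fit(dugong_stack, cells, bg, expansion, mult, max_iter=config.max_iter)
        models[season] = model
        suitability[season] = maxent.predict_logistic(model, dugong_stack)
        season_meta[season] = {
            "n_rarefied": int(len(rare)),
            "settings": {"classes": list(expansion.classes), "reg_multiplier": mult},
            "K": model.n_nonzero,
            "test_auc_mean": auc_mean,
            "test_auc_sd": auc_sd,
            "auc_label": f"AUC ± SD = {auc_mean:.3f} ± {auc_sd:.3f}",
            "converged": bool(model.converged),
        }

    manifest = {
        "site": config.site,
        "seed": config.seed,
        "stage_seeds": seeds,
        "screened_predictors": retained,
        "n_excluded_records": int(n_excluded),
        "annual_mode": bool(annual_mode),
        "seagrass": {
            "n_rarefied": int(len(sg_rare)),
            "K": sg_model.n_nonzero,
            "converged": bool(sg_model.converged),
        },
        "seasons": season_meta,
        "elapsed_s": round(time.time() - t0, 2),
    }

    artifacts = {
        "scenario": scenario,
        "template": template,
        "correlation_table": corr_table,
        "seagrass_model": sg_model,
        "seagrass_suitability": sg_suit,
        "dugong_stack": dugong_stack,
        "models": models,
        "suitability": suitability,
        "eval_tables": eval_tables,
        "overlap_I": overlap_matrix(suitability, "I") if len(suitability) > 1 else None,
        "manifest": manifest,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_grid(sg_suit, outdir / "seagrass_suitability.tif")
        for season, grid in suitability.items():
            write_grid(grid, outdir / f"dugong_suitability_{season}.tif")
        corr_table.to_csv(outdir / "predictor_correlations.csv")
        for season, table in eval_tables.items():
            table.to_csv(outdir / f"settings_eval_{season}.csv", index=False)
        if artifacts["overlap_I"] is not None:
            artifacts["overlap_I"].to_csv(outdir / "overlap_I.csv")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return artifacts


def run_risk_report(
    suitability: dict,
    pressure: Grid,
    mpas: PolygonSet | None,
    surveys: PointSet | None,
    cdh_suitability_cutoff: float = 0.75,
    idw_config: IDWConfig | None = None,
    outdir=None,
) -> dict:
    """Risk chain: combine -> product -> classes -> CDH -> MPA gap -> surveys."""
    combined = combine_seasons(list(suitability.values()))
    pressure_norm = minmax_normalize(pressure)
    risk = risk_surface(combined, pressure_norm)
    risk_class = classify_risk(risk)
    suit_class = classify_suitability(combined)
    cdh = extract_cdh(risk_class, combined)
    high_risk = risk_class.with_values((risk_class.values == RISK_HIGH).astype(float))

    if mpas is not None and len(mpas):
        mpa_mask = rasterize(mpas, risk_class)
    else:
        mpa_mask = risk_class.with_values(np.zeros(risk_class.shape))
    report = mpa_gap_report(high_risk, mpa_mask, cdh_mask=cdh, risk_class=risk_class)

    survey_out = {}
    if surveys is not None and len(surveys) >= 3:
        power, rmse_table = select_power(surveys, risk, idw_config or IDWConfig())
        threat = idw(surveys, risk, power)
        threat_class = classify_threat(threat)
        confusion, kappa = agreement(risk_class, threat_class)
        survey_out = {
            "idw_power": power,
            "rmse_table": rmse_table,
            "threat_surface": threat,
            "threat_class": threat_class,
            "confusion": confusion,
            "kappa": kappa,
        }

    out = {
        "combined_suitability": combined,
        "pressure_norm": pressure_norm,
        "risk": risk,
        "risk_class": risk_class,
        "suitability_class": suit_class,
        "cdh": cdh,
        "mpa_mask": mpa_mask,
        "report": report,
        **survey_out,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("combined_suitability", "risk", "risk_class", "suitability_class", "cdh", "mpa_mask"):
            write_grid(out[name], outdir / f"{name}.tif")
        report.to_frame().to_csv(outdir / "cdh_report.csv", index=False)
        (outdir / "cdh_report.txt").write_text(report.to_text() + "\n")
        if report.class_area_table is not None:
            report.class_area_table.to_csv(outdir / "risk_class_areas.csv", index=False)
        if survey_out:
            write_grid(out["threat_surface"], outdir / "threat_surface.tif")
            out["confusion"].to_csv(outdir / "agreement_confusion.csv")
            (outdir / "agreement.txt").write_text(
                f"IDW power: {out['idw_power']:.3f}\nCohen's kappa: {out['kappa']:.4f}\n"
            )
    return out


def run_all(config: PipelineConfig | None = None, outdir=None) -> dict:
    """Full synthetic-mode pipeline; returns two-stage + risk artifacts."""
    config = config or PipelineConfig()
    stage = run_two_stage(config, outdir=outdir)
    scenario = stage["scenario"]
    risk_out = run_risk_report(
        stage["suitability"],
        scenario.pressure,
        scenario.mpas,
        scenario.survey_points,
        cdh_suitability_cutoff=config.cdh_suitability_cutoff,
        idw_config=config.idw,
        outdir=outdir,
    )
    return {**stage, **risk_out}
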