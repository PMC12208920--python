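"""Run configuration and the end-to-end pipeline.

Stages: quality screen -> exposure coding -> fixed-effects Poisson fit
-> averted events -> scenario forecast -> DiD triangulation ->
descriptive summary.  Every stage writes a CSV into the output
directory and the run is sealed with a machine-readable manifest
(seed, iteration counts, package version, input hash, dropped-record
counts and the design settings in force).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counterfactual import averted_events
from .descriptives import summarize
from .exposure import CovariateDichotomizer, ExposureTransformer
from .fe_poisson import FixedEffectsPoisson
from .io import COVARIATE_COLUMNS, read_panel, write_panel
from .microsim import (ScenarioSpec, apply_scenario, compare_scenarios,
                       extrapolate_covariates, project_outcomes)
from .quality import QualityCriteria, VitalStatisticsFilter
from .synthetic import SimConfig, generate_panel
from .triangulation import PropensityScoreMatcher

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "input", "output_dir", "seed", "iterations", "quality", "exposure",
    "model", "scenarios", "horizon_years", "anchor_years", "did",
    "summary_variables", "simulate",
}


@dataclass
class RunConfig:
    """Validated run configuration (YAML-serialisable)."""

    output_dir: str = "output"
    input: str | None = None
    simulate: dict | None = None
    seed: int | None = None
    iterations: int = 10_000
    quality: dict = field(default_factory=dict)
    exposure: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    scenarios: list = field(default_factory=lambda: [
        {"name": "expansion"}, {"name": "baseline"}, {"name": "austerity"}])
    horizon_years: tuple = (2024, 2030)
    anchor_years: tuple = (2004, 2019)
    did: dict = field(default_factory=dict)
    summary_variables: tuple = ("poverty_rate", "target_coverage")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.input is None and cfg.simulate is None:
            raise ValueError("config needs either 'input' or 'simulate'")
        if cfg.seed is None:
            raise ValueError("seed is mandatory when Monte Carlo stages "
                             "are enabled")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the artefact directory.

    Any stage error aborts the run with the stage name; the partially
    filled manifest is persisted either way.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "iterations": config.iterations, "stages": {}}
    stage = "setup"
    try:
        if config.input is not None:
            panel = read_panel(config.input)
            manifest["input_sha256"] = _hash_file(config.input)
        else:
            sim = SimConfig(**{**config.simulate,
                               "seed": config.simulate.get("seed",
                                                           config.seed)})
            panel, truth = generate_panel(sim)
            write_panel(panel, out / "panel.csv")
            truth.records.to_csv(out / "ground_truth.csv", index=False)
            manifest["input_sha256"] = _hash_file(out / "panel.csv")

        stage = "quality"
        vf = VitalStatisticsFilter(**config.quality).fit(panel)
        vf.report_.to_csv(out / "quality_report.csv")
        panel = vf.transform(panel)
        manifest["stages"]["quality"] = {
            "n_pass": vf.report_.n_pass,
            "criteria": dataclasses.asdict(vf.report_.criteria)}

        stage = "exposure"
        expo = ExposureTransformer(**config.exposure).fit(panel)
        panel = expo.transform(panel)
        dich = CovariateDichotomizer(
            columns=[c for c in COVARIATE_COLUMNS if c in panel.columns]
        ).fit(panel)
        panel = dich.transform(panel)
        panel.to_csv(out / "exposure.csv", index=False)
        manifest["stages"]["exposure"] = {
            "adequacy_cuts": list(expo.adequacy_cuts_),
            "covariate_split": dich.thresholds_,
            "dropped_constant_covariates": dich.dropped_}

        stage = "fit"
        model_kwargs = {"covariates": tuple(dich.thresholds_), **config.model}
        model = FixedEffectsPoisson(**model_kwargs).fit(panel)
        model.rate_ratios().to_csv(out / "fit.csv", index=False)
        manifest["stages"]["fit"] = {
            "terms": model.terms_, "n_obs": model.n_obs_,
            "n_municipalities": model.n_municipalities_,
            "dropped_missing": model.dropped_missing_,
            "dropped_zero_denominator": model.dropped_zero_denominator_,
            "dropped_zero_outcome_municipalities":
                model.dropped_zero_outcome_municipalities_}

        stage = "averted"
        av = averted_events(panel, model, n_iterations=config.iterations,
                            seed=config.seed)
        pd.DataFrame({"year": av.per_year.index,
                      "averted": av.per_year.to_numpy()}
                     ).to_csv(out / "averted.csv", index=False)
        manifest["stages"]["averted"] = {
            "point": av.point, "ci": [av.ci_low, av.ci_high],
            "n_iterations": av.n_iterations, "seed": av.seed}

        stage = "forecast"
        horizon = range(config.horizon_years[0], config.horizon_years[1] + 1)
        stage1 = extrapolate_covariates(panel, horizon)
        stage1d = dich.transform(stage1)
        trajectories = {}
        for sdict in config.scenarios:
            spec = ScenarioSpec(**sdict)
            trajectories[spec.name] = apply_scenario(
                stage1d, spec, panel,
                coverage_cuts=expo.coverage_cuts,
                adequacy_cuts=expo.adequacy_cuts_)
        proj = project_outcomes(trajectories, model,
                                n_iterations=config.iterations,
                                seed=config.seed)
        comp = compare_scenarios(proj, "expansion", "baseline")
        comp.per_year.to_csv(out / "forecast_comparison.csv", index=False)
        manifest["stages"]["forecast"] = {
            "scenarios": list(trajectories),
            "avoidable_expansion_vs_baseline":
                [comp.avoidable, comp.avoidable_low, comp.avoidable_high],
            "n_iterations": comp.n_iterations, "seed": comp.seed}

        stage = "did"
        did_cov = config.did.get("covariates",
                                 [c for c in ("poverty_rate", "gini")
                                  if c in panel.columns])
        psm = PropensityScoreMatcher(
            covariates=did_cov, anchor_year=config.anchor_years[0],
            caliper=config.did.get("caliper", 0.2)).fit(panel)
        did = psm.estimate(panel, config.anchor_years)
        psm.pairs_.to_csv(out / "did_pairs.csv", index=False)
        psm.balance_.to_csv(out / "did_balance.csv")
        manifest["stages"]["did"] = {
            "rr": did.rr, "ci": [did.rr_low, did.rr_high],
            "n_pairs": did.n_pairs, "n_dropped": did.n_dropped}

        stage = "summarize"
        variables = [v for v in config.summary_variables if v in panel.columns]
        anchors = config.anchor_years
        summary = summarize(panel, variables, anchors)
        summary.to_csv(out / "summary.csv", index=False)
        manifest["stages"]["summarize"] = {"variables": variables,
                                           "anchor_years": list(anchors)}
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out
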