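"""End-to-end orchestration: config, cohort I/O, stage execution, manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coendorsement import coendorsement_table
from .correlates import PREDICTOR_COLUMNS, correlate_grid
from .items import ITEM_LABELS, ResponseMatrix
from .network import estimate_network
from .prevalence import prevalence_table
from .synthetic import (
    COVARIATE_COLUMNS,
    SyntheticCohort,
    generate_cohort,
)
from .weighting import MarginSpec, SurveyDesign, margins_from_json, rake

log = logging.getLogger("coendorse")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated run configuration: either file inputs or a simulation preset."""

    out_dir: str = "coendorse_out"
    responses_path: str | None = None
    demographics_path: str | None = None
    margins_path: str | None = None
    preset: str | None = None
    n: int = 5000
    seed: int = 0
    rake_variables: list[str] = field(
        default_factory=lambda: ["age_band", "high_income", "university",
                                 "partnered", "employed"]
    )
    tol: float = 1e-6
    max_iter: int = 200
    trim_cap: float | None = None
    level: float = 0.99
    cv_folds: int = 10
    standardize: bool = True
    n_lambda: int = 100

    def __post_init__(self) -> None:
        file_mode = self.responses_path is not None
        sim_mode = self.preset is not None
        if file_mode == sim_mode:
            raise ConfigError(
                "exactly one of {responses/demographics paths, simulation preset} "
                "must be given"
            )
        if file_mode:
            for name in ("responses_path", "demographics_path"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ConfigError(f"{name} missing or does not exist: {path}")
            if self.margins_path is not None and not Path(self.margins_path).exists():
                raise ConfigError(f"margins file does not exist: {self.margins_path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def digest(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_cohort(
    responses_path, demographics_path
) -> tuple[ResponseMatrix, pd.DataFrame, int]:
    """Read and validate a cohort; returns (responses, demographics, n_dropped).

    Rows with missing demographics are dropped complete-case style; the
    dropped count is returned and logged.
    """
    resp = pd.read_csv(responses_path)
    demo = pd.read_csv(demographics_path)
    if "respondent_id" not in resp.columns or "respondent_id" not in demo.columns:
        raise ConfigError("both files need a respondent_id column")
    for name, df in (("responses", resp), ("demographics", demo)):
        if df["respondent_id"].duplicated().any():
            dupes = df.loc[df["respondent_id"].duplicated(), "respondent_id"]
            raise ConfigError(f"duplicate respondent_id in {name}: {sorted(set(dupes))[:5]}")
    item_cols = [c for c in resp.columns if c != "respondent_id"]
    bad = [
        c for c in item_cols
        if not resp[c].dropna().isin([0, 1]).all()
    ]
    if bad:
        raise ConfigError(f"non-binary item columns: {bad}")
    merged = demo.merge(resp, on="respondent_id", how="inner", validate="1:1")
    demo_cols = [c for c in demo.columns if c != "respondent_id"]
    complete = merged[demo_cols + item_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropped %d rows with missing data (complete-case)", n_dropped)
    merged = merged.loc[complete].reset_index(drop=True)
    responses = ResponseMatrix(
        merged[item_cols].to_numpy(dtype=int), tuple(item_cols)
    )
    demographics = merged[["respondent_id"] + demo_cols]
    return responses, demographics, n_dropped


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Write responses + demographics CSVs and a truth/margins JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resp = cohort.responses.to_frame()
    resp.insert(0, "respondent_id", cohort.demographics["respondent_id"].to_numpy())
    resp_path = out / "responses.csv"
    demo_path = out / "demographics.csv"
    truth_path = out / "truth.json"
    resp.to_csv(resp_path, index=False)
    cohort.demographics.to_csv(demo_path, index=False)
    payload = {
        "tau": cohort.truth.tau.tolist(),
        "omega": cohort.truth.omega.tolist(),
        "beta": cohort.truth.beta.tolist() if cohort.truth.beta is not None else None,
        "labels": list(cohort.truth.labels),
        "population_margins": cohort.population_margins,
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return {
        "responses": str(resp_path),
        "demographics": str(demo_path),
        "truth": str(truth_path),
    }


def _margins_for(config: PipelineConfig, cohort: SyntheticCohort | None,
                 demographics: pd.DataFrame) -> list[MarginSpec]:
    if config.margins_path is not None:
        return [
            m for m in margins_from_json(config.margins_path)
            if m.variable in config.rake_variables
        ]
    if cohort is not None:
        return [
            MarginSpec(var, cohort.population_margins[var])
            for var in config.rake_variables
        ]
    raise ConfigError("no margins available: supply margins_path")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate? -> rake -> prevalence -> correlates -> overlap -> network.

    Writes tidy CSVs plus a JSON manifest to config.out_dir and returns the
    manifest dict.  Stage failures raise with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    stage = "load"
    try:
        cohort = None
        if config.preset is not None:
            stage = "simulate"
            cohort = generate_cohort(config.n, preset=config.preset, seed=config.seed)
            write_cohort(cohort, out / "cohort")
            responses, demographics = cohort.responses, cohort.demographics
            manifest["stages"]["simulate"] = {
                "preset": config.preset, "n": cohort.n,
                "true_edges": sorted(map(list, cohort.truth.edge_set())),
            }
        else:
            responses, demographics, n_dropped = read_cohort(
                config.responses_path, config.demographics_path
            )
            manifest["stages"]["load"] = {
                "n": responses.n, "dropped_incomplete": n_dropped,
            }

        stage = "rake"
        margins = _margins_for(config, cohort, demographics)
        design = rake(
            demographics, margins, tol=config.tol, max_iter=config.max_iter,
            trim_cap=config.trim_cap,
        )
        pd.DataFrame(
            {
                "respondent_id": demographics["respondent_id"],
                "weight": design.weights,
            }
        ).to_csv(out / "weights.csv", index=False)
        manifest["stages"]["rake"] = {
            "n_iter": design.n_iter,
            "max_margin_error": design.max_margin_error,
            "variables": [m.variable for m in margins],
        }

        stage = "prevalence"
        pooled = prevalence_table(responses, design, level=config.level)
        pooled.to_csv(out / "prevalence_pooled.csv", index=False)
        by_country = prevalence_table(
            responses, design, by=demographics["country"],
            group_name="country", level=config.level,
        )
        by_country.to_csv(out / "prevalence_by_country.csv", index=False)
        by_age = prevalence_table(
            responses, design, by=demographics["age_band"],
            group_name="age_band", level=config.level,
        )
        by_age.to_csv(out / "prevalence_by_age.csv", index=False)
        manifest["stages"]["prevalence"] = {"items": len(responses.labels)}

        stage = "correlates"
        grid = correlate_grid(
            responses, demographics, design,
            predictors=tuple(c for c in PREDICTOR_COLUMNS
                             if c in demographics.columns),
            level=config.level,
        )
        grid.to_csv(out / "correlates.csv", index=False)
        manifest["stages"]["correlates"] = {
            "cells": len(grid), "failed": int((grid["error"] != "").sum()),
        }

        stage = "overlap"
        table = coendorsement_table(responses, design)
        table.to_frame().to_csv(out / "coendorsement.csv", index=False)
        manifest["stages"]["overlap"] = {"N_weighted": table.N}

        stage = "network"
        net = estimate_network(
            responses, design, K=config.cv_folds, seed=config.seed,
            standardize=config.standardize, level=config.level,
            n_lambda=config.n_lambda,
        )
        net.edge_table().to_csv(out / "network_edges.csv", index=False)
        net.node_table().to_csv(out / "network_nodes.csv", index=False)
        with open(out / "network_graph.json", "w") as fh:
            json.dump(net.to_graph_json(), fh, indent=2)
        manifest["stages"]["network"] = {
            "edge_count": net.edge_count,
            "mean_support_size": net.mean_support_size,
            "mean_auc": float(np.mean([f.cv_auc for f in net.node_fits])),
        }
        if cohort is not None:
            from .network import edge_recovery_auc

            manifest["stages"]["network"]["edge_recovery_auc"] = (
                edge_recovery_auc(net, cohort.truth.omega)
                if cohort.truth.omega.any()
                else None
            )
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    _write_summary(out, manifest)
    return manifest


def _write_summary(out: Path, manifest: dict) -> None:
    lines = [f"coendorse {manifest['version']}  (config {manifest['config_hash']})"]
    for stage, info in manifest["stages"].items():
        lines.append(f"  {stage}: " + ", ".join(f"{k}={v}" for k, v in info.items()
                                                if k != "true_edges"))
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
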