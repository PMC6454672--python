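"""End-to-end pipeline: simulate (optional) -> clean -> estimate -> derive criteria.

Stages communicate only through documented CSV/JSON files, so any stage can
be run standalone on external data.  Every run writes a manifest recording
the configuration, seeds and package version; identical configs and seeds
yield byte-identical estimate tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bn import BayesianNetworkIncidence
from .cleaning import clean_cohort
from .cohort import CohortConfig, generate_cohort, read_cohort, write_cohort
from .criteria import IncidenceTable, derive_criteria, load_baseline, load_reference_tables, table_from_estimates

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    output_dir: str = "strokescreen_out"
    input_cohort: str | None = None          # CSV path; None -> simulate
    simulate: CohortConfig | None = None
    alpha: float = 0.05
    ks: tuple[int, ...] = (1, 2, 3)
    n_iterations: int = 10000
    fraction: float = 0.8
    semantics: str = "marginal"
    seed: int = 0
    baseline: float | None = None            # None -> packaged baseline
    threshold: float = 2.5
    reference_threshold: float | None = 3.0
    skip_estimate: bool = False              # derive criteria from the packaged tables

    def validate(self) -> None:
        if self.input_cohort is not None and not Path(self.input_cohort).exists():
            raise PipelineError(f"config: input cohort file not found: {self.input_cohort}")
        if not set(self.ks) <= {1, 2, 3}:
            raise PipelineError(f"config: ks must be within {{1,2,3}}, got {self.ks}")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "simulate"}
        d["ks"] = list(self.ks)
        d["simulate"] = self.simulate.to_dict() if self.simulate else None
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a dict of artifact paths.  Raises PipelineError on failure."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    stage = "simulate"
    try:
        if config.input_cohort is not None:
            cohort = read_cohort(config.input_cohort)
        else:
            sim = config.simulate or CohortConfig(seed=config.seed)
            cohort = generate_cohort(sim)
            path = out / "cohort.csv"
            write_cohort(cohort, path, seed=sim.seed)
            artifacts["cohort"] = str(path)

        stage = "clean"
        cleaned, report = clean_cohort(cohort, alpha=config.alpha)
        cleaned_path = out / "cleaned.csv"
        write_cohort(cleaned, cleaned_path, seed=config.seed)
        report.to_json(out / "exclusion_report.json")
        artifacts["cleaned"] = str(cleaned_path)
        artifacts["exclusion_report"] = str(out / "exclusion_report.json")

        baseline = config.baseline if config.baseline is not None else load_baseline()

        stage = "estimate"
        if config.skip_estimate:
            tables = load_reference_tables()
        else:
            est = BayesianNetworkIncidence(
                semantics=config.semantics, n_iterations=config.n_iterations,
                fraction=config.fraction, random_state=config.seed,
            ).fit(cleaned)
            table = est.estimate_table(config.ks)
            est_path = out / "estimates.csv"
            table.to_csv(est_path, index=False, float_format="%.6g")
            artifacts["estimates"] = str(est_path)
            tables = {k: table_from_estimates(table, k, baseline) for k in config.ks}

        stage = "criteria"
        if set(tables) >= {1, 2, 3}:
            cs = derive_criteria(tables, config.threshold, config.reference_threshold)
            (out / "criteria.json").write_text(json.dumps(cs.to_dict(), indent=2))
            (out / "criteria.md").write_text(cs.to_markdown())
            artifacts["criteria"] = str(out / "criteria.json")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-named failure contract
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
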