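"""End-to-end pipeline orchestration and report assembly.

A :class:`PipelineConfig` names the input (a vial-level CSV or a simulation
scenario), the stages to run, and the sampling settings; :func:`run_pipeline`
executes validate -> transforms -> line statistics -> mixed models and writes
one CSV per stage plus a provenance block (config hash, seeds, package
version) so every numeric output is traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .data import FitnessTable, read_fitness_table, validate, write_fitness_table
from .gibbs import AnimalModelVC
from .line_stats import LineAverageModel
from .reml import FitnessLMM
from .simulate import SimulationParams, default_reference_params, simulate

logger = logging.getLogger(__name__)

ALL_STAGES = ("validate", "line_stats", "lmm", "vc")


@dataclass
class PipelineConfig:
    """Flat-schema pipeline configuration (YAML-serialisable)."""

    input_csv: str | None = None          # mutually exclusive with simulate=True
    simulate: bool = False
    sim_params: dict | None = None        # SimulationParams.to_config() payload
    stages: tuple = ALL_STAGES
    n_boot: int = 10_000
    seed: int = 0
    mcmc_chains: int = 3
    mcmc_iters: int = 60_000
    mcmc_burn_in: int = 10_000
    mcmc_thin: int = 50
    mcmc_priors: dict | None = None   # kwargs of AnimalModelVC.fit priors
    out_dir: str = "hemifit_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where outputs land does not change them
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    out_dir: Path
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _load_input(config: PipelineConfig) -> FitnessTable:
    if config.simulate:
        if config.sim_params:
            params = SimulationParams.from_config(config.sim_params)
        else:
            params = default_reference_params(seed=config.seed)
        return simulate(params, seed=config.seed)
    if not config.input_csv:
        raise ValueError("config needs input_csv or simulate: true")
    return read_fitness_table(config.input_csv)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages; outputs land in ``config.out_dir``.

    Any stage error aborts with the stage name; outputs of completed stages
    are preserved on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out_dir=out)
    report.provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_boot": config.n_boot,
        "version": __version__,
        "stages": list(config.stages),
    }

    table = _load_input(config)
    if config.simulate:
        sim_path = out / "simulated_data.csv"
        write_fitness_table(table, sim_path)
        report.outputs["simulated_data"] = sim_path

    stage = "init"
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            if stage == "validate":
                rep = validate(table)
                path = out / "validation.json"
                path.write_text(json.dumps({
                    "n_records": rep.n_records, "n_lines": rep.n_lines,
                    "violations": rep.violations,
                }, indent=2))
                report.outputs["validation"] = path
                report.warnings.extend(rep.violations)
            elif stage == "line_stats":
                res = LineAverageModel(table).fit(
                    n_boot=config.n_boot, seed=config.seed
                )
                path = out / "line_stats.csv"
                _write_csv(res.estimates.drop(columns="spec"), path, report.provenance)
                report.outputs["line_stats"] = path
                lm_path = out / "line_means.csv"
                res.model.line_means.matrix.rename_axis("line").to_csv(lm_path)
                report.outputs["line_means"] = lm_path
            elif stage == "lmm":
                fit = FitnessLMM.from_table(table).fit()
                path = out / "lrt_table.csv"
                _write_csv(fit.lrt_random_terms(), path, report.provenance)
                report.outputs["lmm"] = path
            elif stage == "vc":
                res = AnimalModelVC.from_table(table).fit(
                    chains=config.mcmc_chains, iters=config.mcmc_iters,
                    burn_in=config.mcmc_burn_in, thin=config.mcmc_thin,
                    seed=config.seed, **(config.mcmc_priors or {}),
                )
                path = out / "vc_summary.csv"
                _write_csv(res.summary_frame(), path, report.provenance)
                report.outputs["vc"] = path
                draws_path = out / "vc_draws.csv"
                res.draws_frame().to_csv(draws_path, index=False)
                report.outputs["vc_draws"] = draws_path
            else:
                raise ValueError(f"unknown stage {stage!r}")
            logger.info("stage %s done in %.1fs (%d records)",
                        stage, time.perf_counter() - t0, table.n_records)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "provenance.json").write_text(json.dumps(report.provenance, indent=2))
    report.outputs["provenance"] = out / "provenance.json"
    return report


def _write_csv(frame, path: Path, provenance: dict) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# hemifit {provenance['version']} config={provenance['config_hash']} "
            f"seed={provenance['seed']} n_boot={provenance['n_boot']}\n"
        )
        frame.to_csv(fh, index=False)
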