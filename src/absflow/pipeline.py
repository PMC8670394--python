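"""End-to-end pipeline: knowledge-base construction, workflow building and
execution of the selected algorithms, with a written report bundle.

Stages (each logged, each halting with its name on failure):

1. merge the DM core and medical domain knowledge bases and extract the
   task sub-ontology;
2. generate or load the cohort;
3. profile the data and build the workflow by knowledge-base queries;
4. execute the workflow: impute if the workflow selected an imputation
   algorithm, then run the criteria-function and partition-functional
   analyses it selected;
5. Mann-Whitney comparison report.

Everything is seeded, so re-running a configuration reproduces the bundle
byte for byte.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compare import comparison_suite, format_report
from .criteria import best_subset_profile, cf_dynamics
from .datasets import CohortConfig, CohortDataset, generate
from .impute import ImputationSpec, impute_cohort
from .kb import KnowledgeBase, extract_subontology, load_kb, merge, save_kb
from .knowledge import CONSISTENCY_TASK, load_dm_core, load_medical_domain
from .partition import functional_dynamics
from .workflow import Workflow, build_workflow, profile_data


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    task: str = CONSISTENCY_TASK
    dm_core_path: str | None = None  # defaults to the packaged knowledge bases
    domain_path: str | None = None
    data_path: str | None = None  # long-format CSV; None -> synthetic cohort
    cohort: CohortConfig = field(default_factory=CohortConfig)
    use_extracted: bool = True
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    subset_sizes: tuple[int, ...] = (2, 3, 4)
    alpha: float = 0.05
    restarts: int = 10
    seed: int = 0
    output_dir: str = "absflow_output"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            raw["cohort"] = CohortConfig.from_dict(raw["cohort"])
        if "imputation" in raw and isinstance(raw["imputation"], dict):
            raw["imputation"] = ImputationSpec(**raw["imputation"])
        if "subset_sizes" in raw:
            raw["subset_sizes"] = tuple(raw["subset_sizes"])
        return cls(**raw)


@dataclass
class PipelineResult:
    workflow: Workflow
    output_dir: Path
    tables: dict[str, Path]


def _load_kbs(config: PipelineConfig) -> KnowledgeBase:
    core = (load_kb(config.dm_core_path) if config.dm_core_path
            else load_dm_core())
    domain = (load_kb(config.domain_path) if config.domain_path
              else load_medical_domain())
    return merge(core, domain, "merged")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"absflow {__version__} on Python {platform.python_version()}, "
        f"numpy {np.__version__}",
        f"seed: {config.seed}",
    ]
    tables: dict[str, Path] = {}
    t_start = time.perf_counter()

    def log(stage: str, message: str) -> None:
        dt = time.perf_counter() - t_start
        log_lines.append(f"[{dt:8.2f}s] {stage}: {message}")

    def run_stage(stage: str, fn):
        try:
            result = fn()
        except Exception as exc:
            log(stage, f"FAILED ({exc})")
            (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
            raise PipelineError(stage, exc) from exc
        return result

    # 1. knowledge base
    def stage_kb():
        merged = _load_kbs(config)
        kb = (extract_subontology(merged, config.task)
              if config.use_extracted else merged)
        save_kb(kb, out / "knowledge_base.kb")
        log("knowledge-base", f"{len(kb)} entities, {len(kb.axioms)} axioms"
            + (" (extracted sub-ontology)" if config.use_extracted else ""))
        return kb

    kb = run_stage("knowledge-base", stage_kb)

    # 2. data
    def stage_data():
        if config.data_path:
            ds = CohortDataset.read_csv(config.data_path)
            log("data", f"loaded {config.data_path}: {ds.n_patients} patients")
        else:
            cohort = config.cohort
            if cohort.seed != config.seed:
                cohort = CohortConfig.from_dict({**cohort.to_dict(),
                                                 "seed": config.seed})
            ds = generate(cohort)
            log("data", f"generated cohort: {ds.n_patients} patients, "
                f"{ds.n_parameters} parameters, {ds.n_timepoints} points, "
                f"missing fraction {ds.missing_fraction:.3f}")
        return ds

    dataset = run_stage("data", stage_data)

    # 3. profile + workflow
    def stage_workflow():
        profile = profile_data(dataset, kb, alpha=config.alpha)
        wf = build_workflow(kb, config.task, profile)
        (out / "profile.json").write_text(
            json.dumps({"characteristics": sorted(profile.characteristics),
                        "metadata": profile.metadata}, indent=2, default=float),
            encoding="utf-8")
        (out / "workflow.json").write_text(wf.to_json(), encoding="utf-8")
        log("workflow", f"profile {sorted(profile.characteristics)}; "
            f"selected {wf.selections()}")
        return wf

    workflow = run_stage("workflow", stage_workflow)
    selections = set(workflow.selections())

    # 4. execution
    def stage_impute():
        if "KNN_Imputation_ED" not in selections:
            log("imputation", "skipped (workflow selected no imputation algorithm)")
            return dataset
        completed = impute_cohort(dataset, config.imputation)
        log("imputation", f"k={config.imputation.k}, "
            f"filled {int(dataset.mask.sum())} entries")
        return completed

    completed = run_stage("imputation", stage_impute)

    cf_result = None
    if "CF_Algorithm" in selections:
        def stage_cf():
            res = cf_dynamics(completed)
            path = out / "cf_summary.csv"
            res.summary.to_csv(path, index=False)
            tables["cf_summary"] = path
            if config.subset_sizes:
                est = completed.timepoint_matrix(1)
                ev = completed.timepoint_matrix(completed.n_timepoints)
                prof = best_subset_profile(est, list(config.subset_sizes),
                                           eval_data=ev,
                                           names=completed.parameters)
                spath = out / "subset_profile.csv"
                prof.to_csv(spath, index=False)
                tables["subset_profile"] = spath
            log("criteria-function", f"{len(res.summary)} summary rows")
            return res

        cf_result = run_stage("criteria-function", stage_cf)

    if "Kupershtokh_Mirkin_Trofimov_Algorithm" in selections:
        def stage_functional():
            fd = functional_dynamics(completed, restarts=config.restarts,
                                     seed=config.seed)
            path = out / "functional_dynamics.csv"
            fd.table.to_csv(path, index=False)
            tables["functional_dynamics"] = path
            crit = {str(g): {"F": fd.critical_period(g),
                             "a": fd.critical_period(g, "a")}
                    for g in sorted(fd.table["group"].unique())}
            (out / "critical_periods.json").write_text(
                json.dumps(crit, indent=2), encoding="utf-8")
            (out / "partitions.json").write_text(
                json.dumps({f"group{g}_t{t}": p.to_dict()
                            for (g, t), p in fd.partitions.items()}, indent=2),
                encoding="utf-8")
            log("functional", f"{len(fd.table)} indicator rows")
            return fd

        run_stage("functional", stage_functional)

    # 5. comparisons
    if cf_result is not None:
        def stage_compare():
            report = comparison_suite(cf_result, alpha=config.alpha)
            path = out / "cf_comparisons.csv"
            report.to_csv(path, index=False)
            tables["cf_comparisons"] = path
            (out / "cf_comparisons.txt").write_text(
                format_report(report, config.alpha) + "\n", encoding="utf-8")
            log("comparison", f"{len(report)} contrasts, "
                f"{int(report['significant'].sum())} significant")
            return report

        run_stage("comparison", stage_compare)

    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return PipelineResult(workflow=workflow, output_dir=out, tables=tables)
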