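"""Config-driven pipeline: simulate -> metrics -> inference -> report.

A run is fully determined by a validated :class:`RunConfig` plus one global
seed; the seed is expanded into per-stage substreams so stages can be rerun
independently.  Every artifact is a text file (CSV for tables, JSON for fits
and the manifest, markdown for the report) and the manifest inventories all
of them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .agents import CohortSpec, RTParams, UpdateRuleParams, simulate_cohort
from .metrics import build_analysis_table, condition_summary
from .models import (
    ConditionLearningRateModel,
    QuadraticUpdateModel,
    ReactionTimeModel,
    SegmentedUpdateModel,
    ThresholdLogisticModel,
)
from .recovery import run_recovery
from .report import render_descriptives, render_fit, render_report
from .task_design import BlockSchedule, SegmentSpec, canonical_schedule

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "make_fixtures", "load_config"]

_MODEL_NAMES = ("condition", "quadratic", "segmented", "logistic", "rt")


class SegmentRow(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mean: float
    sd: float = 1.7
    n_trials: int
    trend: str = "randomly_fluctuate"


class SchedulesSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    blocks: list[str] = Field(default_factory=lambda: ["gradual", "abrupt"])
    custom: dict[str, list[SegmentRow]] = Field(default_factory=dict)
    max_step: float = 6.0


class AgentSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = "linear_by_condition"
    n_agents: int = 109
    update_noise_sd: float = 1.5
    p_no_update: float = 0.05
    participant_lr_sd: float = 0.1
    participant_intercept_sd: float = 0.3
    counterbalance: bool = True
    zero_noise: bool = False


class AnalysisSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    models: list[str] = Field(default_factory=lambda: list(_MODEL_NAMES))
    psi_min: float = 1.0
    psi_max: float = 12.0
    psi_step: float = 0.05
    logistic_threshold: float | str = "psi_hat"  # estimated breakpoint by default


class RecoverySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    replicates: int = 10
    include_rt: bool = False


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    schedules: SchedulesSection = Field(default_factory=SchedulesSection)
    agent: AgentSection = Field(default_factory=AgentSection)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)
    recovery: RecoverySection = Field(default_factory=RecoverySection)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class RunManifest(BaseModel):
    config_hash: str
    seed: int | None
    package_version: str
    row_counts: dict[str, int]
    n_rt_excluded: int
    outputs: list[str]

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def _build_params(cfg: RunConfig):
    a = cfg.agent
    up = UpdateRuleParams(
        mode=a.mode,
        update_noise_sd=0.0 if a.zero_noise else a.update_noise_sd,
        p_no_update=0.0 if a.zero_noise else a.p_no_update,
    )
    rp = RTParams().zero_noise() if a.zero_noise else RTParams()
    spec = CohortSpec(
        n_agents=a.n_agents,
        participant_lr_sd=0.0 if a.zero_noise else a.participant_lr_sd,
        participant_intercept_sd=0.0 if a.zero_noise else a.participant_intercept_sd,
        counterbalance=a.counterbalance,
    )
    return spec, up, rp


def _build_schedules(cfg: RunConfig) -> dict[str, BlockSchedule]:
    out: dict[str, BlockSchedule] = {}
    for kind in cfg.schedules.blocks:
        if kind in cfg.schedules.custom:
            segs = tuple(
                SegmentSpec(r.mean, r.sd, r.n_trials, r.trend)
                for r in cfg.schedules.custom[kind]
            )
            out[kind] = BlockSchedule(block_kind=kind, segments=segs)
        else:
            out[kind] = canonical_schedule(kind)
    return out


def run_pipeline(
    config: RunConfig,
    seed: int | None = None,
    out_dir: str | Path = "frogpan_run",
) -> RunManifest:
    """Execute all configured stages, writing artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)
    spec, up, rp = _build_params(config)
    schedules = _build_schedules(config)

    ss = np.random.SeedSequence(seed)
    s_cohort, s_recovery = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))

    outputs: list[str] = []
    row_counts: dict[str, int] = {}

    cohort = simulate_cohort(spec, up, rp, schedules=schedules, seed=s_cohort)
    cohort.to_csv(out / "cohort.csv", index=False)
    outputs.append("cohort.csv")
    row_counts["cohort"] = len(cohort)

    table = build_analysis_table(cohort)
    table.to_csv(out / "analysis.csv", index=False)
    outputs.append("analysis.csv")
    row_counts["analysis"] = len(table)
    n_excluded = int((~table["rt_included"]).sum())

    summary = condition_summary(table)
    summary.to_csv(out / "descriptives.csv", index=False)
    outputs.append("descriptives.csv")

    sections = {"descriptives": render_descriptives(summary)}
    fitted: dict[str, object] = {}
    an = config.analysis
    for name in an.models:
        if name == "condition":
            model = ConditionLearningRateModel().fit(table)
            title = "Condition-wise learning rates (mixed model)"
        elif name == "quadratic":
            model = QuadraticUpdateModel().fit(table)
            title = "Quadratic nonlinearity probe"
        elif name == "segmented":
            model = SegmentedUpdateModel(
                psi_min=an.psi_min, psi_max=an.psi_max, psi_step=an.psi_step
            ).fit(table)
            title = "Segmented breakpoint model"
        elif name == "logistic":
            thr = an.logistic_threshold
            if thr == "psi_hat":
                thr = fitted["segmented"].psi_ if "segmented" in fitted else 5.337
            model = ThresholdLogisticModel(threshold=float(thr)).fit(table)
            title = f"Threshold logistic (|PE| > {float(thr):.3f})"
        elif name == "rt":
            model = ReactionTimeModel().fit(table)
            title = "Reaction-time model"
        else:
            raise ValueError(f"unknown model {name!r} in analysis.models")
        fitted[name] = model
        with open(out / "fits" / f"{name}.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
        outputs.append(f"fits/{name}.json")
        sections[name] = render_fit(title, model)

    if config.recovery.enabled:
        rep = run_recovery(
            spec,
            up,
            rp,
            n_replicates=config.recovery.replicates,
            seed=s_recovery,
            include_rt=config.recovery.include_rt,
        )
        rep.table.to_csv(out / "recovery.csv", index=False)
        outputs.append("recovery.csv")
        row_counts["recovery"] = len(rep.table)

    (out / "report.md").write_text(render_report(sections))
    outputs.append("report.md")

    outputs.append("manifest.json")  # the manifest inventories itself
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=seed,
        package_version=__version__,
        row_counts=row_counts,
        n_rt_excluded=n_excluded,
        outputs=sorted(outputs),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def make_fixtures(seed: int = 0, out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Small cohorts used by the test suite.

    A 5-agent noisy miniature plus zero-noise linear and segmented cohorts
    (exact coefficient recovery); stable given ``seed``.
    """
    rng = np.random.default_rng(seed)
    s1, s2, s3 = (int(v) for v in rng.integers(0, 2**31 - 1, 3))
    mini = simulate_cohort(CohortSpec(n_agents=5), seed=s1)
    spec0 = CohortSpec(n_agents=5, participant_lr_sd=0.0, participant_intercept_sd=0.0)
    zero_linear = simulate_cohort(
        spec0, UpdateRuleParams().zero_noise(), RTParams().zero_noise(), seed=s2
    )
    zero_segmented = simulate_cohort(
        spec0,
        UpdateRuleParams.segmented_defaults().zero_noise(),
        RTParams().zero_noise(),
        seed=s3,
    )
    fixtures = {
        "mini_cohort": mini,
        "zero_noise_linear": zero_linear,
        "zero_noise_segmented": zero_segmented,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in fixtures.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return fixtures
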