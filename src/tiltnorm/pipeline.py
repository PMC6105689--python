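"""Configuration, table serialization, and end-to-end orchestration.

A run is fully described by a `RunConfig` (model, design, cohort, fitting
and analysis blocks plus a master seed) that round-trips through YAML.
`run_pipeline` executes simulate -> fit -> analyze, writing the trial,
participant, fits and report files, and is byte-reproducible given the same
config and seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    DEFAULT_EXCLUSION_THRESHOLD,
    analyze_cohort,
    group_report,
    results_table,
)
from .exceptions import PipelineStageError, ValidationError
from .model import (
    DEFAULT_DECODE_WINDOW,
    DEFAULT_EXCITATORY_HWHH,
    DEFAULT_N_NEURONS,
    DEFAULT_POOL_HWHH,
    NormalizationParams,
    OrientationTuning,
)
from .observer import (
    TRIAL_COLUMNS,
    CohortSpec,
    GroupSpec,
    SessionDesign,
    generate_cohort,
)
from .psychometric import DEFAULT_LAPSE_MAX, DEFAULT_N_BOOTSTRAP

__all__ = [
    "ModelConfig",
    "FittingConfig",
    "AnalysisConfig",
    "RunConfig",
    "RunReport",
    "read_trials",
    "write_trials",
    "run_pipeline",
]

logger = logging.getLogger("tiltnorm")


class TrialSchemaWarning(UserWarning):
    """Accepted-but-flagged deviations in an imported trial table."""


@dataclass(frozen=True)
class ModelConfig:
    """Serializable face of `NormalizationParams` plus decoder settings."""

    r0: float = 0.0
    rmax: float = 50.0
    c50: float = 20.0
    kappa: float = 1.0
    exponent: float = 2.0
    excitatory_hwhh: float = DEFAULT_EXCITATORY_HWHH
    pool_hwhh: float = DEFAULT_POOL_HWHH
    n_neurons: int = DEFAULT_N_NEURONS
    decode_window: float = DEFAULT_DECODE_WINDOW

    def to_params(self) -> NormalizationParams:
        return NormalizationParams(
            r0=self.r0,
            rmax=self.rmax,
            c50=self.c50,
            kappa=self.kappa,
            exponent=self.exponent,
            excitatory_tuning=OrientationTuning.from_half_width(self.excitatory_hwhh),
            pool_tuning=OrientationTuning.from_half_width(self.pool_hwhh),
        )


@dataclass(frozen=True)
class FittingConfig:
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP
    coverage: float = 0.95
    lapse_max: float = DEFAULT_LAPSE_MAX


@dataclass(frozen=True)
class AnalysisConfig:
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD
    alpha: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Complete, seedable description of one simulate-fit-analyze run."""

    schema_version: int = 1
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    design: SessionDesign = field(default_factory=SessionDesign)
    cohort: CohortSpec = field(default_factory=CohortSpec.matched_default)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"]["orientation_levels"] = list(self.design.orientation_levels)
        d["design"]["conditions"] = list(self.design.conditions)
        d["design"]["interval_orders"] = list(self.design.interval_orders)
        d["cohort"]["groups"] = [asdict(g) for g in self.cohort.groups]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        version = d.pop("schema_version", 1)
        if version != 1:
            raise ValidationError(f"unsupported config schema version {version}")
        model = ModelConfig(**d.get("model", {}))
        design_d = dict(d.get("design", {}))
        for key in ("orientation_levels", "conditions", "interval_orders"):
            if key in design_d:
                design_d[key] = tuple(design_d[key])
        design = SessionDesign(**design_d)
        cohort_d = d.get("cohort", {})
        groups = tuple(GroupSpec(**g) for g in cohort_d.get("groups", []))
        cohort = CohortSpec(groups) if groups else CohortSpec.matched_default()
        fitting = FittingConfig(**d.get("fitting", {}))
        analysis = AnalysisConfig(**d.get("analysis", {}))
        return cls(
            schema_version=1,
            seed=int(d.get("seed", 0)),
            model=model,
            design=design,
            cohort=cohort,
            fitting=fitting,
            analysis=analysis,
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        return cls.from_dict(yaml.safe_load(text))


def write_trials(path, trials: pd.DataFrame) -> None:
    """Write a trial table in the package's CSV schema."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table is missing columns: {missing}")
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path, expected_levels=None) -> pd.DataFrame:
    """Read and validate a trial CSV.

    Strict schema: exactly the declared columns; responses in {0, 1, empty};
    interval in {1, 2}.  Orientations outside ``expected_levels`` are
    accepted but flagged with a `TrialSchemaWarning` (supports external
    datasets with other designs).  Errors name the offending field and the
    first offending CSV line (header = line 1).
    """
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if unknown:
        raise ValidationError(f"unknown columns in trial table: {unknown}")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trial table is missing columns: {missing}")

    def _line(mask) -> int:
        return int(np.flatnonzero(mask)[0]) + 2  # +1 header, +1 one-based

    resp = df["response_chose_varied"]
    bad = resp.notna() & ~resp.isin([0, 1])
    if bad.any():
        raise ValidationError(
            f"response_chose_varied must be 0, 1 or empty; "
            f"first offense at line {_line(bad)}"
        )
    bad = ~df["varied_interval"].isin([1, 2])
    if bad.any():
        raise ValidationError(
            f"varied_interval must be 1 or 2; first offense at line {_line(bad)}"
        )
    bad = ~df["condition"].isin(["single", "compound"])
    if bad.any():
        raise ValidationError(
            f"condition must be 'single' or 'compound'; "
            f"first offense at line {_line(bad)}"
        )
    if expected_levels is not None:
        lv = df["varied_orientation_deg"].astype(float)
        off = ~lv.isin([float(x) for x in expected_levels])
        if off.any():
            warnings.warn(
                f"{int(off.sum())} trials have orientations outside the "
                f"configured levels (first at line {_line(off)})",
                TrialSchemaWarning,
                stacklevel=2,
            )
    return df


@dataclass
class RunReport:
    """Summary of one end-to-end run, serializable to JSON."""

    config: dict
    seed: int
    version: str
    n_participants: int
    n_trials: int
    n_excluded: int
    n_not_converged: int
    group_report: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_pipeline(config: RunConfig, outdir=None) -> RunReport:
    """Simulate a cohort, fit every participant, and run the group analysis.

    Writes ``trials.csv``, ``participants.csv``, ``fits.csv`` and
    ``report.json`` under ``outdir`` when given.  Deterministic given the
    config (the master seed drives every draw).
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    try:
        trials, participants = generate_cohort(
            config.cohort, config.design, seed=config.seed,
            model_params=config.model.to_params(),
        )
    except Exception as e:  # noqa: BLE001 - stage tagging
        raise PipelineStageError("simulate", str(e)) from e
    logger.info("simulated %d trials for %d participants",
                len(trials), len(participants))

    try:
        results = analyze_cohort(
            trials,
            participants,
            exclusion_threshold=config.analysis.exclusion_threshold,
            lapse_max=config.fitting.lapse_max,
            n_bootstrap=config.fitting.n_bootstrap,
            coverage=config.fitting.coverage,
            seed=config.seed,
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("fit", str(e)) from e
    for r in results:
        if not r.included:
            logger.info("excluded %s (accuracy %.3f)", r.participant_id,
                        r.overall_accuracy)

    try:
        report = group_report(results, alpha=config.analysis.alpha)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("analyze", str(e)) from e

    n_not_conv = sum(
        1
        for r in results
        for f in (r.fit_single, r.fit_compound)
        if f is not None and not f.converged
    )
    run = RunReport(
        config=config.to_dict(),
        seed=config.seed,
        version=__version__,
        n_participants=len(participants),
        n_trials=len(trials),
        n_excluded=sum(not r.included for r in results),
        n_not_converged=n_not_conv,
        group_report=report,
    )
    if outdir is not None:
        write_trials(outdir / "trials.csv", trials)
        participants.to_csv(outdir / "participants.csv", index=False)
        results_table(results).to_csv(outdir / "fits.csv", index=False)
        run.to_json(outdir / "report.json")
    return run
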