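"""End-to-end run: simulate -> validate -> QC -> metrics -> stats -> report.

Every run is reproducible from its persisted YAML config plus the root
seed; all artifacts are plain CSV/JSON so any stage can be resumed from the
previous stage's output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DesignSpec, DyadParams
from .io_events import read_events, read_meta, validate_events, write_events, write_meta
from .metrics import condition_summary, trial_metrics
from .qc import run_qc
from .simulate import simulate_dataset
from .stats import anova_table, rm_anova

log = logging.getLogger("duetsync")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable configuration of a full analysis run."""

    params: DyadParams = field(default_factory=DyadParams)
    n_pairs: int = 19
    trials_per_condition: int = 32
    accuracy_pool: str = "keystrokes"  # or 'trials'
    per_trial_abs: bool = False
    out_dir: str = "duetsync_run"
    seed: int = 0

    def design(self) -> DesignSpec:
        return DesignSpec(n_pairs=self.n_pairs, trials_per_condition=self.trials_per_condition)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        params = d.pop("params", {})
        return cls(params=DyadParams(**params), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages; returns a name -> path map of written artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    params = dataclasses.replace(config.params, seed=config.seed)
    design = config.design()

    def save(name: str, fn) -> None:
        paths[name] = out / name
        fn(paths[name])

    try:
        events, meta = simulate_dataset(params, design)
    except Exception as exc:  # pragma: no cover - construction errors
        raise PipelineError("simulate", str(exc)) from exc
    save("events.csv", lambda p: write_events(events, p))
    save("trial_meta.csv", lambda p: write_meta(meta, p))
    log.info("simulated %d trials (%d pairs)", len(meta), design.n_pairs)

    try:
        events_rt = read_events(paths["events.csv"])
        meta_rt = read_meta(paths["trial_meta.csv"])
        validate_events(events_rt)
    except Exception as exc:
        raise PipelineError("validate", str(exc)) from exc

    try:
        retained, report = run_qc(events_rt, meta_rt, scores=list(design.pieces), design=design)
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc
    save("qc_flags.csv", lambda p: report.flags.to_csv(p))
    save(
        "qc_report.csv",
        lambda p: report.mean_retained_per_pair().rename("mean_retained_per_pair").to_csv(p),
    )
    log.info(
        "QC retained %d / %d trials; per-pair means by condition: %s",
        report.n_retained,
        report.n_total,
        report.mean_retained_per_pair().round(2).to_dict(),
    )

    try:
        retained_meta = meta_rt.merge(
            report.flags.reset_index()[["pair_id", "session", "trial_id", "retained"]],
            on=["pair_id", "session", "trial_id"],
        )
        retained_meta = retained_meta[retained_meta["retained"]]
        per_trial = trial_metrics(retained, retained_meta)
        summary = condition_summary(
            retained, retained_meta, pool=config.accuracy_pool, per_trial_abs=config.per_trial_abs
        )
    except Exception as exc:
        raise PipelineError("metrics", str(exc)) from exc
    save("trial_metrics.csv", lambda p: per_trial.to_csv(p, index=False))
    save("condition_summary.csv", lambda p: summary.to_csv(p, index=False))

    try:
        tables = stats_tables(summary)
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc
    for name, table in tables.items():
        save(f"{name}.csv", lambda p, t=table: t.to_csv(p, index=False))

    run_log = {
        "duetsync_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_trials": int(len(meta)),
        "n_retained": int(report.n_retained),
        "mean_retained_per_pair": {
            k: float(v) for k, v in report.mean_retained_per_pair().items()
        },
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    save("run_log.json", lambda p: p.write_text(json.dumps(run_log, indent=2) + "\n"))
    return paths


def stats_tables(summary: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The full behavioural inference battery on a ConditionSummary table.

    Mirrors the reported layout: 2 x 2 rmANOVAs (familiarity x tempo) on
    mean absolute asynchrony, asynchrony SD, and lag-0 z; a 2 x 2 x 2 ANOVA
    adding lag (-1 vs +1); and the per-lag 2 x 2 follow-ups.
    """
    df = summary.copy()
    df["familiarity"] = df["condition"].str[0]
    df["tempo"] = df["condition"].str[1]
    out: dict[str, pd.DataFrame] = {}
    out["anova_abs_async"] = anova_table(
        rm_anova(df, "mean_abs_async", ["familiarity", "tempo"])
    )
    out["anova_sd_async"] = anova_table(rm_anova(df, "mean_sd_async", ["familiarity", "tempo"]))
    out["anova_lag0"] = anova_table(rm_anova(df, "z_lag_0", ["familiarity", "tempo"]))

    long = df.melt(
        id_vars=["participant", "familiarity", "tempo"],
        value_vars=["z_lag_m1", "z_lag_p1"],
        var_name="lag",
        value_name="z",
    )
    out["anova_lag_3way"] = anova_table(rm_anova(long, "z", ["familiarity", "tempo", "lag"]))
    for col, name in (("z_lag_m1", "anova_lag_m1"), ("z_lag_p1", "anova_lag_p1")):
        out[name] = anova_table(rm_anova(df, col, ["familiarity", "tempo"]))
    return out
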