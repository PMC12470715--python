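"""File formats binding simulations and metrics into reproducible experiments.

Traces are tidy long-format CSV (run, minute, baseline_sbp, generated_sbp,
bolus_mg, infusion_mg_per_min); floats are written at round-trip precision
so a replayed experiment is byte-identical. The manifest is the fully
resolved run configuration as JSON and is itself a valid ``--config`` input,
which is how exact replay works. Metric reports go out as per-run CSV plus
a JSON summary (mean and SD per metric).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .baseline import BPTrace
from .engine import RunConfig, RunResult
from .kernel import DoseSchedule
from .metrics import BatchReport

__all__ = [
    "write_traces",
    "read_traces",
    "write_manifest",
    "load_config",
    "write_report",
    "read_report_json",
]

TRACE_COLUMNS = [
    "run", "minute", "baseline_sbp", "generated_sbp", "bolus_mg",
    "infusion_mg_per_min",
]


def write_traces(results: list[RunResult], path) -> None:
    df = pd.concat([r.to_frame(run=i) for i, r in enumerate(results)],
                   ignore_index=True)
    df.to_csv(path, index=False)


def read_traces(path) -> dict[int, RunResult]:
    """Read a tidy trace CSV back into per-run results (seed unrecorded)."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FileNotFoundError(f"missing or empty trace file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[int, RunResult] = {}
    for run, grp in df.groupby("run", sort=True):
        grp = grp.sort_values("minute")
        baseline = BPTrace(values=grp["baseline_sbp"].to_numpy(), label="baseline")
        generated = BPTrace(values=grp["generated_sbp"].to_numpy(), label="generated")
        schedule = DoseSchedule(
            bolus=grp["bolus_mg"].to_numpy(),
            infusion=grp["infusion_mg_per_min"].to_numpy(),
        )
        out[int(run)] = RunResult(
            baseline=baseline,
            generated=generated,
            schedule=schedule,
            delta_bp=generated.values - baseline.values,
            seed=-1,
        )
    return out


def write_manifest(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")


def load_config(path) -> RunConfig:
    """Load a run config from YAML or JSON (a manifest is also accepted)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def write_report(report: BatchReport, out_dir, stem: str = "report") -> tuple[Path, Path]:
    """Write per-run rows + summary CSV and a JSON summary; return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"

    per_run = report.per_run_frame()
    summary = report.summary_frame()
    with open(csv_path, "w") as fh:
        per_run.to_csv(fh, index=False)
        fh.write("\n")
        summary.to_csv(fh, index=False)

    payload = {
        "threshold": report.threshold,
        "n_runs": report.n_runs,
        "mean": report.mean(),
        "sd": report.sd(),
        "per_run": per_run.drop(columns="threshold").to_dict(orient="records"),
    }
    json_path.write_text(json.dumps(payload, indent=2) + "\n")
    return csv_path, json_path


def read_report_json(path) -> dict:
    return json.loads(Path(path).read_text())
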