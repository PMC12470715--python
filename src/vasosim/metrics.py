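"""Control-performance metrics for lower-limit blood-pressure control.

All metrics operate on a per-minute sBP trace sampled at minutes
0, 1, ..., duration (n = duration + 1 samples); the "observation period"
denominator is the sample count n throughout, applied identically so the
algebraic identity below holds exactly.

  PTBT   proportion of time below threshold: 100 x #{i : sBP_i <= thr} / n.
         The indicator is inclusive (<=), deliberately distinct from the
         controllers' strict (<) trigger comparison.
  MVBT   mean value below threshold: sum_i max(thr - sBP_i, 0) / n — the
         area under the threshold per sample, i.e. average hypotension depth.
  average sBP   arithmetic mean of the trace.
  average excess   sum_i max(sBP_i - thr, 0) / n, the mean height above
         the threshold (an overtreatment proxy). Identity:
         average excess == average sBP + MVBT - threshold.
  PE / MDPE / MDAPE   performance error against a provisional target T:
         PE_i = (sBP_i - T) x 100 / T; per-run MDPE = median PE (bias),
         per-run MDAPE = median |PE| (inaccuracy); final values are the
         means of the per-run medians across runs. Because PE is a strictly
         increasing transform of sBP, per-run MDPE also equals
         100 x (median(sBP) / T - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baseline import BPTrace

__all__ = [
    "ptbt",
    "mvbt",
    "average_sbp",
    "average_excess",
    "performance_errors",
    "run_mdpe",
    "run_mdape",
    "mdpe_mdape",
    "MetricsReport",
    "BatchReport",
    "compute_report",
    "aggregate",
]


def _values(trace) -> np.ndarray:
    v = trace.values if isinstance(trace, BPTrace) else np.asarray(trace, dtype=float)
    if v.size == 0:
        raise ValueError("empty trace")
    return v


def ptbt(trace, threshold: float) -> float:
    """Percent of samples at or below the threshold."""
    v = _values(trace)
    return 100.0 * float(np.count_nonzero(v <= threshold)) / v.size


def mvbt(trace, threshold: float) -> float:
    """Area under the threshold divided by the sample count, mmHg."""
    v = _values(trace)
    return float(np.maximum(threshold - v, 0.0).sum()) / v.size


def average_sbp(trace) -> float:
    """Arithmetic mean sBP, mmHg."""
    return float(np.mean(_values(trace)))


def average_excess(trace, threshold: float) -> float:
    """Mean height above the threshold, mmHg.

    Equals ``average_sbp + mvbt - threshold`` to machine precision.
    """
    v = _values(trace)
    return float(np.maximum(v - threshold, 0.0).sum()) / v.size


def performance_errors(trace, target: float) -> np.ndarray:
    """Per-sample percentage performance error (sBP - target) x 100 / target."""
    if target <= 0:
        raise ValueError("target must be positive")
    return (_values(trace) - target) * 100.0 / target


def run_mdpe(trace, target: float) -> float:
    """Single-run median performance error (bias), percent."""
    return float(np.median(performance_errors(trace, target)))


def run_mdape(trace, target: float) -> float:
    """Single-run median absolute performance error (inaccuracy), percent."""
    return float(np.median(np.abs(performance_errors(trace, target))))


def mdpe_mdape(traces, target: float) -> tuple[float, float]:
    """Final MDPE and MDAPE: means of the per-run medians across runs."""
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    mdpes = [run_mdpe(t, target) for t in traces]
    mdapes = [run_mdape(t, target) for t in traces]
    return float(np.mean(mdpes)), float(np.mean(mdapes))


@dataclass(frozen=True)
class MetricsReport:
    """All metrics for one run at one threshold."""

    threshold: float
    ptbt: float
    mvbt: float
    average_sbp: float
    average_excess: float
    mdpe: dict          # provisional target -> percent
    mdape: dict         # provisional target -> percent

    def to_dict(self) -> dict:
        d = {
            "threshold": self.threshold,
            "ptbt": self.ptbt,
            "mvbt": self.mvbt,
            "average_sbp": self.average_sbp,
            "average_excess": self.average_excess,
        }
        for t in sorted(self.mdpe):
            d[f"mdpe_{t:g}"] = self.mdpe[t]
        for t in sorted(self.mdape):
            d[f"mdape_{t:g}"] = self.mdape[t]
        return d


def compute_report(
    trace, threshold: float = 85.0, targets=(85.0, 90.0, 95.0, 100.0, 110.0)
) -> MetricsReport:
    """Evaluate every metric on one run's trace."""
    return MetricsReport(
        threshold=float(threshold),
        ptbt=ptbt(trace, threshold),
        mvbt=mvbt(trace, threshold),
        average_sbp=average_sbp(trace),
        average_excess=average_excess(trace, threshold),
        mdpe={float(t): run_mdpe(trace, t) for t in targets},
        mdape={float(t): run_mdape(trace, t) for t in targets},
    )


@dataclass(frozen=True)
class BatchReport:
    """Per-run metric reports plus their cross-run mean and sample SD.

    The final MDPE/MDAPE are the means of the per-run medians; SDs use the
    n-1 denominator and are zero for a single run.
    """

    reports: tuple

    def __post_init__(self):
        if len(self.reports) == 0:
            raise ValueError("need at least one report")
        thresholds = {r.threshold for r in self.reports}
        if len(thresholds) > 1:
            raise ValueError("reports mix different thresholds")
        object.__setattr__(self, "reports", tuple(self.reports))

    @property
    def threshold(self) -> float:
        return self.reports[0].threshold

    @property
    def n_runs(self) -> int:
        return len(self.reports)

    def per_run_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.to_dict() for r in self.reports])
        df.insert(0, "run", np.arange(len(self.reports)))
        return df

    def mean(self) -> dict:
        df = self.per_run_frame().drop(columns=["run", "threshold"])
        return {k: float(v) for k, v in df.mean().items()}

    def sd(self) -> dict:
        df = self.per_run_frame().drop(columns=["run", "threshold"])
        if len(df) == 1:
            return {k: 0.0 for k in df.columns}
        return {k: float(v) for k, v in df.std(ddof=1).items()}

    def summary_frame(self) -> pd.DataFrame:
        mean, sd = self.mean(), self.sd()
        return pd.DataFrame(
            {"metric": list(mean), "mean": list(mean.values()),
             "sd": [sd[k] for k in mean]}
        )


def aggregate(reports) -> BatchReport:
    """Bundle per-run reports into a batch report with mean and SD."""
    return BatchReport(reports=tuple(reports))
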