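"""Baseline systolic blood pressure profiles.

The simulator needs an untreated sBP time course to control against. The
built-in generator emulates a typical intraoperative scenario in which
vasopressor support is frequently needed: an initial hypotensive drop after
anesthetic induction, a transient hypertensive response to surgical
stimulation, then sustained hypotension for the rest of the case. The
profile is a smooth (monotone-cubic) interpolation through a small set of
phase control points; per-run variability is injected separately as a
bounded uniform offset (default +/- 5 mmHg) at every minute.

User-measured or hand-designed profiles can replace the generator via
:func:`load_baseline_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .kernel import _as_rng

__all__ = [
    "BPTrace",
    "BaselinePhases",
    "generate_baseline",
    "add_baseline_noise",
    "load_baseline_csv",
    "save_baseline_csv",
]


@dataclass(frozen=True)
class BPTrace:
    """Per-minute systolic blood pressure, mmHg, minute 0..duration."""

    values: np.ndarray
    label: str = "baseline"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("trace must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(v)):
            raise ValueError("sBP values must be finite")
        if np.any(v <= 0):
            raise ValueError("sBP values must be strictly positive")
        object.__setattr__(self, "values", v)

    @property
    def duration(self) -> int:
        return self.values.size - 1


@dataclass(frozen=True)
class BaselinePhases:
    """Control points of the three-phase baseline profile (all sBP in mmHg).

    start_sbp         pre-induction pressure at minute 0
    induction_end     minute by which induction hypotension is established
    hypo_level        hypotensive plateau level (~70-80)
    stim_onset        minute surgical stimulation begins to raise sBP
    stim_peak_minute  minute of the hypertensive peak
    stim_peak         peak pressure of the stimulation response (> 85)
    stim_end          minute by which the response has largely subsided
    tail_level        sustained hypotension level for the rest of the case
    """

    start_sbp: float = 95.0
    induction_end: int = 8
    hypo_level: float = 66.5
    stim_onset: int = 24
    stim_peak_minute: int = 32
    stim_peak: float = 110.0
    stim_end: int = 60
    tail_level: float = 66.5

    def control_points(self, duration: int) -> tuple[np.ndarray, np.ndarray]:
        t = [
            0,
            self.induction_end,
            self.stim_onset,
            self.stim_peak_minute,
            self.stim_end,
            duration,
        ]
        p = [
            self.start_sbp,
            self.hypo_level,
            self.hypo_level,
            self.stim_peak,
            self.tail_level,
            self.tail_level,
        ]
        return np.asarray(t, dtype=float), np.asarray(p, dtype=float)

    def validate(self, duration: int) -> None:
        order = (0, self.induction_end, self.stim_onset, self.stim_peak_minute,
                 self.stim_end, duration)
        if any(a >= b for a, b in zip(order, order[1:])):
            raise ValueError(
                "phase boundaries must satisfy 0 < induction_end < stim_onset "
                "< stim_peak_minute < stim_end < duration"
            )


def generate_baseline(
    phase_params: BaselinePhases | None = None,
    duration: int = 100,
    rng_seed=None,
    roughness: float = 0.0,
) -> BPTrace:
    """Generate the three-phase baseline sBP profile.

    The profile is a monotone cubic (PCHIP) interpolation through the phase
    control points, deterministic for fixed parameters. ``roughness`` adds a
    slow, smooth wiggle (sum of three random-phase sinusoids of that
    amplitude in mmHg, drawn from ``rng_seed``); it defaults to 0, in which
    case the seed is unused. Fast per-minute measurement noise is separate —
    see :func:`add_baseline_noise`.
    """
    if duration < 10:
        raise ValueError("duration must be at least 10 minutes")
    phases = phase_params or BaselinePhases()
    phases.validate(duration)
    t_pts, p_pts = phases.control_points(duration)
    grid = np.arange(duration + 1, dtype=float)
    values = PchipInterpolator(t_pts, p_pts)(grid)
    if roughness > 0:
        rng = _as_rng(rng_seed)
        wiggle = np.zeros_like(grid)
        for period in (17.0, 29.0, 43.0):
            phase = rng.uniform(0, 2 * np.pi)
            wiggle += np.sin(2 * np.pi * grid / period + phase)
        values = values + roughness * wiggle / 3.0
    return BPTrace(values=values, label="baseline")


def add_baseline_noise(trace: BPTrace, abs_range: float, rng_seed) -> BPTrace:
    """Add an independent uniform offset in [-abs_range, +abs_range] mmHg
    to every minute."""
    if abs_range < 0:
        raise ValueError("abs_range must be non-negative")
    rng = _as_rng(rng_seed)
    offsets = rng.uniform(-abs_range, abs_range, size=trace.values.size)
    return BPTrace(values=trace.values + offsets, label=trace.label)


def load_baseline_csv(path) -> BPTrace:
    """Load a baseline profile from two-column CSV (minute, mmHg).

    Minutes must be contiguous from 0 and pressures strictly positive;
    violations raise ``ValueError`` naming the offending row.
    """
    rows = Path(path).read_text().strip().splitlines()
    if not rows:
        raise ValueError(f"{path}: empty baseline file")
    if not rows[0].split(",")[0].strip().lstrip("-").isdigit():
        rows = rows[1:]  # header
    minutes, pressures = [], []
    for i, row in enumerate(rows):
        parts = row.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path} row {i}: expected 2 columns (minute, mmHg)")
        try:
            minutes.append(int(parts[0]))
            pressures.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: non-numeric cell") from exc
    for expected, got in zip(range(len(minutes)), minutes):
        if got != expected:
            raise ValueError(f"{path}: missing or out-of-order minute {expected}")
    for m, p in zip(minutes, pressures):
        if p <= 0:
            raise ValueError(f"{path}: non-positive sBP {p} at minute {m}")
    return BPTrace(values=np.array(pressures), label="baseline")


def save_baseline_csv(trace: BPTrace, path) -> None:
    lines = ["minute,sbp_mmhg"]
    lines += [f"{t},{float(v)!r}" for t, v in enumerate(trace.values)]
    Path(path).write_text("\n".join(lines) + "\n")
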