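"""Unit-dose pharmacodynamic response and dose-history superposition.

The blood-pressure generation model is linear: a bolus of ``M`` mg given at
minute ``s`` elevates systolic blood pressure by ``M * f(t - s)`` mmHg at
minute ``t``, where ``f`` is the unit-dose response kernel (mmHg per mg,
sampled on whole minutes, with finite support). A continuous infusion at
``C`` mg/min is the same thing repeated every minute: one ``C``-scaled
waveform launched per minute, so the cumulative elevation ``t`` minutes
after starting is ``C * (f(0) + f(1) + ... + f(t))``. The total drug effect
of an arbitrary dosing history is the discrete convolution of the
per-minute dose stream with the kernel.

The true response curve of any particular vasopressor must be measured;
:func:`make_reference_kernel` provides a documented, clinically plausible
stand-in (linear rise to peak, exponential decay, truncated support), and
measured curves can be loaded from CSV via :meth:`ResponseKernel.from_csv`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ResponseKernel",
    "DoseSchedule",
    "DeltaBPTrace",
    "make_reference_kernel",
    "bolus_response",
    "superpose",
    "apply_effect_noise",
]


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class ResponseKernel:
    """Per-minute unit-dose effect curve f(t), mmHg per mg.

    ``values[t]`` is the blood-pressure elevation ``t`` whole minutes after a
    1 mg reference bolus. The curve is non-negative, unimodal, and has finite
    support: it is identically zero beyond ``t_support``.
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("kernel values must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(v)):
            raise ValueError("kernel values must be finite")
        if np.any(v < 0):
            raise ValueError("kernel values must be non-negative")
        # unimodality: once the curve starts falling it may not rise again
        d = np.diff(v)
        falling = False
        for step in d:
            if step < 0:
                falling = True
            elif step > 0 and falling:
                raise ValueError("kernel must be unimodal (single maximum)")
        object.__setattr__(self, "values", v)

    @property
    def t_peak(self) -> int:
        """Minutes to maximal effect."""
        return int(np.argmax(self.values))

    @property
    def t_support(self) -> int:
        """Last minute with nonzero effect (0 for an all-zero kernel)."""
        nz = np.nonzero(self.values)[0]
        return int(nz[-1]) if nz.size else 0

    def effect_at(self, t: int) -> float:
        """f(t); zero beyond the stored support, error for negative t."""
        if t < 0:
            raise ValueError("elapsed time t must be non-negative")
        t = int(t)
        if t >= self.values.size:
            return 0.0
        return float(self.values[t])

    def to_csv(self, path) -> None:
        """Write the kernel as two-column CSV (minute, mmHg_per_mg)."""
        lines = ["minute,mmHg_per_mg"]
        lines += [f"{t},{float(v)!r}" for t, v in enumerate(self.values)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path) -> "ResponseKernel":
        """Load a measured response curve from two-column CSV.

        Minutes must be contiguous from 0; effects non-negative.
        """
        rows = Path(path).read_text().strip().splitlines()
        if rows and not rows[0].split(",")[0].strip().lstrip("-").isdigit():
            rows = rows[1:]  # header
        minutes, effects = [], []
        for i, row in enumerate(rows):
            parts = row.split(",")
            if len(parts) != 2:
                raise ValueError(f"kernel CSV row {i}: expected 2 columns")
            try:
                minutes.append(int(parts[0]))
                effects.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"kernel CSV row {i}: non-numeric cell") from exc
        if minutes != list(range(len(minutes))):
            raise ValueError("kernel CSV minutes must be contiguous from 0")
        return cls(values=np.array(effects))


def make_reference_kernel(
    t_peak: int = 2,
    t_support: int = 10,
    peak_effect: float = 0.4,
    tail_fraction: float = 0.05,
) -> ResponseKernel:
    """Construct the reference unit-dose response curve.

    The curve rises linearly from 0 at t=0 to ``peak_effect`` at ``t_peak``,
    then decays exponentially, reaching ``tail_fraction * peak_effect`` at
    ``t_support``, beyond which it is truncated to exactly zero.

    Parameters
    ----------
    t_peak : int
        Minutes to maximal effect (>= 1).
    t_support : int
        Last minute with nonzero effect (>= t_peak). When equal to
        ``t_peak`` there is no decay segment.
    peak_effect : float
        Maximal elevation per mg of reference drug, mmHg/mg (> 0).
    tail_fraction : float
        Residual fraction of the peak left at ``t_support`` before
        truncation, in (0, 1).
    """
    if int(t_peak) != t_peak or int(t_support) != t_support:
        raise ValueError("t_peak and t_support must be whole minutes")
    t_peak, t_support = int(t_peak), int(t_support)
    if t_peak < 1 or t_support < t_peak:
        raise ValueError("require 1 <= t_peak <= t_support")
    if peak_effect <= 0:
        raise ValueError("peak_effect must be positive")
    if not 0 < tail_fraction < 1:
        raise ValueError("tail_fraction must lie in (0, 1)")

    t = np.arange(t_support + 1, dtype=float)
    rise = peak_effect * t / t_peak
    if t_support > t_peak:
        lam = np.log(1.0 / tail_fraction) / (t_support - t_peak)
        decay = peak_effect * np.exp(-lam * (t - t_peak))
    else:
        decay = np.full_like(t, peak_effect)
    values = np.where(t <= t_peak, rise, decay)
    return ResponseKernel(values=values)


@dataclass(frozen=True)
class DoseSchedule:
    """Per-minute dosing history: bolus amounts (mg) and infusion rates (mg/min).

    Both arrays are indexed by minute 0..duration. On the one-minute grid an
    infusion rate of r mg/min delivers r mg during that minute, so the total
    drug entering at minute s is ``bolus[s] + infusion[s]``.
    """

    bolus: np.ndarray
    infusion: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.bolus, dtype=float)
        c = np.asarray(self.infusion, dtype=float)
        if b.ndim != 1 or c.ndim != 1 or b.size != c.size or b.size < 1:
            raise ValueError("bolus and infusion must be 1-d arrays of equal length")
        for name, arr in (("bolus", b), ("infusion", c)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} entries must be finite")
            if np.any(arr < 0):
                raise ValueError(f"{name} entries must be non-negative")
        object.__setattr__(self, "bolus", b)
        object.__setattr__(self, "infusion", c)

    @classmethod
    def zeros(cls, duration: int) -> "DoseSchedule":
        n = int(duration) + 1
        return cls(bolus=np.zeros(n), infusion=np.zeros(n))

    @property
    def n_minutes(self) -> int:
        return self.bolus.size

    @property
    def dose_per_minute(self) -> np.ndarray:
        """Total drug (mg) entering at each minute."""
        return self.bolus + self.infusion

    def total_dose(self) -> float:
        return float(self.dose_per_minute.sum())

    def scaled(self, alpha: float) -> "DoseSchedule":
        if alpha < 0:
            raise ValueError("scale factor must be non-negative")
        return DoseSchedule(bolus=alpha * self.bolus, infusion=alpha * self.infusion)

    def __add__(self, other: "DoseSchedule") -> "DoseSchedule":
        if self.n_minutes != other.n_minutes:
            raise ValueError("schedules must cover the same minutes")
        return DoseSchedule(
            bolus=self.bolus + other.bolus, infusion=self.infusion + other.infusion
        )


@dataclass(frozen=True)
class DeltaBPTrace:
    """Drug-induced per-minute blood-pressure elevation, mmHg, minute 0..duration."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("trace must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def duration(self) -> int:
        return self.values.size - 1


def bolus_response(kernel: ResponseKernel, dose: float, t: int) -> float:
    """Elevation (mmHg) t minutes after a single bolus: dose * f(t).

    Exactly linear in dose; zero beyond the kernel support.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    return dose * kernel.effect_at(t)


def superpose(
    kernel: ResponseKernel, schedule: DoseSchedule, duration: int | None = None
) -> DeltaBPTrace:
    """Linear superposition of all dose waveforms on the minute grid.

    ΔBP(t) = sum over s <= t of (bolus[s] + infusion[s]) * f(t - s): each
    minute's drug entry launches its own kernel-shaped waveform and the
    waveforms add. This is the discrete convolution of the per-minute dose
    stream with the kernel, truncated to the observation window.
    """
    if duration is None:
        duration = schedule.n_minutes - 1
    if schedule.n_minutes < duration + 1:
        raise ValueError(
            f"schedule covers {schedule.n_minutes - 1} minutes, need {duration}"
        )
    dose = schedule.dose_per_minute[: duration + 1]
    full = np.convolve(dose, kernel.values)
    return DeltaBPTrace(values=full[: duration + 1])


def apply_effect_noise(
    trace: DeltaBPTrace, rel_range: float, rng_seed
) -> DeltaBPTrace:
    """Multiply each minute's ΔBP by an independent uniform factor in
    [1 - rel_range, 1 + rel_range]."""
    if not 0 <= rel_range < 1:
        raise ValueError("rel_range must lie in [0, 1)")
    rng = _as_rng(rng_seed)
    factors = rng.uniform(1.0 - rel_range, 1.0 + rel_range, size=trace.values.size)
    return DeltaBPTrace(values=trace.values * factors)
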