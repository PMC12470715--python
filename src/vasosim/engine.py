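"""Closed-loop simulation engine.

One run advances the system minute by minute over the observation window
(default 100 minutes, 101 samples):

  1. the drug effect ΔBP(t) is the linear superposition of every dose
     placed at minutes <= t, scaled by that minute's multiplicative effect
     noise (default +/- 5%);
  2. generated sBP(t) = noisy baseline sBP(t) + noisy ΔBP(t);
  3. at measurement minutes (every 5 minutes, minute 0 included) the
     controller observes the current generated sBP — measurement happens
     before any new dose is placed — and its command shapes the dose
     stream for the coming interval.

Each run draws its baseline-offset noise and effect noise from independent
substreams spawned from the run seed, so toggling one noise source does not
shift the other. A batch runs ``n_runs`` independent runs seeded
``base_seed + run index``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import BaselinePhases, BPTrace, add_baseline_noise, generate_baseline
from .controllers import ControllerConfig, expand_commands, make_controller
from .kernel import DoseSchedule, ResponseKernel, make_reference_kernel

__all__ = ["RunConfig", "RunResult", "run_once", "run_batch"]

_CONTROLLER_CHOICES = ("A", "B", "C", "D", "none")


@dataclass(frozen=True)
class RunConfig:
    """Full specification of a simulation experiment."""

    duration: int = 100
    n_runs: int = 10
    base_seed: int = 0
    controller: str = "A"                  # "A"|"B"|"C"|"D"|"none"
    noise_abs: float = 5.0                 # baseline offset half-range, mmHg
    noise_rel: float = 0.05                # effect noise half-range, fraction
    threshold: float = 85.0                # metric threshold, mmHg
    targets: tuple = (85.0, 90.0, 95.0, 100.0, 110.0)
    kernel: ResponseKernel = field(default_factory=make_reference_kernel)
    controller_config: ControllerConfig = field(default_factory=ControllerConfig)
    baseline_phases: BaselinePhases = field(default_factory=BaselinePhases)
    baseline: BPTrace | None = None        # explicit profile overrides generator

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        ctrl = "none" if self.controller is None else str(self.controller)
        ctrl = ctrl.upper() if ctrl.upper() in ("A", "B", "C", "D") else ctrl.lower()
        if ctrl not in _CONTROLLER_CHOICES:
            raise ValueError(f"controller must be one of {_CONTROLLER_CHOICES}")
        object.__setattr__(self, "controller", ctrl)
        interval = self.controller_config.measurement_interval
        if self.duration % interval != 0:
            raise ValueError("duration must be divisible by the measurement interval")
        if self.baseline is not None and self.baseline.duration != self.duration:
            raise ValueError("explicit baseline length must match duration + 1")
        object.__setattr__(self, "targets", tuple(float(t) for t in self.targets))

    def clean_baseline(self) -> BPTrace:
        """The noise-free baseline profile this config simulates against."""
        if self.baseline is not None:
            return self.baseline
        return generate_baseline(self.baseline_phases, duration=self.duration)

    # --- round-trip serialization (manifest / YAML config) -----------------

    def to_dict(self) -> dict:
        d = {
            "duration": self.duration,
            "n_runs": self.n_runs,
            "base_seed": self.base_seed,
            "controller": self.controller,
            "noise_abs": self.noise_abs,
            "noise_rel": self.noise_rel,
            "threshold": self.threshold,
            "targets": list(self.targets),
            "kernel": {"values": [float(v) for v in self.kernel.values]},
            "controller_config": {
                "threshold_low": self.controller_config.threshold_low,
                "threshold_high": self.controller_config.threshold_high,
                "bolus_dose": self.controller_config.bolus_dose,
                "measurement_interval": self.controller_config.measurement_interval,
                "infusion_step_up": self.controller_config.infusion_step_up,
                "infusion_cap_factor": self.controller_config.infusion_cap_factor,
            },
            "baseline_phases": {
                "start_sbp": self.baseline_phases.start_sbp,
                "induction_end": self.baseline_phases.induction_end,
                "hypo_level": self.baseline_phases.hypo_level,
                "stim_onset": self.baseline_phases.stim_onset,
                "stim_peak_minute": self.baseline_phases.stim_peak_minute,
                "stim_peak": self.baseline_phases.stim_peak,
                "stim_end": self.baseline_phases.stim_end,
                "tail_level": self.baseline_phases.tail_level,
            },
        }
        if self.baseline is not None:
            d["baseline_sbp"] = [float(v) for v in self.baseline.values]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for key in ("duration", "n_runs", "base_seed", "controller",
                    "noise_abs", "noise_rel", "threshold"):
            if key in d:
                kwargs[key] = d[key]
        if "targets" in d:
            kwargs["targets"] = tuple(d["targets"])
        if "kernel" in d:
            kspec = d["kernel"]
            if "values" in kspec:
                kwargs["kernel"] = ResponseKernel(values=np.asarray(kspec["values"]))
            else:
                kwargs["kernel"] = make_reference_kernel(**kspec)
        if "controller_config" in d:
            kwargs["controller_config"] = ControllerConfig(**d["controller_config"])
        if "baseline_phases" in d:
            kwargs["baseline_phases"] = BaselinePhases(**d["baseline_phases"])
        if "baseline_sbp" in d:
            kwargs["baseline"] = BPTrace(values=np.asarray(d["baseline_sbp"]))
        return cls(**kwargs)


@dataclass(frozen=True)
class RunResult:
    """One closed-loop run: generated(t) = baseline(t) + delta_bp(t) exactly,
    where ``baseline`` already carries the per-run offset noise and
    ``delta_bp`` the noise-scaled drug effect of ``schedule``."""

    baseline: BPTrace
    generated: BPTrace
    schedule: DoseSchedule
    delta_bp: np.ndarray
    seed: int

    def to_frame(self, run: int = 0) -> pd.DataFrame:
        n = self.generated.values.size
        return pd.DataFrame(
            {
                "run": np.full(n, run, dtype=int),
                "minute": np.arange(n),
                "baseline_sbp": self.baseline.values,
                "generated_sbp": self.generated.values,
                "bolus_mg": self.schedule.bolus,
                "infusion_mg_per_min": self.schedule.infusion,
            }
        )


def run_once(cfg: RunConfig, seed: int) -> RunResult:
    """Advance one closed-loop run, fully reproducible per seed."""
    n = cfg.duration + 1
    ss = np.random.SeedSequence(seed)
    base_rng, effect_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    baseline = add_baseline_noise(cfg.clean_baseline(), cfg.noise_abs, base_rng)
    # per-minute effect-noise factors drawn up front so the effect stream is
    # independent of when doses happen to be placed
    factors = effect_rng.uniform(1.0 - cfg.noise_rel, 1.0 + cfg.noise_rel, size=n)

    controller = None
    interval = cfg.controller_config.measurement_interval
    if cfg.controller != "none":
        controller = make_controller(cfg.controller, cfg.controller_config)

    kernel_values = cfg.kernel.values
    klen = kernel_values.size
    dose = np.zeros(n)          # bolus + infusion entering each minute
    bolus = np.zeros(n)
    infusion = np.zeros(n)
    delta = np.zeros(n)
    generated = np.zeros(n)

    def clean_delta_at(t: int) -> float:
        s0 = max(0, t - klen + 1)
        return float(np.dot(dose[s0 : t + 1], kernel_values[: t - s0 + 1][::-1]))

    for t in range(n):
        if controller is not None and t % interval == 0:
            # measure first: generated sBP from doses already placed
            measured = baseline.values[t] + clean_delta_at(t) * factors[t]
            command = controller.step(t, measured)
            segment = expand_commands(command, interval)
            stop = min(t + interval, n)
            width = stop - t
            bolus[t] += segment.bolus[0]
            infusion[t:stop] = segment.infusion[:width]
            dose[t:stop] = bolus[t:stop] + infusion[t:stop]
        delta[t] = clean_delta_at(t) * factors[t]
        generated[t] = baseline.values[t] + delta[t]

    return RunResult(
        baseline=baseline,
        generated=BPTrace(values=generated, label="generated"),
        schedule=DoseSchedule(bolus=bolus, infusion=infusion),
        delta_bp=delta,
        seed=seed,
    )


def run_batch(cfg: RunConfig) -> list[RunResult]:
    """Run ``cfg.n_runs`` independent runs seeded base_seed, base_seed+1, ..."""
    return [run_once(cfg, cfg.base_seed + i) for i in range(cfg.n_runs)]
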