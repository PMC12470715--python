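"""Lower-limit (threshold-triggered) vasopressor dosing algorithms.

Four rule-based strategies mirror common manual practice under intermittent
NIBP monitoring. Each observes the generated sBP once per measurement
interval (default every 5 minutes) and is triggered whenever the reading
drops strictly below the lower threshold (default 85 mmHg):

  A  fixed bolus M on every trigger;
  B  bolus M on the first trigger, half-dose M/2 on every later trigger;
  C  B's bolus protocol plus a continuous infusion that starts at the
     second bolus, at initial rate C0 = M / (minutes between the first two
     boluses), and is thereafter titrated by a simple rule (raised by a
     fixed factor when the reading is below the lower threshold, held
     otherwise, capped at a multiple of C0). Once started the infusion
     never stops;
  D  as C, but the infusion is suspended while the reading exceeds the
     upper threshold (default 105 mmHg) and resumes at the pre-suspension
     rate on the first reading back at or below it.

Controllers emit a :class:`ControlCommand` per measurement; the command is
expanded to a per-minute dose stream for the following interval by
:func:`expand_commands` (bolus at the measurement minute, infusion rate
held constant over the interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernel import DoseSchedule

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "ControlCommand",
    "LowerLimitController",
    "make_controller",
    "expand_commands",
    "ALGORITHMS",
]


@dataclass(frozen=True)
class ControllerConfig:
    """Shared parameters of the four dosing algorithms.

    threshold_low        trigger level, mmHg: dose when measured sBP < this
    threshold_high       suspension level, mmHg (algorithm D only)
    bolus_dose           full bolus M, mg
    measurement_interval minutes between NIBP readings
    infusion_step_up     multiplicative rate increase applied when a
                         below-threshold reading arrives while the infusion
                         runs (C and D)
    infusion_cap_factor  maximum infusion rate, as a multiple of the
                         initial rate C0 (anti-windup)
    """

    threshold_low: float = 85.0
    threshold_high: float = 105.0
    bolus_dose: float = 40.0
    measurement_interval: int = 5
    infusion_step_up: float = 1.25
    infusion_cap_factor: float = 4.0

    def __post_init__(self):
        if not self.threshold_low < self.threshold_high:
            raise ValueError("threshold_low must be below threshold_high")
        if self.bolus_dose <= 0:
            raise ValueError("bolus_dose must be positive")
        if int(self.measurement_interval) != self.measurement_interval or self.measurement_interval < 1:
            raise ValueError("measurement_interval must be a whole number of minutes >= 1")
        if self.infusion_step_up < 1 or self.infusion_cap_factor < 1:
            raise ValueError("infusion_step_up and infusion_cap_factor must be >= 1")


@dataclass
class ControllerState:
    """Mutable per-run controller memory."""

    n_triggers: int = 0
    last_bolus_minute: int | None = None
    infusion_rate: float = 0.0       # currently commanded rate, mg/min
    infusion_active: bool = False
    suspended: bool = False          # algorithm D only
    initial_rate: float = 0.0        # C0, fixed at infusion start
    held_rate: float = 0.0           # rate stashed while suspended


@dataclass(frozen=True)
class ControlCommand:
    """One measurement's output: a bolus (mg) at the measurement minute and
    the infusion rate (mg/min) to hold until the next measurement."""

    bolus: float = 0.0
    infusion_rate: float = 0.0


ALGORITHMS = {
    "A": dict(half_after_first=False, infusion=False, suspendable=False),
    "B": dict(half_after_first=True, infusion=False, suspendable=False),
    "C": dict(half_after_first=True, infusion=True, suspendable=False),
    "D": dict(half_after_first=True, infusion=True, suspendable=True),
}


class LowerLimitController:
    """State machine implementing one of the dosing algorithms A-D."""

    def __init__(self, algorithm: str, config: ControllerConfig | None = None):
        algorithm = algorithm.upper()
        if algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {algorithm!r}; choose from A, B, C, D")
        self.algorithm = algorithm
        self.config = config or ControllerConfig()
        flags = ALGORITHMS[algorithm]
        self._half_after_first = flags["half_after_first"]
        self._infusion = flags["infusion"]
        self._suspendable = flags["suspendable"]
        self.state = ControllerState()

    def reset(self) -> None:
        self.state = ControllerState()

    def step(self, minute: int, measured_sbp: float) -> ControlCommand:
        """Process one NIBP reading taken at ``minute``; return the command
        covering the next measurement interval."""
        cfg, st = self.config, self.state
        bolus = 0.0

        # suspension logic first: the reading decides whether the infusion
        # may run at all during the coming interval (strict "exceeds")
        if self._suspendable and st.infusion_active:
            if measured_sbp > cfg.threshold_high:
                if not st.suspended:
                    st.held_rate = st.infusion_rate
                    st.infusion_rate = 0.0
                    st.suspended = True
            elif st.suspended:
                st.infusion_rate = st.held_rate
                st.held_rate = 0.0
                st.suspended = False

        if measured_sbp < cfg.threshold_low:  # strict "drops below"
            st.n_triggers += 1
            if st.n_triggers == 1 or not self._half_after_first:
                bolus = cfg.bolus_dose
            else:
                bolus = cfg.bolus_dose / 2.0
            if self._infusion:
                if st.n_triggers == 2:
                    dt = minute - st.last_bolus_minute
                    st.initial_rate = cfg.bolus_dose / dt
                    st.infusion_rate = st.initial_rate
                    st.infusion_active = True
                elif st.infusion_active and not st.suspended:
                    st.infusion_rate = min(
                        st.infusion_rate * cfg.infusion_step_up,
                        cfg.infusion_cap_factor * st.initial_rate,
                    )
            st.last_bolus_minute = minute

        return ControlCommand(bolus=bolus, infusion_rate=st.infusion_rate)


def make_controller(
    algorithm: str, config: ControllerConfig | None = None
) -> LowerLimitController:
    return LowerLimitController(algorithm, config)


def expand_commands(command: ControlCommand, measurement_interval: int) -> DoseSchedule:
    """Expand one command into the per-minute doses for its interval.

    The bolus lands at the measurement minute (index 0); the infusion rate
    is held constant over all ``measurement_interval`` minutes.
    """
    if int(measurement_interval) != measurement_interval or measurement_interval < 1:
        raise ValueError("measurement_interval must be a whole number of minutes >= 1")
    n = int(measurement_interval)
    bolus = np.zeros(n)
    bolus[0] = command.bolus
    infusion = np.full(n, command.infusion_rate, dtype=float)
    return DoseSchedule(bolus=bolus, infusion=infusion)
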