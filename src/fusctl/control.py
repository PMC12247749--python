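"""Controller family: open-loop, closed-loop, and ML-assisted closed-loop.

All controllers share the microbubble-kinetics gate: a low-pressure
tracking pulse watches the 4th-harmonic (H4) level; a +10 dB rise over
background turns the controller on, the clearance slope is recorded for a
minimum time, and a 20% decay from the normalized H4 maximum ceases the
controller, freezing the last commanded pressure for the rest of the run.
The reactive safety rule drops pressure 5% after a broadband event; the
ML-assisted variant additionally drops 5% when the predictor flags the
next pulse, acting as if the event had already occurred.  At most one
safety action is taken per pulse, and the pulse after a safety action
never ramps upward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .predict import MLPModel, features_from_frame
from .simulate import SonicationProtocol, SubjectModel
from .spectral import AEFrame

__all__ = [
    "WAITING",
    "RECORDING",
    "ACTIVE",
    "CEASED",
    "ControllerConfig",
    "ControllerState",
    "ControlDecision",
    "PhaseError",
    "tracker_update",
    "cl_step",
    "reactive_safety",
    "ol_step",
    "mlcl_step",
    "Controller",
    "DummyController",
    "OpenLoopController",
    "ClosedLoopController",
    "MLClosedLoopController",
    "make_controller",
]

WAITING = "waiting"
RECORDING = "recording"
ACTIVE = "active"
CEASED = "ceased"

_H7_INDEX = 5  # 7th harmonic within AEFrame.harmonic_db (orders 2..8)


class PhaseError(RuntimeError):
    pass


@dataclass(frozen=True)
class ControllerConfig:
    """Rule constants for one controller arm (see module docstring)."""

    kind: str = "CL"  # OL | CL | MLCL
    target_level_db: float = 32.0  # 7th-harmonic target (CL/MLCL)
    fixed_pressure_mpa: Optional[float] = None  # OL only
    p_init_mpa: float = 0.10
    p_min_mpa: float = 0.02
    p_max_mpa: float = 0.33
    ramp_step: float = 0.05  # multiplicative ramp fraction per pulse
    safety_drop: float = 0.05  # 5% drop on event / positive prediction
    on_threshold_db: float = 10.0  # H4 rise that turns the controller on
    cease_decay: float = 0.20  # fraction below normalized H4 max
    min_record_s: float = 20.0  # 20 s mouse / 40 s rat slope recording
    smoothing_window: int = 3
    deadband_db: float = 1.0
    background_h4_db: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("OL", "CL", "MLCL"):
            raise ValueError(f"kind must be OL, CL or MLCL, got {self.kind!r}")
        if not (0 < self.p_min_mpa <= self.p_init_mpa <= self.p_max_mpa):
            raise ValueError(
                "need 0 < p_min_mpa <= p_init_mpa <= p_max_mpa "
                f"(got p_min_mpa={self.p_min_mpa}, p_init_mpa={self.p_init_mpa}, "
                f"p_max_mpa={self.p_max_mpa})"
            )
        if not (0.0 < self.safety_drop < 1.0):
            raise ValueError("safety_drop must be in (0, 1)")
        if not (0.0 < self.cease_decay < 1.0):
            raise ValueError("cease_decay must be in (0, 1)")
        if self.kind == "OL" and self.fixed_pressure_mpa is None:
            raise ValueError("OL controller requires fixed_pressure_mpa")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")


@dataclass
class ControllerState:
    """Gating phase, pressure command, and H4 tracking statistics."""

    phase: str = WAITING
    pressure_mpa: float = 0.0
    background_h4_db: float = 0.0
    h4_times: list[float] = field(default_factory=list)
    h4_values: list[float] = field(default_factory=list)  # rise over background
    h4_max: float = 0.0
    clearance_slope: float = float("nan")  # d(normalized H4)/dt
    last_h4_norm: float = 0.0
    last_prediction: bool = False
    on_time_s: Optional[float] = None
    last_time_s: Optional[float] = None
    hold_ramp: bool = False
    therapeutic_started: bool = False


def _update_slope(state: ControllerState) -> None:
    if len(state.h4_times) >= 2 and state.h4_max > 0:
        t = np.asarray(state.h4_times)
        v = np.asarray(state.h4_values) / state.h4_max
        state.clearance_slope = float(np.polyfit(t, v, 1)[0])


def tracker_update(
    state: ControllerState, h4_db: float, t_s: float, config: ControllerConfig
) -> ControllerState:
    """Advance the gating state machine with one tracker H4 reading.

    waiting -> recording on a rise of ``on_threshold_db`` over background;
    recording -> active once ``min_record_s`` of slope data accumulated;
    active -> ceased when the normalized H4 level has decayed by
    ``cease_decay`` from its maximum.  Transitions are one-way.
    """
    if not math.isfinite(h4_db):
        raise ValueError("h4_db must be finite")
    if state.last_time_s is not None and t_s <= state.last_time_s:
        raise ValueError(
            f"time must be strictly increasing (got {t_s} after {state.last_time_s})"
        )
    state.last_time_s = t_s

    if state.phase == WAITING:
        if h4_db >= state.background_h4_db + config.on_threshold_db:
            state.phase = RECORDING
            state.on_time_s = t_s

    if state.phase in (RECORDING, ACTIVE):
        rise = max(0.0, h4_db - state.background_h4_db)
        state.h4_times.append(t_s)
        state.h4_values.append(rise)
        state.h4_max = max(state.h4_max, rise)
        state.last_h4_norm = (
            min(1.0, rise / state.h4_max) if state.h4_max > 1e-12 else 0.0
        )
        _update_slope(state)
        if state.phase == RECORDING:
            assert state.on_time_s is not None
            if t_s - state.on_time_s >= config.min_record_s:
                state.phase = ACTIVE
        if state.phase == ACTIVE:
            if state.h4_max > 0 and rise <= (1.0 - config.cease_decay) * state.h4_max:
                state.phase = CEASED
    return state


def _clamp(p: float, config: ControllerConfig) -> float:
    return min(config.p_max_mpa, max(config.p_min_mpa, p))


def cl_step(
    state: ControllerState, smoothed_level_db: float, config: ControllerConfig
) -> float:
    """Multiplicative ramp toward the 7th-harmonic target level.

    Below target minus deadband: pressure * (1 + ramp_step); above target
    plus deadband: pressure * (1 - ramp_step); inside the deadband: hold.
    Upward ramping is suppressed on the pulse after a safety action.
    """
    if state.phase != ACTIVE:
        raise PhaseError(f"cl_step requires active phase, got {state.phase!r}")
    p = state.pressure_mpa
    if smoothed_level_db < config.target_level_db - config.deadband_db:
        if not state.hold_ramp:
            p = p * (1.0 + config.ramp_step)
    elif smoothed_level_db > config.target_level_db + config.deadband_db:
        p = p * (1.0 - config.ramp_step)
    return _clamp(p, config)


def reactive_safety(
    pressure_mpa: float,
    event: bool,
    safety_drop: float = 0.05,
    p_min_mpa: Optional[float] = None,
) -> float:
    """Table-3 reactive rule: reduce pressure by ``safety_drop`` on an
    event; identity otherwise."""
    if pressure_mpa <= 0:
        raise ValueError("pressure must be > 0")
    if not event:
        return pressure_mpa
    p = pressure_mpa * (1.0 - safety_drop)
    if p_min_mpa is not None:
        p = max(p, p_min_mpa)
    return p


def ol_step(
    state: ControllerState, frame: Optional[AEFrame], config: ControllerConfig
) -> float:
    """Open loop: hold the configured pressure; only the reactive safety
    rule (applied by the caller) changes it."""
    if config.fixed_pressure_mpa is None:
        raise ValueError("OL controller requires fixed_pressure_mpa")
    if state.phase != ACTIVE:
        raise PhaseError(f"ol_step requires active phase, got {state.phase!r}")
    return _clamp(state.pressure_mpa, config)


def mlcl_step(
    state: ControllerState,
    frame: AEFrame,
    model: MLPModel,
    config: ControllerConfig,
    subject: SubjectModel,
    smoothed_level_db: float,
) -> tuple[float, float, str]:
    """ML-assisted step: on a positive prediction, skip the ramp and apply
    the 5% safety drop as if the event had occurred; otherwise defer to
    :func:`cl_step`.  Returns (pressure, model output, safety action).
    """
    if state.phase != ACTIVE:
        raise PhaseError(f"mlcl_step requires active phase, got {state.phase!r}")
    x = features_from_frame(frame, state.last_h4_norm, subject, feature_set=12)
    prob, positive = model.predict(x)
    state.last_prediction = positive
    if positive:
        p = _clamp(state.pressure_mpa * (1.0 - config.safety_drop), config)
        return p, prob, "predictive"
    return cl_step(state, smoothed_level_db, config), prob, "none"


@dataclass
class ControlDecision:
    pressure_mpa: float
    phase: str
    prediction: float = float("nan")
    safety_action: str = "none"


class Controller:
    """Base controller: tracker gating, smoothing, reactive safety."""

    def __init__(self, config: ControllerConfig, label: Optional[str] = None):
        self.config = config
        self.label = label or config.kind
        self.state = ControllerState()
        self._tracker_pressure = 0.06
        self._active_h7: list[float] = []

    def reset(self, protocol: SonicationProtocol) -> None:
        self.state = ControllerState(
            background_h4_db=self.config.background_h4_db,
            pressure_mpa=self.config.p_init_mpa,
        )
        self._tracker_pressure = protocol.tracker_pressure_mpa
        self._active_h7 = []

    # -- subclass hooks -------------------------------------------------
    def _initial_pressure(self) -> float:
        return self.config.p_init_mpa

    def _active_step(
        self, prev_frame: Optional[AEFrame]
    ) -> tuple[float, float, str]:
        """Return (pressure, prediction output, safety action)."""
        raise NotImplementedError

    # -- shared loop ----------------------------------------------------
    def _smoothed_level(self) -> float:
        w = self.config.smoothing_window
        if not self._active_h7:
            return float("nan")
        return float(np.median(self._active_h7[-w:]))

    def decide(
        self,
        pulse_index: int,
        t_s: float,
        h4_db: float,
        prev_frame: Optional[AEFrame],
    ) -> ControlDecision:
        st = self.state
        tracker_update(st, h4_db, t_s, self.config)
        if st.phase in (WAITING, RECORDING):
            return ControlDecision(self._tracker_pressure, st.phase)
        if st.phase == CEASED:
            if not st.therapeutic_started:
                # gate closed before therapy began: keep tracking pressure
                return ControlDecision(self._tracker_pressure, st.phase)
            return ControlDecision(st.pressure_mpa, st.phase)
        # active
        if not st.therapeutic_started:
            st.pressure_mpa = _clamp(self._initial_pressure(), self.config)
            st.therapeutic_started = True
            st.hold_ramp = False
            return ControlDecision(st.pressure_mpa, st.phase)
        pressure, prediction, action = self._active_step(prev_frame)
        if (
            action == "none"
            and prev_frame is not None
            and prev_frame.is_event
        ):
            pressure = reactive_safety(
                pressure,
                True,
                self.config.safety_drop,
                self.config.p_min_mpa,
            )
            action = "reactive"
        pressure = _clamp(pressure, self.config)
        st.hold_ramp = action != "none"
        st.pressure_mpa = pressure
        return ControlDecision(pressure, st.phase, prediction, action)

    def observe(self, frame: AEFrame) -> None:
        if self.state.phase in (ACTIVE, CEASED) and self.state.therapeutic_started:
            self._active_h7.append(frame.harmonic_db[_H7_INDEX])


class DummyController(Controller):
    """Constant-pressure controller with no gating (testing aid)."""

    def __init__(self, pressure_mpa: float = 0.0, label: str = "dummy"):
        config = ControllerConfig(
            kind="OL",
            fixed_pressure_mpa=max(pressure_mpa, 1e-6),
            p_init_mpa=0.02,
        )
        super().__init__(config, label)
        self._pressure = pressure_mpa

    def decide(self, pulse_index, t_s, h4_db, prev_frame):  # noqa: D102
        return ControlDecision(self._pressure, ACTIVE)


class OpenLoopController(Controller):
    """Constant commanded pressure with reactive safety and tracker gating."""

    def __init__(self, config: ControllerConfig, label: Optional[str] = None):
        if config.kind != "OL":
            raise ValueError("OpenLoopController requires kind='OL'")
        super().__init__(config, label or f"OL@{config.fixed_pressure_mpa}")

    def _initial_pressure(self) -> float:
        assert self.config.fixed_pressure_mpa is not None
        return self.config.fixed_pressure_mpa

    def _active_step(self, prev_frame):
        return ol_step(self.state, prev_frame, self.config), float("nan"), "none"


class ClosedLoopController(Controller):
    """Feedback ramp toward a 7th-harmonic target level."""

    def __init__(self, config: ControllerConfig, label: Optional[str] = None):
        if config.kind != "CL":
            raise ValueError("ClosedLoopController requires kind='CL'")
        super().__init__(config, label or "CL")

    def _active_step(self, prev_frame):
        smoothed = self._smoothed_level()
        if math.isnan(smoothed):
            return self.state.pressure_mpa, float("nan"), "none"
        return cl_step(self.state, smoothed, self.config), float("nan"), "none"


class MLClosedLoopController(Controller):
    """Closed loop with the MLP safety layer overriding on predictions."""

    def __init__(
        self,
        config: ControllerConfig,
        model: MLPModel,
        subject: SubjectModel,
        label: Optional[str] = None,
    ):
        if config.kind != "MLCL":
            raise ValueError("MLClosedLoopController requires kind='MLCL'")
        super().__init__(config, label or "MLCL")
        self.model = model
        self.subject = subject

    def _active_step(self, prev_frame):
        if prev_frame is None:
            return self.state.pressure_mpa, float("nan"), "none"
        smoothed = self._smoothed_level()
        if math.isnan(smoothed):
            smoothed = self.config.target_level_db  # hold inside deadband
        return mlcl_step(
            self.state, prev_frame, self.model, self.config, self.subject, smoothed
        )


def make_controller(
    config: ControllerConfig,
    model: Optional[MLPModel] = None,
    subject: Optional[SubjectModel] = None,
    label: Optional[str] = None,
) -> Controller:
    if config.kind == "OL":
        return OpenLoopController(config, label)
    if config.kind == "CL":
        return ClosedLoopController(config, label)
    if config.kind == "MLCL":
        if model is None or subject is None:
            raise ValueError("MLCL controller requires a model and a subject")
        return MLClosedLoopController(config, model, subject, label)
    raise ValueError(f"unknown controller kind {config.kind!r}")
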