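"""Stochastic surrogate generator of per-pulse microbubble acoustic emissions.

One simulated sonication is a 130 s train of 10 ms pulses at 1 Hz.  A bolus
kinetics curve (rise times exponential clearance, normalised to peak 1)
drives a latent "instability" accumulator that integrates acoustic drive in
excess of a half-saturation pressure; harmonic levels follow a
linear-then-plateau dose response, ultra-harmonics additionally rise with
instability (the learnable precursor), and rare broadband events are drawn
from a logistic model of instability, tumor presence, and transient bolus
concentration.  Everything is seeded through named substreams so records
are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

from .seeding import named_stream
from .spectral import EVENT_THRESHOLD_DB, AEFrame, detect_broadband

if TYPE_CHECKING:  # pragma: no cover
    from .control import Controller

__all__ = [
    "SonicationProtocol",
    "SubjectModel",
    "GeneratorParams",
    "LatentState",
    "PulseLog",
    "SonicationRecord",
    "mb_concentration",
    "step_instability",
    "event_probability",
    "tracker_h4_level",
    "synth_frame",
    "simulate_run",
    "ktrans_surrogate",
]

_H_SCALES = (0.60, 0.70, 0.80, 0.85, 0.90, 1.00, 0.95)  # orders 2..8 vs 7th
_UH_SCALES = (0.40, 0.38, 0.36, 0.34, 0.32, 0.30, 0.28)  # 1.5 f0 .. 7.5 f0


@dataclass(frozen=True)
class SonicationProtocol:
    """Pulse-train timing and the microbubble-tracking pulse."""

    f0_mhz: float = 0.5
    pulse_length_ms: float = 10.0
    prf_hz: float = 1.0
    duration_s: float = 130.0
    tracker_pressure_mpa: float = 0.06
    record_length_ms: float = 11.0

    def __post_init__(self) -> None:
        n = self.duration_s * self.prf_hz
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("duration_s * prf_hz must be a positive integer")
        if self.tracker_pressure_mpa <= 0:
            raise ValueError("tracker_pressure_mpa must be > 0")

    @property
    def n_pulses(self) -> int:
        return int(round(self.duration_s * self.prf_hz))


@dataclass(frozen=True)
class SubjectModel:
    """Per-subject bolus kinetics, anatomy flags, and skull transmission."""

    species: str = "mouse"
    tumor: bool = False
    target_x_mm: float = 0.0
    target_y_mm: float = 0.0
    skull_transmission: float = 1.0
    arrival_time_s: float = 10.0
    rise_tau_s: float = 5.0
    clearance_tau_s: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species not in ("mouse", "rat"):
            raise ValueError(f"species must be 'mouse' or 'rat', got {self.species!r}")
        if not (0.0 < self.skull_transmission <= 1.0):
            raise ValueError("skull_transmission must be in (0, 1]")
        if not (0 < self.rise_tau_s < self.clearance_tau_s):
            raise ValueError("need 0 < rise_tau_s < clearance_tau_s")

    @classmethod
    def default(
        cls,
        species: str = "mouse",
        tumor: bool = False,
        seed: int = 0,
        target_x_mm: float = 0.0,
        target_y_mm: float = 0.0,
        jitter: bool = True,
    ) -> "SubjectModel":
        """Species defaults; rats clear microbubbles ~2x faster than mice
        and transmit less pressure through the skull.  ``jitter`` applies a
        seeded 5% lognormal perturbation to skull transmission per target.
        """
        if species == "mouse":
            trans, clearance = 1.0, 150.0
        elif species == "rat":
            trans, clearance = 0.8, 75.0
        else:
            raise ValueError(f"unknown species {species!r}")
        if jitter:
            rng = named_stream(seed, "subject-jitter")
            trans = min(1.0, trans * float(np.exp(rng.normal(0.0, 0.05))))
        return cls(
            species=species,
            tumor=tumor,
            target_x_mm=target_x_mm,
            target_y_mm=target_y_mm,
            skull_transmission=trans,
            arrival_time_s=10.0,
            rise_tau_s=5.0,
            clearance_tau_s=clearance,
            seed=seed,
        )


@dataclass(frozen=True)
class GeneratorParams:
    """Dose-response and event-model coefficients (all configurable).

    The 7th-harmonic mean level is ``L_max * tanh(max(0, d - p_threshold)
    / slope_width)`` with acoustic drive ``d = skull_transmission *
    pressure * concentration``; defaults put 32 dB at 0.14 MPa (full
    concentration) with a ~37 dB plateau.  Instability accumulates a
    softplus of the drive in excess of ``p50``; broadband events are
    Bernoulli with logit ``beta0 + beta_instability * instability +
    beta_tumor * tumor + beta_bolus * [concentration > 0.7]``.
    """

    L_max: float = 37.0
    p50: float = 0.11
    slope_width: float = 0.06
    p_threshold: float = 0.061
    drive_softplus_width: float = 0.02
    inst_retention: float = 0.9
    inst_gain: float = 0.22
    inst_sat: float = 0.12
    inst_noise_sd: float = 0.012
    uh_gain: float = 24.0
    event_beta0: float = -52.5
    event_beta_instability: float = 70.0
    event_beta_tumor: float = 3.5
    event_beta_bolus: float = 2.1
    bolus_threshold: float = 0.7
    event_reset: float = 0.6
    event_bb_mean_excess_db: float = 3.0
    level_noise_sd: float = 1.0
    h4_gain_db: float = 20.0
    h4_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.L_max <= 0 or self.slope_width <= 0:
            raise ValueError("L_max and slope_width must be > 0")
        if not (0.0 <= self.inst_retention < 1.0):
            raise ValueError("inst_retention must be in [0, 1)")
        if not (0.0 <= self.event_reset <= 1.0):
            raise ValueError("event_reset must be in [0, 1]")


@dataclass(frozen=True)
class LatentState:
    """Hidden generator state: normalized concentration and instability."""

    concentration: float = 0.0
    instability: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.concentration <= 1.0):
            raise ValueError("concentration must be in [0, 1]")
        if self.instability < 0.0:
            raise ValueError("instability must be >= 0")


def _peak_offset(rise_tau: float, clearance_tau: float) -> float:
    # argmax of (1 - exp(-u/r)) * exp(-u/c): u* = r * log(1 + c/r)
    return rise_tau * math.log(1.0 + clearance_tau / rise_tau)


def mb_concentration(t_s: float, subject: SubjectModel) -> float:
    """Normalized bolus concentration at time ``t_s`` (0 before arrival,
    rise with ``rise_tau_s``, exponential clearance, global max 1)."""
    if t_s < subject.arrival_time_s:
        return 0.0
    u = t_s - subject.arrival_time_s
    r, c = subject.rise_tau_s, subject.clearance_tau_s
    raw = (1.0 - math.exp(-u / r)) * math.exp(-u / c)
    u_star = _peak_offset(r, c)
    peak = (1.0 - math.exp(-u_star / r)) * math.exp(-u_star / c)
    return min(1.0, raw / peak)


def _softplus(x: float) -> float:
    if x > 30.0:
        return x
    return math.log1p(math.exp(x))


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def drive(pressure_mpa: float, concentration: float, subject: SubjectModel) -> float:
    """Effective acoustic drive delivered to circulating bubbles."""
    return subject.skull_transmission * pressure_mpa * concentration


def step_instability(
    state: LatentState,
    pressure_mpa: float,
    subject: SubjectModel,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> LatentState:
    """Advance the leaky instability accumulator by one pulse.

    Uses a softplus of the drive excess above ``p50`` so the update is
    strictly increasing in pressure; small Gaussian noise, floored at 0.
    """
    d = drive(pressure_mpa, state.concentration, subject)
    w = params.drive_softplus_width
    excess = w * _softplus((d - params.p50) / w)
    # saturating accumulation keeps the equilibrium near the event
    # threshold over the eventful pressure range, so threshold crossings
    # are gradual (learnable) rather than single-pulse jumps
    inst = (
        params.inst_retention * state.instability
        + params.inst_gain * math.tanh(excess / params.inst_sat)
        + float(rng.normal(0.0, params.inst_noise_sd))
    )
    return replace(state, instability=max(0.0, inst))


def event_probability(
    state: LatentState, subject: SubjectModel, params: GeneratorParams
) -> float:
    """Per-pulse broadband-event probability under the logistic model."""
    logit = (
        params.event_beta0
        + params.event_beta_instability * state.instability
        + params.event_beta_tumor * (1.0 if subject.tumor else 0.0)
        + params.event_beta_bolus
        * (1.0 if state.concentration > params.bolus_threshold else 0.0)
    )
    return _sigmoid(logit)


def harmonic_mean_level(
    pressure_mpa: float,
    concentration: float,
    subject: SubjectModel,
    params: GeneratorParams,
) -> float:
    """Mean 7th-harmonic level (dB re baseline): linear then plateau."""
    d = drive(pressure_mpa, concentration, subject)
    x = max(0.0, d - params.p_threshold) / params.slope_width
    return params.L_max * math.tanh(x)


def tracker_h4_level(
    concentration: float, params: GeneratorParams, rng: np.random.Generator
) -> float:
    """4th-harmonic level of the low-pressure tracking pulse (dB re
    background), a noisy linear readout of bolus concentration."""
    return params.h4_gain_db * concentration + float(
        rng.normal(0.0, params.h4_noise_sd)
    )


def synth_frame(
    pressure_mpa: float,
    state: LatentState,
    subject: SubjectModel,
    params: GeneratorParams,
    rng: np.random.Generator,
    pulse_index: int = 1,
    time_s: float = 0.0,
    h4_db: Optional[float] = None,
) -> AEFrame:
    """Realize one pulse's AEFrame from the latent state.

    ``h4_db`` overrides the tracking level (the run loop passes the tracker
    pulse's reading); when absent a fresh tracker level is drawn.
    """
    if pressure_mpa < 0:
        raise ValueError("pressure must be >= 0")
    level7 = harmonic_mean_level(pressure_mpa, state.concentration, subject, params)
    noise = rng.normal(0.0, params.level_noise_sd, size=15)
    harmonic = tuple(
        s * level7 + float(noise[i]) for i, s in enumerate(_H_SCALES)
    )
    ultra = tuple(
        s * level7 + params.uh_gain * state.instability + float(noise[7 + i])
        for i, s in enumerate(_UH_SCALES)
    )
    p_event = event_probability(state, subject, params)
    is_event = bool(rng.random() < p_event)
    if is_event:
        bb = EVENT_THRESHOLD_DB + float(
            rng.exponential(params.event_bb_mean_excess_db)
        )
    else:
        bb = min(float(noise[14]), EVENT_THRESHOLD_DB - 0.1)
    if h4_db is None:
        h4_db = tracker_h4_level(state.concentration, params, rng)
    return AEFrame(
        pulse_index=int(pulse_index),
        time_s=float(time_s),
        pressure_mpa=float(pressure_mpa),
        harmonic_db=harmonic,
        ultraharmonic_db=ultra,
        h4_db=float(h4_db),
        broadband_db=bb,
        is_event=detect_broadband(bb),
    )


@dataclass
class PulseLog:
    """One pulse of a sonication record: command, outcome, controller info."""

    frame: AEFrame
    phase: str
    prediction: float  # MLP output in [0,1]; NaN when no model ran
    safety_action: str  # none | reactive | predictive


@dataclass
class SonicationRecord:
    """Full per-pulse log of one sonication run."""

    protocol: SonicationProtocol
    subject: SubjectModel
    controller_label: str
    pulses: list[PulseLog] = field(default_factory=list)
    seed: int = 0
    valid: bool = True
    ktrans: float = float("nan")

    @property
    def n_pulses(self) -> int:
        return len(self.pulses)

    @property
    def frames(self) -> list[AEFrame]:
        return [p.frame for p in self.pulses]

    @property
    def pressures(self) -> np.ndarray:
        return np.array([p.frame.pressure_mpa for p in self.pulses])

    @property
    def events(self) -> np.ndarray:
        return np.array([p.frame.is_event for p in self.pulses], dtype=bool)

    def event_count(self) -> int:
        return int(self.events.sum())


def simulate_run(
    protocol: SonicationProtocol,
    subject: SubjectModel,
    controller: "Controller",
    params: GeneratorParams,
    seed: int,
    latent_log: Optional[list] = None,
) -> SonicationRecord:
    """Run one closed loop: controller proposes a pressure, the generator
    realizes the pulse's emissions, the frame is fed back.

    Bit-reproducible for a fixed ``(config, seed)``.  A controller
    exception aborts the run and returns the partial log with
    ``valid=False``.
    """
    rng_kin = named_stream(seed, "kinetics")
    rng_inst = named_stream(seed, "instability")
    rng_noise = named_stream(seed, "noise")

    record = SonicationRecord(
        protocol=protocol,
        subject=subject,
        controller_label=controller.label,
        seed=int(seed),
    )
    controller.reset(protocol)
    state = LatentState()
    prev_frame: Optional[AEFrame] = None
    dt = 1.0 / protocol.prf_hz
    try:
        for i in range(protocol.n_pulses):
            t = i * dt
            conc = mb_concentration(t, subject)
            h4 = tracker_h4_level(conc, params, rng_kin)
            decision = controller.decide(i + 1, t, h4, prev_frame)
            state = replace(state, concentration=conc)
            state = step_instability(
                state, decision.pressure_mpa, subject, params, rng_inst
            )
            frame = synth_frame(
                decision.pressure_mpa,
                state,
                subject,
                params,
                rng_noise,
                pulse_index=i + 1,
                time_s=t,
                h4_db=h4,
            )
            if latent_log is not None:
                latent_log.append(state)
            if frame.is_event:
                state = replace(
                    state, instability=state.instability * params.event_reset
                )
            controller.observe(frame)
            record.pulses.append(
                PulseLog(
                    frame=frame,
                    phase=decision.phase,
                    prediction=decision.prediction,
                    safety_action=decision.safety_action,
                )
            )
            prev_frame = frame
    except Exception:
        record.valid = False
        raise
    record.ktrans = ktrans_surrogate(record)
    return record


def ktrans_surrogate(
    record: SonicationRecord,
    floor: float = 0.002,
    amplitude: float = 0.02,
    dose_half: float = 2.0e4,
    noise_sd: float = 0.1,
) -> float:
    """Synthetic permeability read-out: a saturating monotone function of
    cumulative 7th-harmonic dose above a background floor.

    Stands in for a DCE-MRI transfer constant so window analyses can be
    exercised; units are arbitrary.  Deterministic given the record and the
    subject's seed (lognormal measurement jitter).
    """
    dose = float(
        sum(max(0.0, f.harmonic_db[5]) for f in record.frames)
    )  # index 5 = 7th harmonic
    rng = named_stream(record.subject.seed, "ktrans")
    jitter = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
    return (floor + amplitude * dose / (dose + dose_half)) * jitter
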