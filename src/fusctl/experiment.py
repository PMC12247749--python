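"""End-to-end experiment pipelines: generate training data, fit the
predictor, and run the controller-comparison arms.

Training records mimic the historical corpus: constant-pressure
sonications across many subjects (tumor and healthy) at a grid of
pressures.  The comparison experiment runs the ML-assisted closed-loop arm
first, derives the open-loop pressures from its commanded mean and max,
then runs the plain closed-loop and open-loop arms on matched subjects.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from .control import (
    ACTIVE,
    CEASED,
    ClosedLoopController,
    ControllerConfig,
    MLClosedLoopController,
    OpenLoopController,
)
from .predict import (
    ConfusionMetrics,
    Dataset,
    MLPModel,
    TrainConfig,
    build_dataset,
    fit_predictor,
)
from .simulate import (
    GeneratorParams,
    SonicationProtocol,
    SonicationRecord,
    SubjectModel,
    simulate_run,
)

__all__ = [
    "generate_training_records",
    "train_default_predictor",
    "run_comparison_experiment",
    "therapeutic_pressures",
]

_TRAIN_PRESSURES = (0.10, 0.14, 0.17, 0.20, 0.23, 0.26, 0.30, 0.33)


def generate_training_records(
    n_runs: int,
    seed: int,
    params: Optional[GeneratorParams] = None,
    protocol: Optional[SonicationProtocol] = None,
    tumor_fraction: float = 0.3,
    species: str = "mouse",
) -> list[SonicationRecord]:
    """Constant-pressure sonications over a pressure grid and mixed
    tumor/healthy subjects — the corpus the predictor learns from."""
    params = params or GeneratorParams()
    protocol = protocol or SonicationProtocol()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_runs):
        pressure = _TRAIN_PRESSURES[i % len(_TRAIN_PRESSURES)]
        subject = SubjectModel.default(
            species=species,
            tumor=bool(rng.random() < tumor_fraction),
            seed=seed * 100003 + i,
            target_x_mm=float(rng.uniform(-3, 3)),
            target_y_mm=float(rng.uniform(-3, 3)),
        )
        controller = OpenLoopController(
            ControllerConfig(
                kind="OL",
                fixed_pressure_mpa=pressure,
                p_init_mpa=min(pressure, 0.33),
                p_max_mpa=0.33,
            )
        )
        records.append(
            simulate_run(protocol, subject, controller, params, seed=seed * 7919 + i)
        )
    return records


def train_default_predictor(
    records: Sequence[SonicationRecord],
    config: Optional[TrainConfig] = None,
) -> tuple[MLPModel, ConfusionMetrics, ConfusionMetrics, Dataset, Dataset]:
    """Build the 12-feature dataset and fit the MLP (80/20, under-sampled)."""
    config = config or TrainConfig(epochs=200)
    dataset = build_dataset(records, feature_set=12)
    return fit_predictor(dataset, config)


def therapeutic_pressures(record: SonicationRecord) -> np.ndarray:
    """Commanded pressures during the active and ceased (held) phases."""
    mask = np.array([p.phase in (ACTIVE, CEASED) for p in record.pulses])
    return record.pressures[mask]


def run_comparison_experiment(
    model: MLPModel,
    seed: int,
    n_per_arm: int = 8,
    target_level_db: float = 36.0,
    params: Optional[GeneratorParams] = None,
    protocol: Optional[SonicationProtocol] = None,
    species: str = "mouse",
    base_config: Optional[ControllerConfig] = None,
) -> dict[str, list[SonicationRecord]]:
    """Run the four-arm comparison: ML-CL, CL, OL(P_Avg), OL(P_Max).

    The open-loop pressures are the mean and max therapeutic pressures
    commanded by the ML-CL arm, as in the benchmarking procedure.
    """
    params = params or GeneratorParams()
    protocol = protocol or SonicationProtocol()
    base = base_config or ControllerConfig(kind="CL", target_level_db=target_level_db)
    base = replace(base, target_level_db=target_level_db)

    def subjects(arm_index: int) -> list[SubjectModel]:
        return [
            SubjectModel.default(
                species=species,
                tumor=False,
                seed=seed * 1009 + arm_index * 211 + i,
            )
            for i in range(n_per_arm)
        ]

    arms: dict[str, list[SonicationRecord]] = {}

    mlcl_cfg = replace(base, kind="MLCL")
    arms["MLCL"] = [
        simulate_run(
            protocol,
            subj,
            MLClosedLoopController(mlcl_cfg, model, subj),
            params,
            seed=seed * 5003 + i,
        )
        for i, subj in enumerate(subjects(0))
    ]

    pressures = np.concatenate(
        [therapeutic_pressures(r) for r in arms["MLCL"]]
    )
    if pressures.size == 0:
        raise RuntimeError("ML-CL arm never reached the active phase")
    p_avg = float(pressures.mean())
    p_max = float(pressures.max())

    cl_cfg = replace(base, kind="CL")
    arms["CL"] = [
        simulate_run(
            protocol,
            subj,
            ClosedLoopController(cl_cfg),
            params,
            seed=seed * 6007 + i,
        )
        for i, subj in enumerate(subjects(1))
    ]
    for label, pressure, arm_index, salt in (
        ("OL_PAvg", p_avg, 2, 7001),
        ("OL_PMax", p_max, 3, 8009),
    ):
        cfg = replace(
            base,
            kind="OL",
            fixed_pressure_mpa=pressure,
            p_init_mpa=min(pressure, base.p_max_mpa),
        )
        arms[label] = [
            simulate_run(
                protocol,
                subj,
                OpenLoopController(cfg, label=label),
                params,
                seed=seed * salt + i,
            )
            for i, subj in enumerate(subjects(arm_index))
        ]
    return arms
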