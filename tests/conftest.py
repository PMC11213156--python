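"""Shared fixtures.

``recovery`` is the expensive one: it simulates the frozen strong-signal
cohort, runs the full two-step pipeline (bi-modal models, Cycle-GANs,
frozen-generator fusion training) once per session, and computes
Integrated-Gradients attributions for the complete-data test subjects.
Several end-to-end checks share it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from neurofuse.config import RunConfig
from neurofuse.features import ModalityInputs
from neurofuse.interpret import AttributionSet, integrated_gradients, make_ig_config
from neurofuse.pipeline import ExperimentResult, evaluate, run_experiment
from neurofuse.presets import (
    DESK_CGAN_HIDDEN,
    DESK_RECOVERY_MISSINGNESS,
    desk_recovery_simspec,
    desk_scale_config,
)
from neurofuse.simulate import GroundTruth, SimulationSpec, mask_inputs, simulate_inputs

RECOVERY_SEED = 3
CLASS_INDEX = {"CN": 0, "AD": 1}


def tiny_config(**overrides) -> RunConfig:
    """Micro-scale config for fast unit tests."""
    params = dict(
        latent_dim=8,
        volume_shape=(6, 6, 6),
        n_components=6,
        n_snps=20,
        n_regions=5,
        epochs_bimodal=2,
        epochs_cgan=2,
        epochs_full=2,
        n_folds=2,
        seed=0,
        encoder_scale={"width": 4, "fc_width": 8},
        ig_steps=8,
    )
    params.update(overrides)
    return RunConfig(**params)


def tiny_simspec(**overrides) -> SimulationSpec:
    params = dict(
        n_per_class={"CN": 8, "AD": 8, "MCInc": 4, "MCIc": 4},
        volume_shape=(6, 6, 6),
        n_components=6,
        n_timepoints=40,
        n_snps=20,
        n_regions=5,
        k_latent=2,
        n_affected_regions=2,
        n_affected_edges=4,
        n_affected_snps=4,
        seed=0,
    )
    params.update(overrides)
    return SimulationSpec(**params)


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_inputs(tiny_simspec())


@dataclass
class RecoveryBundle:
    spec: SimulationSpec
    config: RunConfig
    ground_truth: GroundTruth
    complete: dict[str, ModalityInputs]
    result: ExperimentResult
    test_complete: list[ModalityInputs]
    train_accuracy: float
    attributions: list[AttributionSet]


@pytest.fixture(scope="session")
def recovery() -> RecoveryBundle:
    spec = desk_recovery_simspec(seed=RECOVERY_SEED)
    config = desk_scale_config(seed=RECOVERY_SEED)
    inputs, gt = simulate_inputs(spec)
    complete = {mi.subject_id: mi for mi in inputs}
    cohort = mask_inputs(inputs, DESK_RECOVERY_MISSINGNESS, seed=spec.seed + 1)
    result = run_experiment(
        cohort, config, seed=RECOVERY_SEED, cgan_generator_hidden=DESK_CGAN_HIDDEN
    )
    model = result.full.cv.model
    train_ids = set(result.split.train_ids)
    train = [mi for mi in cohort if mi.subject_id in train_ids]
    train_accuracy = evaluate(model, train).acc
    test_complete = [complete[i] for i in result.split.test_ids]
    igcfg = make_ig_config(
        config.n_snps, seed=RECOVERY_SEED + 199, n_steps=config.ig_steps
    )
    attributions = [
        integrated_gradients(
            model, mi, igcfg, true_label_index=CLASS_INDEX[mi.class_label]
        )
        for mi in test_complete
    ]
    return RecoveryBundle(
        spec=spec,
        config=config,
        ground_truth=gt,
        complete=complete,
        result=result,
        test_complete=test_complete,
        train_accuracy=train_accuracy,
        attributions=attributions,
    )
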