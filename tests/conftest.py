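"""Shared fixtures.

The expensive desk-scale training run (8 subjects x 4 h, reduced model)
is a session fixture so the end-to-end and probe acceptance tests share
one trained model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from stagernet import StagerConfig, TrainConfig, generate_cohort, train_logreg_baseline
from stagernet.training import make_cv_folds, train_single

# Fixed study conditions for the desk-scale run (seeds chosen up front,
# not tuned): cohort seed 11, fold rng 11, training seed 7.
DESK_COHORT_SEED = 11
DESK_TRAIN_SEED = 7


@dataclass
class DeskRun:
    cohort: list
    train_data: list
    val_data: list
    model: object
    curves: object
    val_kappa: float
    logreg_kappa: float


@pytest.fixture(scope="session")
def desk_run() -> DeskRun:
    """Desk-scale end-to-end training shared by the acceptance tests."""
    cohort = generate_cohort(8, 1, 4.0, rng_seed=DESK_COHORT_SEED)
    rng = np.random.default_rng(DESK_COHORT_SEED)
    folds = make_cv_folds([rec.subject_id for rec, _ in cohort], rng)
    train_ids, _ = folds.fold(0)
    train_data = [dv for dv in cohort if dv[0].subject_id in train_ids]
    val_data = [dv for dv in cohort if dv[0].subject_id not in train_ids]

    config = StagerConfig(units_per_layer=16)
    tconfig = TrainConfig(
        seq_len_windows=32,
        batch_size=16,
        batches_per_epoch=4,
        n_epochs=40,
        eval_every=10,
        seed=DESK_TRAIN_SEED,
    )
    model, curves = train_single(
        config, tconfig, train_data, val_data, seed=DESK_TRAIN_SEED
    )
    val_kappa = next(v for v in reversed(curves.val_kappa) if np.isfinite(v))

    _, logreg_report = train_logreg_baseline(train_data, val_data, seed=0)
    return DeskRun(
        cohort=cohort,
        train_data=train_data,
        val_data=val_data,
        model=model,
        curves=curves,
        val_kappa=float(val_kappa),
        logreg_kappa=float(logreg_report.kappa),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for structural/sampling tests (3 subjects x 1 h)."""
    return generate_cohort(3, 1, 1.0, rng_seed=5)
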