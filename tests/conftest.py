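"""Shared fixtures.

The expensive session fixture ``small_experiment_report`` runs the complete
small-profile study once (dataset synthesis, 30-epoch training, evaluation,
Grad-CAM chromaticity, morphology, onset detection); only the tests that
assert on end-to-end behaviour request it.
"""

from __future__ import annotations

import numpy as np
import pytest

from filasense.pipeline import ExperimentConfig, run_experiment
from filasense.synth_scene import DatasetConfig, SceneConfig

MASTER_SEED = 1


def small_scene(**kw) -> SceneConfig:
    """A reduced 480x300 scene for fast dataset tests (geometry scales,
    event statistics and colours unchanged)."""
    defaults = dict(width=480, height=300, stripe_row=150, stripe_length=360,
                    event_sigma_mean=8.0, event_sigma_sd=2.0,
                    event_sigma_min=4.0, event_sigma_max=14.0,
                    event_band_sd=10.0)
    defaults.update(kw)
    return SceneConfig(**defaults)


def tiny_dataset_config(n_train=6, n_val=2, n_test=2, n_rob=2) -> DatasetConfig:
    per = n_train + n_val
    return DatasetConfig(
        curated={c: per for c in ("blank", "chalk", "pollen", "salt")},
        train={c: n_train for c in ("blank", "chalk", "pollen", "salt")},
        val={c: n_val for c in ("blank", "chalk", "pollen", "salt")},
        test={c: n_test for c in ("blank", "chalk", "pollen", "salt")},
        robustness={c: n_rob for c in ("blank", "chalk", "pollen", "salt")},
        scene=small_scene(),
    )


@pytest.fixture(scope="session")
def small_experiment_report() -> dict:
    """The full small-profile study at the default conditions, seed fixed."""
    return run_experiment(ExperimentConfig(seed=MASTER_SEED))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
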