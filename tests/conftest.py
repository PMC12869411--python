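"""Shared fixtures.

Small-image fixtures keep unit tests fast; the two session-scoped study
fixtures run the reduced-scale acceptance experiments once and are shared by
every acceptance test that reads them.
"""

from __future__ import annotations

import numpy as np
import pytest

from vsmo import experiments
from vsmo.gabor import build_filter_bank
from vsmo.observer import ObserverConfig, fit_observer_base
from vsmo.phantoms import ApertureModel, PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def small_phantom() -> PhantomConfig:
    """64-px lumpy background; every other parameter at its default."""
    return PhantomConfig(image_size=64)


@pytest.fixture(scope="session")
def small_bank():
    """8-kernel bank whose supports fit a 64-px image (ws=8 -> 33 px)."""
    return build_filter_bank(
        ws_list=[8.0],
        fc_list=[1.0 / 16.0, 1.0 / 8.0],
        theta_list=[0.0, np.pi / 2],
        phi_list=[0.0, np.pi / 2],
    )


@pytest.fixture(scope="session")
def tiny_dataset(small_phantom):
    return generate_dataset(small_phantom, ApertureModel(1.0), n_pairs=10, seed=101)


@pytest.fixture(scope="session")
def tiny_test_dataset(small_phantom):
    return generate_dataset(small_phantom, ApertureModel(1.0), n_pairs=12, seed=202)


@pytest.fixture(scope="session")
def small_config() -> ObserverConfig:
    return ObserverConfig(n_search_features=2, n_decision_features=2)


@pytest.fixture(scope="session")
def fitted_base(tiny_dataset, small_bank, small_config):
    return fit_observer_base(tiny_dataset, small_bank, small_config)


# ---------------------------------------------------------------------------
# Reduced-scale acceptance studies (session-scoped; minutes each)
# ---------------------------------------------------------------------------

#: fixed acceptance-study seed, chosen once when the suite was written
ACCEPTANCE_SEED = 2025


@pytest.fixture(scope="session")
def training_study():
    """Reduced-scale training-size study: 5 trials, M in {30,100,300,500},
    200 test pairs, default simulator and observer."""
    config = experiments.TrainingSizeConfig(
        m_values=(30, 100, 300, 500),
        n_trials=5,
        n_test_pairs=200,
        seed=ACCEPTANCE_SEED,
    )
    table = experiments.run_training_size_study(config)
    summary = experiments.summarize_training_study(table)
    return config, table, summary


@pytest.fixture(scope="session")
def pinhole_sweep():
    """Reduced-scale aperture sweep over a coarse relative-diameter grid.

    Fits both linear-discriminant modes so the same run backs the trade-off
    check (prewhitening rows) and the PW-vs-NPW ordering check."""
    config = experiments.SweepConfig(
        d_rel_values=(0.4, 1.0, 2.0, 3.0),
        observer_variants=("pw", "npw"),
        n_train_pairs=100,
        n_test_pairs=100,
        seed=ACCEPTANCE_SEED,
    )
    table = experiments.run_pinhole_sweep(config)
    return config, table
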