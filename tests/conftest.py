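"""Shared fixtures: toy complexes and the packaged synthetic benchmark."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sfct import (
    SFCTHyperparams,
    build_training_set,
    filter_training_poses,
    generate_complex_set,
    generate_toy_complex,
    train_sfct,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Fast hyperparameters for unit tests that only need *a* fitted model.
SMALL_HP = SFCTHyperparams(
    n_boost_rounds=2, trees_per_forest=8, max_features=64, max_depth=12,
    use_oob=False, seed=3
)


@pytest.fixture(scope="session")
def toy_complex():
    """One deterministic 20-residue pocket with a 15-atom ligand."""
    return generate_toy_complex(seed=7, n_residues=20, n_ligand_atoms=15)


@pytest.fixture(scope="session")
def benchmark():
    """The packaged synthetic benchmark: 200 natives x 20 decoys, fixed seed.

    The first 160 complexes train the model (with the reference
    hyperparameters: 10 boosting rounds of 50-tree forests,
    max_features=512, max_depth=50); the last 40 are held out with their
    decoy poses and true RMSD labels for evaluation.
    """
    records = generate_complex_set(seed=11, n_complexes=200, n_decoys_per_native=20)
    train_records, holdout_records = records[:160], records[160:]
    train_set = filter_training_poses(build_training_set(train_records))
    model = train_sfct(train_set, SFCTHyperparams(seed=1))
    holdout_set = filter_training_poses(build_training_set(holdout_records))
    return SimpleNamespace(
        records=records,
        train_records=train_records,
        holdout_records=holdout_records,
        train_set=train_set,
        holdout_set=holdout_set,
        model=model,
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """A 25-complex corpus with a quickly trained model, for plumbing tests."""
    records = generate_complex_set(seed=23, n_complexes=25, n_decoys_per_native=10)
    train_set = filter_training_poses(build_training_set(records))
    model = train_sfct(train_set, SMALL_HP)
    return SimpleNamespace(records=records, train_set=train_set, model=model)
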