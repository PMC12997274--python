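"""Shared fixtures: fixture molecules, surrogate model, trained desk model.

The trained desk-scale models (with and without the crossing penalty)
are expensive, so they are built once per session and shared by the
calibration, crossing-suppression and benchmark-separation tests.
"""

from __future__ import annotations

import zlib

import numpy as np
import pytest

from dp5q.model import QuantileShiftRegressor
from dp5q.synthetic import (
    SurrogateShiftModel,
    embed_conformer,
    fixture_molecules,
    simulate_spectrum,
)

# desk-scale study conditions (see docs/methods.md): 240 training
# molecules x 3 replicate spectra, held-out pool of 40
N_TRAIN = 240
N_HELDOUT = 40
N_REPLICATES = 3
SURROGATE_SEED = 3
DESK_CONFIG = dict(
    hidden_width=64,
    n_steps=3,
    cutoff=2.0,
    learning_rate=3e-3,
    max_epochs=700,
    batch_size=64,
    decay_interval=300,
    lr_decay=0.3,
    patience=120,
    random_state=0,
)


def replicate_corpus(mols, surrogate, n_replicates=N_REPLICATES, seed=SURROGATE_SEED):
    """Each molecule appears with `n_replicates` independent spectra."""
    X, Y = [], []
    for rep in range(n_replicates):
        for m in mols:
            rng = np.random.default_rng(
            np.random.SeedSequence([seed, rep, zlib.crc32(m.smiles.encode()) % 2**31]))
            spec, _ = simulate_spectrum(m, surrogate, rng=rng)
            X.append(m)
            Y.append(spec)
    return X, Y


@pytest.fixture(scope="session")
def surrogate():
    return SurrogateShiftModel(seed=SURROGATE_SEED)


@pytest.fixture(scope="session")
def train_molecules():
    return [embed_conformer(m, seed=7) for m in fixture_molecules(N_TRAIN, seed=1)]


@pytest.fixture(scope="session")
def heldout_molecules():
    return [embed_conformer(m, seed=11) for m in fixture_molecules(N_HELDOUT, seed=99)]


@pytest.fixture(scope="session")
def desk_model(train_molecules, surrogate):
    """Quantile net trained under the desk-scale study conditions."""
    X, Y = replicate_corpus(train_molecules, surrogate)
    est = QuantileShiftRegressor(**DESK_CONFIG)
    est.fit(X, Y)
    return est


@pytest.fixture(scope="session")
def desk_model_no_penalty(train_molecules, surrogate):
    """Same run with the crossing penalty switched off (mono_weight=0)."""
    X, Y = replicate_corpus(train_molecules, surrogate)
    est = QuantileShiftRegressor(mono_weight=0.0, **DESK_CONFIG)
    est.fit(X, Y)
    return est
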