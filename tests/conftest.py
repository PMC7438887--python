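from __future__ import annotations

import numpy as np
import pytest

from spikefuse import aer_io, evaluation, synthetic_data
from spikefuse.snn_training import TrainConfig
from spikefuse.spike_encoding import DeltaModConfig

E2E_SEED = 1
E2E_DIFFICULTY = 0.8


@pytest.fixture(scope="session")
def small_manifest() -> aer_io.DatasetManifest:
    return aer_io.DatasetManifest(n_subjects=1, n_sessions=3, n_repetitions=2)


@pytest.fixture(scope="session")
def small_recordings(small_manifest):
    cfg = synthetic_data.SynthConfig(manifest=small_manifest, seed=7, difficulty=0.5)
    recordings, _ = synthetic_data.generate_dataset(cfg)
    return recordings


@pytest.fixture(scope="session")
def small_samples(small_recordings, small_manifest):
    return aer_io.chunk_dataset(small_recordings, small_manifest)


@pytest.fixture(scope="session")
def e2e_manifest() -> aer_io.DatasetManifest:
    return aer_io.DatasetManifest(n_subjects=2)


@pytest.fixture(scope="session")
def e2e_samples(e2e_manifest):
    """Reduced 2-subject campaign (1,500 chunks) at non-trivial difficulty."""
    cfg = synthetic_data.SynthConfig(manifest=e2e_manifest, seed=E2E_SEED,
                                     difficulty=E2E_DIFFICULTY)
    recordings, _ = synthetic_data.generate_dataset(cfg)
    return aer_io.chunk_dataset(recordings, e2e_manifest)


@pytest.fixture(scope="session")
def e2e_cv(e2e_samples):
    """3-fold session-split CV on the reduced synthetic campaign."""
    feats = evaluation.extract_count_features(
        e2e_samples, DeltaModConfig(interpolation_factor=200))
    return evaluation.crossvalidate(
        e2e_samples, k=3, seed=0, cfg=TrainConfig(epochs=8, seed=0),
        features=feats, keep_bundles=True), feats
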