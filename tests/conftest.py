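"""Shared fixtures: synthetic bundles and small hand-built matrices."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mirtarnet import ExpressionMatrix, SimulationConfig, simulate_bundle

#: seed used for every deterministic fixture in the suite
FIXED_SEED = 1


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(rng_seed=FIXED_SEED)


@pytest.fixture(scope="session")
def default_bundle(default_config):
    """Reference noisy scenario: 40 miRNAs (20 regulated), 400 genes, sigma=0.25."""
    return simulate_bundle(default_config)


@pytest.fixture(scope="session")
def noise_free_config(default_config) -> SimulationConfig:
    return dataclasses.replace(default_config, noise_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_bundle(noise_free_config):
    return simulate_bundle(noise_free_config)


def make_matrix(values, feature_ids, timepoints=("d1",), n_replicates=None):
    """Build a small ExpressionMatrix from a (features x samples) array.

    Columns are ordered control then UVB, each (timepoint-major, replicate-minor).
    """
    values = np.asarray(values, dtype=float)
    n_samples = values.shape[1]
    per_cond = n_samples // 2
    n_replicates = n_replicates or per_cond // len(timepoints)
    assert 2 * len(timepoints) * n_replicates == n_samples
    rows = []
    for cond in ("control", "UVB"):
        for tp in timepoints:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {"sample_id": f"{cond}_{tp}_r{rep}", "condition": cond,
                     "timepoint": tp, "replicate": rep}
                )
    meta = pd.DataFrame(rows).set_index("sample_id")
    frame = pd.DataFrame(values, index=list(feature_ids), columns=list(meta.index))
    return ExpressionMatrix(frame, meta)
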