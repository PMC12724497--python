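"""Shared fixtures: small synthetic cohorts and planted co-cluster matrices."""

import numpy as np
import pytest

from pathstrat.features import zscore_columns
from pathstrat.srvcc import TrainConfig
from pathstrat.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject canonical-schema cohort with clear block structure."""
    cfg = SyntheticConfig(
        n_per_group={"PD": 40, "HC": 12, "SWEDD": 8},
        seed=11, shift_scale=3.0, noise_sd=0.6)
    fm, clinical, truth = generate_cohort(cfg)
    return cfg, fm, clinical, truth


@pytest.fixture(scope="session")
def small_cohort_std(small_cohort):
    _, fm, clinical, truth = small_cohort
    return zscore_columns(fm), clinical, truth


@pytest.fixture(scope="session")
def checkerboard():
    """4 row clusters x 3 column clusters at 5-sigma separation."""
    rng = np.random.default_rng(0)
    n, d = 160, 60
    row_labels = rng.integers(0, 4, n)
    col_labels = rng.integers(0, 3, d)
    m = np.array([[1, 1, -1], [1, -1, 1], [-1, 1, 1], [-1, -1, -1]], float) * 2.5
    x = m[row_labels][:, col_labels] + rng.normal(0, 0.5, (n, d))
    return x, row_labels, col_labels


@pytest.fixture()
def fast_train():
    """Short but reliable training schedule for planted-recovery tests."""
    return TrainConfig(epochs=40, pretrain_epochs=15, beta_warmup_epochs=15,
                       latent_dim=5, hidden=(32, 16), batch_size=64,
                       learning_rate=3e-3, seed=3, val_frac=0.2)
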