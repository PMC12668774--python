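"""Shared fixtures.

The expensive pieces — simulating the 60-cell cohort and training the
enhancement model (once supervised-only, once with the adversarial term,
plus a short adversarial run for discriminator probes) — are session
scoped so every test that needs a trained model shares one run.
"""

import numpy as np
import pytest

from schicenh.matio import normalize
from schicenh.model import DiscriminatorConfig, GeneratorConfig
from schicenh.synthetic import default_spec, downsample, simulate_cohort
from schicenh.training import TrainConfig, enhance, make_pairs, train_gan

RATIO = 9.0
N_HOLDOUT = 10
FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_spec():
    return default_spec(n_bins=120, n_cells=60, depth=30_000, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def cohort(fixture_spec):
    return simulate_cohort(fixture_spec)


@pytest.fixture(scope="session")
def split(cohort):
    return cohort[:-N_HOLDOUT], cohort[-N_HOLDOUT:]


@pytest.fixture(scope="session")
def train_pairs(split):
    return make_pairs(split[0], RATIO, seed=11)


@pytest.fixture(scope="session")
def trained_l1(train_pairs):
    tcfg = TrainConfig(epochs=30, lambda_adv=0.0, lr_g=1e-3, lr_d=1e-3,
                       downsample_ratio=RATIO, seed=5)
    return train_gan(train_pairs, GeneratorConfig(), DiscriminatorConfig(), tcfg)


@pytest.fixture(scope="session")
def trained_gan(train_pairs):
    tcfg = TrainConfig(epochs=30, lambda_adv=1.0, lr_g=1e-3, lr_d=1e-3,
                       downsample_ratio=RATIO, seed=5)
    return train_gan(train_pairs, GeneratorConfig(), DiscriminatorConfig(), tcfg)


@pytest.fixture(scope="session")
def short_gan():
    """Small adversarial run where the discriminator still separates classes."""
    spec = default_spec(n_bins=120, n_cells=12, depth=30_000, seed=FIXTURE_SEED)
    cells = simulate_cohort(spec)
    pairs = make_pairs(cells, RATIO, seed=11)
    tcfg = TrainConfig(epochs=5, lambda_adv=1.0, lr_g=1e-3, lr_d=1e-3,
                       downsample_ratio=RATIO, seed=5)
    ckpt, hist = train_gan(pairs, GeneratorConfig(), DiscriminatorConfig(), tcfg)
    return pairs, ckpt, hist


@pytest.fixture(scope="session")
def holdout(split, trained_l1):
    """(truth, downsampled, enhanced) triples for the held-out cells."""
    ckpt, _ = trained_l1
    triples = []
    for i, cell in enumerate(split[1]):
        ds = downsample(cell, RATIO, seed=900 + i)
        triples.append((cell, ds, enhance(ckpt, ds)))
    return triples


@pytest.fixture(scope="session")
def holdout_normalized(holdout, trained_l1):
    ckpt, _ = trained_l1
    out = []
    for truth, ds, enh in holdout:
        out.append(tuple(normalize(m, ckpt.cap).counts for m in (truth, ds, enh)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
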