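"""Shared fixtures: cohorts, a trained GAN bundle and a trained forest.

Seed 1 is the suite-wide convention for data generation; model training
seeds default to 0.  Session scope keeps the expensive artifacts (GAN
training, forest fits) to one instance each.
"""

import logging

import numpy as np
import pytest

import telepain as tp
from telepain import bench as bench_mod
from telepain import gan as gan_mod
from telepain.preprocess import encode, split

logging.disable(logging.WARNING)

COHORT_SEED = 1
TRAIN_SEED = 0


@pytest.fixture(scope="session")
def spec218():
    return tp.default_spec(n=218, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def real218(spec218):
    return tp.sample_cohort(spec218, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def gan_bundle(real218):
    idx = split(len(real218), 0.7, TRAIN_SEED)
    train_df = real218.iloc[idx.train].reset_index(drop=True)
    test_df = real218.iloc[idx.test].reset_index(drop=True)
    M, emap = encode(train_df)
    M_hold, _ = encode(test_df, emap)
    return gan_mod.train(
        M,
        train_df["outcome"].to_numpy(),
        gan_mod.GanConfig(seed=TRAIN_SEED),
        emap,
        holdout=M_hold,
        holdout_labels=test_df["outcome"].to_numpy(),
    )


@pytest.fixture(scope="session")
def fake218(gan_bundle, real218):
    return gan_mod.generate(gan_bundle, len(real218), seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def pooled436():
    spec = tp.default_spec(n=436, seed=COHORT_SEED)
    return spec, tp.sample_cohort(spec, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def rf436(pooled436):
    """Random forest fit on the full pooled cohort (the risk-engine model)."""
    _, pooled = pooled436
    X, y = bench_mod.features(pooled)
    return bench_mod.tune(
        bench_mod.default_specs()[1], X, y, k=5, repeats=3, seed=COHORT_SEED
    )
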