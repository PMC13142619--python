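import numpy as np
import pandas as pd
import pytest

from psomics.data import covariate_design
from psomics.preprocess import split_samples, standardize
from psomics.synthdata import SimConfig, generate_dataset, make_dataset


@pytest.fixture(scope="session")
def planted():
    """Small planted-effect dataset shared across tests (n=120, strong signal)."""
    cfg = SimConfig(n_samples=120, p_dnam=200, p_metab=80, n_causal_dnam=6,
                    n_causal_metab=4, effect_sd=0.8, seed=11)
    dnam, metab, cov, outcome, truth = generate_dataset(cfg)
    return {"cfg": cfg, "dnam": dnam, "metab": metab, "cov": cov,
            "outcome": outcome, "truth": truth}


@pytest.fixture(scope="session")
def planted_train(planted):
    """Standardized training half of the planted dataset plus design matrix."""
    split = split_samples(planted["dnam"].sample_ids, seed=5)
    train_std, _ = standardize(planted["dnam"].subset_samples(split.train_ids))
    design = covariate_design(planted["cov"]).loc[split.train_ids]
    y = planted["outcome"].subset(split.train_ids)
    return {"split": split, "X": train_std, "design": design, "y": y,
            "truth": planted["truth"]}


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny complete dataset for harness-level tests."""
    cfg = SimConfig(n_samples=80, p_dnam=60, p_metab=40, n_causal_dnam=4,
                    n_causal_metab=3, effect_sd=1.0, block_size=5, seed=23)
    ds, truth = make_dataset(cfg)
    return ds, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ordinal_sample(rng):
    """Moderate proportional-odds sample with known slopes."""
    n, p = 400, 3
    X = rng.normal(size=(n, p))
    beta = np.array([0.9, -0.6, 0.0])
    lat = X @ beta + rng.logistic(size=n)
    th = np.quantile(lat, [0.25, 0.55, 0.8])
    y = (lat[:, None] > th[None, :]).sum(1)
    return X, y, beta
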