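import numpy as np
import pandas as pd
import pytest

from colonyflux import ColonyConfig, FeatureSeries, HmmModel


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_config():
    """Small colony for fast end-to-end checks."""
    return ColonyConfig(n_birds={"pre_laying": 2, "incubation": 2, "chick_rearing": 2})


@pytest.fixture
def toy_model():
    """Well-separated hand-set model in canonical (flight, colony, water) order."""
    return HmmModel(
        init=np.array([0.2, 0.5, 0.3]),
        trans=np.array([[0.8, 0.1, 0.1], [0.05, 0.9, 0.05], [0.1, 0.1, 0.8]]),
        zero_mass=np.array([0.02, 0.95, 0.9]),
        shape=np.array([120.0, 2.0, 2.0]),
        rate=np.array([120.0 / 3.5, 1.0, 1.0]),
        p_near=np.array([0.1, 0.98, 0.05]),
    )


def make_features(wingbeat, near, window=15.0) -> FeatureSeries:
    """Assemble a FeatureSeries from raw observation arrays (NaN = missing)."""
    w = np.asarray(wingbeat, float)
    nr = np.asarray(near, float)
    dist = np.where(np.isnan(nr), np.nan, np.where(nr == 1.0, 100.0, 10_000.0))
    return FeatureSeries(
        t0=pd.Timestamp("2019-06-01"),
        midpoints=(np.arange(len(w)) + 0.5) * window,
        wingbeat=w,
        dominance=np.where(w > 0, 0.9, 0.05),
        dist_m=dist,
        window=window,
    )


def sample_from_model(model: HmmModel, T: int, rng: np.random.Generator) -> FeatureSeries:
    """Draw one observation sequence from an HmmModel (generative twin)."""
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(3, p=model.init)
    for t in range(1, T):
        states[t] = rng.choice(3, p=model.trans[states[t - 1]])
    zero = rng.random(T) < model.zero_mass[states]
    w = np.where(zero, 0.0, rng.gamma(model.shape[states], 1.0 / model.rate[states]))
    nr = (rng.random(T) < model.p_near[states]).astype(float)
    fs = make_features(w, nr)
    return fs, states
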