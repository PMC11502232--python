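"""Shared fixtures: small synthetic recordings generated at test time."""

import numpy as np
import pytest

import ensemble_dynamics as ed
from ensemble_dynamics.datatypes import EpochSet


@pytest.fixture(scope="session")
def small_recording():
    """A compact multi-session recording with planted 7-population structure."""
    etho = ed.generate_ethogram(4, 600, seed=101)
    ds, truth = ed.generate_population_spikes(etho, n_cells_per_pop=12, seed=101)
    return {"etho": etho, "dataset": ds, "truth": truth}


@pytest.fixture(scope="session")
def small_features(small_recording):
    fm = ed.build_feature_matrix(
        small_recording["dataset"], small_recording["etho"]
    )
    truth = small_recording["truth"]
    names = sorted({v for v in truth.populations.values()})
    code = {n: i for i, n in enumerate(names)}
    truth_labels = np.array([code[truth.populations[k]] for k in fm.cells])
    return {"fm": fm, "truth_labels": truth_labels, "code": code}


@pytest.fixture(scope="session")
def alternating_epochs():
    """Artificial disjoint gamma/nonrhythmic epoch sets over 600 s."""
    T = 600.0
    g = np.array([[t, t + 0.15] for t in np.arange(1.0, T - 1, 2.0)])
    nr = np.array([[t, t + 0.4] for t in np.arange(0.3, T - 1, 2.0)])
    return {
        "gamma": EpochSet("slow_gamma", g),
        "nonrhythmic": EpochSet("nonrhythmic", nr),
        "span": (0.0, T),
    }


def poisson_train(rng, rate_hz, t_stop, t_start=0.0):
    n = rng.poisson(rate_hz * (t_stop - t_start))
    return np.sort(rng.uniform(t_start, t_stop, n))
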