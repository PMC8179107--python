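import numpy as np
import pytest

import loopmsm as lm
from loopmsm import msm as msm_mod
from loopmsm import tica as tica_mod


@pytest.fixture(scope="session")
def toy():
    """Small planted two-loop ensemble shared across the suite.

    6 trajectories x 2500 frames keeps every stage well inside a minute
    while sampling ~60 slow-block transitions.
    """
    return lm.gen_toy_loop_trajectory(n_traj=6, n_frames=2500, seed=7)


@pytest.fixture(scope="session")
def toy_features(toy):
    defs = lm.enumerate_ca_pairs(toy.ensemble.topology)
    fm = lm.compute_features(toy.ensemble, defs)
    kept, _ = lm.prune_features(fm)
    return kept


@pytest.fixture(scope="session")
def toy_projection(toy_features):
    model = lm.fit_tica(toy_features, lag=5, n_components=4)
    proj = tica_mod.project(model, toy_features)
    segs = np.cumsum(toy_features.segment_lengths)[:-1]
    return model, np.split(proj, segs)


@pytest.fixture(scope="session")
def toy_dtrajs(toy_projection):
    _, parts = toy_projection
    return msm_mod.cluster_microstates(parts, k=40, seed=3)
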