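import numpy as np
import pytest

import ligandmsm as lm

TWO_STATE_T = np.array([[0.9, 0.1], [0.2, 0.8]])


@pytest.fixture(scope="session")
def block_chain():
    """12-microstate, 3-block reversible chain with exact ground truth."""
    spec = lm.MetastableChainSpec(12, 3, intra_rate=0.3, inter_rate=0.01, seed=1)
    T, blocks = lm.build_metastable_chain(spec)
    gt = lm.analytic_ground_truth(T, blocks)
    return spec, T, blocks, gt


@pytest.fixture(scope="session")
def block_chain_sample(block_chain):
    """5 trajectories × 40 000 steps sampled from the block chain."""
    _, T, _, _ = block_chain
    return lm.sample_discrete_trajectories(T, n_trajs=5, n_steps=40_000, seed=2)


@pytest.fixture(scope="session")
def toy_complex():
    """Small toy bead complex with 3 designed binding modes."""
    spec = lm.default_toy_spec(n_modes=3, seed=0)
    traj, gt = lm.generate_toy_complex_trajectories(spec, n_steps=4000, seed=1, n_trajs=3)
    return spec, traj, gt


@pytest.fixture(scope="session")
def two_state_features():
    """Hidden two-state chain (p=q=0.05) with 1 informative + 9 noise dims."""
    p = 0.05
    T = np.array([[1 - p, p], [p, 1 - p]])
    labels = lm.sample_discrete_trajectories(T, n_trajs=4, n_steps=50_000, seed=7)
    means = np.zeros((2, 10))
    means[0, 0], means[1, 0] = -1.0, 1.0
    sd = 0.1
    fs = lm.emit_feature_trajectories(labels, means, sd, seed=8)
    return T, labels, fs, sd
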