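import numpy as np
import pandas as pd
import pytest

from rpnma.ipd import Design, IPDDataset, NetworkSpec
from rpnma.sampler import MCMCSettings
from rpnma.simulate import SimSpec, TrialPlan, WeibullBaseline, simulate_network


@pytest.fixture
def two_arm_network():
    return NetworkSpec(
        treatments=("A", "B"), reference="A",
        designs=(Design(("A", "B"), "A"),),
    )


@pytest.fixture
def loop_network():
    """Three treatments, three two-arm designs, one closed loop."""
    return NetworkSpec(
        treatments=("A", "B", "C"), reference="A",
        designs=(
            Design(("A", "B"), "A"),
            Design(("A", "C"), "A"),
            Design(("B", "C"), "B"),
        ),
        loops=(("A", "B", "C"),),
    )


@pytest.fixture
def cervical_network():
    from rpnma.simulate import cervical_like_network

    return cervical_like_network()


def make_weibull_trials(network, design_trials, n_per_arm, lam=0.15, shape=1.1):
    plans = []
    k = 0
    for design, n_tr in design_trials:
        for _ in range(n_tr):
            plans.append(TrialPlan(
                trial_id=f"T{k + 1:02d}", design=design, n_per_arm=n_per_arm,
                baseline=WeibullBaseline(lam * (1 + 0.1 * (k % 3)),
                                         shape * (1 + 0.05 * (k % 2)))))
            k += 1
    return tuple(plans)


@pytest.fixture
def small_pairwise_data(two_arm_network):
    """3 trials of A vs B, true logHR -0.3, ~80 patients per arm."""
    spec = SimSpec(
        network=two_arm_network,
        trials=make_weibull_trials(two_arm_network,
                                   [(two_arm_network.designs[0], 3)], 80),
        true_beta=np.array([-0.3]),
        admin_horizon=10.0, dropout_rate=0.02, seed=42,
    )
    data, truth = simulate_network(spec)
    return data, truth


@pytest.fixture
def loop_data(loop_network):
    """Consistent loop network, one trial per design."""
    spec = SimSpec(
        network=loop_network,
        trials=make_weibull_trials(
            loop_network, [(d, 1) for d in loop_network.designs], 120),
        true_beta=np.array([-0.3, 0.2]),
        admin_horizon=10.0, dropout_rate=0.02, seed=7,
    )
    data, truth = simulate_network(spec)
    return data, truth


@pytest.fixture
def fast_settings():
    return MCMCSettings(chains=2, burnin=400, iterations=400, seed=11)


@pytest.fixture
def tiny_ipd_df():
    return pd.DataFrame({
        "trial": ["t1", "t1", "t1", "t1"],
        "treatment": ["A", "A", "B", "B"],
        "time": [1.0, 2.0, 1.5, 3.0],
        "event": [1, 0, 1, 1],
    })


@pytest.fixture
def tiny_dataset(tiny_ipd_df):
    return IPDDataset(tiny_ipd_df)
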