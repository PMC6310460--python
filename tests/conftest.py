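import numpy as np
import pytest

from ntpchain.chain_model import InternalChainSpec, embed_chain
from ntpchain.synthetic_data import (
    IonPlan,
    SegmentPlan,
    SyntheticTrajectoryConfig,
    generate_trajectory,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_chain():
    """A chain embedded from the default internal spec."""
    return embed_chain(InternalChainSpec())


@pytest.fixture(scope="session")
def extended_chain():
    """Extended chain matching the reference transition-state geometry."""
    return embed_chain(
        InternalChainSpec(theta_bridge=136.3, target_d_pa_pg=5.40))


@pytest.fixture(scope="session")
def k_trajectory():
    """Three-segment synthetic trajectory with K ions (session-cached)."""
    config = SyntheticTrajectoryConfig(
        segments=[
            SegmentPlan.from_reference("K", "BETA_GAMMA", 800),
            SegmentPlan.from_reference("K", "ALPHA_BETA_GAMMA", 600),
            SegmentPlan.from_reference("NH4", "BETA_GAMMA_CURLED", 600),
        ],
        ions=[
            IonPlan(species="K", site="BG", bound_fraction=0.95),
            IonPlan(species="K", site="AG", bound_fraction=0.5),
        ],
        seed=42,
    )
    traj, truth = generate_trajectory(config)
    return traj, truth, config


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
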