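import numpy as np
import pytest

from foldflux import (
    FunnelModelParams,
    GridSpec,
    Trajectory,
    TrajectoryEnsemble,
    simulate_funnel_ensemble,
)


@pytest.fixture(scope="session")
def funnel_ensemble():
    """A modest funnel first-passage ensemble shared across tests."""
    return simulate_funnel_ensemble(FunnelModelParams(seed=0), 60)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_first_passage_ensemble(rng, ndim=3, n_traj=5, x_span=(0.3, 8.7)):
    """Small random ensemble drifting monotonically in g1 (complete runs)."""
    trajs = []
    for _ in range(n_traj):
        n = int(rng.integers(20, 40))
        x = np.linspace(x_span[0], x_span[1], n) + rng.normal(0, 0.3, n)
        x[0], x[-1] = x_span
        rest = rng.normal(4.0, 1.0, (n, ndim - 1))
        trajs.append(Trajectory(np.column_stack([x, rest]), 1.0))
    kind = "cv3" if ndim == 3 else "cv2"
    return TrajectoryEnsemble(trajs, 0.01, kind)


@pytest.fixture()
def random_ensemble_3d(rng):
    return random_first_passage_ensemble(rng, ndim=3)


@pytest.fixture()
def random_ensemble_2d(rng):
    return random_first_passage_ensemble(rng, ndim=2)
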