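import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import navdecode as nd
from navdecode.bold import VoxelTuningSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def arena():
    return nd.ArenaSpec(25.0)


@pytest.fixture(scope="session")
def short_trajectory(arena):
    """300 s of simulated walking at 10 Hz: enough events for decoding."""
    return nd.simulate_trajectory(arena, 300.0, 0.1, 40.0, 2.0, seed=11)


def simulate_session(
    subject: int,
    session: int = 0,
    gain: float = 1.5,
    tuning_sd: float = 30.0,
    noise_sd: float = 4.0,
    n_voxels: int = 40,
    duration: float = 300.0,
    turn_volatility: float = 40.0,
):
    """One subject-session: trajectory -> tuned BOLD -> cleaned examples.

    The voxel population is keyed by subject only, so sessions of the same
    subject share tuning structure; trajectory and noise are per-session.
    Returns the ExampleSet (or None if the class-distribution gate fails).
    """
    arena = nd.ArenaSpec(25.0)
    traj = nd.simulate_trajectory(
        arena, duration, 0.1, turn_volatility, 2.0, seed=1000 * subject + session
    )
    spec = VoxelTuningSpec(
        n_voxels, tuning_sd=tuning_sd, gain=gain, noise_sd=noise_sd
    ).sample_population(seed=subject)
    run = nd.generate_tuned_bold(traj, spec, seed=900_000 + 1000 * subject + session)
    es = nd.events_to_examples(
        nd.extract_events(traj), nd.clean_signal(run),
        session_id=f"sub{subject:02d}_ses{session}",
    )
    ok, _ = nd.check_class_distribution(es)
    return es if ok else None


@pytest.fixture(scope="session")
def toy_separable_examples():
    """Six well-separated clusters in six dimensions: trivially decodable."""
    rng = np.random.default_rng(0)
    centers = np.arange(30.0, 360.0, 60.0)
    X, y, onsets = [], [], []
    for i, c in enumerate(centers):
        pts = np.zeros((8, 6))
        pts[:, i] = 10.0
        pts += 0.01 * rng.standard_normal(pts.shape)
        X.append(pts)
        y.extend([c] * 8)
    X = np.vstack(X)
    y = np.array(y)
    order = rng.permutation(len(y))  # interleave classes across time
    return nd.ExampleSet(X[order], y[order], np.arange(len(y), dtype=float), centers)
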