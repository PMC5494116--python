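import numpy as np
import pytest

from excnvss import CoverageTrack, SimConfig, TargetSet, simulate_dataset


@pytest.fixture
def toy_targets() -> TargetSet:
    """Five targets on two chromosomes, lengths 100/60/29/90/200."""
    return TargetSet(
        chroms=np.array(["chr1", "chr1", "chr1", "chr2", "chr2"], dtype=object),
        starts=np.array([100, 500, 900, 0, 1000]),
        ends=np.array([200, 560, 929, 90, 1200]),
    )


@pytest.fixture
def flat_tracks(toy_targets):
    """Constant-depth test/control pair over the toy targets."""
    n = toy_targets.total_length
    test = CoverageTrack(np.full(n, 40.0), toy_targets, "test")
    control = CoverageTrack(np.full(n, 40.0), toy_targets, "control")
    return test, control


@pytest.fixture(scope="session")
def small_dataset():
    """One seeded simulated replicate small enough for fast unit tests."""
    config = SimConfig(n_targets=1200, n_events=8, seed=42)
    return simulate_dataset(config)
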