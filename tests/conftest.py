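import numpy as np
import pytest

from crowdtraj import build_helix, TwoStateSpec, gen_two_state

try:
    from hypothesis import settings, HealthCheck
    settings.register_profile(
        "ci", derandomize=True, deadline=None,
        suppress_health_check=[HealthCheck.too_slow])
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def two_conformers():
    """Helix vs extended-strand Calpha conformers, well separated in RMSD."""
    a = build_helix(15)
    b = np.column_stack([np.zeros(15), np.zeros(15),
                         0.38 * np.arange(15.0)])
    b = b - b.mean(axis=0)
    return a, b


@pytest.fixture(scope="session")
def two_state_traj(two_conformers):
    a, b = two_conformers
    spec = TwoStateSpec(conformer_a=a, conformer_b=b, mean_dwell=50,
                        noise_sigma=0.02, n_frames=2000, seed=7)
    return gen_two_state(spec)
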