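import numpy as np
import pytest
from hypothesis import settings

import eegsel as es

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_leadfield() -> es.LeadField:
    """16-channel / 60-source spherical fixture shared across tests."""
    return es.build_spherical_leadfield(16, 60, seed=0)


@pytest.fixture(scope="session")
def medium_leadfield() -> es.LeadField:
    """64-channel / 300-source fixture large enough for dataset simulation."""
    return es.build_spherical_leadfield(64, 300, seed=0)


def random_leadfield(d: int, n: int, seed: int) -> es.LeadField:
    """Random dense lead field with valid geometry, for algebraic oracles.

    The matrix entries are arbitrary Gaussians — the geometric invariants
    (electrodes outside the source sphere, unit orientations) still hold, so
    solver closed forms can be exercised on unstructured systems.
    """
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((d, n))
    src = es.headmodel.fibonacci_sphere(n, 70.0, rng)
    elec = es.headmodel.fibonacci_sphere(d, 92.0, rng)
    ori = src / np.linalg.norm(src, axis=1, keepdims=True)
    labels = [f"C{i}" for i in range(d)]
    return es.LeadField(m, labels, elec, src, ori)


def noiseless_single_source_trial(leadfield: es.LeadField, vertex: int, seed: int = 0) -> es.Trial:
    """One-source trial without noise, ground truth at ``vertex``."""
    spec = es.SourceSpec(
        region="occipital",
        vertex_index=vertex,
        position=leadfield.source_positions[vertex],
        center=0.5,
        width=0.12,
        frequency=19.0,
    )
    fs, duration = 200.0, 1.0
    t = np.arange(int(round(duration * fs))) / fs
    x = es.source_timecourse(spec, t)[None, :]
    y = es.project_and_add_noise(x, [vertex], leadfield, None, seed)
    return es.Trial(y, x, (spec,), fs, duration, None, seed)
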